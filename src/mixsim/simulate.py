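"""Genotype and mixture simulation under Hardy–Weinberg equilibrium.

Contributors are drawn i.i.d. from a group's allele-frequency table (two
independent allele draws per locus, theta = 0, no relatedness).  A mixture
is the per-locus set union of its contributors' alleles: presence/absence
only — no peak heights, and no simulated dropout or drop-in, so a POI+
mixture always contains every POI allele.

Two scenario kinds are produced:

* POI+ — the person of interest is contributor #1; power is estimated from
  these.
* POI− — the POI is an extra, independent draw from the same group and does
  not contribute; false positive rates are estimated from these.

Under both downstream hypotheses the non-POI contributors are treated as
known, leaving exactly one unknown (the POI under H_p, an unrelated
individual under H_d).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .freqtables import FrequencyTable


@dataclass(frozen=True)
class Genotype:
    """Unordered allele pair per locus; equal labels mean a homozygote."""

    alleles_by_locus: Mapping[str, tuple[str, str]]

    def is_heterozygous(self, locus: str) -> bool:
        a, b = self.alleles_by_locus[locus]
        return a != b


@dataclass(frozen=True)
class MixtureProfile:
    """Per-locus sets of observed alleles (the evidence G)."""

    observed_alleles_by_locus: Mapping[str, frozenset[str]]
    contributor_count: int

    def __post_init__(self) -> None:
        for locus, alleles in self.observed_alleles_by_locus.items():
            if not 1 <= len(alleles) <= 2 * self.contributor_count:
                raise ValueError(
                    f"{locus}: {len(alleles)} observed alleles impossible for "
                    f"{self.contributor_count} contributors"
                )


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation design cell.

    ``sim_table`` drives the genotype draws; ``ref_table`` is the reference
    used downstream for LRs (equal to ``sim_table`` in the
    correct-reference study).
    """

    contributors: int
    poi_present: bool
    sim_table: FrequencyTable
    ref_table: FrequencyTable
    n_reps: int
    seed: int

    def __post_init__(self) -> None:
        if self.contributors < 1:
            raise ValueError("contributors must be >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def correct_reference(self) -> bool:
        return self.sim_table is self.ref_table or (
            self.sim_table.group_id == self.ref_table.group_id
        )


def _locus_distributions(
    table: FrequencyTable,
) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per-locus (labels, probabilities); sums renormalised internally so a
    QC-tolerated deviation from 1 does not bias sampling."""
    out = {}
    for locus, freqs in table.loci.items():
        labels = list(freqs)
        p = np.array([freqs[a] for a in labels], dtype=float)
        out[locus] = (labels, p / p.sum())
    return out


def sample_genotype(
    table: FrequencyTable,
    rng: np.random.Generator,
    _dists: dict[str, tuple[list[str], np.ndarray]] | None = None,
) -> Genotype:
    """Draw one individual: two independent alleles per locus under HWE."""
    dists = _dists if _dists is not None else _locus_distributions(table)
    alleles = {}
    for locus, (labels, p) in dists.items():
        i, j = rng.choice(len(labels), size=2, p=p)
        alleles[locus] = (labels[i], labels[j])
    return Genotype(alleles)


def build_mixture(genotypes: Sequence[Genotype]) -> MixtureProfile:
    """Per-locus union of contributor alleles; order-independent."""
    if not genotypes:
        raise ValueError("need at least one contributor")
    locus_set = set(genotypes[0].alleles_by_locus)
    for g in genotypes[1:]:
        if set(g.alleles_by_locus) != locus_set:
            raise ValueError("contributors have mismatched locus sets")
    observed = {
        locus: frozenset(
            a for g in genotypes for a in g.alleles_by_locus[locus]
        )
        for locus in genotypes[0].alleles_by_locus
    }
    return MixtureProfile(observed, len(genotypes))


def simulate_scenario(
    spec: ScenarioSpec,
) -> Iterator[tuple[MixtureProfile, Genotype, list[Genotype]]]:
    """Yield ``(mixture, poi, known_others)`` triples for one design cell.

    Each replicate runs on its own deterministic substream spawned from the
    scenario seed, so results do not depend on evaluation order.  POI+:
    the POI is contributor #1.  POI−: the mixture is built from
    ``contributors`` independent draws and the POI is one further
    independent draw from the same simulation table.  ``known_others`` are
    always the non-POI contributors (contributors #2..k in POI+, and all
    but the first — who plays the true unknown — in POI−).
    """
    dists = _locus_distributions(spec.sim_table)
    root = np.random.SeedSequence(spec.seed)
    for child in root.spawn(spec.n_reps):
        rng = np.random.default_rng(child)
        contributors = [
            sample_genotype(spec.sim_table, rng, dists)
            for _ in range(spec.contributors)
        ]
        mixture = build_mixture(contributors)
        if spec.poi_present:
            poi = contributors[0]
        else:
            poi = sample_genotype(spec.sim_table, rng, dists)
        known_others = contributors[1:]
        yield mixture, poi, known_others


def simulated_mean_heterozygosity(
    table: FrequencyTable, n_individuals: int, rng: np.random.Generator
) -> float:
    """Mean observed heterozygosity of simulated individuals.

    Draws ``n_individuals`` HWE genotypes per locus (vectorised) and returns
    the overall fraction of heterozygous locus-genotypes — the sampler's
    own validation statistic, expected to match the table's average
    expected heterozygosity.
    """
    het_total = 0
    n_loci = len(table.loci)
    for labels, p in _locus_distributions(table).values():
        draws = rng.choice(len(labels), size=(n_individuals, 2), p=p)
        het_total += int((draws[:, 0] != draws[:, 1]).sum())
    return het_total / (n_individuals * n_loci)


def dump_replicates(
    spec: ScenarioSpec, path: str | Path, max_reps: int | None = None
) -> None:
    """Audit dump: one TSV row per replicate and locus."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("replicate\tlocus\tobserved\tpoi_genotype\n")
        for i, (mixture, poi, _) in enumerate(simulate_scenario(spec)):
            if max_reps is not None and i >= max_reps:
                break
            for locus, alleles in mixture.observed_alleles_by_locus.items():
                a, b = poi.alleles_by_locus[locus]
                fh.write(
                    f"{i}\t{locus}\t{','.join(sorted(alleles))}\t{a}/{b}\n"
                )
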