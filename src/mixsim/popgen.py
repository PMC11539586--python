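"""Population-genetic summaries: expected heterozygosity, Weir–Cockerham
F_ST, F_ST-threshold panel pruning, and the Pearson correlation test.

Genetic diversity of a group is the average expected heterozygosity
``mean_l (1 - sum_i p_i^2)`` over loci — the group-level predictor used
throughout the accuracy study.

Pairwise F_ST uses the Weir & Cockerham (1984) theta-hat estimator, which
accounts for unequal sample sizes and combines variance components as a
ratio of sums over all alleles and shared loci.  Because the inputs are
published *frequencies* rather than genotypes, observed heterozygote
frequencies are taken at their Hardy–Weinberg values ``2 p (1 - p)`` per
group; that substitution is the one modelling choice in the estimator here.

Panel pruning removes, iteratively, one member of the closest pair of groups
until every remaining pair exceeds an F_ST threshold — the procedure used to
cut a large panel down to a computationally tractable, genetically diverse
subset before the mis-specified-reference study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .freqtables import FrequencyTable


def locus_heterozygosity(frequencies: Mapping[str, float]) -> float:
    """Expected heterozygosity ``1 - sum_i p_i^2`` of one locus."""
    if not frequencies:
        raise ValueError("locus has no alleles")
    for allele, p in frequencies.items():
        if not (0.0 < p <= 1.0):
            raise ValueError(f"frequency of allele {allele!r} must be in (0, 1]")
    return 1.0 - float(sum(p * p for p in frequencies.values()))


def genetic_diversity(table: FrequencyTable) -> float:
    """Average expected heterozygosity over a table's loci (unweighted)."""
    if not table.loci:
        raise ValueError(f"{table.group_id}: table has no loci")
    return float(np.mean([locus_heterozygosity(f) for f in table.loci.values()]))


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta-hat for a pair of groups
# ---------------------------------------------------------------------------


def _wc_components(
    p1: float, p2: float, n1: float, n2: float
) -> tuple[float, float, float]:
    """Variance components (a, b, c) for one allele, two populations.

    ``n1, n2`` are diploid sample sizes (individuals); heterozygote
    frequencies are the HWE values ``2 p (1 - p)``.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    h1 = 2.0 * p1 * (1.0 - p1)
    h2 = 2.0 * p2 * (1.0 - p2)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (inner - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(a: FrequencyTable, b: FrequencyTable) -> float:
    """Multi-allele, multi-locus Weir–Cockerham theta-hat between two groups.

    Components are summed over every allele of every shared locus and
    combined as a ratio of sums.  Slightly negative estimates are a known
    property of the estimator and are returned as-is.
    """
    shared = [locus for locus in a.loci if locus in b.loci]
    if not shared:
        raise ValueError(
            f"no shared loci between {a.group_id!r} and {b.group_id!r}"
        )
    num = 0.0
    den = 0.0
    for locus in shared:
        fa, fb = a.loci[locus], b.loci[locus]
        for allele in sorted(set(fa) | set(fb)):
            ca, cb, cc = _wc_components(
                fa.get(allele, 0.0),
                fb.get(allele, 0.0),
                float(a.sample_size),
                float(b.sample_size),
            )
            num += ca
            den += ca + cb + cc
    if den == 0.0:
        return 0.0  # both groups monomorphic for the same allele everywhere
    return num / den


@dataclass(frozen=True)
class FstMatrix:
    """Symmetric matrix of pairwise theta-hat values, zero diagonal."""

    group_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.group_ids),) * 2:
            raise ValueError("matrix shape does not match group_ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("F_ST matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        i, j = self.group_ids.index(a), self.group_ids.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("group_id\t" + "\t".join(self.group_ids) + "\n")
            for gid, row in zip(self.group_ids, self.values):
                fh.write(gid + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FstMatrix":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        ids = tuple(lines[0].rstrip("\n").split("\t")[1:])
        rows = [
            [float(x) for x in line.split("\t")[1:]] for line in lines[1 : 1 + len(ids)]
        ]
        return cls(ids, np.array(rows))


def fst_matrix(tables: Sequence[FrequencyTable]) -> FstMatrix:
    """All pairwise theta-hat values for a panel."""
    ids = tuple(t.group_id for t in tables)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate group_ids in panel")
    n = len(tables)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pairwise_fst(tables[i], tables[j])
    return FstMatrix(ids, values)


@dataclass(frozen=True)
class Removal:
    group_id: str
    partner_id: str
    fst: float
    iteration: int


@dataclass(frozen=True)
class PrunedPanel:
    kept: tuple[str, ...]
    removed: tuple[Removal, ...]
    threshold: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "kept": list(self.kept),
                    "removed": [
                        {
                            "group_id": r.group_id,
                            "partner_id": r.partner_id,
                            "fst": r.fst,
                            "iteration": r.iteration,
                        }
                        for r in self.removed
                    ],
                    "threshold": self.threshold,
                    "seed": self.seed,
                },
                indent=2,
            ),
            encoding="utf-8",
        )


def prune_by_fst(
    tables: Sequence[FrequencyTable],
    threshold: float = 0.005,
    exempt: Iterable[str] = (),
    seed: int = 0,
    matrix: FstMatrix | None = None,
) -> PrunedPanel:
    """Iteratively drop one member of the lowest-F_ST pair until every pair
    among kept groups exceeds ``threshold`` (strict stop rule).

    Exempt groups are never removed: when the minimum pair has one exempt
    member the other is removed; pairs with both members exempt are skipped
    when searching for the minimum.  Ties on the minimum are broken
    lexicographically on the sorted id pair; among a non-exempt pair the
    removed member is chosen uniformly at random (seeded), so the result is
    bit-reproducible for a given seed.

    Pairwise theta-hat values are independent of panel composition, so the
    matrix is computed once and only shrunk — identical outcome to
    recomputation, O(n^2) total.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    exempt_set = set(exempt)
    ids = [t.group_id for t in tables]
    unknown = exempt_set - set(ids)
    if unknown:
        raise ValueError(f"exempt ids not in panel: {sorted(unknown)}")
    mat = matrix if matrix is not None else fst_matrix(tables)
    if tuple(ids) != mat.group_ids:
        raise ValueError("matrix group_ids do not match panel order")
    rng = np.random.default_rng(seed)
    kept = list(ids)
    removed: list[Removal] = []
    iteration = 0
    while len(kept) > 1:
        iteration += 1
        best: tuple[float, str, str] | None = None
        for i, gi in enumerate(kept):
            for gj in kept[i + 1 :]:
                if gi in exempt_set and gj in exempt_set:
                    continue
                v = mat.get(gi, gj)
                key = tuple(sorted((gi, gj)))
                if best is None or (v, key) < (best[0], tuple(sorted(best[1:]))):
                    best = (v, gi, gj)
        if best is None or best[0] > threshold:
            break
        v, gi, gj = best
        if gi in exempt_set:
            victim = gj
        elif gj in exempt_set:
            victim = gi
        else:
            victim = (gi, gj)[rng.integers(2)]
        partner = gj if victim == gi else gi
        kept.remove(victim)
        removed.append(Removal(victim, partner, v, iteration))
    return PrunedPanel(tuple(kept), tuple(removed), threshold, seed)


def pearson_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and two-sided p (t distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
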