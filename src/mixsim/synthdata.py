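"""Synthetic allele-frequency panels with controlled diversity and
controlled between-group divergence.

The generator stands in for published STR frequency tables: 13 loci, 8–14
alleles per locus, integer STR-like allele labels, frequencies summing to
exactly 1 per locus.  Two handles matter:

* **Diversity.**  Per locus, frequencies follow a geometric-decay profile
  ``p_i ∝ r^i``.  Expected heterozygosity ``1 - Σ p_i²`` is then a smooth,
  strictly increasing function of the decay parameter ``r`` on (0, 1], so a
  bracketed root-finder can hit any achievable diversity target (anything
  below ``1 - 1/m`` for ``m`` alleles) essentially exactly.  Every locus in a
  base table shares the target, so the group mean — the study's predictor —
  equals the target by construction.

* **Divergence.**  A derived group is drawn per locus from a Dirichlet
  distribution centred on the base frequencies with concentration
  ``(1 - F)/F`` — the Balding–Nichols drift model — giving pairs with a
  known expected F_ST for estimator-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.optimize import brentq

from .freqtables import FrequencyTable

#: CODIS locus names in a fixed order, used to name synthetic loci so the
#: generated tables pass the completeness QC unchanged.
_CODIS_ORDER: tuple[str, ...] = (
    "CSF1PO",
    "D3S1358",
    "D5S818",
    "D7S820",
    "D8S1179",
    "D13S317",
    "D16S539",
    "D18S51",
    "D21S11",
    "FGA",
    "TH01",
    "TPOX",
    "vWA",
)


def _locus_names(n_loci: int) -> list[str]:
    names = list(_CODIS_ORDER[:n_loci])
    names += [f"EXTRA{i + 1}" for i in range(max(0, n_loci - len(_CODIS_ORDER)))]
    return names


def _geometric_heterozygosity(r: float, m: int) -> float:
    w = r ** np.arange(m)
    p = w / w.sum()
    return 1.0 - float(p @ p)


def geometric_locus_frequencies(target: float, n_alleles: int) -> np.ndarray:
    """Frequencies ``p_i ∝ r^i`` with ``1 - Σ p_i²`` equal to ``target``.

    Raises for targets outside ``(0, 1 - 1/n_alleles)``.
    """
    if n_alleles < 2:
        raise ValueError("need at least 2 alleles")
    upper = 1.0 - 1.0 / n_alleles
    if not (0.0 < target < upper):
        raise ValueError(
            f"target diversity {target} unachievable with {n_alleles} alleles; "
            f"must lie in (0, {upper:.6g})"
        )
    r = brentq(
        lambda r: _geometric_heterozygosity(r, n_alleles) - target,
        1e-12,
        1.0,
        xtol=1e-16,
        rtol=8.9e-16,
    )
    w = r ** np.arange(n_alleles)
    return w / w.sum()


def make_table(
    target_diversity: float,
    n_loci: int = 13,
    alleles_per_locus: tuple[int, int] = (8, 14),
    seed: int = 0,
    *,
    group_id: str | None = None,
    sample_size: int = 500,
) -> FrequencyTable:
    """One synthetic group whose every locus has the target heterozygosity.

    Allele counts per locus are drawn uniformly from ``alleles_per_locus``
    (inclusive); labels are consecutive STR-like integers with a random
    start.  The returned table passes QC with per-locus sums exactly 1.
    """
    lo, hi = alleles_per_locus
    if not 2 <= lo <= hi:
        raise ValueError("alleles_per_locus bounds must satisfy 2 <= lo <= hi")
    rng = np.random.default_rng(seed)
    loci: dict[str, dict[str, float]] = {}
    for name in _locus_names(n_loci):
        m = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(5, 11))
        p = geometric_locus_frequencies(target_diversity, m)
        order = rng.permutation(m)  # decouple frequency rank from label order
        loci[name] = {str(start + i): float(p[order[i]]) for i in range(m)}
    gid = group_id if group_id is not None else f"synth_d{target_diversity:.4f}"
    return FrequencyTable(gid, sample_size, loci)


def perturb_table(
    base: FrequencyTable, f: float, seed: int = 0, *, group_id: str | None = None
) -> FrequencyTable:
    """Balding–Nichols drift: per locus, draw derived frequencies from a
    Dirichlet centred on the base with concentration ``(1 - f)/f``.

    A zero-frequency guard (1e-9 floor, then renormalise) keeps every allele
    present so the result is a valid table.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("f must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    conc = (1.0 - f) / f
    loci: dict[str, dict[str, float]] = {}
    for locus, freqs in base.loci.items():
        labels = list(freqs)
        alpha = conc * np.array([freqs[a] for a in labels])
        draw = rng.dirichlet(alpha)
        draw = np.maximum(draw, 1e-9)
        draw = draw / draw.sum()
        loci[locus] = {a: float(p) for a, p in zip(labels, draw)}
    gid = group_id if group_id is not None else f"{base.group_id}_bn{f:g}"
    return FrequencyTable(gid, base.sample_size, loci)


def sister_pair(
    base: FrequencyTable, f: float, seed: int = 0
) -> tuple[FrequencyTable, FrequencyTable]:
    """Two groups independently drifted from ``base`` at the same F.

    This is the construction whose *pairwise* Weir–Cockerham theta-hat is
    expected to be near F: both sisters sit at divergence F from the common
    ancestor.  (A base/derived pair, by contrast, has expected pairwise
    theta-hat near F/2, the ancestor being undrifted.)
    """
    ss = np.random.SeedSequence([seed])
    s1, s2 = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    return (
        perturb_table(base, f, seed=s1, group_id=f"{base.group_id}_sisA"),
        perturb_table(base, f, seed=s2, group_id=f"{base.group_id}_sisB"),
    )


@dataclass(frozen=True)
class SynthPanelSpec:
    """Design of a synthetic panel.

    ``diversity_targets`` gives one base group per value; when
    ``divergence_f`` > 0, each base group additionally gets ``satellites``
    Balding–Nichols-derived neighbours at that F.
    """

    diversity_targets: tuple[float, ...]
    n_loci: int = 13
    alleles_per_locus: tuple[int, int] = (8, 14)
    divergence_f: float = 0.0
    satellites: int = 1
    sample_size: int = 500
    seed: int = 0


def make_panel(spec: SynthPanelSpec) -> list[FrequencyTable]:
    """Generate the panel a :class:`SynthPanelSpec` describes.

    Group ids encode the target diversity; base tables appear in target
    order, each followed by its satellites.
    """
    tables: list[FrequencyTable] = []
    for idx, target in enumerate(spec.diversity_targets):
        base = make_table(
            target,
            spec.n_loci,
            spec.alleles_per_locus,
            seed=_panel_seed(spec.seed, idx, 0),
            group_id=f"G{idx + 1:02d}_d{target:.4f}",
            sample_size=spec.sample_size,
        )
        tables.append(base)
        if spec.divergence_f > 0:
            for s in range(spec.satellites):
                tables.append(
                    perturb_table(
                        base,
                        spec.divergence_f,
                        seed=_panel_seed(spec.seed, idx, s + 1),
                        group_id=f"{base.group_id}_sat{s + 1}",
                    )
                )
    return tables


def _panel_seed(root_seed: int, group_index: int, member_index: int) -> int:
    """Deterministic per-member seed below 2**31."""
    ss = np.random.SeedSequence([root_seed, group_index, member_index])
    return int(ss.generate_state(1)[0] % (2**31))


def evenly_spaced_targets(
    n: int = 15, lo: float = 0.67, hi: float = 0.80
) -> tuple[float, ...]:
    """Diversity targets evenly spanning the observed group range."""
    return tuple(float(t) for t in np.linspace(lo, hi, n))
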