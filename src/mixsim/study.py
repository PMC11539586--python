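"""Accuracy studies: false positive rate and power of semi-continuous LR
mixture interpretation, under correctly and mis-specified reference
allele-frequency distributions.

Design
------
A *cell* is one combination of (simulation group, reference group,
contributor count k, POI state).  Per cell, ``n_reps`` mixtures are
simulated from the simulation table, LRs are computed against the reference
table, and the proportion with LR strictly above the decision threshold is
tallied: power for POI+ cells, false positive rate (FPR) for POI− cells.

* Correct-reference study: reference = simulation group; every group ×
  k ∈ {2..6} × {POI+, POI−}.
* Mis-specified study: every *ordered* pair of panel groups (the diagonal
  reproduces the correct-reference cells exactly under the shared seed
  policy), same cell structure.

Seeding: each cell gets its own ``SeedSequence`` keyed on
``(root_seed, crc32(sim_id), crc32(ref_id), k, poi_state)``, so cells are
reproducible independently of execution order and the mis-specified
diagonal is bit-identical to the correct-reference run.

Engine
------
Cells run through a vectorised likelihood engine that evaluates, per locus,
the prosecution likelihood and the defense sum over the single unknown
contributor's genotypes in closed form over numpy arrays.  It implements
exactly the model in :mod:`mixsim.likelihood` restricted to the study's
conditions (one unknown, drop-in c = 0); equivalence with the scalar
engine is asserted in the test suite.  Cells with drop-in > 0 fall back to
the scalar object path.  Mis-specified cells floor *all*
simulation-spectrum alleles absent from the reference once per cell (the
scalar path floors per profile; difference is O(freq_floor)).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .freqtables import FrequencyTable
from .likelihood import AlleleAbsentError, LRParams, compute_lr
from .popgen import genetic_diversity, pairwise_fst, pearson_test
from .simulate import ScenarioSpec, simulate_scenario

DEFAULT_CONTRIBUTORS: tuple[int, ...] = (2, 3, 4, 5, 6)


# ---------------------------------------------------------------------------
# Design bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellSpec:
    """One scheduled simulation cell (not yet executed)."""

    sim_id: str
    ref_id: str
    contributors: int
    poi_present: bool
    n_reps: int


def cell_seed_sequence(
    root_seed: int, sim_id: str, ref_id: str, k: int, poi_present: bool
) -> np.random.SeedSequence:
    """Deterministic per-cell seed stream (crc32 of the group ids)."""
    return np.random.SeedSequence(
        [
            root_seed,
            zlib.crc32(sim_id.encode()),
            zlib.crc32(ref_id.encode()),
            k,
            int(poi_present),
        ]
    )


def plan_correct_reference_study(
    tables: Sequence[FrequencyTable],
    contributors: Iterable[int] = DEFAULT_CONTRIBUTORS,
    n_reps: int = 100_000,
    poi_states: tuple[bool, ...] = (True, False),
) -> list[CellSpec]:
    """Enumerate the correct-reference design without executing it.

    At nominal settings (5 contributor counts, both POI states, 100,000
    replicates) this schedules 1,000,000 LR evaluations per group.
    """
    return [
        CellSpec(t.group_id, t.group_id, k, poi, n_reps)
        for t in tables
        for k in contributors
        for poi in poi_states
    ]


def plan_misspecified_study(
    panel: Sequence[FrequencyTable],
    contributors: Iterable[int] = DEFAULT_CONTRIBUTORS,
    n_reps: int = 10_000,
    poi_states: tuple[bool, ...] = (True, False),
) -> list[CellSpec]:
    """Every ordered (simulation, reference) pair, diagonal included."""
    return [
        CellSpec(sim.group_id, ref.group_id, k, poi, n_reps)
        for sim in panel
        for ref in panel
        for k in contributors
        for poi in poi_states
    ]


def scheduled_evaluations(cells: Sequence[CellSpec]) -> int:
    """Total number of LR evaluations a plan would perform."""
    return sum(c.n_reps for c in cells)


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AccuracyEstimate:
    """FPR (POI−) or power (POI+) for one executed cell, with Wilson CI."""

    group_id: str
    ref_id: str
    contributors: int
    poi_present: bool
    n_reps: int
    n_positive: int
    rate: float
    threshold: float
    infinite_lr_count: int = 0
    degenerate_count: int = 0
    ci_low: float = 0.0
    ci_high: float = 1.0


@dataclass(frozen=True)
class StudyResult:
    estimates: tuple[AccuracyEstimate, ...]
    diversity_by_group: Mapping[str, float]
    fst_by_pair: Mapping[tuple[str, str], float]
    params: LRParams
    threshold: float
    root_seed: int
    log10_lrs: Mapping[tuple[str, str, int, bool], np.ndarray] | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-estimate table."""
        return pd.DataFrame(
            [
                {
                    "group_id": e.group_id,
                    "ref_id": e.ref_id,
                    "contributors": e.contributors,
                    "poi_present": e.poi_present,
                    "n_reps": e.n_reps,
                    "n_positive": e.n_positive,
                    "rate": e.rate,
                    "threshold": e.threshold,
                    "infinite_lr_count": e.infinite_lr_count,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                }
                for e in self.estimates
            ]
        )


def _make_estimate(
    cell: CellSpec,
    log10_lrs: np.ndarray,
    threshold: float,
) -> AccuracyEstimate:
    with np.errstate(invalid="ignore"):
        positives = log10_lrs > np.log10(threshold) if threshold > 0 else ~np.isneginf(
            log10_lrs
        )
    n_positive = int(np.count_nonzero(positives & ~np.isnan(log10_lrs)))
    n_degenerate = int(np.isnan(log10_lrs).sum())
    rate = n_positive / cell.n_reps
    lo, hi = proportion_confint(n_positive, cell.n_reps, alpha=0.05, method="wilson")
    lo, hi = min(float(lo), rate), max(float(hi), rate)  # guard FP round-off
    return AccuracyEstimate(
        group_id=cell.sim_id,
        ref_id=cell.ref_id,
        contributors=cell.contributors,
        poi_present=cell.poi_present,
        n_reps=cell.n_reps,
        n_positive=n_positive,
        rate=rate,
        threshold=threshold,
        infinite_lr_count=int(np.isposinf(log10_lrs).sum()),
        degenerate_count=n_degenerate,
        ci_low=float(lo),
        ci_high=float(hi),
    )


# ---------------------------------------------------------------------------
# Vectorised cell engine (one unknown, drop-in = 0)
# ---------------------------------------------------------------------------


def _locus_spectra(
    sim_freqs: Mapping[str, float],
    ref_freqs: Mapping[str, float],
    params: LRParams,
    locus: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (sampling, reference) probability vectors over the allele
    union; simulation-only alleles are floored into the reference spectrum
    (or raise, per policy) and both vectors renormalised."""
    labels = list(sim_freqs) + [a for a in ref_freqs if a not in sim_freqs]
    missing = [a for a in sim_freqs if a not in ref_freqs]
    if missing and params.floor_policy == "error":
        raise AlleleAbsentError(
            f"allele(s) {', '.join(sorted(missing))} absent from reference "
            f"at locus {locus}"
        )
    sim_p = np.array([sim_freqs.get(a, 0.0) for a in labels])
    ref_p = np.array(
        [ref_freqs.get(a, params.freq_floor) for a in labels]
    )
    return sim_p / sim_p.sum(), ref_p / ref_p.sum()


def _batch_locus_ratio(
    contrib: np.ndarray,
    poi: np.ndarray,
    ref_p: np.ndarray,
    d_het: float,
    d_hom: float,
) -> np.ndarray:
    """Per-replicate locus LR for given allele-index genotypes.

    ``contrib`` has shape (n, k, 2): contributor #1 is the true donor whose
    place the unknown takes under the defense; contributors #2..k are the
    known others under both hypotheses.  ``poi`` (n, 2) is the POI genotype
    (equal to ``contrib[:, 0]`` in POI+ scenarios).  ``ref_p`` (m,) is the
    reference allele spectrum.  The observed set is the union of the
    contributors' alleles — no simulated dropout or drop-in.

    The common knowns-only product cancels between the hypotheses, so the
    ratio is the POI's per-allele adjustment factors over the HWE-weighted
    sum of the unknown's, restricted to genotypes carrying every observed
    allele no known carries (drop-in 0 makes others impossible).
    """
    n, k, _ = contrib.shape
    m = len(ref_p)
    rows = np.arange(n)

    observed = np.zeros((n, m), dtype=bool)
    for j in range(k):
        observed[rows, contrib[:, j, 0]] = True
        observed[rows, contrib[:, j, 1]] = True

    # dropout products and carrier flags over the known non-POI contributors
    dk = np.ones((n, m))
    known_carrier = np.zeros((n, m), dtype=bool)
    for j in range(1, k):
        x, y = contrib[:, j, 0], contrib[:, j, 1]
        het = x != y
        d = np.where(het, d_het, d_hom)
        dk[rows, x] *= d
        known_carrier[rows, x] = True
        hr = rows[het]
        dk[hr, y[het]] *= d[het]
        known_carrier[hr, y[het]] = True

    # adjustment factor for the extra contributor (POI or unknown) carrying
    # allele a once: observed -> (1 - Dk d)/(1 - Dk), unobserved -> d
    denom0 = np.where(known_carrier, 1.0 - dk, 1.0)
    r_het = np.where(observed, (1.0 - dk * d_het) / denom0, d_het)
    r_hom = np.where(observed, (1.0 - dk * d_hom) / denom0, d_hom)

    uncovered = observed & ~known_carrier
    ucnt = uncovered.sum(axis=1)

    # prosecution: POI is the extra contributor, genotype conditioned
    u, v = poi[:, 0], poi[:, 1]
    het_poi = u != v
    base = np.where(het_poi, r_het[rows, u] * r_het[rows, v], r_hom[rows, u])
    covered = (
        ucnt
        - uncovered[rows, u].astype(np.int64)
        - np.where(het_poi, uncovered[rows, v], False).astype(np.int64)
    ) == 0
    num = base * covered

    # defense: sum over the unknown's genotypes, HWE-weighted
    p2 = ref_p * ref_p
    s1 = r_het @ ref_p
    den = np.empty(n)
    mask0 = ucnt == 0
    if mask0.any():
        full = s1 * s1 - (r_het * r_het) @ p2 + r_hom @ p2
        den[mask0] = full[mask0]
    mask1 = ucnt == 1
    if mask1.any():
        x = uncovered.argmax(axis=1)
        px_rx = ref_p[x] * r_het[rows, x]
        den1 = 2.0 * px_rx * (s1 - px_rx) + p2[x] * r_hom[rows, x]
        den[mask1] = den1[mask1]
    mask2 = ucnt == 2
    if mask2.any():
        x = uncovered.argmax(axis=1)
        rest = uncovered.copy()
        rest[rows, x] = False
        y = rest.argmax(axis=1)
        den2 = 2.0 * ref_p[x] * ref_p[y] * r_het[rows, x] * r_het[rows, y]
        den[mask2] = den2[mask2]
    den[ucnt > 2] = 0.0  # unreachable in-study: one unknown covers <= 2

    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def _cell_log10_lrs_batch(
    sim_table: FrequencyTable,
    ref_table: FrequencyTable,
    cell: CellSpec,
    params: LRParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """log10 LR per replicate for one cell, vectorised over replicates."""
    n, k = cell.n_reps, cell.contributors
    total = np.zeros(n)
    for locus in sim_table.loci:
        if locus not in ref_table.loci:
            raise KeyError(
                f"locus {locus!r} missing from reference table "
                f"{ref_table.group_id!r}"
            )
        sim_p, ref_p = _locus_spectra(
            sim_table.loci[locus], ref_table.loci[locus], params, locus
        )
        m = len(sim_p)
        contrib = rng.choice(m, size=(n, k, 2), p=sim_p)
        if cell.poi_present:
            poi = contrib[:, 0, :]
        else:
            poi = rng.choice(m, size=(n, 2), p=sim_p)
        ratio = _batch_locus_ratio(contrib, poi, ref_p, params.d_het, params.d_hom)
        with np.errstate(divide="ignore", invalid="ignore"):
            total = total + np.log10(ratio)
    return total


def _cell_log10_lrs_scalar(
    sim_table: FrequencyTable,
    ref_table: FrequencyTable,
    cell: CellSpec,
    params: LRParams,
    seed: int,
) -> np.ndarray:
    """Reference object path: simulate_scenario + compute_lr, replicate by
    replicate.  Used when the batch engine's preconditions do not hold."""
    spec = ScenarioSpec(
        contributors=cell.contributors,
        poi_present=cell.poi_present,
        sim_table=sim_table,
        ref_table=ref_table,
        n_reps=cell.n_reps,
        seed=seed,
    )
    out = np.empty(cell.n_reps)
    for i, (mixture, poi, known_others) in enumerate(simulate_scenario(spec)):
        out[i] = compute_lr(mixture, poi, known_others, ref_table, params).log10_lr
    return out


def run_cell(
    sim_table: FrequencyTable,
    ref_table: FrequencyTable,
    cell: CellSpec,
    params: LRParams,
    root_seed: int,
) -> np.ndarray:
    """Execute one cell; returns the per-replicate log10 LRs."""
    ss = cell_seed_sequence(
        root_seed, cell.sim_id, cell.ref_id, cell.contributors, cell.poi_present
    )
    if params.drop_in == 0.0:
        return _cell_log10_lrs_batch(
            sim_table, ref_table, cell, params, np.random.default_rng(ss)
        )
    return _cell_log10_lrs_scalar(
        sim_table, ref_table, cell, params, int(ss.generate_state(1)[0] % (2**31))
    )


# ---------------------------------------------------------------------------
# Study runners
# ---------------------------------------------------------------------------


def _execute(
    cells: Sequence[CellSpec],
    tables_by_id: Mapping[str, FrequencyTable],
    params: LRParams,
    threshold: float,
    seed: int,
    keep_lrs: bool,
) -> tuple[list[AccuracyEstimate], dict | None]:
    estimates = []
    stored: dict[tuple[str, str, int, bool], np.ndarray] | None = (
        {} if keep_lrs else None
    )
    for cell in cells:
        log10_lrs = run_cell(
            tables_by_id[cell.sim_id], tables_by_id[cell.ref_id], cell, params, seed
        )
        estimates.append(_make_estimate(cell, log10_lrs, threshold))
        if stored is not None:
            stored[(cell.sim_id, cell.ref_id, cell.contributors, cell.poi_present)] = (
                log10_lrs
            )
    return estimates, stored


def run_correct_reference_study(
    tables: Sequence[FrequencyTable],
    contributors: Iterable[int] = DEFAULT_CONTRIBUTORS,
    n_reps: int = 100_000,
    params: LRParams = LRParams(),
    threshold: float = 1.0,
    seed: int = 0,
    keep_lrs: bool = False,
    poi_states: tuple[bool, ...] = (True, False),
) -> StudyResult:
    """FPR and power per group × contributor count with the correct
    reference (reference table = simulation table in every cell)."""
    contributors = tuple(contributors)
    cells = plan_correct_reference_study(tables, contributors, n_reps, poi_states)
    tables_by_id = {t.group_id: t for t in tables}
    estimates, stored = _execute(
        cells, tables_by_id, params, threshold, seed, keep_lrs
    )
    return StudyResult(
        estimates=tuple(estimates),
        diversity_by_group={t.group_id: genetic_diversity(t) for t in tables},
        fst_by_pair={},
        params=params,
        threshold=threshold,
        root_seed=seed,
        log10_lrs=stored,
    )


def run_misspecified_study(
    panel: Sequence[FrequencyTable],
    contributors: Iterable[int] = DEFAULT_CONTRIBUTORS,
    n_reps: int = 10_000,
    params: LRParams = LRParams(),
    threshold: float = 1.0,
    seed: int = 0,
    keep_lrs: bool = False,
    poi_states: tuple[bool, ...] = (True, False),
) -> StudyResult:
    """FPR and power for every ordered (simulation, reference) pair of the
    panel, diagonal (correct specification) included."""
    if len(panel) < 2:
        raise ValueError("mis-specified study needs a panel of >= 2 groups")
    contributors = tuple(contributors)
    cells = plan_misspecified_study(panel, contributors, n_reps, poi_states)
    tables_by_id = {t.group_id: t for t in panel}
    estimates, stored = _execute(
        cells, tables_by_id, params, threshold, seed, keep_lrs
    )
    fst = {}
    for i, a in enumerate(panel):
        for b in panel[i + 1 :]:
            v = pairwise_fst(a, b)
            fst[(a.group_id, b.group_id)] = v
            fst[(b.group_id, a.group_id)] = v
    return StudyResult(
        estimates=tuple(estimates),
        diversity_by_group={t.group_id: genetic_diversity(t) for t in panel},
        fst_by_pair=fst,
        params=params,
        threshold=threshold,
        root_seed=seed,
        log10_lrs=stored,
    )


# ---------------------------------------------------------------------------
# Correlation analyses and threshold sweeps
# ---------------------------------------------------------------------------


def correlate_fpr_diversity(
    result: StudyResult, contributors: int
) -> tuple[float, float]:
    """Pearson test of per-group FPR against genetic diversity
    (correct-reference POI− cells at the given contributor count)."""
    pts = [
        (result.diversity_by_group[e.group_id], e.rate)
        for e in result.estimates
        if not e.poi_present
        and e.group_id == e.ref_id
        and e.contributors == contributors
    ]
    if len(pts) < 3:
        raise ValueError("need FPR estimates for at least 3 groups")
    div, fpr = zip(*pts)
    return pearson_test(div, fpr)


def correlate_fpr_fst(result: StudyResult, contributors: int) -> tuple[float, float]:
    """Pearson test of off-diagonal FPR against pairwise F_ST between the
    simulation and reference groups; each unordered pair contributes two
    points (the two orderings)."""
    pts = [
        (result.fst_by_pair[(e.group_id, e.ref_id)], e.rate)
        for e in result.estimates
        if not e.poi_present
        and e.group_id != e.ref_id
        and e.contributors == contributors
    ]
    if len(pts) < 3:
        raise ValueError("need at least 3 off-diagonal FPR estimates")
    fst, fpr = zip(*pts)
    return pearson_test(fst, fpr)


def threshold_sweep(
    result: StudyResult, thresholds: Sequence[float]
) -> pd.DataFrame:
    """Re-classify stored LRs at each threshold without re-simulation."""
    if result.log10_lrs is None:
        raise ValueError(
            "raw LRs were not retained; rerun the study with keep_lrs=True"
        )
    rows = []
    for (sim_id, ref_id, k, poi), log10_lrs in result.log10_lrs.items():
        cell = CellSpec(sim_id, ref_id, k, poi, len(log10_lrs))
        for threshold in thresholds:
            est = _make_estimate(cell, log10_lrs, threshold)
            rows.append(
                {
                    "group_id": sim_id,
                    "ref_id": ref_id,
                    "contributors": k,
                    "poi_present": poi,
                    "threshold": threshold,
                    "n_reps": est.n_reps,
                    "n_positive": est.n_positive,
                    "rate": est.rate,
                }
            )
    return pd.DataFrame(rows)
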