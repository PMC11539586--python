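"""Semi-continuous (presence/absence) likelihood-ratio engine.

The model is the standard Gill/Balding/Haned presence–absence factorisation
with probabilistic dropout and drop-in.  For a hypothesised set of
contributors at one locus, with D(a) the probability that allele ``a``
dropped out of every carrier —

    D(a) = prod over carriers of a of (d_het if the carrier is heterozygous
                                       else d_hom)

— the locus likelihood multiplies, over alleles:

* carried and observed:      1 - D(a)
* carried, not observed:     D(a)
* observed, not carried:     c * p_a          (drop-in)

and one factor ``(1 - c)`` when no drop-in was needed at the locus.
Unknown contributors are summed out over all unordered genotypes weighted by
their Hardy–Weinberg probabilities (theta = 0 throughout: genotype
probabilities are plain products of allele frequencies, no co-ancestry
correction).

The likelihood ratio compares the prosecution hypothesis (POI contributed,
all contributors known) against the defense hypothesis (an unknown,
unrelated individual contributed in the POI's place; the other contributors
remain known):

    LR = P(G | H_p) / P(G | H_d),

multiplied across loci.  LR > threshold (default 1, strict) is an
"inclusion".

Alleles present in a profile but absent from the reference table — the
normal case under reference-group mis-specification — are handled by a
frequency floor: they enter the reference spectrum at ``freq_floor`` and the
spectrum is renormalised, or raise, per ``floor_policy``.

The engine is deterministic by contract: identical inputs give bit-identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations_with_replacement, product
from typing import Mapping, Sequence

from .freqtables import FrequencyTable
from .simulate import Genotype, MixtureProfile

#: Co-ancestry coefficient; fixed — genotype probabilities are pure HWE.
THETA = 0.0


class AlleleAbsentError(KeyError):
    """An observed or known allele is missing from the reference table and
    ``floor_policy`` is ``"error"``."""


@dataclass(frozen=True)
class LRParams:
    """Parameters of the semi-continuous model.

    d_het
        Dropout probability per allele of a heterozygote.
    d_hom
        Dropout probability of a homozygote's (jointly considered) alleles.
        Kept independent of ``d_het`` rather than forced to its square; the
        defaults happen to satisfy the square relation.
    drop_in
        Per-locus drop-in rate ``c``; each unexplained observed allele costs
        ``c * p_a``, and a single ``(1 - c)`` applies when none is needed.
    freq_floor
        Frequency substituted for profile alleles absent from the reference.
    floor_policy
        ``"floor"`` to substitute and renormalise, ``"error"`` to raise.
    """

    d_het: float = 0.01
    d_hom: float = 0.0001
    drop_in: float = 0.0
    freq_floor: float = 1e-4
    floor_policy: str = "floor"

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_het < 1.0:
            raise ValueError("d_het must lie in [0, 1)")
        if not 0.0 <= self.d_hom < 1.0:
            raise ValueError("d_hom must lie in [0, 1)")
        if self.drop_in < 0.0:
            raise ValueError("drop_in must be >= 0")
        if self.freq_floor <= 0.0:
            raise ValueError("freq_floor must be > 0")
        if self.floor_policy not in ("floor", "error"):
            raise ValueError("floor_policy must be 'floor' or 'error'")


@dataclass(frozen=True)
class LRResult:
    """A likelihood ratio with its per-locus decomposition.

    ``lr`` is +inf when the defense likelihood is zero while the
    prosecution's is not; ``degenerate`` marks the pathological case where
    both hypotheses assign the evidence probability zero at some locus.
    """

    lr: float
    log10_lr: float
    per_locus_ratios: Mapping[str, float]
    infinite: bool = False
    degenerate: bool = False


def _effective_frequencies(
    ref_freqs: Mapping[str, float],
    profile_alleles: set[str],
    params: LRParams,
    locus: str = "?",
) -> dict[str, float]:
    """Reference spectrum with floored entries for profile alleles missing
    from the table, renormalised to sum to 1."""
    missing = sorted(a for a in profile_alleles if a not in ref_freqs)
    if missing and params.floor_policy == "error":
        raise AlleleAbsentError(
            f"allele(s) {', '.join(missing)} absent from reference at locus {locus}"
        )
    eff = dict(ref_freqs)
    for a in missing:
        eff[a] = params.freq_floor
    total = sum(eff.values())
    return {a: p / total for a, p in eff.items()}


def _set_likelihood(
    observed: frozenset[str] | set[str],
    genotypes: Sequence[tuple[str, str]],
    probs: Mapping[str, float],
    params: LRParams,
) -> float:
    """Likelihood of the observed allele set given a full contributor set."""
    dropout: dict[str, float] = {}
    for x, y in genotypes:
        if x == y:
            dropout[x] = dropout.get(x, 1.0) * params.d_hom
        else:
            dropout[x] = dropout.get(x, 1.0) * params.d_het
            dropout[y] = dropout.get(y, 1.0) * params.d_het
    lik = 1.0
    for a, d in dropout.items():
        lik *= (1.0 - d) if a in observed else d
    unexplained = [a for a in observed if a not in dropout]
    if unexplained:
        for a in unexplained:
            lik *= params.drop_in * probs[a]
    else:
        lik *= 1.0 - params.drop_in
    return lik


def locus_likelihood(
    observed: frozenset[str] | set[str],
    known_genotypes: Sequence[tuple[str, str]],
    n_unknown: int,
    ref_freqs: Mapping[str, float],
    params: LRParams,
    *,
    locus: str = "?",
) -> float:
    """P(observed alleles | knowns + ``n_unknown`` unknown contributors).

    Unknowns are summed over all unordered genotypes built from the
    reference spectrum (floored/renormalised as needed), weighted by HWE
    probabilities ``p^2`` / ``2 p q``.
    """
    if not observed:
        raise ValueError(f"locus {locus}: observed allele set is empty")
    if n_unknown < 0:
        raise ValueError("n_unknown must be >= 0")
    profile_alleles = set(observed) | {a for g in known_genotypes for a in g}
    probs = _effective_frequencies(ref_freqs, profile_alleles, params, locus)
    known = [tuple(g) for g in known_genotypes]
    if n_unknown == 0:
        return _set_likelihood(observed, known, probs, params)
    alleles = sorted(probs)
    genos = list(combinations_with_replacement(alleles, 2))
    weights = {
        (u, v): (probs[u] * probs[v] if u == v else 2.0 * probs[u] * probs[v])
        for u, v in genos
    }
    total = 0.0
    for assignment in product(genos, repeat=n_unknown):
        w = 1.0
        for g in assignment:
            w *= weights[g]
        total += w * _set_likelihood(observed, known + list(assignment), probs, params)
    return total


def compute_lr(
    mixture: MixtureProfile,
    poi: Genotype,
    known_others: Sequence[Genotype],
    ref_table: FrequencyTable,
    params: LRParams = LRParams(),
) -> LRResult:
    """Likelihood ratio for the POI over a mixture.

    Numerator: contributors = POI plus the known others, no unknowns.
    Denominator: the known others plus one unknown in the POI's place.
    The total LR is the product of per-locus ratios.
    """
    per_locus: dict[str, float] = {}
    log10 = 0.0
    infinite = degenerate = False
    for locus, observed in mixture.observed_alleles_by_locus.items():
        if locus not in ref_table.loci:
            raise KeyError(
                f"locus {locus!r} missing from reference table {ref_table.group_id!r}"
            )
        ref_freqs = ref_table.loci[locus]
        knowns = [g.alleles_by_locus[locus] for g in known_others]
        num = locus_likelihood(
            observed,
            knowns + [poi.alleles_by_locus[locus]],
            0,
            ref_freqs,
            params,
            locus=locus,
        )
        den = locus_likelihood(observed, knowns, 1, ref_freqs, params, locus=locus)
        if den == 0.0:
            if num == 0.0:
                degenerate = True
                per_locus[locus] = math.nan
            else:
                infinite = True
                per_locus[locus] = math.inf
            continue
        ratio = num / den
        per_locus[locus] = ratio
        log10 += math.log10(ratio) if ratio > 0.0 else -math.inf

    if degenerate:
        return LRResult(math.nan, math.nan, per_locus, infinite, True)
    if infinite:
        return LRResult(math.inf, math.inf, per_locus, True, False)
    lr = 1.0
    for ratio in per_locus.values():
        lr *= ratio
    return LRResult(lr, log10, per_locus, False, False)


def classify(lr: float, threshold: float = 1.0) -> bool:
    """Inclusion decision: strictly ``lr > threshold``.

    +inf counts as inclusion; NaN (degenerate) does not.
    """
    if lr < 0:
        raise ValueError("lr must be >= 0")
    return lr > threshold
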