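"""Independent oracles used by the test suite.

These deliberately take different computational routes from the package:
the locus-likelihood oracle sums over the *dropout event space* instead of
multiplying per-allele survival factors, and the F_ST oracle is a direct
biallelic transcription of the two-population variance-component formulas.
"""

from __future__ import annotations

from itertools import combinations_with_replacement, product


def brute_force_locus_likelihood(
    observed: set[str],
    known_genotypes: list[tuple[str, str]],
    n_unknown: int,
    ref_freqs: dict[str, float],
    d_het: float,
    d_hom: float,
    drop_in: float = 0.0,
    freq_floor: float = 1e-4,
) -> float:
    """Locus likelihood by explicit enumeration of dropout events.

    Every contributor contributes "carrier units": a heterozygote one unit
    per allele (drop prob d_het each), a homozygote a single joint unit
    (drop prob d_hom).  Each of the 2^units dropout outcomes is enumerated;
    the surviving alleles must be a subset of the observed set and every
    observed allele not surviving must drop in (probability c * p_a), with
    one factor (1 - c) when no drop-in is needed.  Unknown contributors are
    summed over unordered HWE-weighted genotypes first.
    """
    profile = set(observed) | {a for g in known_genotypes for a in g}
    eff = dict(ref_freqs)
    for a in profile:
        if a not in eff:
            eff[a] = freq_floor
    total_p = sum(eff.values())
    probs = {a: p / total_p for a, p in eff.items()}

    genos = list(combinations_with_replacement(sorted(probs), 2))

    def hwe(g: tuple[str, str]) -> float:
        u, v = g
        return probs[u] * probs[v] if u == v else 2.0 * probs[u] * probs[v]

    def event_sum(genotypes: list[tuple[str, str]]) -> float:
        units: list[tuple[frozenset[str], float]] = []
        for x, y in genotypes:
            if x == y:
                units.append((frozenset({x}), d_hom))
            else:
                units.append((frozenset({x}), d_het))
                units.append((frozenset({y}), d_het))
        carried = {a for alleles, _ in units for a in alleles}
        total = 0.0
        for outcome in product([False, True], repeat=len(units)):
            prob = 1.0
            surviving: set[str] = set()
            for (alleles, d), dropped in zip(units, outcome):
                prob *= d if dropped else (1.0 - d)
                if not dropped:
                    surviving |= alleles
            if not surviving <= observed:
                continue
            needed = observed - surviving
            # drop-in only explains alleles no contributor carries; a carried
            # allele that dropped from every carrier cannot re-appear
            if needed & carried:
                continue
            if needed:
                for a in needed:
                    prob *= drop_in * probs[a]
            else:
                prob *= 1.0 - drop_in
            total += prob
        return total

    if n_unknown == 0:
        return event_sum(known_genotypes)
    result = 0.0
    for assignment in product(genos, repeat=n_unknown):
        w = 1.0
        for g in assignment:
            w *= hwe(g)
        result += w * event_sum(known_genotypes + list(assignment))
    return result


def wc_biallelic_fst(
    p1: float, p2: float, n1: float, n2: float, hwe_het: bool = True
) -> float:
    """Two-population, biallelic Weir–Cockerham theta-hat, transcribed
    directly from the 1984 variance-component definitions; heterozygote
    frequencies at their HWE values."""
    a_sum = b_sum = c_sum = 0.0
    for pa, pb in ((p1, p2), (1.0 - p1, 1.0 - p2)):
        nbar = (n1 + n2) / 2.0
        nc = (2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)) / 1.0
        pbar = (n1 * pa + n2 * pb) / (2.0 * nbar)
        s2 = (n1 * (pa - pbar) ** 2 + n2 * (pb - pbar) ** 2) / nbar
        hbar = (n1 * 2.0 * pa * (1.0 - pa) + n2 * 2.0 * pb * (1.0 - pb)) / (
            2.0 * nbar
        )
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - 0.5 * s2 - 0.25 * hbar)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - 0.5 * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum / (a_sum + b_sum + c_sum)
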