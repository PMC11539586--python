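# Methods

## Scope and pipeline

`mixsim` estimates the accuracy of semi-continuous DNA-mixture
interpretation as a function of (a) the genetic diversity of the
contributors' group and (b) mis-specification of the reference
allele-frequency distribution. The pipeline is: frequency-table QC →
(optionally) F_ST-based panel pruning → HWE mixture simulation →
likelihood-ratio evaluation → FPR/power tallies and correlation analyses.
All randomness flows from explicit integer seeds.

## Frequency tables and QC

A `FrequencyTable` is one group's per-locus allele→frequency map plus a
donor count. Allele labels stay text so microvariants ("9.3") are never
coerced. The QC ladder mirrors how published aggregate tables are vetted:

* completeness over the 13 original core CODIS loci (extra loci allowed);
* per-locus frequency sums within [0.99, 1.01], bounds inclusive — the
  permissive reading, affecting only boundary tables;
* an optional source-concordance hook (expected SHA-256 digest) standing in
  for the manual comparison of aggregate tables against source papers,
  which is literature work no code can automate.

QC filters; it never repairs. Renormalisation exists only as an explicit
`FrequencyTable.normalized()` call for synthetic workflows. Tables lacking
a donor count default to N = 200 with a logged warning, because the
Weir–Cockerham estimator needs a sample size and published tables do not
always carry one.

## Population-genetic summaries

Genetic diversity is the unweighted mean over loci of expected
heterozygosity `1 − Σ p_i²`.

Pairwise F_ST is the Weir–Cockerham (1984) θ̂: per allele and locus the
variance components a, b, c are computed for the two groups (unequal sample
sizes handled by the n_c term) and combined as a ratio of sums across all
alleles and shared loci. Because the inputs are published frequencies, not
genotypes, observed heterozygote frequencies are taken at their HWE values
`2p(1−p)` per group — the one modelling substitution in the estimator, made
explicit because θ̂'s h̄ term is otherwise data-driven. Slightly negative
estimates (a known small-sample property) are reported as-is, never
clamped.

Panel pruning iterates: find the kept pair with the lowest θ̂ (ties broken
lexicographically on the sorted id pair); stop when the minimum strictly
exceeds the threshold (default 0.005); otherwise remove one member
uniformly at random from a seeded generator. Exempt groups are never
removed; pairs with both members exempt are skipped in the minimum search.
Pairwise θ̂ values do not depend on panel composition, so the matrix is
computed once and shrunk rather than recomputed — identical output, O(n²)
total.

## Simulation

Contributors are i.i.d. HWE draws (two independent alleles per locus,
θ = 0, no relatedness); locus distributions are renormalised internally so
a QC-tolerated sum deviation cannot bias sampling. Mixtures are per-locus
set unions — presence/absence only, no peak heights, and no simulated
dropout or drop-in, so every contributor allele is present in the evidence.
POI-present scenarios make the POI contributor #1; POI-absent scenarios
draw the POI as one extra independent individual from the same simulation
group. Under both downstream hypotheses the non-POI contributors are known,
leaving exactly one unknown.

`simulate_scenario` gives each replicate its own `SeedSequence` substream,
so streams are reproducible and independent of evaluation order.

Sampler fidelity is validated the natural way: the fraction of heterozygous
locus-genotypes among 100,000 simulated individuals per group is compared
with the table's average expected heterozygosity (`tests/test_acceptance.py`
asserts squared correlation ≥ 0.9999 across a panel and agreement within
0.005 per group). The validation panel spans diversity 0.60–0.85 — wider
than the 0.67–0.80 study range — because the statistic's sampling noise
(SE ≈ 4e−4 per group at 13 loci × 1e5 individuals) is a fixed numerator
while the between-group spread is the denominator: the wider panel makes the
check informative about sampler bias rather than borderline by
construction.

## Likelihood-ratio engine

The semi-continuous model is the standard presence/absence factorisation
(Gill/Balding/Haned lineage): dropout independent across carriers with
`D(a) = Π d_carrier`, drop-in `c·p_a` per observed allele carried by no
hypothesised contributor, one `(1 − c)` factor when no drop-in is needed,
and unknowns summed over unordered HWE-weighted genotypes. Parameters:

| parameter | default | meaning |
|---|---|---|
| `d_het` | 0.01 | dropout probability per heterozygous allele copy |
| `d_hom` | 0.0001 | dropout probability of a homozygote's alleles |
| `drop_in` (c) | 0 | per-locus drop-in rate |
| `freq_floor` | 1e−4 | frequency substituted for alleles absent from the reference |
| θ | 0 (fixed) | no co-ancestry correction |

`d_hom` is an independent parameter, not forced to `d_het²` (the defaults
happen to satisfy the square relation). `c = 0` is safe in-study: with all
non-POI contributors known and one unknown under the defense, every
observed allele is explainable, so the defense likelihood cannot vanish.
Profile alleles missing from the reference (the normal situation under
mis-specification) are floored at `freq_floor` and the spectrum
renormalised; `floor_policy="error"` turns this into a hard error naming
locus and allele.

The engine is deterministic by contract — identical inputs give
bit-identical outputs — and is verified against two independent oracles:
closed forms for single-source LRs (`1/(2pq)`, `1/p²`) and a brute-force
enumerator over the *dropout event space* (every carrier unit drops or
not), which takes a different computational route from the per-allele
factorisation.

### Vectorised study engine

Study cells run through a numpy engine rather than per-replicate objects.
Per locus, the knowns-only factors cancel between numerator and
denominator, leaving the POI's per-allele adjustment factors over an
HWE-weighted closed-form sum over the unknown's genotypes, restricted to
genotypes covering every observed allele no known carries (at most two,
since the unknown stands in for one individual). The restriction has three
cases (0, 1 or 2 uncovered alleles), each O(alleles) per replicate. The
scalar and vectorised paths are asserted equal (relative 1e−9) on identical
genotypes across randomised cases; the algebraic cancellation also makes
degenerate monomorphic loci yield LR = 1 exactly, so the strict LR > 1
rule behaves correctly there. Two intentional restrictions: cells with
`drop_in > 0` fall back to the scalar object path, and mis-specified cells
floor *all* simulation-spectrum alleles absent from the reference once per
cell, whereas the scalar engine floors per profile (difference
O(`freq_floor`) relative).

## Study designs and seed policy

Correct-reference study: every group × k ∈ {2..6} × {POI+, POI−}, default
100,000 replicates per cell (1,000,000 LRs per group). Mis-specified
study: every *ordered* (simulation, reference) pair including the
diagonal, default 10,000 replicates per cell (100,000 LRs per ordered
pair). Desk-scale defaults used in the shipped tests and acceptance script
are 2,000–20,000 replicates per cell, which keeps the full suite in
minutes on one core while leaving binomial noise well below the effects
measured.

Each cell's generator is seeded by
`SeedSequence([root, crc32(sim_id), crc32(ref_id), k, poi_state])`, so the
mis-specified diagonal reproduces the correct-reference cells bit-for-bit
and results are independent of execution order.

Rates are exact tallies `n_positive / n_reps` with 95% Wilson intervals
attached (point estimates are what the study design reports; the intervals
are a convenience). Infinite LRs count as inclusions and are tallied
separately; degenerate both-hypotheses-zero replicates are flagged and
never counted as inclusions. Raw log10 LRs are stored only on request
(`keep_lrs`) so nominal-scale runs tally online in bounded memory.

Correlation analyses are plain Pearson tests (r and the two-sided p from
the t distribution with n−2 df); FPR-vs-diversity uses the correct-
reference POI− cells, FPR-vs-F_ST the off-diagonal POI− cells with each
unordered pair contributing both orderings. We report r (and r² where
useful) separately rather than conflating the two.

## Synthetic panels

Base tables use geometric-decay locus profiles `p_i ∝ r^i`: expected
heterozygosity is then smooth and strictly increasing in `r`, so bracketed
root-finding hits any target below `1 − 1/m` to 1e−9. All loci in a base
table share the group's target — real tables vary by locus, but the
study's predictor is the group mean, which this preserves while making
target-hitting exactly testable. Allele counts per locus are drawn from
8–14, labels are consecutive STR-like integers, loci carry the core CODIS
names so generated tables pass the QC ladder unchanged, and the label
order is decoupled from frequency rank.

Divergence uses the Balding–Nichols drift model: derived frequencies are
Dirichlet draws centred on the base with concentration `(1 − F)/F`, with a
1e−9 zero-guard and renormalisation. Note the geometry: a base→derived
pair has expected pairwise θ̂ ≈ F/2 (the base is the undrifted ancestor),
while a pair of *sisters* independently drifted at F has expected pairwise
θ̂ ≈ F — `sister_pair` exists for exactly that reason and is the
construction used in estimator-recovery tests (median θ̂ within 30% of F
at F ∈ {0.005, 0.02, 0.1}, 13 loci, n = 500; the residual downward bias at
F = 0.005 is the estimator's finite-sample correction acting on
noise-free frequencies).

What the generator does **not** emulate: real CODIS allele-label
distributions and microvariant structure, per-locus diversity variation
within a group, linkage, and sampling noise in the published frequencies
themselves. Passing tests therefore demonstrate the method's behaviour
under clean HWE inputs with controlled diversity/divergence, not the full
messiness of published tables.

## Numerical choices and degenerate inputs

* Frequencies are parsed and re-serialised via `repr`, so CSV round trips
  are exact.
* Monomorphic loci contribute LR = 1 exactly (no discriminating
  information) in both engines.
* `classify` is strictly greater-than; LR exactly at the threshold is an
  exclusion.
* Pruning with a threshold below the minimum pairwise θ̂ is the identity;
  a zero threshold with strictly positive θ̂ removes nothing (strict stop
  rule).
* Pearson tests refuse inputs with fewer than three points or zero
  variance rather than returning NaN.

## Known limitations

* Presence/absence only: no peak heights, stutter, degradation, or
  simulated dropout/drop-in in the evidence profiles; the dropout
  parameters live solely inside the LR model.
* One unknown contributor in the study designs (the engine's
  `locus_likelihood` accepts more, but that surface is outside the studies
  and lightly tested).
* No co-ancestry (θ = 0) anywhere, and no mixed-group mixtures: all
  contributors and the POI come from the same simulation group.
* Published-table ingestion is format-level only; fetching data and
  auditing source-paper concordance or consent remain manual.
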