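# mixsim

How accurate is forensic DNA-mixture interpretation when the people in the
mixture come from groups with different levels of genetic diversity — or
when the analyst's reference allele frequencies come from the wrong group?

`mixsim` is a simulation pipeline for studying exactly that question. It is
aimed at forensic-genetics and population-genetics researchers who want a
fully scripted, seedable re-analysis environment: it reads (or synthesises)
STR allele-frequency tables, simulates presence/absence DNA mixtures under
Hardy–Weinberg equilibrium, evaluates semi-continuous likelihood ratios
with dropout parameters, and estimates false positive rates and power
across groups, contributor counts, and reference-group choices.

## The model

A mixture profile `G` is the per-locus set union of its contributors'
alleles (no peak heights, no simulated dropout or drop-in). The strength of
evidence that a person of interest (POI) contributed is the likelihood
ratio

```
LR = P(G | Hp) / P(G | Hd)
```

where `Hp` says the POI contributed and `Hd` says an unknown, unrelated
individual contributed in the POI's place; the non-POI contributors are
known under both hypotheses. Per locus, with `D(a)` the probability that
allele `a` dropped out of every carrier (dropout `d_het = 0.01` per
heterozygous allele, `d_hom = 0.0001` per homozygote), a hypothesised
contributor set has likelihood

```
prod over carried a:   (1 - D(a))  if a observed,   D(a)  otherwise
  x  c * p_a           per observed allele carried by no one (drop-in, c = 0 by default)
  x  (1 - c)           when no drop-in is needed
```

and the unknown under `Hd` is summed over all genotypes weighted by their
Hardy–Weinberg probabilities (θ = 0). `LR > 1` (strict) counts as an
inclusion; the false positive rate (FPR) is the fraction of POI-absent
mixtures crossing the threshold, and power is the fraction of POI-present
mixtures doing so.

Around that core sit the population-genetic pieces the study design needs:
genetic diversity (average expected heterozygosity `1 − Σ p_i²` over loci),
pairwise Weir–Cockerham F_ST, iterative F_ST-threshold panel pruning, a QC
ladder for published frequency tables (13-core-CODIS completeness, locus
sums within [0.99, 1.01]), and a synthetic-panel generator that hits any
diversity target to 1e−9 and produces Balding–Nichols-diverged neighbours
with known expected F_ST.

## Worked example

```python
import mixsim as mx

panel = mx.make_panel(
    mx.SynthPanelSpec(diversity_targets=mx.evenly_spaced_targets(5), seed=7)
)
result = mx.run_correct_reference_study(panel, contributors=(2, 6),
                                        n_reps=5000, seed=11)
frame = result.to_frame()
print(frame[~frame.poi_present][["group_id", "contributors", "rate"]]
      .to_string(index=False))
r, p = mx.correlate_fpr_diversity(result, 6)
print(f"k=6 FPR vs diversity: r = {r:.3f}, p = {p:.2e}")
```

prints

```
   group_id  contributors   rate
G01_d0.6700             2 0.0000
G01_d0.6700             6 0.0042
G02_d0.7025             2 0.0000
G02_d0.7025             6 0.0026
G03_d0.7350             2 0.0000
G03_d0.7350             6 0.0016
G04_d0.7675             2 0.0000
G04_d0.7675             6 0.0010
G05_d0.8000             2 0.0000
G05_d0.8000             6 0.0000
k=6 FPR vs diversity: r = -0.986, p = 2.00e-03
```

Each `rate` row is a false positive rate: the proportion of 5,000 simulated
mixtures *not* containing the POI that nonetheless produced LR > 1. Two-
contributor mixtures are essentially never misinterpreted; six-contributor
mixtures are, and more often for groups with lower genetic diversity
(`G01`, diversity 0.67, FPR 0.0042) than higher (`G05`, diversity 0.80,
FPR 0.0000) — the negative Pearson correlation on the last line. Power
(POI-present rows, not shown) is 1.0 throughout.

The same machinery runs reference-group mis-specification
(`run_misspecified_study`, every ordered simulation/reference pair) and
threshold sweeps over stored LRs. A thin CLI mirrors the library:

```
mixsim synth-panel --targets 0.67:0.80:15 --seed 11 --out panel/
mixsim qc --in panel/ --loci codis13 --out qc.json
mixsim fst --in panel/ --out fst.tsv
mixsim prune --in panel/ --threshold 0.005 --seed 7 --out pruned.json
mixsim study-correct --config study.yaml --in panel/ --out results/
mixsim report-correlations --in results/
```

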