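# Methods

## Model

`bdmseed` implements a parent-of-origin Bateson–Dobzhansky–Muller (BDM)
viability model for hybrid seeds. A model instance is defined by two
counts: `m ≥ 1` maternal-incompatibility loci (labelled `R`, `S`, …; the
incompatible allele is the selfer-origin allele) and `p ≥ 1`
paternal-incompatibility loci (`A`, `B`, …; the incompatible allele is the
outcrosser-origin allele). The lethality rule is a fixed conjunction on
the gamete pair that forms a seed:

> a seed is lethal iff its maternal gamete carries the incompatible allele
> at **every** maternal locus and its paternal gamete carries the
> incompatible allele at **every** paternal locus.

Assumptions baked into the implementation:

* **Unlinked loci, Mendelian transmission.** Every heterozygous locus
  transmits either allele with probability 1/2, independently across loci;
  no recombination-fraction parameter exists and no gametophytic selection
  acts on pollen.
* **Gametophytic maternal requirement.** Lethality is evaluated on the
  gamete pair, not on the maternal sporophyte. For a heterozygous `Rr`
  mother the gametophytic and sporophytic readings differ; the
  gametophytic one is implemented (it reflects the biology of the
  endosperm's central cell, whose nuclei derive from the same megaspore as
  the egg). The two coincide whenever the mother is homozygous, which
  covers every tester used in the backcross designs the package targets.
* **Binary fate.** A seed is viable or dead; there is no dosage-graded
  severity or partial penetrance.

All model-side probability is carried as `fractions.Fraction`. The
predictions of interest are small rationals (1/16, 3/40, 1/120, …) and the
test suite pins them exactly; floating point appears only at presentation
and in the stochastic simulators.

## Cross engine

`cross(maternal, paternal, model)` enumerates the product of the two exact
gamete distributions, accumulates the lethal mass as the abortion rate and
renormalises viable offspring by `1 − abortion_rate`. Survivor
distributions are kept over **ordered** genotypes (maternal vs paternal
allele tracked per locus) because downstream lethality is
parent-of-origin aware; order-insensitive views are derived on demand. A
fully lethal cross returns an empty, explicitly flagged survivor map so
callers cannot silently draw offspring from it. The unconditioned zygote
distribution (selection switched off) is exposed separately.

RIL construction (`advance_ssd`, `ril_panel_distribution`) models
single-seed descent: each line advances one selfing generation by drawing
from the survivor distribution of its self-cross, so viability selection
acts at every generation. The generation count is a free parameter (the
published RIL panel's depth is not fixed by the analyses the package
reproduces); six generations — a typical RIL depth — is the default in
examples and tests. Selection can be disabled to obtain the neutral
single-seed-descent baseline, under which each paternal locus fixes the
incompatible allele with probability → 1/2 and the fully incompatible
`ABC` line class approaches 1/8; with selection this class is strictly
purged every generation and the majority of deep lines trigger no
abortion at all: at generation 6 the exact fraction of lines still able to
trigger > 0 abortion is 47851/655360 ≈ 7.3%, well below the 1/8
no-selection bound (computed, not assumed — see the cross-engine tests).

## F2 class distribution and survivor conditioning

The theoretical distribution of F2 plants over abortion-rate classes is
computed in four exact steps: form the F1 (outcrosser seed parent ×
selfer pollen donor), self it, keep the **survivor** genotype
distribution, and classify each genotype by its pollen lethal fraction on
the tester (default: the pure selfer, homozygous for `R` with no
`A/B/C` alleles; arbitrary testers are supported).

Survivor conditioning is the one modelling step that is easy to miss: the
F2 plants that can be phenotyped as pollen donors are, by construction,
seeds that escaped the F2 abortion episode, and the dead class is exactly
the one enriched for `R`-plus-`ABC` combinations. Conditioning therefore
shifts the class distribution — the fully aborting class is 1/120
conditioned versus 1/64 unconditioned for `p = 3`. Both variants are
exposed (`conditioned=` flag); the conditioned one is the default and a
regression test pins the difference.

## Inference

* **Class assignment.** Each plant (n seeds scored, k aborted) is assigned
  the class `c` maximising the binomial likelihood at the noise-adjusted
  rate `c(1−ε) + (1−c)ε`. The mis-scoring rate ε (default 0.01) keeps the
  boundary classes 0 and 1 at nonzero likelihood; exact ties break toward
  the smaller class, and as `n → ∞` the rule is consistent for data
  generated at any class rate.
* **Goodness of fit.** Pearson chi-square of class counts against the
  model's class distribution, after pooling adjacent classes (ascending
  rate order) until every expected count reaches `pooling_min`
  (default 5); df = pooled classes − 1. The pooling map is part of the
  result so analyses stay auditable. With class counts drawn from the true
  class distribution the test is well calibrated (measured type-I error
  0.058 at α = 0.05, 250 plants, 1000 replicates).
* **A calibration caveat.** The *full* pipeline — seed-level binomial
  noise, then maximum-likelihood binning, then chi-square — is mildly
  anticonservative at moderate seed counts, because binomial overlap
  between neighbouring classes (0 ↔ 1/8 ↔ 1/4) makes the induced
  assigned-class distribution differ slightly from the theoretical one:
  at 30 seeds per plant and ε = 0.01 the induced mismatch corresponds to a
  noncentrality of ≈ 1.0 for a 250-plant panel (≈ 13% rejection of the
  true model). The distortion oscillates with the integer seed count
  (assignment boundaries are knife-edge near n ≈ 20) and vanishes by
  ≈ 100 seeds per plant, where assignment is essentially error-free.
  Practitioners comparing a fitted model's absolute p-value to α should
  prefer many seeds per plant; model *ranking* is far more robust, see
  below.
* **Model selection.** Candidates are ranked by p-value; the maximum wins
  and `p > α` (default 0.05) flags candidates the data cannot reject. On
  simulated 250-plant × 30-seed panels generated under `p = 3`, the
  three-locus model is selected over the two-locus model in 100/100
  replicates and survives the α = 0.05 rejection check in the large
  majority, because the two-locus model predicts no 12.5% class and seven
  times too many fully aborting plants.
* **Binary trait.** `binarize_abortion` codes 1 for plants with abortion
  rate strictly above 2% (configurable), the preparation step for
  downstream QTL mapping, together with the log-rate histogram used to
  justify such a threshold (zero rates fall in a floor bin).
* **Intervals.** Wilson score intervals for abortion proportions
  (scipy's implementation), chosen over Wald for boundary behaviour.

## Synthetic data

The simulator draws F2 genotypes by inverse-CDF sampling from the exact
survivor distribution (no rejection loop), then scores each plant with
binomially distributed aborted-seed counts at the genotype's pollen lethal
fraction passed through the symmetric mis-scoring channel ε. Defaults
describe the emulated experimental conditions: 250-plant panels; seeds per plant
either fixed or truncated-Poisson with mean 25 (a plausible per-plant
scoring scale for this crucifer; the real per-silique counts are not part
of the inputs); ε = 0.01, deliberately below the 2% binarization threshold
so scoring noise alone cannot flip a binary call. F1-selfing seed sets
(default 7 mothers) and RIL panels (single-seed descent with selection,
advanced by genotype-grouped multinomial draws, which is distributionally
identical to per-line draws and fast at 10⁵ lines) round out the designs.
A beta-binomial over-dispersion switch exists for intra-plant correlation
but is off by default — real overdispersion across siliques of one plant
is unknown. All draws flow from a single integer seed through one
`numpy.random.Generator`, so every simulator is bit-reproducible.

What the generator does **not** emulate: maternal-background effects on
abortion severity, linkage between incompatibility loci, segregation
distortion through pollen, per-silique batch structure, and the
out-of-model ≈ 50% abortion observed in the outcrosser-♀ × selfer-♂
direction (attributed to a distinct endosperm mechanism; the BDM model
predicts 0 for that direction and the package does not pretend
otherwise). Tests passing on synthetic panels therefore demonstrate the
correctness and calibration of the machinery under the stated model, not
the truth of the model for any particular dataset.

## Problem sizes and numerics

Exhaustive checks run over all genotypes for every locus configuration
with up to 4–5 total loci (4ᴸ ordered gamete pairs per cross; the
brute-force oracles in the test suite re-enumerate these independently of
the library code). Stochastic bridge tests use 10⁵ draws with 3–4
standard-error tolerances; the model-recovery study uses 100 panels of
250 plants × 30 seeds; chi-square calibration uses 1000 replicates. The
acceptance script averages 200 seeded replicates of the 207-seed
F1-selfing design. Everything runs in seconds on one core; exact
`Fraction` arithmetic makes equality assertions literal, with no numeric
tolerances anywhere in the exact half of the package.

## Known limitations

* The maternal requirement is gametophytic by design; sporophytic
  maternal control would need a different rule for heterozygous mothers.
* No linkage, imprinting mechanism, dosage sensitivity or partial
  penetrance; the endosperm 2m:1p dosage is the biological motivation for
  the parent-of-origin rule but is not modelled mechanistically.
* Cross outcomes are expectations — finite-population drift within a
  cross is only represented in the stochastic simulators, not in the
  exact engine.
* Absolute goodness-of-fit p-values from plant-level binning are mildly
  optimistic against rejection at moderate seed counts (see the
  calibration caveat above).
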