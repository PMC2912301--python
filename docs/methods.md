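# Methods

This note documents the statistical model implemented by `gbpcr`, the
defaults it ships, the synthetic-data generators used to exercise it, and
the numerical and design choices made where more than one reasonable option
existed.

## Model

### Observation layer

Genotype calls are collapsed to `y ∈ {NoCall, Het, NHet}`. Conditional on
the normal-cell genotype `x ∈ {Het, Hom}` and the aberration class `w` of
the surrounding region, calls are independent categorical draws from the
emission table `P(y | x, w)`. The abnormal-cell genotype is a deterministic
function of `(x, w)` — a loss turns Het into a single-allele state read as
NHet, a homozygous deletion leaves nothing to call — so it is composed into
the table analytically rather than represented at run time. Two structural
facts are built in:

- the gain class shares the normal class's rows (`P(y|x, 1) = P(y|x, 0)`):
  duplicating one allele does not change which genotype the caller sees;
- the IBD/UPD class has a single unconditional row `P(y | w = -3)`: inside a
  copy-neutral LOH region the detected genotype no longer depends on the
  normal-cell genotype (in a somatic isodisomy it is a duplicated single
  allele; in autozygosity/germ-line isodisomy conditioning is vacuous).

Unknown `x` is marginalized with the per-SNP heterozygosity prior ν_i taken
from array annotation: `P(y|w, ν) = ν P(y|Het,w) + (1-ν) P(y|Hom,w)`.

**Shipped emission defaults** (`src/gbpcr/data/default_emission_params.tsv`)
are implementation defaults chosen to encode the qualitative structure
above for mixed tumor/normal samples — heterozygosity survives a loss
rarely (`P(Het|Het,-1) = 0.05`), Hom is essentially never read Het,
homozygous deletion inflates NoCall to 0.6, one-allele amplification
pushes Het toward NHet (`P(Het|Het,2) = 0.45`), the IBD/UPD row carries 2%
residual Het and the normal-region NoCall rate. They are meant to be
replaced by per-platform estimates from paired normal/tumor samples
(`--emission-table`); no published per-platform values are reproduced here.

### NoCall sample-noise adjustment

NoCall rates mix a technical component with a per-sample noise factor, so a
table estimated on reference samples misstates a noisy sample's NoCall
behavior — and an inflated sample NoCall rate mimics homozygous deletion
and biases IBD/UPD calls. With `P(x=Het) = 1/2` for a generic SNP, the
reference class-level rate is `r2(z) = (P(NoCall|Het,z) + P(NoCall|Hom,z))/2`;
the sample's `r1(z)` is the observed NoCall frequency in regions
preliminarily classified as `z` from the CN profile alone (classes with
fewer than 100 SNPs fall back to the genome-wide frequency — rare classes
give unstable estimates). Each NoCall entry is rescaled by
`min(1, r1(z)/r2(z))` (the cap guards pathologically noisy samples); the
IBD/UPD row uses the normal-class factor, since its NoCall rate tracks the
normal-region rate. Het/NHet entries are rescaled proportionally so rows
stay stochastic — this preserves their odds while absorbing the adjusted
NoCall mass; the alternative (shifting the freed mass to one outcome) would
distort the Het/NHet balance for no reason.

### Class priors from the copy-number profile

The segmented log2ratio profile enters only through the prior. Estimated
segment levels, pooled at dataset level and weighted by segment length, are
fitted with a 1-D normal mixture by EM (3–5 components; deterministic given
the initialization; component sds floored at 1e-3). The heaviest component
is anchored to normal copy number (cn2) and neighbours labeled by rank
(cn0, cn1 below; cn34, amp above). The level axis is then cut into five
intervals, one per event code, at the equal-Mahalanobis intersection of
adjacent components, `(μ₁σ₂ + μ₂σ₁)/(σ₁+σ₂)`; missing outer components fall
back to μ_cn1 − 3σ_cn1 and μ_cn34 + 3σ_cn34. A packaged reference mixture
(idealized log2(CN/2) positions: −2, −1, 0, 0.8, 1.6; sd 0.15–0.2) serves
when no dataset-level fit is wanted and as the generators' level
dictionary.

A profile segment with posterior mean μ̂ and variance ρ̂ gets prior mass
`P(Z = z) = Gaussian(μ̂, ρ̂)`-mass of interval z (a point mass at ρ̂ = 0).
Model levels then allocate classes:

- **Model 1** (CN events only): classes {−2, −1, 0, 2}, normal and gain
  pooled;
- **Model 2** adds IBD/UPD: `π(−3) = p_upd · P_Z(0)`,
  `π(0) = (1 − p_upd) · P_Z(0)` — an IBD/UPD event exists only at normal
  copy number;
- **Model 3** splits normal and gain; `p_upd` multiplies only the CN=2
  component mass, leaving the gain mass untouched (same rationale).

Each model is nested in the next: Model 2 at `p_upd = 0` is Model 1, and
Model 3 with zero gain mass is Model 2 — the test suite checks both
identities exactly. `p_upd` defaults to 10⁻⁴ per SNP; published estimates
from homozygosity surveys place it at ~10⁻³ for ≥50-SNP regions down to
~10⁻⁴ for multi-megabase regions, and both magnitudes are sensible
settings (`--p-upd`).

### Segmentation posterior

The aberration profile is piecewise constant with `K ~ ∝ 1/k²` on
{1..k_max} (heavier penalty on extra segments than a uniform prior, to
suppress false discoveries) and boundaries uniform over ordered interior
positions given K. The single-segment evidence is

```
A(i, j) = Σ_w  π̄_(i,j](w) · Π_{l=i+1}^{j} P(y_l | w, ν_l)
```

with `π̄` the arithmetic mean of the per-SNP priors over the candidate
segment. Forward/backward dynamic programming over A yields `P(K|y)`, the
per-position breakpoint posterior `p_i`, and the evidence, all exactly;
per-segment class posteriors for fixed boundaries are
`∝ π̄(w)·exp(loglik)`. Everything runs in log-space with streaming
log-sum-exp (products of thousands of per-SNP probabilities underflow
linear space); SNPs with zero probability under a class veto that class for
every segment containing them via a cumulative zero-count, since −∞
cumulants cannot be differenced. The O(k_max·n²) kernels are numba-compiled
with an equivalent numpy fallback; a 2520-SNP chromosome at k_max = 50
takes a few seconds, and per-chromosome (or per-arm) processing is the
supported scale.

**Candidate-segment prior.** Averaging the per-SNP priors arithmetically is
a genuine design choice. A per-SNP *product* would charge `p_upd` once per
SNP and make copy-neutral LOH — invisible in the CN profile — undetectable,
defeating the model's purpose; the arithmetic mean charges one `p_upd`
factor per segment, matching the Model-2 prior semantics. The cost of the
choice is that boundary evidence comes almost entirely from the LOH
likelihood: a candidate boundary between profile segments of identical
genotype behavior (normal vs gain) adds no evidence, so pure-CN transitions
are typically not split and a planted gain can stay merged with flanking
normal segments (its class only surfaces when the boundary estimate happens
to isolate it). Gains are fundamentally CN-driven calls; consumers who need
them delimited should keep the CN profile's own segmentation alongside the
output. A second consequence is identifiability at boundaries: a
normal-to-loss boundary is located only up to the nearest heterozygous SNP,
since homozygous flanks emit identically under both classes — exact
boundary recovery therefore holds only where boundaries are flanked by
informative SNPs, and the likelihood-dominance tests construct exactly that
situation.

### Estimators and calling

- `K̂₀₁` — MAP over `P(K|y)` (0-1 loss; ties to the smaller k);
- `T̂_BinErr` — the k−1 interior positions with the largest `p_i` (ties
  leftmost). High sensitivity, but it harvests near-duplicate positions on
  the shoulders of strong peaks;
- `T̂_PeakMax` — `p` is smoothed with a symmetric moving average
  (half-width 3 SNPs by default; 0 disables), maximal runs above `thr1`
  form peaks, each peak contributes the position of its *raw* maximum, and
  peaks whose raw maximum falls below `thr2` are dropped. Threshold rules:
  `005` = max(0.005, q95(p)); `01` = max(0.01, q95); `01_90` = max(0.01,
  q90); `mad` = median + 3·MAD; explicit numeric thresholds and mixed
  pairs are allowed.
- Classes per segment by MAP; ties go to the class nearest 0, negative
  before positive (conservative calls, deterministic output). A zero
  posterior normalizer — the signature of a missed boundary pooling
  incompatible data — raises a diagnostic naming the segment (CLI exit
  code 3). Adjacent equal-class segments are merged for reporting, with the
  raw segmentation retained.

Coordinates are half-open `(t_{p-1}, t_p]` in SNP-index space internally
and 0-based half-open (BED-style) in all outputs. Autosomes only by
default: the CN = 2 baseline presumes diploidy, which fails on X/Y
(`--include-sex-chromosomes` overrides, with that caveat).

## Synthetic data

`simulate_dataset` draws whole samples from the generative model on a fixed
15-segment, 2520-SNP profile layout (rescalable to any n): normal-cell
genotypes from the het priors, one event code per segment from a
per-segment prior table (consecutive equal draws merge in the truth),
observed calls from the emission table. Two prior designs ship: a diffuse
design whose rows spread mass over 2–3 classes per segment (hard boundary
estimation), and a peaked design with 0.9 on one class per segment (easy).
Segment CN means sit at the mixture mean of the drawn class plus
N(0, 0.05²) jitter — only to avoid degenerate exact-threshold placement —
with posterior variance 0.01.

`simulate_lohcn_sample` plants copy-neutral LOH / loss / gain regions in a
diploid background. SNR is defined as (loss-to-normal level shift)/(per-SNP
noise sd), so sd = 1/SNR with the reference mixture; inside copy-neutral
LOH regions the underlying genotype is forced Hom with residual Het rate
ε = 0.02 by default (the homozygosity-survey convention for IBD regions;
the discrimination study uses ε = 0 to plant literally all-Hom runs). The
profile keeps the true region boundaries, with means either exact
("oracle") or the empirical means of the noised raw values ("noisy");
re-segmenting the raw values is the job of the upstream CN segmenter and is
out of scope here.

Per-SNP het priors default to i.i.d. Beta(1.5, 3.5) (mean ≈ 0.3, with a
tail of nearly monomorphic SNPs) — a stand-in for real array annotation.
What the generators do *not* emulate: probe-level intensity noise, spatial
artifacts, wave patterns in log2ratio, linkage between neighbouring SNPs'
heterozygosity, tumor-content titration, and CN-profile segmentation error
beyond the level noise. Passing tests therefore demonstrate correctness of
the inference machinery under the stated model, not robustness to
real-array artifacts upstream of it.

## Error measures

Segment-number errors (0-1, absolute, squared); boundary measures on the
interior boundary sets — sensitivity `|t̂ ∩ t⁰|/|t⁰|`, FDR `|t̂ \ t⁰|/|t̂|`,
and a binary error defined here as the normalized Hamming distance between
boundary indicator vectors — with exact matching by default and an optional
±window (greedy nearest, each true boundary matched once); per-SNP profile
errors (sum 0-1 error, SSQ on numeric codes, per-class sensitivity/FDR);
and LOH TPR/FPR over SNPs inside/outside true LOH regions ({−3, −2, −1}),
stratified into informative (called) and non-informative (NoCall) SNPs.

## Study scales and observed behavior

The estimator-comparison study defaults to the reduced n = 500 layout with
50 samples (the full 2520-SNP design runs through the same API at a few
seconds per sample). On the diffuse design the peak estimator wins
decisively on profile-level error — roughly 5× lower sum 0-1 error and SSQ
than K̂₀₁/T̂_BinErr, because BinErr's duplicated near-peak picks fragment
segments and break the level calls — while under *exact-match* scoring its
boundary FDR is not lower: BinErr's duplicate shots register exact hits,
and a peak's single maximum is often 1–3 SNPs off (homozygous flanks again)
or merges twin boundaries of 4-SNP segments under smoothing. With windowed
matching the gap narrows but does not reverse under the shipped emission
defaults. Both halves of that comparison are reported by
`scripts/acceptance.py` as measured.

The discrimination study (50-SNP all-Hom runs at normal vs loss CN level,
n = 200, SNR 5, Model 2 defaults, k_max = 20) sits deliberately at the
detection edge: such a run carries ≈ 50 × 0.33 nats of likelihood signal
against ≈ 21 nats of segmentation-plus-`p_upd` prior cost at
`p_upd = 10⁻⁴`, so the measured correct-discrimination rate is ~0.9–1.0
depending on the replicate stream (at `p_upd = 10⁻³`, the magnitude
published surveys associate with 50-SNP regions, it is ~1.0). The loss arm
is essentially always correct.

## Known limitations

- Gains/amplifications are delimited only where boundaries are otherwise
  identifiable (see candidate-segment prior above).
- Boundary locations are identifiable only up to the nearest informative
  SNP.
- No allelic copy number / B-allele frequency modelling; the CN profile is
  trusted as given.
- Whole-genome single-pass DP is quadratic in n; process per chromosome.
- X/Y need a different baseline and are excluded by default.
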