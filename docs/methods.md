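# Methods

## Overview

`ciberdyn` models a dual-guide CRISPRi screen in which every construct
carries two CRISPRi guides and a matched pair of expressed random barcodes:
a 22-nt barcode downstream of the constitutive *UBC6* promoter (the
normalizer, tracking how many cells carry the construct) and a 23-nt
barcode downstream of the *PCL5* promoter (a strong Gcn4 target, tracking
integrated stress response activity). The screen design is eight samples:
pre-induction, post-guide-induction, then low (0.56 μM) and high (14 μM)
sulfometuron methyl at 0.25, 1 and 4 h — seven post-induction ISR
measurements per perturbation.

## Ground-truth model

Each guide has a fitness effect γ (log2 per population doubling, ≤ 0 for
deleterious guides) and a latent ISR activity surface

    a(d, t) = β0 + A · d^h / (d^h + EC50^h) · f(t; τ, α),
    f(t) = (1 − e^(−t/τ)) · ((1 − α) + α e^(−t/(3τ))),

in log2 units relative to the wildtype (negative-control) response at the
same dose and time; controls therefore have an identically zero surface.
`f` rises with time constant τ and, for adaptation fraction α > 0, relaxes
toward (1 − α) of its peak (the relaxation time constant is fixed at 3τ —
slow relative to onset, one fewer free parameter). At d = 0 the surface
reduces to the basal shift β0, which is what the post-induction sample
measures.

Five dynamics classes encode the qualitative phenotype families observed
in such screens, assigned per gene so that guides against the same gene
share a class (defaults in `TruthParams`; all draws are uniform over the
stated ranges):

| class | γ | β0 | EC50 | τ (h) | α | rationale |
|---|---|---|---|---|---|---|
| neutral | 0 | 0 | — | — | 0 | controls and inert guides |
| translation | U(−0.5, −0.1) | −k·γ, k = 2 | 0.5 μM | 0.3–0.6 | 0–0.2 | tRNA charging/processing, Pol III, eIF2(B): ISR tracks the growth defect proportionately |
| pcl5_feedback | 0 | U(0.8, 1.5) | 0.5 μM | fast | 0 | loss of the Pcl5 negative-feedback arm: activation without growth cost, undamped |
| ribi | U(−0.5, −0.15) | U(−1.5, −0.6) | 0.5 × **4.5** μM | 1.0–1.5 | 0–0.1 | ribosome biogenesis: low basal ISR, ~4.5-fold dose-sensitivity shift (within the observed 4–5-fold), slow onset |
| proteasome | U(−0.35, −0.05) | U(−0.8, −0.3) | 0.5 × 2 μM | 0.6–1.0 | 0.2–0.4 | weaker, damped intermediate |

Amplitudes A are U(1.5, 2.5) log2 (U(2, 3) for pcl5_feedback). The
translation-class EC50 of 0.5 μM places the low dose near half-maximal
response, matching a regime in which the low dose is clearly inducing but
not saturating. A dual-guide perturbation is additive in latent activity
(a1 + a2 + η, η = 0 by default) and in fitness (γ1 + γ2).

**Reporter saturation.** A transcriptional reporter has a finite dynamic
range, and dual-guide phenotypes in this kind of screen fall within the
range delineated by single guides rather than multiplying without bound.
Latent activity is therefore mapped to expression through a smooth clamp in
linear space, `expr = 1/(2^−a + 2^−5) + 2^−5` (configurable floor/ceiling
of ±5 log2 ≈ 32-fold), applied identically to the expression model and to
the recorded truth, so the truth table is exactly the estimand of the
assay. Without this transfer, pairs of two strong activators would command
hundreds-fold reporter induction and, through amplicon competition, starve
every other construct of reads.

## Count model

At `elapsed_h` hours after guide induction a construct's frequency is
proportional to `f0 · 2^((1+γ)·elapsed/t_d)` with doubling time t_d = 2 h
and a log-normal initial representation f0 (σ = 0.5 log2, the
transformation-bottleneck spread). The default induction window is 8 h —
four population doublings, the effective exponential growth a culture
traverses between induction and harvest when it is grown from low to
mid-log density (clock time is longer, but growth beyond mid-log is not
exponential). An optional dose-dependent growth penalty during treatment
exists and is off by default, as fitness phenotypes are referenced to the
induction window.

Each of the two reporter amplicons receives half the per-sample sequencing
depth (default 2×10⁶ reads/sample total), allocated by expression share
within the reporter. Counts are negative binomial with dispersion φ = 0.05
(variance μ + φμ²), realized as a gamma–Poisson mixture whose gamma factor
is **shared between the two reporters of a construct within a sample**:
clone-abundance fluctuations (growth and harvest stochasticity) hit both
barcodes of the same cells equally and cancel in the matched PCL5:UBC6
ratio, which is the design rationale for dual reporters. Marginal counts
are exactly NB(μ, φ); only the ratio enjoys the cancellation. Residual
per-amplicon noise is Poisson.

Short reporter reads are `[8-nt UMI][1 fixed base][20-nt reporter
anchor][barcode][constant tail]`, emitted at a fixed 75-nt read length with
per-base substitution errors (default 0.1%) and Poisson PCR duplication of
each molecule's UMI. Long construct reads interleave five fixed 20-mer
anchors with the two protospacers and the two barcodes; a 1% chimera rate
replaces the PCL5-side barcode with that of another construct, creating
novel barcode pairings that mapping must reject. Anchor sequences are the
package's own fixed 20-mers, configurable for real data; reporter identity
is encoded by the anchor.

## Inference

Per barcode clone and sample, ISR is `log2((c_PCL5+ε)/(c_UBC6+ε))` with
ε = 0.5 (the half-count pseudocount also minimizes the log bias of Poisson
counts) and delta-method variance `(1/ln2)²·(1/(c_PCL5+ε)+1/(c_UBC6+ε))`;
growth is the log2 change of the clone's share of total UBC6 counts versus
the pre-induction sample. Clones of one perturbation are combined by
inverse-variance weighting.

The delta-method variance reflects counting noise only, so a global
variance-inflation factor is estimated from the weighted residual scatter
between clones of the same perturbation and sample (pooled over all
perturbations with ≥ 2 clones, floored at 1, separately for ISR and
growth) and multiplied into clone variances before weighting. In practice
the ISR inflation is ≈ 1 (the matched ratio cancels clone noise) while the
growth inflation absorbs the NB overdispersion (≈ 1 + 2φ·μ̄), keeping Wald
z-scores calibrated — verified by the null-calibration test.

Estimates are centred per sample on the negative-control (HO × HO)
perturbations, median by default; the median of the controls is exactly
zero afterwards (the construct generator keeps all control × control pairs
fully barcoded, and their odd count — 15 pairs from 6 control guides —
makes the centred median exact in floating point). Perturbations with
fewer than 2 barcode clones are dropped (configurable), then two-sided
Wald p-values get Benjamini–Hochberg correction across perturbations
within each sample.

Dynamics readouts are differences of per-sample estimates (dose contrasts
at a timepoint, time contrasts within a dose) with standard errors in
quadrature — matching figure-level comparisons rather than a joint
time-course fit, which is deliberately out of scope. Single-guide
phenotypes are inverse-variance means over a guide's pairings with
negative-control guides (each non-control guide gets ≥ 3 control partners
by construction); interactions are η̂ = pair − (g1 + g2). Guides with
protospacer GC < 25% are flagged (strict inequality; flagging, not
deletion, keeps counts auditable).

## Barcode mapping and counting

Long-read parsing matches anchors within a substitution budget (default 1)
at the fixed layout offsets, falling back to a Hamming scan; protospacers
resolve to the unique nearest library guide (ties fail as ambiguous).
Barcode pairs supported by more than one distinct guide pair are dropped
as ambiguous — never majority-voted, because assignment errors propagate
multiplicatively into phenotypes — and pairs with support < 3 are dropped
as low-support. This trades recall for precision; precision on simulated
data is ≥ 99% at default noise and chimeric pairings are eliminated by
the concordance and support rules.

Short-read counting collapses exact (barcode, UMI) duplicates per sample
(no 1-mismatch UMI clustering: per-barcode depth is modest and clustering
adds bias), making counts idempotent under re-reading a file. Barcodes
within one mismatch of exactly one known barcode are rescued; ties stay
unassigned.

## Validation utilities

Plate-reader growth curves are fit to the logistic
`N(t) = K/(1 + ((K−N0)/N0)e^(−rt))` (initialized from the curve maximum,
first positive reading, and early log-linear slope; bounded least squares)
and summarized by the closed-form area under the curve on [0, t_end],
evaluated in an overflow-safe form; near-constant curves return the flat
limit (r = 0, AUC = c·t_end) and degenerate data raise an error rather
than fitting silently. qPCR fold changes use the efficiency-corrected
ΔΔCt method, `efficiency^(−ΔΔCt)`, with efficiency 2 by default and
configurable since single-assay efficiencies are rarely calibrated.

## What the simulation does and does not emulate

The generator reproduces the statistical structure the inference relies
on: barcode-level replication, fitness-driven frequency drift, matched
dual-reporter expression with shared clone noise, dose/time ISR dynamics
classes, sequencing error, PCR duplication, and chimeric long reads. It
does not model sequence-dependent guide efficacy, cell-cycle or lag-phase
effects, indels (substitution errors only — real long-read pipelines need
indel-aware matching), UMI saturation at extreme depth, or batch/replicate
structure (the design is single-replicate, as is common for this assay).
Passing recovery tests therefore demonstrates correctness of the
estimators under this noise model, not robustness to every artifact of
real libraries.

## Numerical and design choices

- Default problem sizes: the reference analysis uses 230 guides (6
  controls), 5,000 guide pairs, 3 barcodes per pair (5% singletons) and
  2×10⁶ reads/sample; read-level checks run on a 60-guide, 800-pair
  library, sizes at which every stage's behaviour is already asymptotic.
- Determinism: a `SimConfig` seed fully determines all outputs;
  derived seeds (+1, +2, …) separate the count, short-read and long-read
  streams.
- Degenerate inputs: zero sequencing depth warns and returns zero counts;
  empty read sets warn and return empty maps; missing pre-induction sample
  or absent controls raise configuration errors.
- Tie-breaks: equal-distance protospacer or barcode matches are treated as
  failures/unassigned rather than resolved arbitrarily.
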