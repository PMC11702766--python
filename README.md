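# ciberdyn

Simulation and inference for **dual-reporter CiBER-seq screens** of
integrated stress response (ISR) dynamics in budding yeast.

CiBER-seq (CRISPR interference with barcoded expression reporter
sequencing) reads out a molecular phenotype — here, activity of the ISR —
across thousands of genetic perturbations in a single bulk RNA sequencing
sample. Each dual-guide CRISPRi construct carries two matched random
barcodes expressed from divergent promoters: a *PCL5*-promoter barcode
(a strong Gcn4 target, reporting ISR activity) and a *UBC6*-promoter
barcode (constitutively expressed, tracking cell number). Treating cells
with titratable doses of sulfometuron methyl (SM, an inhibitor of
branched-chain amino acid synthesis) and sampling a dose-by-time grid turns
ISR *dynamics* — sensitivity, onset, and adaptation — into a measurable,
multi-dimensional phenotype per perturbation.

`ciberdyn` is aimed at method developers and screen analysts who need a
ground-truthed, end-to-end test bed for this class of experiment: a
generative model with known per-guide dynamics, the read-level
bioinformatics (barcode-to-guide assignment, UMI-deduplicated counting),
and the statistical inference that turns counts into phenotypes.

## The model and estimators

**Ground truth.** Each guide *g* carries a fitness effect γ_g (log2 per
doubling) and a latent ISR activity surface over dose *d* (μM SM) and
treatment time *t* (h):

    a_g(d, t) = β0_g + A_g · d^h / (d^h + EC50_g^h) · f(t; τ_g, α_g)
    f(t) = (1 − e^(−t/τ)) · ((1 − α) + α·e^(−t/3τ))

a Hill dose response times a saturating onset that relaxes toward (1 − α)
of its peak when the adaptation fraction α > 0. Guides belong to dynamics
classes — neutral, translation-limiting (β0 = −k·γ, proportionate growth
and ISR effects), *PCL5*-feedback loss (activation without growth cost),
ribosome biogenesis (reduced basal ISR, EC50 shifted ~4.5-fold, slowed
onset), and proteasome (a weaker, damped version). Pairs are additive in
latent activity (plus an optional interaction η), then passed through a
saturating reporter transfer with a finite dynamic range.

**Counts.** Construct frequencies drift as 2^((1+γ)·elapsed/t_d); the PCL5
reporter is expressed at 2^a per cell against a constant UBC6 normalizer;
counts are negative binomial with dispersion φ, realized as a gamma–Poisson
mixture whose gamma factor is shared between a construct's two reporters
within a sample (clone-abundance noise cancels in the matched ratio — the
reason the dual-reporter design has low background).

**Inference.** Per barcode clone and sample,

    ISR:    r = log2((c_PCL5 + ε) / (c_UBC6 + ε))
    growth: log2 change of the clone's UBC6 share vs the pre-induction sample

with delta-method variances, inverse-variance weighting across a
perturbation's barcode clones (after estimating a residual variance
inflation from between-clone scatter), median centring on negative-control
(HO × HO) perturbations, a ≥2-barcode filter, and Wald z / Benjamini–
Hochberg q per sample. Dose and time contrasts, single-guide phenotypes
from guide × control pairings, and pair interactions η̂ = pair − (g1 + g2)
are computed downstream.

## Worked example

```python
import numpy as np
from scipy import stats
from ciberdyn import (SimConfig, default_design, generate_constructs,
                      generate_guide_library, generate_truth)
from ciberdyn.simulate import simulate_screen
from ciberdyn.inference import infer_phenotypes
from ciberdyn.dynamics import single_guide_phenotypes, rank_separation

library = generate_guide_library(n_guides=230, n_controls=6, n_genes=185, seed=1)
constructs = generate_constructs(library, n_pairs=5000, seed=2)
truth = generate_truth(library, seed=3)
sim = simulate_screen(library, constructs, truth, default_design(),
                      SimConfig(rng_seed=4, library_size_per_sample=2_000_000))

pheno = infer_phenotypes(sim.counts, sim.manifest)
m = pheno.merge(sim.truth_phenotypes, on=["perturbation", "sample_id"])
print(f"{m.perturbation.nunique()} perturbations x {m.sample_id.nunique()} post-induction samples")
print(f"ISR recovery:    r = {stats.pearsonr(m.isr_true, m.isr_log2fc)[0]:.3f}, "
      f"RMSE = {np.sqrt(np.mean((m.isr_log2fc - m.isr_true)**2)):.3f}")
g = m.dropna(subset=["growth_log2fc"])
print(f"growth recovery: r = {stats.pearsonr(g.growth_true, g.growth_log2fc)[0]:.3f}")

singles, _ = single_guide_phenotypes(pheno, sim.manifest, library.control_ids)
wide = singles.pivot_table(index="guide", columns="sample_id", values="isr_log2fc")
wide["class"] = truth.guides["class_label"].reindex(wide.index)
ddose = wide["high_1h"] - wide["low_1h"]
for cls in ["translation", "ribi"]:
    sel = wide["class"] == cls
    print(f"{cls:12s} n={sel.sum():3d}  low-dose ISR median = {wide.loc[sel,'low_1h'].median():+.2f}  "
          f"dose contrast (1 h) median = {ddose[sel].median():+.2f}")
_, p = rank_separation(ddose[wide['class']=='ribi'], ddose[wide['class']=='translation'])
print(f"rank test (ribi dose contrast > translation): p = {p:.1e}")
```

prints:

```
4759 perturbations x 7 post-induction samples
ISR recovery:    r = 0.986, RMSE = 0.235
growth recovery: r = 0.960
translation  n= 71  low-dose ISR median = +1.44  dose contrast (1 h) median = +0.66
ribi         n= 38  low-dose ISR median = -0.77  dose contrast (1 h) median = +0.96
rank test (ribi dose contrast > translation): p = 1.0e-09
```

Read it as: across ~4,800 dual-guide perturbations measured seven times
each, the pipeline recovers the simulated ISR surface to r = 0.99 with
0.24 log2-unit error and fitness to r = 0.96. Translation-limiting guides
are strongly ISR-activated already at the low SM dose, while
ribosome-biogenesis guides sit *below* baseline at low dose but respond
disproportionately at high dose — the dose-sensitivity shift the dynamics
contrasts are built to detect, and the ranks separate decisively.

A CLI mirrors the pipeline stages for file-based work
(`ciber generate / assign / count / infer / dynamics / growth-fit / qpcr`;
`cibersim generate` is an alias).

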