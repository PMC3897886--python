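# blastoderm-atlas

Quantitative spatio-temporal atlases of segmentation-gene expression in
dipteran blastoderm embryos.

## The problem

In early fly and midge embryos, segmentation genes are expressed in
spatial patterns along the antero-posterior (A-P) axis that change from
one nuclear division cycle to the next: the gap gene *hunchback* (Hb)
forms a broad anterior domain, the pair-rule gene *even-skipped* (Eve)
resolves into a series of stripes, and both patterns shift anteriorly
over time.  Comparing these dynamics between species (here: a moth-midge-
like pattern with six pre-gastrulation Eve stripes and large anterior
shifts, versus a fruit-fly-like pattern with seven stripes and smaller
shifts) requires turning noisy per-embryo confocal images into a single
*integrated atlas*: one averaged expression profile per gene per
developmental time class, on a common spatial scale.

This package implements the full quantification chain:

1. **Segmentation** — watershed splitting of the nuclear counterstain,
   mean fluorescence per nucleus, pixel → % egg length (EL) conversion.
2. **Profile extraction** — a lateral strip covering 10% of embryo
   height; quadratic background-floor estimation and subtraction; A-P
   orientation from the anterior Hb domain.
3. **Staging** — cleavage cycles C10–C14A from nuclear density
   (density doubles per cycle); C14A time classes T1–T8 from the stripe
   formation sequence, verified by clustering: all embryo pairs are
   fitted against each other with quadratic splines, the upper-tail
   probability of the resulting χ²_ν statistic defines a distance in
   [0, 1], and mean-linkage agglomeration — refined by the stripe-1/6
   intensity- and width-ratio signature merged into one variable by PCA —
   is cut at the desired number of classes.
4. **Registration** — per embryo, a least-squares quadratic spline of the
   Eve profile; its extrema are ground control points (GCPs); a 1D affine
   map x → a·x + b per embryo aligns shared GCPs to the per-class mean
   (two-pass, cohort-mean map gauge-fixed to the identity).  The same map
   is applied to every channel.
5. **Integration** — 100 A-P bins, averaged across embryos, Gaussian-
   smoothed with a kernel of three internuclear spacings, scaled to a
   0–255 relative range per gene.
6. **Features** — stripe peak positions from a quadratic-spline refit
   (exact derivative roots), half-maximum domain boundaries after a
   dyadic Haar denoising pass, stripe identity tracking across classes,
   total anterior shifts in % EL and in nuclei, Eve domain widths
   (peak of stripe 1 to peak of stripe 6 or 7), and the two-sided Welch
   t-test, t = (m_a − m_b)/√(s_a²/n_a + s_b²/n_b) with
   Welch–Satterthwaite degrees of freedom, on unranked and ranked widths.

Because no public dataset of this kind exists, the package ships a
first-class synthetic-data generator (`blastoderm_atlas.synthetic`):
stripes are Gaussian bumps, domains are products of logistic sigmoids,
so every ground-truth peak and half-maximum edge is analytic.  Cohorts
carry per-embryo affine positional jitter, a paraboloid staining
background and per-nucleus Gaussian noise, and can be rendered to 16-bit
TIFF images.  Every downstream stage is validated by parameter recovery
against this ground truth.

## Worked example

```python
from blastoderm_atlas import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(cohort=CohortConfig(n_embryos_per_class=30, seed=42))
result = run_pipeline(config, out_dir="results/clogmia")
print(result.shifts.round(2))
```

prints the per-stripe anterior shifts recovered from the integrated
atlas (this exact table is produced by `analysis/04_build_atlases.py` +
`analysis/05_stripe_dynamics.py` at seed 42):

```
 stripe appearance_class final_class  shift  shift_nuclei
      1               T2          T8   5.61          5.95
      2               T3          T8   5.98          6.33
      3               T5          T8   6.67          7.06
      4               T6          T8   4.84          5.12
      5               T6          T8   4.72          5.00
      6               T5          T8   3.71          3.93
```

Each row is one Eve stripe: the class at which it first resolves, and
how far its peak travels toward the anterior between then and the end of
T8 — in % egg length and in units of the cohort's mean internuclear
spacing.  The anterior stripes shift the most; stripe 6, which forms de
novo near the posterior pole, shifts the least.  The recovered mean
shift is ~5.6 nuclei for the midge preset versus ~2.3 for the fly preset
(whose shifts instead increase posteriorly), while the midge Hb
posterior boundary drifts only ~2% EL — so Eve stripe 2 overtakes the Hb
boundary during C14A.  The Eve domain width (stripe 1 to 6, ~50% EL)
stays constant across T5–T8 and exceeds the fly's stripe-1-to-7 extent
(~36% EL); the Welch test on those widths prints
`t = 22.81, df = 3.21, p = 1.16e-04`.

The numbered drivers under `analysis/` run the same chain step by step
(simulate → segment → stage → register/integrate → stripe dynamics) and
write their tables under `results/`.

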