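# Methods

## The kinetic model

Lipid redistribution after a plasma-membrane (PM) pulse is modelled as a
linear compartmental system over the organelles {PM, Endo, Golgi, ER,
Mito}. The state vector x(t) holds the fraction of total lipid signal per
compartment and obeys

    dx/dt = A x,
    A[j,i] = k_{i->j},   A[i,i] = -Σ_j k_{i->j} - k_dec,

with first-order transport rate constants k (min⁻¹) and an optional
uniform content-decay rate k_dec. Two structural assumptions shape the
preset topologies: direct PM→ER transfer is exclusively non-vesicular
(lipid-transfer proteins at contact sites), and the PM→Endo→Golgi→ER chain
is exclusively vesicular. Anterograde ER→PM flux is captured by a single
summary rate k_ER–PM that lumps vesicular and non-vesicular modes.

Presets:

| id | structure |
|----|-----------|
| `1a` | PM→Endo→Golgi→ER, PM⇄ER, ER⇄Mito (7 edges) |
| `1b` | 1a + explicit anterograde legs ER→Golgi→Endo→PM (10 edges) |
| `2a`, `2b` | same topologies + uniform content decay fixed from MS |
| `3a` | 2a + endosomal recycling Endo→PM |
| `3b` | 2b (the recycling edge already exists among the anterograde legs) |
| `pm_er` | reduced two-compartment PM⇄ER exchange |

Design choices where the design was genuinely open:

- In the `b` variants the summary rate k_ER–PM is **retained** alongside
  the explicit vesicular legs: it then represents the non-vesicular
  anterograde component, which the explicit legs do not carry. Anterograde
  leg rates are weakly identified from retrograde pulse data; the
  identifiability report flags rates whose Monte Carlo coefficient of
  variation exceeds 0.5.
- Content decay is a *uniform* first-order loss on all compartments with a
  rate fixed externally (from the mono-exponential fit to total
  bifunctional content by MS), not a free parameter — otherwise it trades
  off against every outflux rate.
- Lipid droplets are read out by imaging but not modelled as a kinetic
  compartment; droplet signal is part of the residual.
- Time is minutes throughout; rates are min⁻¹.

Because the system is linear, trajectories are computed exactly as
x(t) = expm(At) x0 — there is no integration error, and solver agreement
with the closed-form two-compartment solution
x_PM(t) = x_eq + (x0 − x_eq)e^(−(k₁+k₂)t), x_eq = k₂/(k₁+k₂) is verified
to 1e-8 in the tests.

Derived quantities: the quasi-equilibrium constant K = k_PM–ER/k_ER–PM
(steady-state ER:PM partitioning) and the non-vesicular share of
retrograde PM exit k_PM–ER/(k_PM–ER + k_PM–Endo).

## Fitting and uncertainty

The objective is the weighted sum of squared residuals
Σ ((model − mean)/sd)² over timepoints and organelles; observations with
zero s.d. get a floor of 1e-3 fraction units. Minimization uses bounded
trust-region least squares (rates in [0, 10] min⁻¹) from 20 (default)
log-uniform starting points over [1e-4, 10] min⁻¹, because rates span
orders of magnitude; the best converged start wins and the whole procedure
is deterministic given a seed. The initial state defaults to the
normalized t = 0 data means and can be overridden.

Uncertainty follows a parametric Monte Carlo scheme: each of 100 runs
(default) resamples every observation from Normal(mean, sd), refits from
the point estimate, and the reported mean ± s.d. per rate is computed over
the run estimates — not from the point fit's covariance. Runs that fail to
converge are dropped with a warning; more than 20% failures is an error.

Conditions are compared by fold change (ratio of rate means with
first-order error propagation) and by Cohen's d,
d = |m_a − m_b|/s_pooled with the classic two-sample pooled s.d.,
classified on half-open intervals: negligible ≤ 0.01 < very small
≤ 0.20 < small ≤ 0.50 < medium ≤ 0.80 < large ≤ 1.20 < very large
≤ 2.00 < huge.

## Signal partitioning

Probability maps (one per organelle marker, values in [0, 1]) are
binarized at 0.5 by default. Pixels in exactly one mask are unambiguous:
they assign their full lipid intensity to that organelle and define its
empirical intensity distribution — a 64-bin histogram over the image's
intensity range with add-one smoothing (so in-range densities never
vanish). Each ambiguous pixel's intensity I is split among its overlapping
organelles with weights proportional to the densities f_o(I); identical
distributions therefore split exactly 50/50, and a winner-takes-all mode
assigns whole pixels to the maximum-likelihood organelle instead.
Pixels outside every mask are unassigned and excluded from fractions;
total intensity (assigned + unassigned) always equals the image sum.
The weighting uses the pixel intensity only — no spatial prior — which is
the simplest defensible reading of distribution-based partitioning.
Organelles with zero unambiguous pixels are excluded from overlap
weighting with a warning; fewer than 50 unambiguous pixels flags the
distribution as unreliable.

## Metabolism from species tables

Bifunctional probes are isobaric with native species whose acyl chains
carry two extra CH₂ groups; the monoisotopic difference between the
diazirine N₂ (28.0061 Da) and C₂H₄ (28.0313 Da) is 25.2 mDa, requiring a
resolving power of m/Δm ≈ 31,700 at m/z 800 — well within ultra-high
resolution FT-MS (420,000 at m/z 800). Classification uses an explicit
boolean column when present, else the formula rule "nitrogen count equals
the class's native count + 2".

The supplied-species fraction of the bifunctional pool is computed per
replicate and summarized as mean ± 95% t-distribution CI across
replicates. Turnover is fitted as f(t) = f₀e^(−k_met·t). Two estimators
are provided:

- `fit_monoexponential`: unweighted least squares on one series, s.e. from
  the fit covariance (an optional sigma enables weighting).
- `fit_monoexponential_by_replicate`: fits each replicate separately and
  reports the mean rate with s.e. = sd/√n across replicates. This is the
  pipeline default when replicates exist, because the covariance s.e. of a
  single fit to the mean curve underestimates between-replicate
  variability (in calibration simulations its z-scores have s.d. ≈ 1.4),
  whereas replicate-level s.e. is honestly t-distributed. Note that with
  n = 6 replicates a ±2 s.e. interval has ≈ 90% nominal coverage, not 95%.

A species whose total decline is below 5% is not fitted (near-stable case,
e.g. sphingomyelin, whose supplied fraction stays above 90%); linear
interpolation is reported instead. Rising fractions clip k_met at 0 with a
warning. The transport/metabolism ratio k_PM–ER/k_met uses first-order
error propagation, which matches a direct sampling oracle within 10% for
coefficients of variation below 0.2; rate correlations across species use
OLS/Pearson.

## Synthetic data

The generators emulate the statistical structure the analysis assumes:

- **Time courses**: 5 timepoints {0, 4, 30, 120, 1440} min (bracketing the
  early 4/30-min readouts and the 24-h endpoint), 5 fields of view per
  timepoint, Gaussian per-field noise on fractions (default s.d. 0.02)
  truncated to [0, 1]; means/s.d./n recorded raw, never renormalized.
- **Images**: organelle regions as rectangles/disks with designed overlap;
  each overlap pixel is truly owned by exactly one organelle (drawn
  uniformly among its markers), with intensity from the owner's level plus
  Gaussian noise (s.d. = 10% of local mean) or Poisson noise. Ground-truth
  per-organelle totals are returned for recovery checks.
- **MS tables**: the supplied species holds e^(−k_met·t) of the
  bifunctional pool (remainder spread over product classes), the pool
  itself is 2 mol% of the lipidome at t = 0 (within the 1–3% loading
  regime of cyclodextrin delivery) decaying at the content-decay rate;
  6 replicates (three biological × two technical) with multiplicative
  noise of CV 0.1.
- Default rate constants put transport 30× above metabolism
  (k_PM–ER = 0.15 min⁻¹, k_met = 0.005 min⁻¹), inside the observed 10–60×
  separation.

What the generators deliberately do **not** emulate: microscope PSFs and
pixel-classifier errors (probability maps are crisp), photo-crosslinking
chemistry, per-cell heterogeneity (fractions are per field of view),
isotope interference in MS, and correlated noise between technical
replicates. Passing tests therefore demonstrate correctness of the
estimation machinery under the stated noise model, not robustness to every
artefact of real microscopy or spectrometry.

## Numerical choices and limitations

- Exact matrix-exponential propagation; agreement with oracles to ≤1e-8.
- Bounded trf least squares; multi-start count trades runtime for
  robustness (calibration shows failures at the default settings are
  noise-driven, not optimizer-driven).
- Recovery calibration (simulations in the test suite and acceptance
  script): for preset 1a with rates log-uniform in [0.02, 0.6] min⁻¹ and
  noise s.d. 0.02, both PM exit rates land within 25% of truth in ≈90% of
  repetitions; k_met lands within 2 s.e. in ≈90% of runs at replicate CV
  0.1 (see the coverage remark above).
- Identifiability is reported, not enforced: anterograde-leg rates in the
  `b` presets typically exceed the CV flag threshold on retrograde data.
- No nonlinear/saturable kinetics, no spatial modelling, no leaflet
  resolution, no Bayesian posteriors; preset comparison is by objective
  value only.
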