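# lipoflux

Quantitative analysis of interorganelle lipid transport and metabolism in
mammalian cells, from pulse–chase experiments with bifunctional
(diazirine + alkyne) lipid probes.

A lipid probe is delivered to the plasma membrane (PM), and its
redistribution across organelles — endosomes, Golgi, endoplasmic reticulum
(ER) and mitochondria — is followed by fluorescence imaging, while
species-resolved mass spectrometry tracks its metabolic conversion.
`lipoflux` turns those measurements into rate constants:

- **Signal partitioning** — assigns the lipid fluorescence channel to
  organelles using pixel-classifier probability maps. Pixels covered by a
  single organelle mask define per-organelle lipid intensity
  distributions; where masks overlap, each pixel's intensity *I* is split
  between organelles *o* with likelihood weights
  *w\_o = f\_o(I) / Σ f\_o′(I)*. Total intensity is conserved exactly.
- **Compartmental kinetics** — linear first-order transport models
  *dx/dt = A x* over {PM, Endo, Golgi, ER, Mito}, solved exactly by matrix
  exponential. Preset topologies cover retrograde vesicular transport
  (PM→Endo→Golgi→ER), direct non-vesicular PM→ER exchange, a summary
  anterograde ER→PM rate, ER⇄mitochondria exchange, explicit anterograde
  vesicular legs, MS-fixed content decay, and a reduced PM⇄ER model.
- **Fitting and uncertainty** — global bounded least squares with
  multi-start initialization; uncertainty from 100 parametric Monte Carlo
  runs (resample every observation from Normal(mean, s.d.), refit);
  condition comparison by fold change with error propagation and Cohen's
  *d* in pooled-s.d. units (very small > 0.01, small > 0.20, medium > 0.50,
  large > 0.80, very large > 1.20, huge > 2.00).
- **Derived quantities** — quasi-equilibrium constant
  *K = k\_PM–ER / k\_ER–PM* and the non-vesicular share of retrograde PM
  exit, *k\_PM–ER / (k\_PM–ER + k\_PM–Endo)*.
- **Metabolism from MS** — bifunctional vs native species discrimination
  by exact mass (the diazirine N₂, 28.0061 Da, vs two CH₂, 28.0313 Da — a
  25.2-mDa doublet), supplied-species and total-bifunctional fractions
  over time, mono-exponential turnover rates *k*\_met, and the
  transport/metabolism rate ratio.
- **Synthetic data** — generators for time courses, toy organelle images
  and MS species tables with known ground truth, so every stage is
  testable end to end.

## Worked example

```python
import lipoflux as lf

# ground truth: non-vesicular PM->ER at 0.2/min, return at 0.1/min
truth = lf.GroundTruth(rate_params={"k_PM_ER": 0.2, "k_ER_PM": 0.1}, seed=11)
model = lf.build_model("pm_er")
tc = lf.gen_timecourse(truth, model, lf.NoiseSpec(sd_fraction=0.02))

fit = lf.mc_uncertainty(model, tc, n_mc=100, seed=1, x0=truth.initial_state)
for name, (mean, sd) in fit.summary.items():
    print(f"{name}: {mean:.3f} +/- {sd:.3f} min^-1")
print(f"K = {lf.quasi_equilibrium(fit.point_estimate):.2f}")
```

prints

```
k_PM_ER: 0.205 +/- 0.007 min^-1
k_ER_PM: 0.104 +/- 0.005 min^-1
K = 1.97
```

i.e. the Monte Carlo mean ± s.d. of each fitted rate constant recovers the
generating truth, and the quasi-equilibrium constant K ≈ 2 says this lipid
partitions about 2:1 into the ER at steady state.

The same analysis runs from the shell:

```sh
lipoflux generate --preset pm_er --seed 11 --out tc.csv
lipoflux fit --preset pm_er --data tc.csv --n-mc 100 --seed 1 --out fit.json
lipoflux run --config pipeline.yaml     # full partition -> fit -> metabolism bundle
```

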