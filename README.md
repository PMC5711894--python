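# granuvisc

**FLIM molecular-rotor viscometry of mucin granules.**

Airway mucus pathology in cystic fibrosis (CF) may begin before secretion, in
the packaging of the mucin matrix inside secretory granules. A
viscosity-sensitive BODIPY molecular rotor reports that intragranular
microviscosity through its fluorescence lifetime, measured per pixel by
TCSPC-based FLIM. `granuvisc` implements the complete analysis for such
experiments — and, because no raw imaging data are publicly available, a
ground-truthed simulator that regenerates the study conditions so every stage
is testable end to end:

1. **`flim_synth`** — granule phantoms → photon-limited TCSPC stacks.
   Presets: `nonCF` (one population, 521 ± 60 cP), `CF` (164 ± 40 cP at
   weight 0.7 plus 501 ± 60 cP at 0.3), `nonrotor_control` (viscosity-blind
   dye).
2. **`decay_fit`** — multi-exponential fits I(t) = Σ Aᵢ exp(−t/τᵢ)
   (IRF-aware, bin-integrated, variable projection), component count chosen
   by the reduced-χ² ≈ 1 criterion; per-pixel lifetime images.
3. **`rotor_calibration`** — Förster-Hoffmann power law τ = a·η^x fitted in
   log-log space, valid for η ≥ 20 cP, with glycerol-water viscosity
   standards and relative quantum yields (fluorescein, Q_ref = 0.95).
4. **`granule_segmentation`** — trainable pixel classification (random
   forest over a fixed feature stack, the Weka-workflow analogue),
   circularity filtering (4πA/P² ≥ 0.8), cluster annotation, size
   distributions.
5. **`population_analysis`** — per-granule viscosities, Gaussian-mixture
   fits with BIC model selection (k ≤ 3), group comparisons.
6. **`pipeline_io`** — end-to-end orchestration, OME-TIFF/CSV/JSON formats,
   run manifests, and the `granuvisc` CLI.

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

```python
from granuvisc.pipeline_io import PipelineConfig, run_pipeline

report, manifest = run_pipeline(PipelineConfig(group="CF", n_images=12, seed=1))
m = report.selected
print(f"N={report.n_granules}, k={m.k}")
for mean, se, w in zip(m.means, m.mean_standard_errors, m.weights):
    print(f"  population: {mean:.1f} +- {se:.2f} cP  (weight {w:.3f})")
```

prints

```
N=600, k=2
  population: 163.6 +- 2.01 cP  (weight 0.708)
  population: 501.1 +- 4.57 cP  (weight 0.292)
```

i.e. from 600 accepted granules across 12 simulated CF images the
mixture analysis selects two viscosity populations: a dominant low-viscosity
population at 163.6 ± 2.0 cP (fitted mean ± SE) and a minority population at
501.1 ± 4.6 cP — recovering the generating means (164 and 501 cP) within one
standard error. The same run for `group="nonCF"` selects a single population
at 521.0 ± 2.5 cP. The per-group reports also carry the clustered-versus-
individual granule comparison (component-mean differences well within 3
combined SEs — cluster membership does not shift viscosity) and full
rejection/exclusion bookkeeping.

The same computation is scripted, stage by stage, under `analysis/`
(`01_simulate_datasets.py` … `05_population_analysis.py`), each writing its
tables under `results/`. Or from the shell:

```bash
granuvisc run-all --preset CF --n-images 12 --seed 1 --out results/CF
granuvisc simulate --preset nonCF --n-images 2 --seed 1 --out scratch/sim
granuvisc calibrate --points results/calibration_points.csv --out curve.json
```

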