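#!/usr/bin/env python
"""Build the lifetime-viscosity calibration from glycerol-water standards.

Emulates the calibration experiment: glycerol-water mixtures in 10% volume
increments provide known viscosities at 20 degC; the rotor's lifetime at each
standard is generated from the package's default power law.  The
Forster-Hoffmann fit is then re-estimated from those points, restricted to
viscosities above 20 cP where the rotor responds, and saved for the pipeline.

Outputs: results/calibration_points.csv, results/calibration_curve.json.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from granuvisc.rotor_calibration import (
    CalibrationPoint,
    default_calibration,
    fit_forster_hoffmann,
    glycerol_water_viscosity,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

truth = default_calibration()
points = []
for frac in np.arange(0.0, 1.01, 0.1):
    eta = glycerol_water_viscosity(frac, temperature=20.0)
    tau = truth.a * eta**truth.x  # unclipped: sub-domain standards keep their raw value
    points.append({"glycerol_volume_fraction": round(frac, 1),
                   "viscosity_cP": eta, "lifetime_ns": tau})
df = pd.DataFrame(points)
df.to_csv(OUT / "calibration_points.csv", index=False)

fit = fit_forster_hoffmann(
    [CalibrationPoint(p["viscosity_cP"], p["lifetime_ns"], label=str(p["glycerol_volume_fraction"]))
     for p in points],
    domain_min=20.0,
)
(OUT / "calibration_curve.json").write_text(json.dumps(fit.to_dict(), indent=2, sort_keys=True))

print(f"{len(df)} glycerol-water standards, "
      f"{fit.n_points_excluded} below the 20 cP domain excluded")
print(f"fitted: tau = {fit.a:.4f} * eta^{fit.x:.4f}  (r2 = {fit.fit_r2:.6f})")
print(f"wrote {OUT / 'calibration_curve.json'}")
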