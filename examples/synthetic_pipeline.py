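"""End-to-end run on a synthetic bundle with known ground truth.

Generates a full synthetic input set (monthly CO2, SST anomaly ensembles,
emissions table) whose increments obey the regression by construction,
writes it to disk, then calibrates and forecasts through the file-driven
pipeline and compares against the generator's bookkeeping.
"""

import tempfile
from pathlib import Path

from ninocast import GeneratorConfig, RunConfig, generate_bundle, run_forecast, write_fixture_bundle

cfg = GeneratorConfig(start_year=1959, end_year=2016, seed=42, residual_sd=0.25)
truth = generate_bundle(cfg).truth

with tempfile.TemporaryDirectory() as tmp:
    paths = write_fixture_bundle(cfg, tmp)
    run_cfg = RunConfig(
        co2_path=str(paths["co2"]),
        emissions_path=str(paths["emissions"]),
        sst_path=str(paths["sst"]),
        target_year=2016,
        calibration_years=(1960, 2014),
        seasonal_reference_years=(2000, 2010),
        split=cfg.split,
        output_dir=str(Path(tmp) / "reports"),
    )
    result = run_forecast(run_cfg)

a1, a2n, a3e = result.components
print(f"true coefficients      : {cfg.alphas}")
print(f"forecast increment     : {result.increment_central:.2f} +/- {result.increment_two_sd:.2f} ppm")
print(f"  = intercept {a1:.2f} + ENSO term {a2n:.2f} + emissions term {a3e:.2f}")
print(f"true 2016 increment    : {truth.increments[2016]:.2f} ppm "
      f"(of which ENSO {truth.contributions[2016]:.2f} ppm)")
print(f"forecast annual mean   : {result.annual_mean:.2f} ppm")
print("The forecast recovers the injected increment within its 2 s.d. range;")
print("the decomposition shows how much of it the ENSO term carries.")
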