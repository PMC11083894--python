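"""Fit the photobleaching trend models for every dye x microscope condition.

Simulates 10-acquisition relative-intensity series (5 ROIs each) at the
slopes observed for each probe/microscope combination, fits all four
location x dispersion Gaussian ML models, and selects per condition by the
penalized minus log-likelihood (AIC = −logL + k). Also runs one full
image-based series (stacks → MIP → ROI means → fit) as an end-to-end check.

Writes results/photostability_fits.csv: one row per condition per model,
with the selected model flagged.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mitoquant import (
    SimCellParams,
    SimSeriesParams,
    build_series,
    compare_models_aic,
    fit_all_models,
    fold_variation,
    simulate_intensity_series,
    simulate_series,
)
from mitoquant.stack_io import RoiRect

SEED = 2026
RESULTS = Path(__file__).resolve().parents[1] / "results"

# slope of relative intensity per normalized series time, per condition
CONDITIONS = [
    ("TMRM", "CLSM", -0.03),
    ("TMRM", "SDCM", -0.14),
    ("CMXRos", "CLSM", -0.16),
    ("CMXRos", "SDCM", 0.0),
    ("JC-1 C1", "SDCM", -0.27),
    ("JC-1 C2", "SDCM", -0.07),
]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for j, (dye, scope, slope) in enumerate(CONDITIONS):
        rng = np.random.default_rng(SEED + j)
        series = simulate_intensity_series(
            slope, 0.05, dye=dye, microscope=scope, rng=rng
        )
        fits = fit_all_models(series)
        best = compare_models_aic(fits)
        for f in fits:
            rows.append(
                {
                    "dye": dye,
                    "microscope": scope,
                    "planted_slope": slope,
                    "model": f.spec.label(),
                    "alpha": round(f.alpha, 4),
                    "beta": round(f.beta, 4),
                    "gamma": round(f.gamma, 4),
                    "delta": round(f.delta, 4),
                    "minus_log_likelihood": round(f.minus_log_likelihood, 3),
                    "k": f.n_params,
                    "aic": round(f.aic, 3),
                    "selected": f is best,
                }
            )
        fold = fold_variation(series, acquisition=9)
        flat = "horizontal line" if best.spec.location_form == "constant" else "trend"
        print(
            f"{dye:8s} {scope}: planted {slope:+.2f} -> fitted {best.beta:+.3f} "
            f"({flat}; fold spread at acq 10: {fold:.2f})"
        )

    pd.DataFrame(rows).to_csv(RESULTS / "photostability_fits.csv", index=False)

    # end-to-end: render actual stacks, measure ROI means off the MIPs
    sp = SimSeriesParams(cell=SimCellParams(seed=SEED), decay_slope=-0.14)
    stacks, truth = simulate_series(sp)
    rois = [RoiRect(f"r{i}", 30 + 12 * i, 30 + 10 * i, 33, 33) for i in range(5)]
    series = build_series([s.mito for s in stacks], rois, "TMRM", "SDCM")
    best = compare_models_aic(fit_all_models(series))
    print(
        f"\nimage-based TMRM SDCM series: planted -0.14 -> fitted {best.beta:+.3f} "
        f"(model {best.spec.label()})"
    )


if __name__ == "__main__":
    main()
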