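#!/usr/bin/env python
"""Subthreshold F-V linearity across a batch of simulated cells.

Simulates 9 cells under the current-clamp step protocol, runs each
recording through the full bit-plane pipeline (log-correction, 2 kHz
low-pass, ~100 Hz binning), and regresses dF/F against the steady-state
membrane-potential change through the origin. Writes the per-cell slopes
and uncentered R^2 values and prints the batch summary.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from spadvi import camera, neuron, workbench


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-cells", type=int, default=9)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    sensor = workbench.default_sensor()
    footprint = workbench.default_footprint(sensor)
    indicator = camera.IndicatorModel(
        coupling_per_mV=0.002,
        baseline_brightness=workbench.brightness_for_roi_counts(
            workbench.STEP_ROI_COUNTS, footprint, sensor))
    cell = neuron.CellMembraneModel(resistance_MOhm=100.0, tau_membrane_ms=15.0)
    protocol = neuron.StepProtocol.default_current()

    rows = []
    for k in range(args.n_cells):
        res = workbench.step_experiment(cell, protocol, indicator, sensor,
                                        footprint, seed=1000 * args.seed + k)
        sm, reg = res["step_metrics"], res["fv"]
        rows.append({"cell": k, "slope_per_mV": reg.slope,
                     "r_squared": reg.r_squared,
                     "baseline_counts": sm.baseline_F,
                     **{f"dFF_{int(dv):+d}mV": d
                        for dv, d in zip(sm.dV_mV, sm.dFF)}})
    df = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "fv_regression.csv", index=False)

    print(df.to_string(index=False, float_format=lambda x: f"{x:.5g}"))
    print(f"\nmean R^2 over {args.n_cells} cells: "
          f"{df.r_squared.mean():.4f} +- {df.r_squared.sem():.4f} (SEM)")
    print(f"mean slope: {df.slope_per_mV.mean():.5f} per mV "
          f"(true coupling 0.00200, attenuated by windowing, saturation "
          f"and dark counts)")


if __name__ == "__main__":
    main()
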