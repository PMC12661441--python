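"""Extract within-oligomer liganded populations from the simulated titration.

Reads the spectra written by 01_simulate_titration.py, applies the windowed
peak extraction at each oligomer's representative charge state, and writes
the tidy population matrix (titration point x oligomer x bound count) to
results/.  Prints the worst absolute deviation from the simulation's ground
truth as a self-check.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hexalig.extraction import build_grid, integrate_windows, normalize_within_oligomer
from hexalig.io import read_spectrum_csv, write_population_csv
from hexalig.lattice import default_topologies
from hexalig.nms import SpectrumModel

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim_titration"
RESULTS = ROOT / "results"


def main() -> None:
    truth = json.loads((SIM / "ground_truth.json").read_text())
    model = SpectrumModel(**truth["scenario"]["spectrum_model"])
    topologies = default_topologies()
    grid = build_grid(model, topologies)

    matrices, worst = [], 0.0
    truth_df = pd.DataFrame(truth["population_rows"])
    for point in sorted(truth_df.titration_point.unique()):
        spec = read_spectrum_csv(SIM / f"spectrum_{point:02d}.csv")
        l_tot = truth_df[truth_df.titration_point == point].L_tot.iloc[0]
        pm = normalize_within_oligomer(
            integrate_windows(spec, grid),
            meta={"titration_point": int(point), "l_tot": float(l_tot)},
        )
        matrices.append(pm)
        sub = truth_df[truth_df.titration_point == point]
        for j in range(1, 7):
            ref = sub[sub.j == j].sort_values("k").fraction.to_numpy()
            worst = max(worst, np.abs(pm.fractions[j] - ref).max())

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "population_matrix.csv"
    write_population_csv(out, matrices)
    print(f"wrote {out}")
    print(f"worst |extracted - truth| fraction across all rows: {worst:.4f}")
    print(
        "Within-oligomer fractions survive the spectral round trip even though "
        "cross-oligomer ion counts are deliberately uninformative."
    )


if __name__ == "__main__":
    main()
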