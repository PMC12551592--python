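"""Run the two-stage backscatter study for phantom Cases I-IV.

Each case: stage 1 scores the no-backscatter phantom dose D1 and captures
the forward phase space at Z = -51 cm; stage 2 replays it (recycled 3x)
through the MV imager and beam stopper and scores the backscatter dose D2.
Depth-dose tables go to results/, bulky binary artifacts (dose grids,
phase spaces) to scratch/.

Run from the repository root (about a minute per million histories):

    python analysis/02_run_cases.py [histories] [seed]
"""

import json
import sys
from pathlib import Path

from exitdose.analysis import depth_dose
from exitdose.io import save_provenance, write_dose_grid, write_phase_space
from exitdose.materials import MaterialPack
from exitdose.pipeline import CaseConfig, run_case

RESULTS = Path("results")
SCRATCH = Path("scratch")

if __name__ == "__main__":
    histories = int(float(sys.argv[1])) if len(sys.argv) > 1 else 1_000_000
    seed = int(sys.argv[2]) if len(sys.argv) > 2 else 20_001
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    pack = MaterialPack()
    summary = {}
    for label in ("I", "II", "III", "IV"):
        case = CaseConfig.preset(label, histories=histories, seed=seed)
        res = run_case(case, pack=pack)
        curve = depth_dose(res)
        curve.to_frame().to_csv(RESULTS / f"depth_dose_case_{label}.csv",
                                index=False)
        write_dose_grid(SCRATCH / f"case_{label}_d1.h5", res.d1)
        write_dose_grid(SCRATCH / f"case_{label}_d2.h5", res.d2)
        write_phase_space(SCRATCH / f"case_{label}_forward.phsp.h5",
                          res.forward_records)
        write_phase_space(SCRATCH / f"case_{label}_backscatter.phsp.h5",
                          res.backscatter_records)
        save_provenance(SCRATCH / f"case_{label}_provenance.json",
                        res.provenance)
        summary[label] = {
            "distal_fraction_2mm_pct": curve.distal_fraction("2mm"),
            "distal_fraction_0.02mm_pct": curve.distal_fraction("0.02mm"),
            "forward_plane_weight": res.forward_records.total_weight,
            "backscatter_plane_weight":
                res.backscatter_records.total_weight,
        }
        print(f"case {label}: distal backscatter "
              f"{summary[label]['distal_fraction_2mm_pct']:.2f}% of local "
              f"dose ({histories:.0e} histories)")
    (RESULTS / "case_summary.json").write_text(
        json.dumps({"histories": histories, "seed": seed,
                    "cases": summary}, indent=2))
    print("wrote results/case_summary.json and per-case depth-dose tables")
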