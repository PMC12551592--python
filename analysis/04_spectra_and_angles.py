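"""Spectral and angular characterisation of the backscattered photons.

Case II, 28 x 28 cm open field: energy spectra of all photons on the
forward plane (-51 cm) and of the backscattered photons (-50.5 cm), their
mean energies and number ratio, and the mean energy / intensity as a
function of angular divergence (1-degree position-based rings).

Tables go to results/, figures to scratch/figures/.

Run from the repository root:  python analysis/04_spectra_and_angles.py [histories]
"""

import json
import sys
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from exitdose.analysis import FEATURE_EDGES, angular_profile, spectrum
from exitdose.pipeline import CaseConfig, run_case

RESULTS = Path("results")
FIGS = Path("scratch/figures")

if __name__ == "__main__":
    histories = int(float(sys.argv[1])) if len(sys.argv) > 1 else 2_000_000
    RESULTS.mkdir(exist_ok=True)
    FIGS.mkdir(parents=True, exist_ok=True)
    res = run_case(CaseConfig.preset("II", histories=histories, seed=30_001))

    fwd = spectrum(res.forward_records, histories)
    back = spectrum(res.backscatter_records, histories,
                    reference=res.forward_records)
    fine = spectrum(res.backscatter_records, histories, edges=FEATURE_EDGES)
    prof = angular_profile(res.backscatter_records)

    fwd.to_frame().to_csv(RESULTS / "spectrum_forward_caseII.csv",
                          index=False)
    back.to_frame().to_csv(RESULTS / "spectrum_backscatter_caseII.csv",
                           index=False)
    prof.to_frame().to_csv(RESULTS / "angular_profile_caseII.csv",
                           index=False)
    headline = {
        "histories": histories,
        "forward_mean_mev": fwd.mean_energy,
        "backscatter_mean_mev": back.mean_energy,
        "photon_number_ratio_pct": back.count_ratio_pct,
        "ring_mean_0_6_mev": prof.pooled_mean_energy(0, 6),
        "ring_mean_6_13_mev": prof.pooled_mean_energy(6, 13),
        "peak_511_kev": fine.has_peak_in(0.46, 0.56),
        "peak_pb_k_band": fine.has_peak_in(0.070, 0.090),
    }
    (RESULTS / "spectral_summary.json").write_text(
        json.dumps(headline, indent=2))
    print(json.dumps(headline, indent=2))

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4))
    c = 0.5 * (fwd.edges[:-1] + fwd.edges[1:])
    ax1.semilogy(c, fwd.value, label="all photons, -51 cm")
    ax1.semilogy(c, back.value, label="backscattered, -50.5 cm")
    ax1.set_xlabel("energy (MeV)")
    ax1.set_ylabel("fluence spectrum (1/MeV per primary)")
    ax1.legend()
    mid = 0.5 * (prof.ring_edges_deg[:-1] + prof.ring_edges_deg[1:])
    ax2.plot(mid, prof.mean_energy, "o-")
    ax2.set_xlabel("divergence from beam axis (deg)")
    ax2.set_ylabel("mean energy (MeV)")
    fig.tight_layout()
    fig.savefig(FIGS / "spectra_angles_caseII.png", dpi=150)
    print(f"wrote {FIGS / 'spectra_angles_caseII.png'}")
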