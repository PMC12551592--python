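# Methods

`exitdose` models the question "how much of the dose on the beam-exit side
of a patient comes back off the beam stopper and MV imager of a ring-gantry
linac?" with a deliberately small, fully self-contained photon Monte Carlo.
This note records the model, its parameters, the numerical choices, and what
the simplifications mean for interpreting results.

## Coordinate system and geometry

IEC 61217 coordinates in cm: X lateral, Y longitudinal (bore axis), Z
vertical. The gantry is fixed at 0°, the photon source sits at
(0, 0, +100) (100 cm source–axis distance) and the beam travels along −Z.
Regions, in priority order (first containing region wins; everything else
is world air):

| region | shape, size | material (density g/cm³) | placement |
|---|---|---|---|
| couch (Case I) | two 1 mm skins + 5 cm core, 46 cm wide | carbon fibre (1.7) / foam (0.05) | directly under the phantom |
| phantom | elliptical cylinder, 40 × 25 cm diameters, 30 cm long (Y) | water (1.0) | exit surface at Z = −(50 − d) |
| EPID stack | Cu 1 mm / Gd₂O₂S 0.49 mm / a-Si 0.7 mm / Al 1 mm / Pb 3 mm, 43 × 43 cm | see table files | a-Si detector plane at Z = −54 (SID 154 cm) |
| beam stopper | 75.4 × 66 × 17.2 cm box | 1 cm steel shell, Pb–3%Sb core (11.0) | top face at Z = −62.6 |
| bore envelope | cylinder r = 50 about Y | air | centred on isocenter |

d is the gap between the phantom exit surface and the bore. The published
description ties the setups to two distances — "13 cm from the beam
stopper" for Cases I–III and "5 cm from the bore" for Case IV — which are
mutually inconsistent if both are measured to the stopper face. We read
the 13 cm as the gap to the top of the imager assembly (taken at
Z = −52.0), giving d = 11 cm for Cases I–III, and d = 5 cm for Case IV;
with d measured to the stopper face instead, Case IV would no longer be
the closest setup. All placements are config-overridable.

The "partial" elliptical phantom is modelled with the full 40 × 25 cm
cross-section (length-truncated reading): the scored depth range 0–250 mm
spans the whole 25 cm minor axis, which requires the full cross-section.
The couch is not specified in the source material; a generic carbon-fibre
sandwich (two 1 mm skins around a 5 cm, 0.05 g/cm³ foam core) is used and
exposed in the configuration.

## Photon physics

Cross-sections live in committed per-material CSV tables (80 log-spaced
energies, 1 keV–7 MeV; columns photoelectric / incoherent / pair / total in
cm²/g), generated by `tools/build_xs_tables.py` from an analytic model:

* **Incoherent (Compton)** — exact integrated Klein–Nishina per electron
  × N_A·Z/A. Free-electron approximation: no binding suppression or
  Doppler broadening (overestimates incoherent scattering below
  ~100 keV in high-Z materials).
* **Photoelectric** — per-atom cross-sections anchored to published
  mass-attenuation values for O, Fe and Pb at 0.1 MeV and for O and Pb at
  0.5 and 1 MeV, interpolated quadratically in ln σ vs ln Z, with E⁻³
  behaviour below 0.1 MeV, piecewise power laws between the anchors and
  E⁻¹ above 1 MeV. Lead carries K (88 keV) and L (13 keV) edges as
  multiplicative jumps (×0.21 below K, further ×0.10 below L). Sb and Gd
  edges are neglected (3% alloy fraction and a 0.49 mm layer
  respectively). Accuracy versus published tables is a few percent for
  water above 100 keV and ~5–15% for lead in the 0.1–0.5 MeV range.
* **Pair production** — Z^2.2 scaling with a ((E−1.022)/E)³ threshold
  shape calibrated at O/Pb 6 MeV values; exactly zero below 1.022 MeV.
* **Rayleigh (coherent) scattering is omitted** — it transports no energy
  and at these energies redirects only a few percent of interactions;
  a known deviation from condensed-history production codes.

Interaction sampling: the kind is drawn proportionally to the interpolated
partial coefficients. Compton uses Kahn's rejection method for the
Klein–Nishina distribution (validated against a quadrature oracle in the
test suite). Photoelectric absorption in lead-bearing materials emits
characteristic fluorescence: above the K edge a K vacancy forms with
probability 0.8 and radiates with yield 0.96 (Kα 74.97 keV : Kβ 84.94 keV
= 0.8 : 0.2); otherwise an L vacancy radiates with yield 0.39
(10.55 : 12.61 keV = 0.55 : 0.45), isotropically. Exact line weights are a
modelling choice; they set the 72–88 keV and 9–13 keV spectral bands, not
any dose endpoint. Pair production deposits E − 1.022 MeV at the vertex
and emits two back-to-back 511 keV photons with isotropic orientation
(local annihilation approximation).

**Kerma approximation.** Electrons and positrons are not transported: the
energy transferred to charged particles is deposited at the photon
interaction vertex. Consequences: no build-up at beam entry, no
build-down at the exit surface, and no charged-particle component in the
backscatter. The transport cutoff is 10 keV (photons below it deposit
locally); it is configurable, and must be lowered to ~5 keV to observe
the Pb L lines, which sit at the default cutoff.

## Transport and scoring

Analog tracking (no splitting or implicit capture): free paths are sampled
from exp(−μs) with log-log interpolated total attenuation; boundaries are
exact ray–solid intersections (boxes, circular and elliptical cylinders);
phase-space planes are exact ray–plane crossings between steps, so there
are no step-size artifacts. The world is a 6 m box of air; particles
leaving it are tallied as escaped. A per-run energy ledger
(launched = phantom dose + elsewhere + escaped + captured) closes to
~1e-12 relative and is asserted at 1e-6 in tests.

Dose is scored in the phantom on a grid with 2 mm depth resolution over
0–248 mm, 0.02 mm over the last 2 mm (248–250 mm), and 24 mm laterally in
X and Y, centred on the phantom axis (the axis follows the Case III
lateral offset). Per-voxel first and second moments are accumulated per
primary history — secondaries and all recycled replicas of a history share
its id — giving correct batch statistics under recycling.

**Random numbers.** Every history owns a counter-based splitmix64 stream
keyed by (seed, history id, record ordinal, stage/replica tag). Runs are
bit-reproducible, independent of execution order and buffer sizes, and —
important for the case comparisons — running two *geometries* with the
same seed pairs the histories (common random numbers), so paired
differences such as "couch in / couch out" carry far less variance than
independent runs.

## Two-stage backscatter isolation

Stage 1 terminates every photon moving toward the imager on the plane at
Z = −51 cm; the phantom dose D₁ therefore contains no backscatter by
construction. Stage 2 replays the captured records — each re-emitted 3×
with weight 1/3 (the study's only variance-reduction device) — through
the imager and stopper; photons crossing Z = −50.5 cm moving toward the
isocenter are recorded once per particle (non-terminating plane: they
must continue into the phantom to deposit D₂). D_tot = D₁ + D₂ holds
voxelwise exactly. The backscatter contribution is reported as
100·D₂/(D₁+D₂) ("percent of the local dose"); D₂/D₁ is available behind a
configuration flag and differs by < 0.05 points at these magnitudes.

## Source model and calibration

The proprietary vendor phase space is replaced by a point source
collimated to an ideal rectangle (default 28 × 28 cm at the isocenter,
the machine maximum; no MLC leaf geometry, no off-axis softening, no
electron contamination — the endpoint sits behind ≥ 25 cm of water where
contaminant electrons cannot reach). Energies follow
p(E) ∝ (E/6)^a·exp(−b·E/6) on [0.05, 6] MeV. (a, b) are calibrated so
the all-photon mean energy on the −51 cm plane behind the Case II phantom
is 1.2 MeV: a small grid over a with bisection in b (the exit mean is
monotone in b), at 1.5 × 10⁵ histories per evaluation, on a seed
independent of the production runs. The shipped defaults
(a = 1.0, b = 8.19) are the result of this procedure; the full study
recalibrates at run time.

## Analysis endpoints and estimators

* **Depth dose / contribution curves** — central-axis column of the dose
  grids with per-bin standard errors; the distal ("exit-side skin") value
  is quoted for the last 2 mm bin (the aggregated 248–250 mm sub-voxels).
* **0.02 mm sub-voxel estimate** — in a photon-kerma model both dose
  components vary by < 3% across the final 2 mm and there is no
  charged-particle build-down, so the sub-voxel ratio is estimated from
  the pooled fine bins; the raw per-sub-voxel tallies (far too sparse at
  10⁷ histories for a 20 µm voxel) remain available. Note this is the one
  endpoint where the missing electron transport matters qualitatively:
  a sharp sub-millimetre rise of the backscatter share at the interface
  (reported as 1.5% → 2% in the reference data) cannot appear in a kerma
  model, which is why the fine and 2 mm estimates coincide here.
* **Spectra** — normalised by simulated primaries × bin width (20 keV
  below 1 MeV, 100 keV above); mean energies are computed from raw
  records and are binning-independent. Peak detection (511 keV
  annihilation line, Pb K band) uses a finer 5 keV binning below
  200 keV, since 20 keV bins smear the Kα/Kβ doublet into the continuum.
* **Angular decomposition** — 1° rings in divergence angle
  atan(r/150.5 cm) from the record's *position* on the −50.5 cm plane
  (the plane-ring reading; a direction-vector variant exists behind a
  flag). Band means pool rings 0–6° and 6–13°.

## Problem sizes

The reference study used 5 × 10⁹ incident electrons; this package runs
5 × 10⁶ histories per case (10⁷ for the fine distal endpoint) — a
~1000× scale-down chosen so the complete study (calibration, four cases,
the fine rerun and all analyses) finishes in roughly ten minutes on one
core. At this size the distal-voxel backscatter fractions carry relative
standard errors of 20–35%; the spectral and angular endpoints, which pool
hundreds of thousands of records, are determined to better than 1%.

## What the synthetic conditions do and do not show

The generator + simplified physics reproduce: exponential attenuation and
beam hardening in water, the soft (≲ 2 MeV, mean ≈ 0.27 MeV) backscatter
spectrum governed by Compton kinematics (180° ceiling mc²/2 = 0.2555 MeV),
the 511 keV annihilation line, Pb K fluorescence, the ~6–7% backscatter
photon-number albedo of the imager/stopper stack, and the growth of the
relative backscatter contribution as the phantom approaches the bore.

They do **not** reproduce: electron-mediated effects (entrance/exit
build-up and build-down, backscattered electrons reaching the phantom
through air — a plausible contributor to the reference couch sensitivity,
where removing the couch more than doubled the distal backscatter share),
Rayleigh scattering, bound-Compton corrections, the FFF fluence horn, or
heterogeneous anatomy. In particular, the couch comparison (Case I vs
II) comes out qualitatively different in a photon-only model: the couch's
few-percent attenuation of returning photons is offset by Compton
in-scatter toward the central axis, so removing the couch barely changes
— and can slightly lower — the distal backscatter share here, whereas the
reference data show it more than doubling, consistent with the couch
filtering backscattered electrons that a kerma model does not transport.
The cross-case ordering with the couch involved is therefore not a
reliable output of this model.

## Known limitations

Photon-only kerma dosimetry (no charged-particle equilibrium corrections);
analytic cross-section fits rather than evaluated nuclear data; no gantry
or collimator rotation; ideal rectangular fields; absolute calibration
(Gy/MU) out of scope.
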