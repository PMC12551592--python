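"""Two-stage backscatter-isolation study orchestration (Cases I-IV).

Stage 1 transports source photons through the phantom down to a terminating
phase-space plane at Z = -51 cm, scoring the no-backscatter phantom dose D1.
Stage 2 replays the captured records (recycled, default 3x) through the MV
imager and the beam stopper, records upward-moving photons on a
non-terminating backscatter plane at Z = -50.5 cm, and scores the phantom
dose D2 deposited by the returning radiation.  The backscatter contribution
to the local dose is D2 / (D1 + D2).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from . import geometry as geo
from .geometry import build_geometry
from .materials import DEFAULT_CUTOFF, MaterialPack
from .source import (DEFAULT_A, DEFAULT_B, SAD, SourceConfig,
                     spectrum_inverse_cdf)
from .transport import (BACKSCATTER_PLANE_Z, FORWARD_PLANE_Z, DoseGrid,
                        PhaseSpaceBatch, PlaneSpec, TallySummary, track,
                        track_source)

GAP_TO_ASSEMBLY = 13.0  # cm, phantom exit surface to imager assembly (I-III)
_PRESET_GAP = geo.BORE_RADIUS + geo.EPID_ASSEMBLY_TOP + GAP_TO_ASSEMBLY
# bore gap d giving a 13 cm exit-to-assembly gap: d = 50 - (52 - 13) = 11 cm


@dataclass(frozen=True)
class CaseConfig:
    """One phantom setup of the backscatter study.

    ``bore_gap_cm`` is the distance d from the phantom exit surface to the
    bore envelope; the presets give d = 11 cm (a 13 cm gap to the imager
    assembly, Cases I-III) and d = 5 cm (Case IV, the closest allowed
    approach).
    """

    label: str = "custom"
    bore_gap_cm: float = _PRESET_GAP
    couch: bool = False
    lateral_offset_cm: float = 0.0
    field_x: float = 28.0
    field_y: float = 28.0
    histories: int = 5_000_000
    seed: int = 1
    recycle: int = 3
    spectrum_a: float = DEFAULT_A
    spectrum_b: float = DEFAULT_B
    phantom_material: str = "water"
    void_stopper: bool = False  # imager + stopper replaced by vacuum
    cutoff: float = DEFAULT_CUTOFF
    backscatter_metric: str = "local"  # local: D2/(D1+D2); stage1: D2/D1

    def __post_init__(self):
        if self.bore_gap_cm < 0:
            raise ValueError("bore gap d must be non-negative")
        if self.recycle < 1:
            raise ValueError("recycle factor must be >= 1")
        if abs(self.lateral_offset_cm) + geo.PHANTOM_AX > geo.BORE_RADIUS:
            raise ValueError("lateral offset puts the phantom outside the "
                             "bore")

    @classmethod
    def preset(cls, label: str, **overrides) -> "CaseConfig":
        presets = {
            "I": dict(bore_gap_cm=_PRESET_GAP, couch=True,
                      lateral_offset_cm=0.0),
            "II": dict(bore_gap_cm=_PRESET_GAP, couch=False,
                       lateral_offset_cm=0.0),
            "III": dict(bore_gap_cm=_PRESET_GAP, couch=False,
                        lateral_offset_cm=5.0),
            "IV": dict(bore_gap_cm=5.0, couch=False, lateral_offset_cm=0.0),
        }
        if label not in presets:
            raise ValueError(f"unknown case preset {label!r} "
                             f"(choose from {', '.join(presets)})")
        return cls(label=label, **{**presets[label], **overrides})

    @property
    def source(self) -> SourceConfig:
        return SourceConfig(field_x=self.field_x, field_y=self.field_y,
                            a=self.spectrum_a, b=self.spectrum_b,
                            histories=self.histories, seed=self.seed)

    def phantom_z_top(self) -> float:
        return -(geo.BORE_RADIUS - self.bore_gap_cm) + 2 * geo.PHANTOM_AZ

    def geometry_hash(self) -> str:
        """Hash of everything that defines the tracking problem geometry."""
        fields = {k: v for k, v in asdict(self).items()
                  if k not in ("histories", "seed", "recycle", "label")}
        return hashlib.sha256(
            json.dumps(fields, sort_keys=True).encode()).hexdigest()[:16]

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    """Output of a full two-stage case run (all doses per launched primary)."""

    case: CaseConfig
    d_total: DoseGrid
    d1: DoseGrid
    d2: DoseGrid
    forward_records: PhaseSpaceBatch
    backscatter_records: PhaseSpaceBatch
    tally1: TallySummary
    tally2: TallySummary
    provenance: dict


def _fresh_grid(case: CaseConfig) -> DoseGrid:
    return DoseGrid(x_center=case.lateral_offset_cm,
                    z_top=case.phantom_z_top())


def _pack(case: CaseConfig) -> MaterialPack:
    return MaterialPack(cutoff=case.cutoff)


def run_stage1(case: CaseConfig, pack: Optional[MaterialPack] = None):
    """Source -> phantom -> terminating forward plane at Z = -51 cm.

    Returns (D1 dose grid, captured forward-plane records, tally).
    """
    pack = pack or _pack(case)
    geom = build_geometry(case)
    grid = _fresh_grid(case)
    plane = PlaneSpec(FORWARD_PLANE_Z, direction=-1, terminate=True)
    if case.field_x * case.field_y == 0.0:
        # zero-measure aperture: nothing is emitted
        empty = PhaseSpaceBatch(*[np.zeros(0)] * 8, plane=plane,
                                n_primaries=0)
        empty.meta = {"geometry_hash": case.geometry_hash()}
        tally = TallySummary(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, (0.0,), (0,))
        return grid, empty, tally
    inv_cdf = spectrum_inverse_cdf(case.spectrum_a, case.spectrum_b)
    grid, (records,), tally = track_source(
        geom, inv_cdf, case.histories, case.field_x / 2.0, case.field_y / 2.0,
        SAD, [plane], grid, case.seed, pack=pack)
    if len(records) == 0 and case.field_x * case.field_y > 0:
        warnings.warn(f"case {case.label}: no particles captured on the "
                      "forward plane; field likely misconfigured")
    records.meta = {"geometry_hash": case.geometry_hash()}
    return grid, records, tally


def run_stage2(case: CaseConfig, forward_records: PhaseSpaceBatch,
               pack: Optional[MaterialPack] = None):
    """Replay captured records into the imager/stopper; score backscatter.

    The backscatter plane at Z = -50.5 cm is non-terminating: captured
    photons continue into the phantom and deposit D2.  Returns
    (D2 dose grid, backscatter-plane records, tally).
    """
    meta_hash = getattr(forward_records, "meta", {}).get("geometry_hash")
    if meta_hash is not None and meta_hash != case.geometry_hash():
        raise ValueError("stage-2 geometry does not match the geometry the "
                         "phase space was recorded in")
    pack = pack or _pack(case)
    geom = build_geometry(case)
    grid = _fresh_grid(case)
    plane = PlaneSpec(BACKSCATTER_PLANE_Z, direction=+1, terminate=False)
    grid, (records,), tally = track(
        geom, forward_records, [plane], grid,
        case.seed, pack=pack, recycle=case.recycle)
    # normalise per stage-1 primary, not per replayed record
    grid.n_primaries = forward_records.n_primaries or case.histories
    return grid, records, tally


def run_case(case: CaseConfig,
             pack: Optional[MaterialPack] = None) -> StudyResult:
    """Run both stages with a shared geometry and assemble the StudyResult."""
    pack = pack or _pack(case)
    d1, forward, tally1 = run_stage1(case, pack=pack)
    d2, backscatter, tally2 = run_stage2(case, forward, pack=pack)
    d_total = d1.added(d2)
    provenance = {
        "case": asdict(case),
        "config_hash": case.config_hash(),
        "geometry_hash": case.geometry_hash(),
        "seeds": {"stage1": case.seed, "stage2": case.seed},
        "forward_plane": {"z_cm": FORWARD_PLANE_Z,
                          "weight": forward.total_weight,
                          "count": len(forward)},
        "backscatter_plane": {"z_cm": BACKSCATTER_PLANE_Z,
                              "weight": backscatter.total_weight,
                              "count": len(backscatter)},
        "energy_ledger": {"stage1_closure": tally1.closure(),
                          "stage2_closure": tally2.closure()},
    }
    return StudyResult(case, d_total, d1, d2, forward, backscatter,
                       tally1, tally2, provenance)
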