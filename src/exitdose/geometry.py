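"""Exit-side beamline geometry in IEC 61217 coordinates.

The model covers the region a treatment beam traverses after leaving the
patient on a ring-gantry machine with gantry fixed at 0 degrees (source at
(0, 0, +100) cm, beam along -Z):

* a water phantom -- elliptical cylinder, 40 x 25 cm main diameters, 30 cm
  long along Y, positioned by its exit (bottom) surface;
* an optional carbon-fibre sandwich couch directly under the phantom;
* the MV-imager (EPID) stack: Cu build-up plate / phosphor scintillator /
  a-Si panel / Al plate / Pb backscatter shield, active area 43 x 43 cm,
  detector plane at source-to-imager distance 154 cm (Z = -54);
* the beam stopper: 75.4 x 66 x 17.2 cm lead-antimony core in a 1 cm steel
  shell, top face at Z = -62.6;
* the bore envelope: an air cylinder of radius 50 cm about the Y axis.

Regions are listed in priority order; the first region containing a point
wins, and everything else is world air.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from . import kernels
from .materials import MaterialPack

BORE_RADIUS = 50.0
EPID_ASSEMBLY_TOP = -52.0     # top of the imager/stopper assembly envelope
EPID_DETECTOR_Z = -54.0       # a-Si detector plane (SID 154 cm)
EPID_HALF = 21.5              # 43 x 43 cm active area
STOPPER_TOP = -62.6
STOPPER_XYZ = (75.4, 66.0, 17.2)
STOPPER_SHELL = 1.0
PHANTOM_AX = 20.0             # X half-axis (40 cm diameter)
PHANTOM_AZ = 12.5             # Z half-axis (25 cm diameter)
PHANTOM_LENGTH = 30.0         # along Y
COUCH_HALF_WIDTH = 23.0
COUCH_SKIN = 0.1
COUCH_CORE = 5.0


@dataclass(frozen=True)
class Region:
    name: str
    shape: str  # box | ycyl | yellip
    params: tuple
    material: str

    def as_dict(self):
        return {"name": self.name, "shape": self.shape,
                "params": list(self.params), "material": self.material}


@dataclass
class Ray:
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("ray direction must be a unit vector")
        self.direction = d


_SHAPE_CODE = {"box": kernels.SHAPE_BOX, "ycyl": kernels.SHAPE_YCYL,
               "yellip": kernels.SHAPE_YELLIP}


class GeometryModel:
    """Ordered solid regions with point location and ray-boundary stepping."""

    def __init__(self, regions: List[Region], world_material: str = "air",
                 phantom_region: str = "phantom"):
        self.regions = list(regions)
        self.world_material = world_material
        self.phantom_region = phantom_region
        n = len(self.regions)
        self.shape_code = np.empty(n, dtype=np.int64)
        self.params = np.zeros((n, 6))
        for i, r in enumerate(self.regions):
            self.shape_code[i] = _SHAPE_CODE[r.shape]
            self.params[i, :len(r.params)] = r.params
        self._names = [r.name for r in self.regions]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def phantom_index(self) -> int:
        try:
            return self._names.index(self.phantom_region)
        except ValueError:
            return -1

    def locate(self, point) -> Optional[Region]:
        """Region containing the point, or None for world air."""
        x, y, z = (float(c) for c in point)
        i = kernels.locate_kernel(x, y, z, self.shape_code, self.params,
                                  self.n_regions)
        return None if i < 0 else self.regions[i]

    def material_at(self, point) -> str:
        r = self.locate(point)
        return self.world_material if r is None else r.material

    def distance_to_boundary(self, ray: Ray):
        """(distance to the next region change, region ref beyond it).

        Returns (distance, 'escaped') when the ray leaves the world box
        before meeting any region boundary.
        """
        o, d = ray.origin, ray.direction
        if np.max(np.abs(o)) >= kernels._WORLD_HALF:
            raise ValueError("ray origin outside world")
        here = self.locate(o)
        t = 0.0
        # step across hidden (same-classification) boundaries
        for _guard in range(4 * self.n_regions + 4):
            x, y, z = o + t * d
            tb, tw = kernels.next_boundary(x, y, z, d[0], d[1], d[2],
                                           self.shape_code, self.params,
                                           self.n_regions)
            if tw <= tb:
                return t + tw, "escaped"
            t += tb
            beyond = self.locate(o + (t + 1e-7) * d)
            if beyond is not here:
                name = self.world_material if beyond is None else beyond.name
                return t, name
        return t, "escaped"

    def material_pack_indices(self, pack: MaterialPack) -> np.ndarray:
        return np.array([pack.index[r.material] for r in self.regions],
                        dtype=np.int64)

    def kernel_args(self, pack: MaterialPack):
        return (self.shape_code, self.params,
                self.material_pack_indices(pack), self.n_regions,
                pack.index[self.world_material], self.phantom_index())

    def dump(self) -> str:
        return json.dumps(
            {"world_material": self.world_material,
             "regions": [r.as_dict() for r in self.regions]}, indent=2)


def build_geometry(case) -> GeometryModel:
    """Assemble the exit-side geometry for a phantom setup (case preset).

    ``case`` is a :class:`exitdose.pipeline.CaseConfig`.  Raises
    ``ValueError`` when the phantom placement collides with another region.
    """
    regions: List[Region] = []
    yh = PHANTOM_LENGTH / 2.0
    z_bot = -(BORE_RADIUS - case.bore_gap_cm)
    z_top = z_bot + 2 * PHANTOM_AZ
    xc = case.lateral_offset_cm
    zc = z_bot + PHANTOM_AZ

    if z_bot - (COUCH_CORE + 2 * COUCH_SKIN if case.couch else 0.0) \
            < EPID_ASSEMBLY_TOP:
        raise ValueError("phantom/couch placement reaches into the imager "
                         "assembly")
    max_r = np.hypot(PHANTOM_AX + abs(xc), max(abs(z_bot), abs(z_top)))
    if np.hypot(abs(xc) + PHANTOM_AX, 0) > BORE_RADIUS or z_bot < -BORE_RADIUS:
        raise ValueError("phantom extends outside the bore")
    del max_r

    if case.couch:
        x0, x1 = xc - COUCH_HALF_WIDTH, xc + COUCH_HALF_WIDTH
        z1 = z_bot
        regions.append(Region("couch_skin_top", "box",
                              (x0, x1, -50.0, 50.0, z1 - COUCH_SKIN, z1),
                              "carbon_fiber"))
        regions.append(Region("couch_core", "box",
                              (x0, x1, -50.0, 50.0,
                               z1 - COUCH_SKIN - COUCH_CORE, z1 - COUCH_SKIN),
                              "foam"))
        regions.append(Region("couch_skin_bottom", "box",
                              (x0, x1, -50.0, 50.0,
                               z1 - 2 * COUCH_SKIN - COUCH_CORE,
                               z1 - COUCH_SKIN - COUCH_CORE),
                              "carbon_fiber"))

    regions.append(Region("phantom", "yellip",
                          (xc, zc, PHANTOM_AX, PHANTOM_AZ, -yh, yh),
                          case.phantom_material))

    # EPID stack, a-Si detector plane centred at Z = -54
    asi_half = 0.07 / 2.0
    z_asi_top = EPID_DETECTOR_Z + asi_half
    layers = [
        ("epid_copper", "copper", 0.1),
        ("epid_scintillator", "scintillator", 0.049),
        ("epid_asi", "silicon_panel", 0.07),
        ("epid_aluminum", "aluminum", 0.1),
        ("epid_lead", "lead", 0.3),
    ]
    z_hi = z_asi_top + 0.049 + 0.1  # copper top
    epid_mat = {True: "vacuum", False: None}[case.void_stopper]
    for name, mat, thick in layers:
        regions.append(Region(name, "box",
                              (-EPID_HALF, EPID_HALF, -EPID_HALF, EPID_HALF,
                               z_hi - thick, z_hi),
                              epid_mat or mat))
        z_hi -= thick

    sx, sy, sz = STOPPER_XYZ
    z0, z1 = STOPPER_TOP - sz, STOPPER_TOP
    t = STOPPER_SHELL
    regions.append(Region("stopper_core", "box",
                          (-sx / 2 + t, sx / 2 - t, -sy / 2 + t, sy / 2 - t,
                           z0 + t, z1 - t),
                          epid_mat or "lead_antimony"))
    regions.append(Region("stopper_shell", "box",
                          (-sx / 2, sx / 2, -sy / 2, sy / 2, z0, z1),
                          epid_mat or "steel"))

    regions.append(Region("bore", "ycyl",
                          (0.0, 0.0, BORE_RADIUS, -100.0, 100.0),
                          epid_mat or "air"))
    # a voided assembly also voids the surrounding air, so nothing at all
    # can scatter below the phantom (the "no scatterer" null geometry)
    return GeometryModel(regions,
                         world_material="vacuum" if case.void_stopper
                         else "air")
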