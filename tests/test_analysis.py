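"""Analysis endpoints: depth-dose curves, spectra, angular decomposition."""

import numpy as np
import pytest

from exitdose.analysis import (DEFAULT_SPECTRUM_EDGES, angular_profile,
                               backscatter_fraction, depth_dose,
                               divergence_angle_deg, spectrum)
from exitdose.transport import DoseGrid, PhaseSpaceBatch, PlaneSpec


def _batch(energy, x=None, y=None, weight=None, u=None, w=None,
           n_primaries=1):
    energy = np.atleast_1d(np.asarray(energy, dtype=float))
    n = len(energy)
    zeros = np.zeros(n)
    return PhaseSpaceBatch(
        energy, zeros if x is None else np.asarray(x, float),
        zeros if y is None else np.asarray(y, float),
        zeros if u is None else np.asarray(u, float), zeros,
        np.full(n, 1.0) if w is None else np.asarray(w, float),
        np.ones(n) if weight is None else np.asarray(weight, float),
        np.arange(n), plane=PlaneSpec(-50.5, +1),
        n_primaries=n_primaries)


# ---------------------------------------------------------------------------
# depth dose / fractions
# ---------------------------------------------------------------------------

def _uniform_result(value1, value2):
    class R:  # minimal StudyResult stand-in with congruent grids
        pass

    d1 = DoseGrid(0.0, -14.0)
    d2 = DoseGrid(0.0, -14.0)
    d1.s1[:] = value1
    d2.s1[:] = value2
    d1.s2[:] = d2.s2[:] = 1e-12
    d1.n_primaries = d2.n_primaries = 100
    r = R()
    r.d1, r.d2 = d1, d2
    r.d_total = d1.added(d2)
    r.d_total.n_primaries = 100

    class C:
        backscatter_metric = "local"

    r.case = C()
    return r


def test_uniform_grid_fraction_50_percent():
    """A synthetic grid with D2 = D1 everywhere gives 50% at all depths."""
    curve = depth_dose(_uniform_result(2.0, 2.0))
    assert np.allclose(curve.fraction_pct, 50.0)
    assert curve.distal_fraction("2mm") == pytest.approx(50.0)
    assert curve.distal_fraction("0.02mm") == pytest.approx(50.0)


def test_fraction_metric_definitions():
    r = _uniform_result(3.0, 1.0)
    local = backscatter_fraction(r.d1, r.d2, "local")
    stage1 = backscatter_fraction(r.d1, r.d2, "stage1")
    assert np.allclose(local, 25.0)
    assert np.allclose(stage1, 100.0 / 3.0)
    with pytest.raises(ValueError):
        backscatter_fraction(r.d1, r.d2, "other")


def test_fraction_matches_independent_ratio(small_case_ii):
    """Curve fractions equal the ratio recomputed from the raw grids."""
    curve = depth_dose(small_case_ii)
    d1 = small_case_ii.d1.dose()[:, 8, 6]
    d2 = small_case_ii.d2.dose()[:, 8, 6]
    with np.errstate(invalid="ignore"):
        expected = np.where(d1 + d2 > 0, 100 * d2 / (d1 + d2), 0.0)
    assert np.allclose(curve.fraction_pct, expected, atol=1e-12)


def test_empty_grid_raises():
    r = _uniform_result(1.0, 1.0)
    r.d1.n_primaries = 0
    with pytest.raises(ValueError, match="empty"):
        depth_dose(r)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def test_spectrum_normalisation_single_record():
    """One 1.0 MeV record, one primary, 0.1 MeV bins: value 10 /MeV."""
    s = spectrum(_batch([1.0]), primaries=1,
                 edges=np.arange(0.0, 6.6, 0.1))
    i = np.searchsorted(s.edges, 1.0, side="right") - 1
    assert s.value[i] == pytest.approx(10.0)
    assert s.mean_energy == pytest.approx(1.0)


def test_spectrum_integral_equals_weight():
    rng = np.random.default_rng(4)
    b = _batch(rng.uniform(0.02, 6.0, 5000),
               weight=rng.uniform(0.1, 2.0, 5000), n_primaries=777)
    s = spectrum(b, primaries=777)
    integral = (s.value * np.diff(s.edges)).sum() * 777
    assert integral == pytest.approx(b.total_weight, rel=1e-9)


def test_mean_energy_binning_invariant():
    rng = np.random.default_rng(8)
    b = _batch(rng.uniform(0.02, 6.0, 3000),
               weight=rng.uniform(0.1, 2.0, 3000))
    raw = np.average(b.energy, weights=b.weight)
    for edges in (np.linspace(0, 6.5, 14), DEFAULT_SPECTRUM_EDGES):
        s = spectrum(b, primaries=10, edges=edges)
        assert s.mean_energy == pytest.approx(raw, rel=1e-12)


def test_spectrum_errors():
    with pytest.raises(ValueError, match="primaries"):
        spectrum(_batch([1.0]), primaries=0)
    empty = PhaseSpaceBatch(*[np.zeros(0)] * 8, z=np.zeros(0))
    with pytest.raises(ValueError, match="empty"):
        spectrum(empty, primaries=10)


def test_count_ratio_vs_reference():
    b = _batch([0.3] * 10)
    ref = _batch([1.0] * 40)
    s = spectrum(b, primaries=100, reference=ref)
    assert s.count_ratio_pct == pytest.approx(25.0)


# ---------------------------------------------------------------------------
# angular decomposition
# ---------------------------------------------------------------------------

def test_ring_assignment_boundary():
    """A record at r = 15.82 cm on the -50.5 cm plane sits at 6.0 degrees
    and lands in the [6, 7) ring (half-open, lower edge inclusive)."""
    r = 150.5 * np.tan(np.radians(6.0))
    assert r == pytest.approx(15.82, abs=0.01)
    b = _batch([1.0], x=[r], y=[0.0])
    ang = divergence_angle_deg(b, 150.5)
    assert ang[0] == pytest.approx(6.0, abs=1e-9)
    prof = angular_profile(b)
    assert prof.source_to_plane_cm == pytest.approx(150.5)
    iring = int(np.nanargmax(np.nan_to_num(prof.weight)))
    assert prof.ring_edges_deg[iring] == pytest.approx(6.0)


def test_isotropic_constant_energy_stream():
    """A fixed-energy stream reports that energy in every occupied ring."""
    rng = np.random.default_rng(12)
    b = _batch(np.full(5000, 0.42), x=rng.uniform(-30, 30, 5000),
               y=rng.uniform(-30, 30, 5000), n_primaries=5000)
    prof = angular_profile(b)
    occupied = prof.weight > 0
    assert np.allclose(prof.mean_energy[occupied], 0.42)


def test_ring_intensity_area_closure():
    """Sum over rings of intensity x ring area recovers the weight that
    falls inside the ring system."""
    rng = np.random.default_rng(13)
    b = _batch(np.ones(20000), x=rng.uniform(-25, 25, 20000),
               y=rng.uniform(-25, 25, 20000), n_primaries=1)
    prof = angular_profile(b)
    edges_r = 150.5 * np.tan(np.radians(prof.ring_edges_deg))
    areas = np.pi * np.diff(edges_r**2)
    recovered = (prof.intensity * areas).sum() * 1  # n_primaries = 1
    rr = np.hypot(b.x, b.y)
    inside = b.weight[rr < edges_r[-1]].sum()
    assert recovered == pytest.approx(inside, rel=1e-9)


def test_direction_basis_flag():
    b = _batch([1.0], x=[10.0], y=[0.0], u=[np.sin(np.radians(30))],
               w=[np.cos(np.radians(30))])
    pos = divergence_angle_deg(b, 150.5, basis="position")
    dirn = divergence_angle_deg(b, 150.5, basis="direction")
    assert pos[0] == pytest.approx(np.degrees(np.arctan(10 / 150.5)))
    assert dirn[0] == pytest.approx(30.0, abs=1e-9)
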