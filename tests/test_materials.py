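"""Materials module: cross-section tables, Compton kinematics, samplers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from exitdose import kernels
from exitdose.materials import (MATERIAL_NAMES, FluorescenceShell, Material,
                                compton_scattered_energy, get_material,
                                get_table, mu_total, sample_compton,
                                sample_interaction_kind, sample_pair,
                                sample_photoelectric)

M_EC2 = 0.510998950


# ---------------------------------------------------------------------------
# table invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", MATERIAL_NAMES)
def test_table_invariants(name):
    """Total equals the sum of partials; coefficients are sane everywhere."""
    t = get_table(name)
    assert np.all(np.isfinite(t.total)) and np.all(t.total > 0)
    for col in (t.photoelectric, t.incoherent, t.pair):
        assert np.all(col >= 0) and not np.any(np.isnan(col))
    partial_sum = t.photoelectric + t.incoherent + t.pair
    assert np.max(np.abs(partial_sum - t.total) / t.total) < 1e-9
    # pair production strictly zero below threshold
    assert np.all(t.pair[t.energy < 2 * M_EC2] == 0.0)
    # log-spaced grid covering the specified range
    assert t.energy[0] == pytest.approx(0.001) and \
        t.energy[-1] == pytest.approx(7.0)
    assert np.diff(np.log(t.energy)).std() < 1e-9


def test_material_validation():
    with pytest.raises(ValueError, match="mass fractions"):
        Material("bad", 1.0, ((1, 0.5), (8, 0.4)))
    with pytest.raises(ValueError, match="density"):
        Material("bad", -1.0, ((1, 1.0),))
    with pytest.raises(ValueError, match="edge"):
        FluorescenceShell("K", 0.088, ((0.09, 1.0),), 0.9, 0.8)
    # fluorescence lines must sit strictly below their shell edge
    for shell in get_material("lead").fluorescence:
        for e, _p in shell.lines:
            assert e < shell.edge


# ---------------------------------------------------------------------------
# mu_total
# ---------------------------------------------------------------------------

def test_mu_total_endpoints_and_knots():
    """Interpolation passes exactly through the committed table rows."""
    for name in ("water", "lead"):
        t = get_table(name)
        rho = get_material(name).density
        for i in (0, 17, 40, len(t.energy) - 1):
            assert mu_total(name, float(t.energy[i])) == \
                pytest.approx(rho * t.total[i], rel=1e-9)


def test_mu_total_log_log_interpolation():
    """Agrees with a hand log-log interpolation of the bracketing rows."""
    t = get_table("water")
    e = 1.25
    i = np.searchsorted(t.energy, e) - 1
    f = (math.log(e) - math.log(t.energy[i])) / \
        (math.log(t.energy[i + 1]) - math.log(t.energy[i]))
    expected = math.exp((1 - f) * math.log(t.total[i])
                        + f * math.log(t.total[i + 1]))
    assert mu_total("water", e) == pytest.approx(expected, rel=1e-6)
    # and the value is physically sensible for water around 1.25 MeV
    assert 0.05 < mu_total("water", 1.25) < 0.08


def test_mu_total_range_error():
    with pytest.raises(ValueError, match="water") as err:
        mu_total("water", 8.0)
    assert "8.0" in str(err.value)
    with pytest.raises(ValueError, match="lead"):
        mu_total("lead", 1e-4)


# ---------------------------------------------------------------------------
# Compton kinematics and Klein-Nishina sampling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("energy,theta,expected", [
    (6.0, math.pi, 0.24506),
    (0.511, math.pi / 2, 0.2555),
    (1.0, 0.0, 1.0),
])
def test_compton_scattered_energy(energy, theta, expected):
    assert compton_scattered_energy(energy, theta) == \
        pytest.approx(expected, abs=5e-5)


def test_compton_scattered_energy_domain():
    with pytest.raises(ValueError):
        compton_scattered_energy(-1.0, 0.5)
    with pytest.raises(ValueError):
        compton_scattered_energy(1.0, 3.5)


@given(st.floats(0.02, 7.0))
@settings(max_examples=50, deadline=None)
def test_backscatter_energy_bound(energy):
    """180-degree single-scatter energy never exceeds mc^2/2 = 0.2555 MeV.

    This kinematic ceiling is what drives the soft backscatter spectrum."""
    assert compton_scattered_energy(energy, math.pi) <= M_EC2 / 2 + 1e-12


def test_sample_compton_consistency(rng):
    """Every sampled pair satisfies the Compton formula; kinematic bound."""
    for energy in (0.1, 0.511, 2.0, 6.0):
        for _ in range(200):
            eprime, theta, electron = sample_compton(energy, rng)
            assert eprime == pytest.approx(
                compton_scattered_energy(energy, theta), abs=1e-9)
            assert electron == pytest.approx(energy - eprime, abs=1e-12)
    # at 6 MeV no backward-hemisphere scatter exceeds mc^2
    es, cs = kernels.sample_compton_many(6.0, 20000, 99)
    assert np.all(es[cs < 0.0] < M_EC2)


def _klein_nishina_pdf(energy):
    """Normalised KN pdf of cos(theta) by numerical quadrature."""
    a = energy / M_EC2

    def dsdcos(c):
        r = 1.0 / (1.0 + a * (1.0 - c))  # E'/E
        return r**2 * (r + 1.0 / r - (1.0 - c**2))

    norm, _ = integrate.quad(dsdcos, -1, 1)
    return lambda c: dsdcos(c) / norm, dsdcos


def test_klein_nishina_sampler_vs_quadrature():
    """Sampled cos(theta) histogram matches the KN differential
    cross-section (quadrature oracle), chi-square p > 0.001 on 50 bins."""
    energy = 0.5
    n = 1_000_000
    _es, cos = kernels.sample_compton_many(energy, n, 2024)
    edges = np.linspace(-1, 1, 51)
    observed, _ = np.histogram(cos, bins=edges)
    pdf, _ = _klein_nishina_pdf(energy)
    expected = np.array([integrate.quad(pdf, lo, hi)[0]
                         for lo, hi in zip(edges[:-1], edges[1:])]) * n
    expected *= observed.sum() / expected.sum()
    chi2, p = stats.chisquare(observed, expected)
    assert p > 0.001


def test_sampled_mean_scattered_energy():
    """Mean E' from the sampler matches the quadrature first moment."""
    energy = 1.0
    es, _cos = kernels.sample_compton_many(energy, 200_000, 7)
    pdf, _ = _klein_nishina_pdf(energy)
    a = energy / M_EC2
    mean_quad, _ = integrate.quad(
        lambda c: pdf(c) * energy / (1.0 + a * (1.0 - c)), -1, 1)
    assert es.mean() == pytest.approx(mean_quad, rel=0.01)


# ---------------------------------------------------------------------------
# photoelectric + fluorescence, pair production
# ---------------------------------------------------------------------------

def test_photoelectric_lead_lines(rng):
    """Characteristic photons fall only in the K (72-88 keV) or
    L (9-13 keV) bands; energy is conserved at the vertex."""
    lead = get_material("lead")
    seen_k = seen_l = False
    for _ in range(3000):
        out = sample_photoelectric(lead, 0.2, rng)
        assert out.kind == "photoelectric"
        assert out.total_energy == pytest.approx(0.2, abs=1e-9)
        for e, d in out.secondary_photons:
            assert (0.072 <= e <= 0.088) or (0.009 <= e <= 0.013)
            assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-9)
            seen_k |= e > 0.05
            seen_l |= e < 0.02
    assert seen_k and seen_l


def test_photoelectric_below_k_edge(rng):
    """Below the 88 keV K edge no K-line photon is ever emitted."""
    lead = get_material("lead")
    for _ in range(2000):
        out = sample_photoelectric(lead, 0.05, rng)
        for e, _d in out.secondary_photons:
            assert e < 0.02  # L lines only


def test_photoelectric_water_no_secondaries(rng):
    for energy in (0.05, 0.5, 2.0):
        out = sample_photoelectric(get_material("water"), energy, rng)
        assert out.secondary_photons == ()
        assert out.deposited == energy


def test_pair_production(rng):
    out = sample_pair(2.0, rng)
    assert out.deposited == pytest.approx(0.978, abs=1e-3)
    (e1, d1), (e2, d2) = out.secondary_photons
    assert e1 == e2 == pytest.approx(0.511, abs=1e-3)
    assert float(np.dot(d1, d2)) == pytest.approx(-1.0, abs=1e-9)
    assert sample_pair(1.03, rng).deposited == pytest.approx(0.008, abs=1e-3)
    with pytest.raises(ValueError):
        sample_pair(1.0, rng)


@given(st.sampled_from(["water", "lead", "steel", "copper"]),
       st.floats(1.05, 6.9))
@settings(max_examples=40, deadline=None)
def test_vertex_energy_conservation(name, energy):
    """Incident energy = local deposit + secondaries at every vertex."""
    rng = np.random.default_rng(77)
    mat = get_material(name)
    for out in (sample_photoelectric(mat, energy, rng),
                sample_pair(energy, rng)):
        assert out.total_energy == pytest.approx(energy, abs=1e-9)


def test_interaction_kind_ratios(rng):
    """Sampling the interaction kind reproduces partial/total ratios
    within 3-sigma binomial error over 1e5 draws."""
    for name, energy in (("water", 0.05), ("lead", 0.3), ("lead", 3.0)):
        t = get_table(name)
        i = np.searchsorted(t.energy, energy)
        # exact interpolated shares at this energy via the table
        from exitdose.materials import default_pack
        p = default_pack()
        im = p.index[name]
        pe, inc, pair = kernels.mu_partials_kernel(
            im, energy, p.loge0, p.dloge, p.ne, p.mu4)
        probs = np.array([pe, inc, pair]) / (pe + inc + pair)
        n = 100_000
        kinds = [sample_interaction_kind(name, energy, rng)
                 for _ in range(n)]
        for k, label in enumerate(("photoelectric", "compton", "pair")):
            obs = sum(1 for x in kinds if x == label) / n
            sigma = math.sqrt(max(probs[k] * (1 - probs[k]), 1e-12) / n)
            assert abs(obs - probs[k]) < 3.5 * sigma + 1e-9
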