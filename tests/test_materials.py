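"""Semi-affine fiber law: stiffness, energy, orientation-averaged stress."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spherotfm as sp
from spherotfm.materials import MaterialParameters, fiber_tension


E = math.e


class TestFiberStiffness:
    @pytest.mark.parametrize(
        "eps,expected",
        [
            (0.0, 1645.0),                 # linear plateau value
            (0.0405, 1645.0 * E),          # one stiffening decay length past onset
            (-0.0008, 1645.0 / E),         # one buckling decay length
            (0.0075, 1645.0),              # value continuous at the onset strain
        ],
    )
    def test_branch_values(self, collagen12, eps, expected):
        assert sp.fiber_stiffness(eps, collagen12) == pytest.approx(expected, rel=1e-12)

    def test_continuity_at_joins_exact(self, collagen12):
        es = collagen12.eps_s
        h = 1e-14
        assert sp.fiber_stiffness(-h, collagen12) == pytest.approx(
            sp.fiber_stiffness(h, collagen12), rel=1e-10)
        assert sp.fiber_stiffness(es - h, collagen12) == pytest.approx(
            sp.fiber_stiffness(es + h, collagen12), rel=1e-10)

    def test_rejects_non_finite(self, collagen12):
        with pytest.raises(ValueError):
            sp.fiber_stiffness(float("nan"), collagen12)


class TestFiberEnergy:
    @pytest.mark.parametrize(
        "eps,expected",
        [
            (0.0, 0.0),
            (0.005, 0.0205625),        # k0 eps^2 / 2 in the linear branch
            # frozen from adaptive double quadrature of the stiffness law
            (-0.05, 0.0647472),
            (0.1, 23.9231444829),
        ],
    )
    def test_values(self, collagen12, eps, expected):
        assert sp.fiber_energy(eps, collagen12) == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_c1_and_convex_on_grid(self, collagen12):
        eps = np.arange(-0.5, 1.0, 0.01)
        w = sp.fiber_energy(eps, collagen12)
        second = np.diff(w, 2)
        assert np.all(second >= -1e-12)
        # w' matches centered difference of w away from the kinks; the FD
        # truncation error on the exponential branch is (h/ds)^2/6 ~ 1.5%
        mid = eps[1:-1]
        smooth = (np.abs(mid) > 0.02) & (np.abs(mid - collagen12.eps_s) > 0.04)
        fd = (w[2:] - w[:-2]) / 0.02
        assert np.allclose(fiber_tension(mid[smooth], collagen12), fd[smooth],
                           rtol=2e-2)

    def test_tension_zero_at_origin(self, collagen12):
        assert fiber_tension(0.0, collagen12) == 0.0

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(eps=st.floats(-0.9, 1.5))
    def test_energy_derivatives_consistent(self, eps):
        # w'(eps) is the derivative of w and kappa(eps) its second
        # derivative, at any strain away from the branch joins
        params = sp.get_preset("collagen-1.2")
        h = 1e-6
        if min(abs(eps), abs(eps - params.eps_s)) < 10 * h:
            return
        w = sp.fiber_energy(np.array([eps - h, eps, eps + h]), params)
        scale = max(abs(w[1]), 1e-6)
        assert (w[2] - w[0]) / (2 * h) == pytest.approx(
            fiber_tension(eps, params), rel=1e-5, abs=1e-6 * scale)
        assert (w[2] - 2 * w[1] + w[0]) / h**2 == pytest.approx(
            sp.fiber_stiffness(eps, params), rel=1e-3, abs=1e-3)


class TestUniaxialStress:
    def test_unstrained_reference(self, collagen12):
        assert sp.uniaxial_stress(0.0, collagen12) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_tension(self, collagen12):
        s1 = sp.uniaxial_stress(0.005, collagen12)
        s2 = sp.uniaxial_stress(0.01, collagen12)
        assert 0 < s1 < s2

    def test_quadrature_convergence(self, collagen12):
        eps = np.linspace(-0.3, 0.5, 17)
        eps = eps[np.abs(eps) > 1e-9]
        s_lo = sp.uniaxial_stress(eps, collagen12, n_quad=200)
        s_hi = sp.uniaxial_stress(eps, collagen12, n_quad=400)
        assert np.all(np.abs(s_hi - s_lo) <= 1e-3 * np.abs(s_hi))

    def test_rejects_total_compression(self, collagen12):
        with pytest.raises(ValueError):
            sp.uniaxial_stress(-1.0, collagen12)

    def test_secant_matches_tangent(self, collagen12):
        # at a smooth strain point the secant slope equals the tangent
        e0, h = 0.1, 1e-4
        secant = (sp.uniaxial_stress(e0 + h, collagen12)
                  - sp.uniaxial_stress(e0 - h, collagen12)) / (2 * h)
        assert secant == pytest.approx(sp.tangent_stiffness(e0, collagen12), rel=1e-6)
        # at zero strain the buckling kink separates the one-sided slope
        # (k0/5) from the central tangent by a couple of percent
        assert sp.uniaxial_stress(1e-4, collagen12) / 1e-4 == pytest.approx(
            sp.tangent_stiffness(0.0, collagen12), rel=0.03)


class TestTangentStiffness:
    def test_zero_strain_value(self, collagen12):
        # collagen 1.2 mg/ml: reported zero-strain gel stiffness 316 Pa
        assert sp.tangent_stiffness(0.0, collagen12) == pytest.approx(316.0, rel=0.05)

    def test_strain_stiffening_and_buckling(self, collagen12):
        k0 = sp.tangent_stiffness(0.0, collagen12)
        assert sp.tangent_stiffness(0.2, collagen12) > sp.tangent_stiffness(0.05, collagen12)
        assert sp.tangent_stiffness(-0.2, collagen12) < k0

    def test_buckling_disabled_limit(self, collagen12):
        # with buckling switched off the sphere average <cos^4> = 1/5 applies
        no_buckling = MaterialParameters(
            k0=collagen12.k0, d0=1e9, ds=collagen12.ds, eps_s=collagen12.eps_s)
        assert sp.tangent_stiffness(0.0, no_buckling) == pytest.approx(
            collagen12.k0 / 5.0, rel=1e-4)


class TestPresetsAndLoading:
    @pytest.mark.parametrize("name,k0", [
        ("collagen-0.6", 447.0), ("collagen-1.2", 1645.0), ("collagen-2.4", 5208.0),
    ])
    def test_presets(self, name, k0):
        p = sp.get_preset(name)
        assert (p.k0, p.d0, p.ds, p.eps_s) == (k0, 0.0008, 0.033, 0.0075)

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            sp.get_preset("fibrin-4.0")

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            MaterialParameters(k0=-1, d0=0.0008, ds=0.033, eps_s=0.0075)

    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_load_from_file(self, tmp_path, suffix, collagen12):
        path = tmp_path / f"mat{suffix}"
        if suffix == ".json":
            path.write_text('{"k0": 1645, "d0": 0.0008, "ds": 0.033, "eps_s": 0.0075}')
        else:
            path.write_text("k0: 1645\nd0: 0.0008\nds: 0.033\neps_s: 0.0075\n")
        assert sp.load_material(path) == collagen12
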