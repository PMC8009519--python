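"""CMC breakpoint fit, g(r) -> I(Q) transform, Ornstein-Zernike fit, and the
packing-parameter classifier."""

import numpy as np
import pytest

from hpfsurf.observables import RDFResult
from hpfsurf.postanalysis import (fit_cmc, fit_oz, packing_parameter,
                                  saxs_from_rdf)


def piecewise(conc, cmc=20.0, m1=-0.002, m2=-0.02):
    """Two lines meeting at the CMC (monomer fraction stays in [0, 1])."""
    conc = np.asarray(conc, dtype=float)
    y_at_cmc = 0.9 + m1 * cmc
    return np.where(conc <= cmc, 0.9 + m1 * conc,
                    y_at_cmc + m2 * (conc - cmc))


class TestCMC:
    def test_exact_piecewise_recovered_to_machine_precision(self):
        conc = np.array([1.0, 5.0, 10.0, 15.0, 25.0, 30.0, 40.0])
        fit = fit_cmc(conc, piecewise(conc))
        assert fit.cmc == pytest.approx(20.0, abs=1e-9)

    def test_noisy_planted_breakpoint_within_tolerance(self):
        rng = np.random.default_rng(42)
        conc = np.array([1, 2, 5, 10, 15, 25, 35, 50], dtype=float)
        y = piecewise(conc) * (1 + 0.01 * rng.standard_normal(len(conc)))
        fit = fit_cmc(conc, np.clip(y, 0, 1))
        assert abs(fit.cmc - 20.0) <= 1.0

    def test_rescaling_concentrations_rescales_cmc(self):
        conc = np.array([1.0, 5.0, 10.0, 15.0, 25.0, 30.0, 40.0])
        y = piecewise(conc)
        base = fit_cmc(conc, y).cmc
        scaled = fit_cmc(conc * 3.0, y).cmc
        assert scaled == pytest.approx(3.0 * base, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_cmc([1, 10, 30], [0.9, 0.8, 0.3])

    def test_parallel_regimes_rejected(self):
        conc = np.array([1.0, 2.0, 30.0, 40.0])
        y = 0.9 - 0.001 * conc
        with pytest.raises(ValueError):
            fit_cmc(conc, y)


def oz_rdf(xi=1.0, c=0.2, r_max=30.0, dr=0.01):
    r = np.arange(dr, r_max, dr)
    return RDFResult(r=r, g=1.0 + (c / r) * np.exp(-r / xi),
                     selection_a="s", selection_b="s", n_frames=1)


class TestSAXS:
    def test_uniform_g_gives_flat_intensity(self):
        r = np.arange(0.05, 10.0, 0.05)
        rdf = RDFResult(r=r, g=np.ones_like(r), selection_a="s",
                        selection_b="s", n_frames=1)
        curve = saxs_from_rdf(rdf, 1.0)
        assert np.allclose(curve.I, 1.0)
        assert curve.converged

    def test_oz_analytic_fourier_pair(self):
        """g = 1 + (c/r) e^{-r/xi}  <->  I = 1 + 4 pi rho c xi^2/(1+Q^2 xi^2)."""
        xi, c, rho = 1.0, 0.2, 0.5
        curve = saxs_from_rdf(oz_rdf(xi, c), rho)
        expected = 1.0 + 4 * np.pi * rho * c * xi**2 / (1 + curve.Q**2 * xi**2)
        assert np.allclose(curve.I, expected, rtol=0.01)

    def test_excess_intensity_linear_in_density(self):
        curve1 = saxs_from_rdf(oz_rdf(), 0.5)
        curve2 = saxs_from_rdf(oz_rdf(), 1.0)
        assert np.allclose(curve2.I - 1.0, 2.0 * (curve1.I - 1.0), rtol=1e-9)

    def test_direct_summation_oracle(self):
        """Trapezoid transform against a plain direct sum on a coarse table."""
        rng = np.random.default_rng(1)
        r = np.linspace(0.1, 5.0, 60)
        g = 1.0 + 0.3 * np.exp(-r) * np.cos(2 * r) + 0.01 * rng.standard_normal(60)
        g[-1] = 1.0
        rdf = RDFResult(r=r, g=g, selection_a="s", selection_b="s", n_frames=1)
        Q = np.linspace(0.2, 4.0, 20)
        curve = saxs_from_rdf(rdf, 0.7, Q=Q)
        for k, q in enumerate(Q):
            integrand = (g - 1.0) * r**2 * np.sin(q * r) / (q * r)
            direct = 1.0 + 4 * np.pi * 0.7 * np.trapezoid(integrand, r)
            assert curve.I[k] == pytest.approx(direct, abs=1e-6)

    def test_unconverged_tail_flagged(self):
        r = np.linspace(0.1, 2.0, 40)
        rdf = RDFResult(r=r, g=1.0 + 0.5 * np.exp(-r / 5.0), selection_a="s",
                        selection_b="s", n_frames=1)
        curve = saxs_from_rdf(rdf, 0.5)
        assert not curve.converged
        assert curve.warning is not None


class TestOZFit:
    def test_planted_parameters_recovered_with_noise(self):
        rng = np.random.default_rng(7)
        Q = np.linspace(0.05, 5.0, 120)
        I = 100.0 / (1 + Q**2 * 4.0) * (1 + 0.02 * rng.standard_normal(len(Q)))
        fit = fit_oz(Q, I)
        assert abs(fit.I0 - 100.0) / 100.0 < 0.05
        assert abs(fit.xi - 2.0) / 2.0 < 0.05

    def test_flat_curve_gives_zero_correlation_length(self):
        Q = np.linspace(0.1, 5.0, 50)
        fit = fit_oz(Q, np.full_like(Q, 7.0))
        assert fit.xi == pytest.approx(0.0, abs=1e-4)
        assert fit.I0 == pytest.approx(7.0, rel=1e-6)

    @pytest.mark.parametrize("xi", [0.1, 0.5, 1.0, 3.0, 10.0])
    def test_noiseless_recovery_across_xi_range(self, xi):
        Q = np.linspace(0.02, 5.0, 200)
        fit = fit_oz(Q, 10.0 / (1 + Q**2 * xi**2))
        assert fit.xi == pytest.approx(xi, rel=1e-4)

    def test_round_trip_through_fourier_transform(self):
        """saxs_from_rdf on the OZ-form g(r) refits the planted xi within 3%."""
        xi, c, rho = 1.0, 0.2, 0.5
        curve = saxs_from_rdf(oz_rdf(xi, c), rho)
        # the excess intensity I(Q) - 1 has the pure OZ form I0/(1+Q^2 xi^2)
        fit = fit_oz(curve.Q, curve.I - 1.0)
        assert abs(fit.xi - xi) / xi < 0.03
        assert abs(fit.I0 - 4 * np.pi * rho * c * xi**2) \
            / (4 * np.pi * rho * c * xi**2) < 0.03


class TestPackingParameter:
    def test_reference_geometry_is_cylindrical(self):
        res = packing_parameter(0.603, 1.55, 1.0)
        assert res.N_s == pytest.approx(0.603 / 1.55, rel=1e-12)
        assert res.N_s == pytest.approx(0.389, abs=5e-4)
        assert res.shape == "cylinder"

    def test_contour_length_geometry_is_spherical(self):
        res = packing_parameter(0.603, 1.55, 1.5)
        assert res.N_s == pytest.approx(0.259, abs=5e-4)
        assert res.shape == "sphere"

    def test_unit_ratio_sits_on_bilayer_boundary(self):
        res = packing_parameter(1.0, 1.0, 1.0)
        assert res.N_s == 1.0
        assert res.shape == "bilayer"

    def test_classification_monotone_in_tail_length(self):
        order = {"sphere": 0, "cylinder": 1, "bilayer": 2, "inverted": 3}
        prev = None
        for lt in np.linspace(0.2, 3.0, 30):
            cls = order[packing_parameter(0.603, 1.55, lt).shape]
            if prev is not None:
                assert cls <= prev   # longer tail never increases N_s class
            prev = cls

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            packing_parameter(0.0, 1.0, 1.0)
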