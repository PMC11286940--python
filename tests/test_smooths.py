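"""Cyclic spline basis construction and penalized GAM/HGAM fits."""

import numpy as np
import pandas as pd
import pytest

from isodiet.smooths import (
    build_cyclic_basis,
    fit_gam,
    fit_hgam,
    occurrence_curves,
)

# reference design matrix from an independent cyclic-cubic-spline
# construction: 5 evenly spaced knots on [1, 366], evaluated at
# x = (1, 50, 100, 200, 300, 366); coefficients are knot values
REFERENCE_X5 = np.array([
    [1.000000000000000, 0.000000000000000, 0.000000000000000, 0.000000000000000],
    [0.544755730469362, 0.641718279663871, -0.100133989003051, -0.086340021130182],
    [-0.053338070058635, 0.984535740083338, 0.073752869411877, -0.004950539436580],
    [-0.020088232647931, -0.091005781238352, 0.933823046293607, 0.177270967592676],
    [0.295904086453805, -0.041536446993319, -0.108570514913230, 0.854202875452744],
    [1.000000000000000, 0.000000000000000, 0.000000000000000, 0.000000000000000],
])

# reference penalty (normalized to unit spectral norm), same construction
REFERENCE_S5 = np.array([
    [0.31250, -0.25000, 0.18750, -0.25000],
    [-0.25000, 0.31250, -0.25000, 0.18750],
    [0.18750, -0.25000, 0.31250, -0.25000],
    [-0.25000, 0.18750, -0.25000, 0.31250],
])


class TestBasis:
    def test_matches_reference_construction(self):
        b = build_cyclic_basis(5)
        X = b.design_matrix([1, 50, 100, 200, 300, 366])
        assert np.allclose(X, REFERENCE_X5, atol=1e-9)
        assert np.allclose(b.penalty, REFERENCE_S5, atol=1e-9)

    def test_wrap_point_rows_identical(self):
        b = build_cyclic_basis(6)
        assert np.allclose(b.design_matrix([1.0]), b.design_matrix([366.0]),
                           atol=1e-12)

    def test_constant_in_null_space(self):
        b = build_cyclic_basis(7)
        ones = np.ones(b.n_coef)
        assert np.abs(b.penalty @ ones).max() < 1e-12
        # constant function reproduced exactly with constant coefficients
        x = np.linspace(1, 366, 50)
        assert np.allclose(b.design_matrix(x) @ (3.0 * ones), 3.0, atol=1e-10)

    def test_penalty_psd(self):
        for k in (4, 6, 8):
            evals = np.linalg.eigvalsh(build_cyclic_basis(k).penalty)
            assert evals.min() > -1e-10

    def test_continuity_across_wrap(self):
        """Value, slope and curvature agree on both sides of the wrap."""
        b = build_cyclic_basis(6)
        rng = np.random.default_rng(0)
        beta = rng.standard_normal(b.n_coef)

        def f(x):
            return (b.design_matrix(np.atleast_1d(x)) @ beta).item()

        h = 1e-3
        for order, tol in ((0, 1e-10), (1, 1e-5), (2, 1e-2)):
            # central stencils straddling the wrap from either side
            pts_lo = np.array([f(1.0 + i * h) for i in (-2, -1, 0, 1, 2)])
            pts_hi = np.array([f(366.0 + i * h) for i in (-2, -1, 0, 1, 2)])
            d_lo = np.diff(pts_lo, n=order)[len(pts_lo) // 2 - order] / h ** order
            d_hi = np.diff(pts_hi, n=order)[len(pts_hi) // 2 - order] / h ** order
            assert d_lo == pytest.approx(d_hi, abs=tol * max(1.0, abs(d_lo)))

    def test_k_too_small(self):
        with pytest.raises(ValueError):
            build_cyclic_basis(3)


class TestGamFit:
    def test_flat_bernoulli_truth(self, rng):
        x = rng.uniform(1, 366, 500)
        y = (rng.random(500) < 0.5).astype(float)
        fit = fit_gam(x, y, family="binomial", k=6)
        days = np.arange(1, 367)
        assert np.abs(fit.predict(days) - 0.5).max() < 0.1
        assert fit.edf < 2.5

    def test_sinusoid_recovery(self, rng):
        x = rng.uniform(1, 366, 400)
        truth = np.sin(2 * np.pi * x / 366)
        y = truth + 0.2 * rng.standard_normal(400)
        fit = fit_gam(x, y, family="gaussian", k=8)
        assert np.corrcoef(fit.predict(x), truth)[0, 1] > 0.95
        assert fit.p_value < 1e-6

    def test_huge_lambda_gives_constant(self, rng):
        x = rng.uniform(1, 366, 200)
        y = np.sin(2 * np.pi * x / 366) + 0.1 * rng.standard_normal(200)
        fit = fit_gam(x, y, family="gaussian", k=8, lambda_grid=[1e9])
        days = np.arange(1, 367)
        assert np.ptp(fit.predict(days)) < 1e-4
        assert fit.predict(days).mean() == pytest.approx(y.mean(), abs=1e-3)
        assert fit.edf == pytest.approx(1.0, abs=1e-3)

    def test_periodicity_of_fits(self, rng):
        x = rng.uniform(1, 366, 150)
        y = np.cos(2 * np.pi * x / 366) + 0.3 * rng.standard_normal(150)
        fit = fit_gam(x, y, family="gaussian", k=6)
        assert abs(fit.predict([1.0])[0] - fit.predict([366.0])[0]) < 1e-10

    def test_edf_bounds(self, rng):
        x = rng.uniform(1, 366, 100)
        y = rng.standard_normal(100)
        fit = fit_gam(x, y, family="gaussian", k=8)
        assert 1.0 - 1e-6 <= fit.edf <= 7.0 + 1e-6

    def test_roughness_monotone_in_lambda(self, rng):
        """More smoothing never increases the fitted roughness."""
        x = rng.uniform(1, 366, 200)
        y = np.sin(4 * np.pi * x / 366) + 0.2 * rng.standard_normal(200)
        b = build_cyclic_basis(8)
        rough = []
        for lam in (1e-3, 1e0, 1e3, 1e6):
            fit = fit_gam(x, y, family="gaussian", basis=b, lambda_grid=[lam])
            beta = fit.coefficients
            rough.append(float(beta @ b.penalty @ beta))
        assert all(a >= b_ - 1e-12 for a, b_ in zip(rough, rough[1:]))

    def test_gaussian_reduces_to_ridge(self, rng):
        """Fixed-lambda Gaussian fit equals the closed-form penalized solve."""
        x = rng.uniform(1, 366, 60)
        y = rng.standard_normal(60)
        b = build_cyclic_basis(6)
        lam = 2.5
        fit = fit_gam(x, y, family="gaussian", basis=b, lambda_grid=[lam])
        X = b.design_matrix(x)
        beta_ref = np.linalg.solve(X.T @ X + lam * b.penalty, X.T @ y)
        assert np.allclose(fit.coefficients, beta_ref, atol=1e-10)

    def test_reml_option_reasonable(self, rng):
        x = rng.uniform(1, 366, 300)
        truth = np.sin(2 * np.pi * x / 366)
        y = truth + 0.3 * rng.standard_normal(300)
        fit = fit_gam(x, y, family="gaussian", k=8, criterion="reml")
        assert np.corrcoef(fit.predict(x), truth)[0, 1] > 0.95

    def test_binomial_requires_01(self, rng):
        with pytest.raises(ValueError):
            fit_gam(np.arange(20.0), np.full(20, 0.5), family="binomial")


class TestHGam:
    def test_shared_truth_agreement(self, rng):
        x = rng.uniform(1, 366, 400)
        truth = np.sin(2 * np.pi * x / 366)
        y = truth + 0.2 * rng.standard_normal(400)
        groups = np.repeat(["g1", "g2"], 200)
        h = fit_hgam(x, y, groups, k=8)
        days = np.arange(1, 367, 10, dtype=float)
        diff = h.predict(days, "g1") - h.predict(days, "g2")
        assert np.abs(diff).max() < 0.25

    def test_constant_offset_in_intercepts(self, rng):
        x = rng.uniform(1, 366, 500)
        base = 0.5 * np.sin(2 * np.pi * x / 366)
        offset = 2.0
        y = np.where(np.arange(500) < 250, base, base + offset)
        y = y + 0.05 * rng.standard_normal(500)
        groups = np.repeat(["a", "b"], 250)
        h = fit_hgam(x, y, groups, k=8)
        assert (h.intercepts["b"] - h.intercepts["a"]) == pytest.approx(
            offset, abs=0.05
        )

    def test_singleton_group_rejected(self, rng):
        x = rng.uniform(1, 366, 11)
        y = rng.standard_normal(11)
        with pytest.raises(ValueError):
            fit_hgam(x, y, ["a"] * 10 + ["b"], k=4)


class TestOccurrence:
    def _tables(self, rng, peak_day=200):
        n = 250
        days = rng.uniform(1, 366, n)
        stomachs = pd.DataFrame(
            {"stomach_id": [f"s{i}" for i in range(n)], "day_of_year": days}
        )
        # von-Mises-shaped seasonal occurrence probability
        kappa = 2.0
        prob = np.exp(kappa * np.cos(2 * np.pi * (days - peak_day) / 366))
        prob = 0.05 + 0.85 * (prob - prob.min()) / (prob.max() - prob.min())
        present = rng.random(n) < prob
        prey = pd.DataFrame(
            {
                "stomach_id": [f"s{i}" for i in np.flatnonzero(present)],
                "taxon_name": "Caranx crysos",
                "taxon_rank": "species",
                "family": "Carangidae",
                "count": 1,
                "wet_weight_g": 5.0,
            }
        )
        return prey, stomachs

    def test_peak_recovery(self, rng):
        prey, stomachs = self._tables(rng, peak_day=200)
        out = occurrence_curves(prey, stomachs, k=6)
        row = out[out["taxon"] == "Carangidae"].iloc[0]
        assert not row["degenerate"]
        assert abs(row["peak_day"] - 200) <= 20
        curve = row["fit"].predict(np.arange(1, 367))
        assert ((curve > 0) & (curve < 1)).all()

    def test_all_present_flagged_degenerate(self):
        stomachs = pd.DataFrame(
            {"stomach_id": [f"s{i}" for i in range(20)],
             "day_of_year": np.linspace(1, 366, 20)}
        )
        prey = pd.DataFrame(
            {
                "stomach_id": stomachs["stomach_id"],
                "taxon_name": "X", "taxon_rank": "species", "family": "Xidae",
                "count": 1, "wet_weight_g": 1.0,
            }
        )
        out = occurrence_curves(prey, stomachs, k=6)
        assert out.iloc[0]["degenerate"]
        assert out.iloc[0]["fit"] is None
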