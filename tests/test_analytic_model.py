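"""Linkage-equilibrium flux engine: fixation probability, integrals, roots."""

import numpy as np
import pytest

from mutvortex.analytic_model import (
    ModelParams,
    VortexModel,
    beneficial_flux,
    deleterious_flux,
    drought_meltdown_ratio,
    env_rate,
    find_ncrit,
    flux_derivative,
    net_flux,
    pfix,
    sweep,
    whitlock_ncrit,
)
from mutvortex.dfe import ExponentialBeneficialDFE, GammaDeleteriousDFE
from mutvortex.exceptions import InvalidParameterError, NoRootError


def _chain_absorption_probability(s: float, two_n: int) -> float:
    """Absorption probability at 2N copies for a single copy, by linear solve.

    Birth-death Moran chain on mutant copy number k: per event one of the
    2N copies dies uniformly and is replaced by a copy drawn with success
    ratio e^s per mutant copy.  Independent oracle for the closed-form
    fixation probability.
    """
    m = two_n
    r = np.exp(s)
    # interior states 1..m-1; u_0 = 0, u_m = 1
    a = np.zeros((m - 1, m - 1))
    b = np.zeros(m - 1)
    for k in range(1, m):
        up = (k * r / (k * r + (m - k))) * ((m - k) / m)
        down = ((m - k) / (k * r + (m - k))) * (k / m)
        stay = 1.0 - up - down
        row = k - 1
        a[row, row] = 1.0 - stay
        if k + 1 <= m - 1:
            a[row, row + 1] = -up
        else:
            b[row] += up  # u_m = 1
        if k - 1 >= 1:
            a[row, row - 1] = -down
    u = np.linalg.solve(a, b)
    return float(u[0])


class TestPfix:
    @pytest.mark.parametrize("n", [10, 100, 3666])
    def test_neutral_limit(self, n):
        assert pfix(0.0, n) == pytest.approx(1.0 / (2 * n))
        # continuity: tiny s approaches the limit
        assert pfix(1e-13, n) == pytest.approx(1.0 / (2 * n), rel=1e-6)

    @pytest.mark.parametrize(
        "s, n, expected",
        [
            # frozen from a 12-digit symbolic evaluation of the closed form
            (0.001, 3666, 1.00015453148e-3),
            (-0.001, 3666, 6.55019546716e-7),
        ],
    )
    def test_high_precision_values(self, s, n, expected):
        assert pfix(s, n) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("s", [-0.3, -0.05, -0.001, 0.001, 0.05, 0.3])
    @pytest.mark.parametrize("two_n", [4, 10, 20])
    def test_matches_birth_death_chain(self, s, two_n):
        oracle = _chain_absorption_probability(s, two_n)
        assert pfix(s, two_n / 2) == pytest.approx(oracle, abs=1e-12, rel=1e-12)

    def test_overflow_safe_extremes(self):
        with np.errstate(over="raise", invalid="raise", divide="raise"):
            assert pfix(-1000.0, 1e6) == 0.0
            assert pfix(1000.0, 10) == pytest.approx(1.0)
            assert pfix(-0.5, 1e6) >= 0.0
            arr = pfix(np.array([-1000.0, -0.5, -1e-16, 0.3, 1000.0]), 1e6)
        assert np.all((arr >= 0) & (arr <= 1))

    def test_vector_agrees_with_scalar(self):
        s = np.linspace(-0.2, 0.2, 101)
        vec = pfix(s, 500)
        scal = np.array([pfix(float(x), 500) for x in s])
        np.testing.assert_allclose(vec, scal, rtol=1e-14)

    def test_rejects_small_n(self):
        with pytest.raises(InvalidParameterError):
            pfix(0.01, 0.5)


class TestFluxes:
    def test_zero_rates(self, default_params):
        from dataclasses import replace

        assert deleterious_flux(replace(default_params, ud=0.0), 1000) == 0.0
        assert beneficial_flux(replace(default_params, ub=0.0), 1000) == 0.0

    @pytest.mark.parametrize("n", [300, 1000, 3666])
    def test_deleterious_flux_monte_carlo(self, default_params, n, rng):
        draws = default_params.deleterious_dfe.sample(10**7, rng)
        vals = 2.0 * draws * pfix(draws, n)
        mc = default_params.ud * n * vals.mean()
        se = default_params.ud * n * vals.std() / np.sqrt(len(vals))
        quad = deleterious_flux(default_params, n)
        assert quad < 0
        assert abs(quad - mc) < 3 * se
        assert abs(quad - mc) < 0.005 * abs(quad)

    @pytest.mark.parametrize("n", [300, 1000, 3666])
    def test_beneficial_flux_monte_carlo(self, default_params, n, rng):
        draws = default_params.beneficial_dfe.sample(10**7, rng)
        vals = 2.0 * draws * pfix(draws, n)
        mc = default_params.ub * n * vals.mean()
        se = default_params.ub * n * vals.std() / np.sqrt(len(vals))
        quad = beneficial_flux(default_params, n)
        assert quad > 0
        assert abs(quad - mc) < 3 * se
        assert abs(quad - mc) < 0.005 * quad

    def test_flux_magnitudes_monotone_in_n(self, default_params):
        ns = [100, 500, 2000, 10_000, 100_000]
        vds = [abs(deleterious_flux(default_params, n)) for n in ns]
        vbs = [beneficial_flux(default_params, n) for n in ns]
        assert all(a > b for a, b in zip(vds, vds[1:]))  # |vd| shrinks with N
        assert all(a < b for a, b in zip(vbs, vbs[1:]))  # vb grows with N

    def test_large_n_beneficial_saturation(self):
        # pfix -> 1-e^-s at large N, so vb/N -> Ub * E[2s(1-e^-s)]
        params = ModelParams(
            ud=0.0,
            ub=0.01,
            deleterious_dfe=GammaDeleteriousDFE(0.169, 0.056),
            beneficial_dfe=ExponentialBeneficialDFE(0.001),
        )
        n = 5e6
        per_capita = beneficial_flux(params, n) / n
        rng = np.random.default_rng(7)
        draws = params.beneficial_dfe.sample(10**6, rng)
        limit = params.ub * np.mean(2 * draws * -np.expm1(-draws))
        assert per_capita == pytest.approx(limit, rel=0.01)

    def test_net_flux_composition(self, default_params):
        from dataclasses import replace

        params = replace(default_params, delta_env=-1e-6)
        fx = net_flux(params, 2000)
        assert fx.vnet == fx.vd + fx.vb + params.delta_env
        empty = replace(params, ud=0.0, ub=0.0)
        assert net_flux(empty, 2000).vnet == -1e-6


class TestNcrit:
    def test_sign_change_around_root(self, default_params, fitted_default):
        assert net_flux(default_params, 2000).vnet < 0
        assert net_flux(default_params, 6000).vnet > 0
        assert 2000 < fitted_default.ncrit < 6000

    def test_root_is_zero_of_vnet(self, default_params, fitted_default):
        assert abs(net_flux(default_params, fitted_default.ncrit).vnet) < 1e-10

    def test_constructed_root(self, default_params):
        from dataclasses import replace

        # scale Ub so vb exactly cancels vd at N=5000
        target = 5000.0
        vd = deleterious_flux(default_params, target)
        vb_unit = beneficial_flux(replace(default_params, ub=1.0), target)
        params = replace(default_params, ub=-vd / vb_unit)
        assert find_ncrit(params) == pytest.approx(target, rel=1e-3)

    def test_no_root_when_no_beneficials(self, default_params):
        from dataclasses import replace

        with pytest.raises(NoRootError) as exc:
            find_ncrit(replace(default_params, ub=0.0))
        assert exc.value.endpoints is not None

    def test_vnet_increasing_through_tipping_point(self, default_params, fitted_default):
        nc = fitted_default.ncrit
        ns = np.linspace(nc / 2, 2 * nc, 6)
        vals = [net_flux(default_params, n).vnet for n in ns]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestDerivatives:
    def test_zero_rate_derivative(self, default_params):
        from dataclasses import replace

        assert flux_derivative(replace(default_params, ud=0.0), 1000, "deleterious") == 0.0

    @pytest.mark.parametrize("which", ["deleterious", "beneficial"])
    def test_central_difference_agreement(self, default_params, which):
        n = 3000.0
        flux = deleterious_flux if which == "deleterious" else beneficial_flux
        analytic = flux_derivative(default_params, n, which)
        numeric = (flux(default_params, n + 1) - flux(default_params, n - 1)) / 2.0
        assert analytic == pytest.approx(numeric, rel=1e-3)

    def test_both_positive_at_ncrit(self, fitted_default):
        assert fitted_default.ratio_result.dvd_dN > 0
        assert fitted_default.ratio_result.dvb_dN > 0

    def test_delta_env_does_not_change_derivatives(self, default_params):
        from dataclasses import replace

        env = replace(default_params, delta_env=-1.5e-5)
        for which in ("deleterious", "beneficial"):
            assert flux_derivative(default_params, 4000, which) == pytest.approx(
                flux_derivative(env, 4000, which), rel=1e-12
            )

    def test_invalid_which(self, default_params):
        with pytest.raises(InvalidParameterError):
            flux_derivative(default_params, 1000, "neutral")


class TestRatio:
    def test_scale_invariance_of_mutation_rates(self, default_params, fitted_default):
        from dataclasses import replace

        base = fitted_default.ratio
        for factor in (0.5, 2.0, 5.0):
            scaled = replace(
                default_params, ud=default_params.ud * factor, ub=default_params.ub * factor
            )
            res = drought_meltdown_ratio(scaled)
            assert res.ratio == pytest.approx(base, rel=1e-4)
            assert res.ncrit == pytest.approx(fitted_default.ncrit, rel=1e-4)

    def test_monotone_in_beneficial_effect(self):
        # weaker beneficial effects make drought (slightly) less important
        ratios = [
            drought_meltdown_ratio(ModelParams.default(sb_mean=sb)).ratio
            for sb in (0.0004, 0.001, 0.003)
        ]
        assert ratios[0] < ratios[1] < ratios[2]

    def test_monotone_in_deleterious_effect(self, default_params):
        from dataclasses import replace

        from mutvortex.dfe import with_mean

        ratios = []
        for sd in (-0.004, -0.0095, -0.02):
            dfe = with_mean(default_params.deleterious_dfe, sd)
            ratios.append(
                drought_meltdown_ratio(replace(default_params, deleterious_dfe=dfe)).ratio
            )
        # stronger deleterious effects make drought less important
        assert ratios[0] > ratios[1] > ratios[2]

    def test_monotone_in_cv(self, default_params):
        from dataclasses import replace

        from mutvortex.dfe import with_cv

        ratios = []
        for cv in (1.2, 2.4, 3.6):
            dfe = with_cv(default_params.deleterious_dfe, cv)
            ratios.append(
                drought_meltdown_ratio(replace(default_params, deleterious_dfe=dfe)).ratio
            )
        # overdispersion of deleterious effects favours drought
        assert ratios[0] < ratios[1] < ratios[2]


class TestWhitlockClosedForm:
    def test_unit_cube_root(self):
        params = ModelParams(
            ud=1.0,
            ub=1.0,
            deleterious_dfe=GammaDeleteriousDFE(1.0, 0.25),
            beneficial_dfe=ExponentialBeneficialDFE(0.25),
        )
        assert whitlock_ncrit(params) == pytest.approx(2.0)

    def test_cube_root_homogeneity(self, default_params):
        from dataclasses import replace

        base = whitlock_ncrit(default_params)
        assert whitlock_ncrit(replace(default_params, ud=8 * default_params.ud)) == pytest.approx(
            2 * base
        )

    def test_underestimates_quadrature_root(self, default_params, fitted_default):
        assert whitlock_ncrit(default_params) < fitted_default.ncrit


class TestEnvRate:
    def test_range_endpoints(self):
        assert env_rate(1e5) == pytest.approx(-1e-6)
        assert env_rate(10**2.5) == pytest.approx(-(10**-3.5))

    def test_round_trip(self):
        delta = -1.5e-5
        gens = -0.1 / delta
        assert gens == pytest.approx(20000 / 3)
        assert env_rate(gens) == pytest.approx(delta)

    def test_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            env_rate(0.0)


class TestSweep:
    def test_single_cell_matches_direct(self, fitted_default):
        df = sweep()
        assert len(df) == 1
        assert df.loc[0, "ncrit"] == pytest.approx(fitted_default.ncrit, rel=1e-6)
        assert df.loc[0, "ratio"] == pytest.approx(fitted_default.ratio, rel=1e-6)

    def test_no_root_rows_flagged_not_dropped(self):
        df = sweep(delta_env=(0.0, -1.0))
        assert len(df) == 2
        bad = df[df.status != "ok"]
        assert len(bad) == 1
        assert np.isnan(bad.iloc[0]["ncrit"])

    def test_ncrit_increases_with_environmental_decline(self):
        df = sweep(delta_env=(0.0, -5e-6, -1.5e-5))
        ncrits = df.sort_values("delta_env", ascending=False)["ncrit"].to_numpy()
        assert ncrits[0] < ncrits[1] < ncrits[2]


class TestModelObject:
    def test_summary_contains_headline_quantities(self, fitted_default):
        text = fitted_default.summary()
        assert "Ncrit" in text and "drought:meltdown" in text
        assert f"{fitted_default.ncrit:.1f}" in text

    def test_from_preset_equivalent_to_params(self, fitted_default):
        res = VortexModel.from_preset().fit()
        assert res.ncrit == fitted_default.ncrit
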