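"""Fitting machinery: objective, goodness-of-fit, multistart, filters."""

import numpy as np
import pytest
from scipy import stats

import meiqxkin as mk
from meiqxkin.fitting import (
    P_VALUE_GATE,
    SearchSpace,
    _monotone_verdict,
    _ResidualProblem,
    filter_fits,
    fit_multistart,
)
from meiqxkin.model import SPECIES


# ---------------------------------------------------------------------------
# chi-square objective
# ---------------------------------------------------------------------------


def test_chi_square_zero_for_generating_parameters(nominal_params, noise_free_obs):
    assert mk.chi_square(nominal_params, noise_free_obs) < 1e-6


def test_chi_square_unit_for_one_sigma_offset(nominal_params, noise_free_obs):
    """Multiplying one observation by exp(sigma) adds exactly one unit."""
    table = noise_free_obs.table.copy()
    mask = (
        (table.compound == "c_hydroxy_meiqx") & (table.time_h == 24.0) & (table.dose_uM == 1.0)
    )
    assert mask.sum() == 1
    table.loc[mask, "y_obs_M"] *= np.exp(table.loc[mask, "sigma_log"])
    shifted = mk.ObservationSet(
        table=table,
        sigma_log=noise_free_obs.sigma_log,
        log_floor_M=noise_free_obs.log_floor_M,
    )
    assert mk.chi_square(nominal_params, shifted) == pytest.approx(1.0, abs=1e-3)


def test_chi_square_matches_loop_oracle(nominal_params, hl1_obs):
    """Vectorised objective equals a plain record-by-record summation."""
    total = 0.0
    floor = hl1_obs.log_floor_M
    cache = {}
    for row in hl1_obs.table.itertuples(index=False):
        key = row.dose_uM
        if key not in cache:
            cache[key] = mk.simulate(
                nominal_params, row.dose_uM * 1e-6, t_grid=np.array([0.0, 24.0])
            )
        traj = cache[key]
        ym = traj.states[0 if row.time_h == 0.0 else 1, SPECIES.index(row.compound)]
        r = (np.log(max(ym, floor)) - np.log(max(row.y_obs_M, floor))) / row.sigma_log
        total += r * r
    assert mk.chi_square(nominal_params, hl1_obs) == pytest.approx(total, rel=1e-9)


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def test_goodness_pvalue_limits():
    assert mk.goodness_pvalue(0.0, 48, 22) == 1.0
    assert mk.goodness_pvalue(1e6, 48, 22) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        mk.goodness_pvalue(1.0, 10, 10)


def test_goodness_pvalue_at_dof_matches_simulation_oracle(rng):
    """Survival probability at chi2 = dof, checked against Monte Carlo."""
    dof = 26
    p = mk.goodness_pvalue(float(dof), 48, 22)
    draws = rng.chisquare(dof, size=400_000)
    assert p == pytest.approx(float(np.mean(draws > dof)), abs=3e-3)
    assert 0.4 < p < 0.6


# ---------------------------------------------------------------------------
# search space and parameter transform
# ---------------------------------------------------------------------------


def test_search_space_validation():
    with pytest.raises(ValueError):
        SearchSpace(bounds={"k1": (1.0, 0.5)}, scale={"k1": "log"})
    with pytest.raises(ValueError):
        SearchSpace(bounds={"k1": (0.0, 1.0)}, scale={"k1": "log"})
    with pytest.raises(ValueError):
        SearchSpace(bounds={"k1": (0.0, 1.0)}, scale={"k1": "weird"})


def test_decode_respects_sigmoid_constraint(hl1_obs, rng):
    """Transformed draws always decode to valid parameters with a + b <= 1."""
    prob = _ResidualProblem("dose_dependent", hl1_obs, SearchSpace.default("dose_dependent"))
    for _ in range(50):
        params = prob.decode(prob.sample_start(rng))
        d = params.dist
        assert d.alpha_sigmoid.a + d.alpha_sigmoid.b <= 1.0 + 1e-12
        assert d.beta_sigmoid.a + d.beta_sigmoid.b <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# multistart determinism and self-consistency
# ---------------------------------------------------------------------------


def test_fit_multistart_deterministic(noise_free_obs):
    a = fit_multistart("saturation", noise_free_obs, n_starts=1, seed=77, max_nfev=60)
    b = fit_multistart("saturation", noise_free_obs, n_starts=1, seed=77, max_nfev=60)
    assert a[0].chi2 == b[0].chi2
    assert a[0].params == b[0].params


def test_fit_multistart_validates_n_starts(noise_free_obs):
    with pytest.raises(ValueError):
        fit_multistart("saturation", noise_free_obs, n_starts=0)


# ---------------------------------------------------------------------------
# a-posteriori filters
# ---------------------------------------------------------------------------


class _FakeTraj:
    def __init__(self, states):
        self.states = states
        self.times = np.linspace(0.0, 24.0, len(states))


def test_monotone_verdict_detects_product_dip():
    n = 50
    states = np.zeros((n, 8))
    states[:, 0] = np.linspace(1e-6, 0.0, n)  # parent decays
    good = np.linspace(0.0, 1e-6, n)
    for k in range(1, 8):
        states[:, k] = good
    assert _monotone_verdict(_FakeTraj(states.copy()), 1e-15) is None
    dipped = states.copy()
    dipped[25, 2] -= 5e-8  # transient dip in a terminal product
    assert "meiqx_n2_gl" in _monotone_verdict(_FakeTraj(dipped), 1e-15)
    twopeak = states.copy()
    twopeak[:, 5] = 1e-7 * np.abs(np.sin(np.linspace(0, 2 * np.pi, n)))
    assert "single-peaked" in _monotone_verdict(_FakeTraj(twopeak), 1e-15)


def test_filter_accepts_generating_parameters(nominal_params, noise_free_obs):
    """The truth has p = 1 and trivially satisfies its own filters."""
    chi2 = mk.chi_square(nominal_params, noise_free_obs)
    fit = mk.FitResult(
        params=nominal_params,
        chi2=chi2,
        p_value=mk.goodness_pvalue(chi2, 48, 22),
        n_data=48, n_free=22, start_index=0, seed=0, converged=True,
    )
    ens = filter_fits([fit], noise_free_obs)
    assert len(ens) == 1
    assert ens.filter_log[0]["verdict"] == "accepted"


def test_filter_rejects_low_pvalue(nominal_params, noise_free_obs):
    fit = mk.FitResult(
        params=nominal_params, chi2=500.0,
        p_value=mk.goodness_pvalue(500.0, 48, 22),
        n_data=48, n_free=22, start_index=1, seed=0, converged=True,
    )
    ens = filter_fits([fit], noise_free_obs)
    assert len(ens) == 0
    assert "below gate" in ens.filter_log[0]["verdict"]


def test_filter_rejects_c_hydroxy_deviation(nominal_params, noise_free_obs):
    """Shrinking the observed C-Hydroxy value by 20% puts the (perfectly
    simulated) model outside the ±10% deviation band."""
    table = noise_free_obs.table.copy()
    mask = (
        (table.compound == "c_hydroxy_meiqx") & (table.time_h == 24.0) & (table.dose_uM == 1.0)
    )
    table.loc[mask, "y_obs_M"] /= 1.2
    shifted = mk.ObservationSet(
        table=table, sigma_log=noise_free_obs.sigma_log,
        log_floor_M=noise_free_obs.log_floor_M,
    )
    chi2 = mk.chi_square(nominal_params, shifted)
    fit = mk.FitResult(
        params=nominal_params, chi2=chi2,
        p_value=mk.goodness_pvalue(chi2, 48, 22),
        n_data=48, n_free=22, start_index=0, seed=0, converged=True,
    )
    ens = filter_fits([fit], shifted)
    if fit.p_value >= P_VALUE_GATE:
        assert len(ens) == 0
        assert "C-Hydroxy" in ens.filter_log[0]["verdict"]


# ---------------------------------------------------------------------------
# hypothesis comparison
# ---------------------------------------------------------------------------


def test_compare_hypotheses_on_saturation_truth(saturation_params):
    """Data generated under fixed partition coefficients do not reject the
    saturation hypothesis, and the nested dose-dependent model is never
    worse than the saturation one at equal budget."""
    obs = mk.generate_observations(
        mk.GeneratorConfig(true_params=saturation_params, noise_sd_log=0.05, seed=23)
    )
    report = mk.compare_hypotheses(obs, n_starts=20, seed=5)
    assert report.verdict["saturation"] == "accepted"
    assert report.best_chi2["dose_dependent"] <= report.best_chi2["saturation"] + 1e-6
    # Table-style local scores: 8 compounds x 3 doses per hypothesis
    counts = report.local_chi2.groupby("hypothesis").size()
    assert set(counts) == {24}


# ---------------------------------------------------------------------------
# ensemble serialisation
# ---------------------------------------------------------------------------


def test_ensemble_round_trip(tmp_path, nominal_params, noise_free_obs):
    chi2 = mk.chi_square(nominal_params, noise_free_obs)
    fit = mk.FitResult(
        params=nominal_params, chi2=chi2,
        p_value=mk.goodness_pvalue(chi2, 48, 22),
        n_data=48, n_free=22, start_index=3, seed=9, converged=True,
    )
    ens = mk.Ensemble(accepted=[fit], hypothesis="dose_dependent", filter_log=[])
    path = tmp_path / "ens.json"
    ens.to_json(path)
    back = mk.Ensemble.from_json(path)
    assert back.hypothesis == "dose_dependent"
    assert back.accepted[0].params == nominal_params
    assert back.accepted[0].chi2 == fit.chi2
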