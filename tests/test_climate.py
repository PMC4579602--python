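"""DHM machinery, exceedance probabilities, trajectories and downscaling."""

import numpy as np
import pytest

from conftest import make_forcing
from reefplan.climate import (
    ForcingError,
    TaxonParams,
    TrajectoryConfigError,
    TrajectoryParams,
    TrajectoryState,
    annual_max_dhm,
    compute_dhm,
    degradation_rate,
    degrade_habitat,
    dhm_exceedance,
    expected_bleaching_mortality,
    interpolate_to_grid,
    monthly_climatology_max,
    run_trajectory,
    step_trajectory,
)

YEARS = np.arange(1865, 2051)


def constant_forcing(value=27.0, n_runs=2, n_cells=1, omega=3.8):
    sst = np.full((n_cells, n_runs, YEARS.size, 12), float(value))
    f = make_forcing(sst, YEARS)
    f.aragonite[:] = omega
    return f


# ------------------------------------------------------------ climatology


def test_climatology_constant():
    assert monthly_climatology_max(constant_forcing(28.0))[0] == pytest.approx(28.0)


def test_climatology_seasonal_peak():
    sst = np.full((1, 1, YEARS.size, 12), 27.0)
    sst[0, 0, :, :] = 27.0 + 3.0 * np.cos(2 * np.pi * (np.arange(12) - 5) / 12)
    f = make_forcing(sst, YEARS)
    assert monthly_climatology_max(f)[0] == pytest.approx(30.0)


def test_climatology_averages_runs():
    sst = np.empty((1, 2, YEARS.size, 12))
    sst[0, 0] = 27.0
    sst[0, 1] = 29.0
    f = make_forcing(sst, YEARS)
    assert monthly_climatology_max(f)[0] == pytest.approx(28.0)


def test_climatology_missing_reference_years():
    f = make_forcing(np.full((1, 1, 50, 12), 27.0), np.arange(1865, 1915))
    with pytest.raises(ForcingError, match="missing"):
        monthly_climatology_max(f)


# -------------------------------------------------------------------- DHM


def test_dhm_zero_below_climatology():
    assert compute_dhm(np.full(12, 27.0), 28.0) == 0.0


def test_dhm_four_consecutive_hot_months():
    sst = np.full(12, 27.0)
    sst[3:7] = 29.0  # +1 over a 28-degree threshold, 4 months in a row
    assert compute_dhm(sst, 28.0) == pytest.approx(4.0)


def test_dhm_nonadjacent_hot_months_do_not_accumulate():
    sst = np.full(12, 27.0)
    sst[0] = 30.0
    sst[6] = 30.0  # +2 each, but no 4-month window holds both
    assert compute_dhm(sst, 28.0) == pytest.approx(2.0)


def test_dhm_translation_invariance():
    rng = np.random.default_rng(2)
    for _ in range(20):
        sst = 27.0 + rng.normal(0, 1.5, 12)
        clim = 27.5
        shift = rng.uniform(-3, 3)
        assert compute_dhm(sst + shift, clim + shift) == pytest.approx(
            compute_dhm(sst, clim), abs=1e-10
        )


def test_annual_max_dhm_matches_scalar_version():
    rng = np.random.default_rng(3)
    sst = 27.0 + rng.normal(0, 1.0, (2, 3, 5, 12))
    f = make_forcing(sst, np.arange(2000, 2005), aragonite=np.full((2, 5), 3.8))
    clim = np.array([27.2, 27.6])
    dhm = annual_max_dhm(f, clim)
    for c in range(2):
        for r in range(3):
            for y in range(5):
                assert dhm[c, r, y] == pytest.approx(
                    compute_dhm(sst[c, r, y], clim[c])
                )


# ------------------------------------------------------------- exceedance


@pytest.mark.parametrize("n_runs, expected_n", [(8, 80), (2, 20)])
def test_exceedance_sample_counts(n_runs, expected_n):
    dhm = np.zeros((1, n_runs, 15))
    result = dhm_exceedance(dhm, window=10)
    assert result.n_samples[-1] == expected_n
    assert not result.truncated[-1]
    assert result.truncated[0]
    assert result.n_samples[0] == n_runs  # truncated edge window


def test_exceedance_zero_stress():
    result = dhm_exceedance(np.zeros((2, 2, 12)))
    assert np.all(result.prob == 0.0)


def test_exceedance_monotone_and_bounded():
    rng = np.random.default_rng(4)
    dhm = rng.exponential(2.0, (3, 4, 20))
    prob = dhm_exceedance(dhm).prob
    assert prob.min() >= 0 and prob.max() <= 1
    assert (np.diff(prob, axis=-1) <= 1e-12).all()  # non-increasing in x


def test_exceedance_counts_by_hand():
    dhm = np.array([[[0.5, 1.5, 2.5, 3.5]]])  # 1 cell, 1 run, 4 years
    result = dhm_exceedance(dhm, window=10)
    # year 3 window holds all 4 samples; 3 exceed 1, 2 exceed 2
    assert result.prob[0, 3, 0] == pytest.approx(3 / 4)
    assert result.prob[0, 3, 1] == pytest.approx(2 / 4)


# ------------------------------------------------------------- trajectory


def toy_params():
    return TrajectoryParams(
        branching=TaxonParams("branching", r=0.3, mu=(0.2, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)),
        massive=TaxonParams("massive", r=0.1, mu=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)),
        alpha=0.5,
        omega_ref=3.5,
        beta=0.2,
        t_opt=29.0,
    )


def test_step_stress_free_is_logistic_growth():
    params = toy_params()
    cp, cm = step_trajectory(
        np.array([15.0]), np.array([15.0]), np.zeros((1, 8)),
        np.array([29.0]), np.array([3.5]), params,
    )
    assert cp[0] == pytest.approx(15 + 0.3 * 15 * 0.7)
    assert cm[0] == pytest.approx(15 + 0.1 * 15 * 0.7)


def test_step_lethal_limit_collapses_cover():
    params = TrajectoryParams(
        branching=TaxonParams("branching", r=0.3, mu=(1.0,) * 8),
        massive=TaxonParams("massive", r=0.1, mu=(1.0,) * 8),
    )
    probs = np.zeros((1, 8))
    probs[0, :] = [1, 0, 0, 0, 0, 0, 0, 0]  # P(DHM>1)=1: every year bleaches
    m = expected_bleaching_mortality(probs, np.ones(8))
    assert m[0] == pytest.approx(1.0)
    cp, cm = np.array([15.0]), np.array([15.0])
    for _ in range(5):
        cp, cm = step_trajectory(
            cp, cm, probs, np.array([27.0]), np.array([3.8]), params
        )
    assert cp[0] + cm[0] < 10.0


def test_step_single_hand_computed_oracle():
    """Independent spreadsheet arithmetic for one step from 15/15 cover."""
    params = toy_params()
    probs = np.zeros((1, 8))
    probs[0, 0] = 0.5
    probs[0, 1] = 0.25
    # class probabilities: P(>1)-P(>2)=0.25 in class 1, P(>2)-P(>3)=0.25 in class 2
    m_p = 0.25 * 0.2 + 0.25 * 0.4
    m_m = 0.25 * 0.1 + 0.25 * 0.2
    expected_cp = 15 + 0.3 * 1.0 * 15 * (1 - 30 / 100) - m_p * 15
    expected_cm = 15 + 0.1 * 1.0 * 15 * (1 - 30 / 100) - m_m * 15
    cp, cm = step_trajectory(
        np.array([15.0]), np.array([15.0]), probs,
        np.array([29.0]), np.array([3.5]), params,
    )
    assert cp[0] == pytest.approx(expected_cp)
    assert cm[0] == pytest.approx(expected_cm)


def test_invalid_mortality_rejected():
    with pytest.raises(TrajectoryConfigError):
        TaxonParams("bad", r=0.3, mu=(0.5,) * 7 + (1.5,))


def test_trajectory_initialized_at_thirty_percent():
    traj = run_trajectory(constant_forcing())
    assert traj.years[0] == 1865
    assert traj.total[:, 0] == pytest.approx(30.0)


def test_trajectory_stress_free_non_decreasing():
    traj = run_trajectory(constant_forcing(omega=4.0))
    assert (np.diff(traj.total, axis=1) >= -1e-9).all()
    assert traj.at_year(2050)[0] >= traj.at_year(1865)[0]


def test_trajectory_identical_forcing_identical_output():
    traj = run_trajectory(constant_forcing(n_cells=2))
    assert np.allclose(traj.total[0], traj.total[1])


def test_trajectory_bounds_under_random_forcing():
    rng = np.random.default_rng(5)
    sst = 28.0 + rng.normal(0, 2.0, (2, 2, YEARS.size, 12))
    sst += np.linspace(0, 4, YEARS.size)[None, None, :, None]
    f = make_forcing(sst, YEARS)
    f.aragonite[:] = np.linspace(4.0, 2.5, YEARS.size)[None, :]
    traj = run_trajectory(f)
    assert traj.cover_branching.min() >= 0
    assert traj.cover_massive.min() >= 0
    assert traj.total.max() <= 100.0 + 1e-9


def test_degradation_monotone_in_thermal_stress():
    """Warmer late-century forcing never yields less 2010->2030 decline."""
    def decline(extra_warming):
        sst = np.full((1, 2, YEARS.size, 12), 27.5)
        ramp = np.clip((YEARS - 2000) / 30.0, 0, None) * extra_warming
        sst += ramp[None, None, :, None]
        f = make_forcing(sst, YEARS)
        f.aragonite[:] = 3.8
        return degradation_rate(run_trajectory(f))[0]

    rates = [decline(w) for w in (0.0, 1.5, 3.0)]
    assert rates[0] <= rates[1] <= rates[2]


# ------------------------------------------------------------ degradation


def make_traj(c2010, c2030):
    years = np.arange(2005, 2035)
    cov = np.zeros((1, years.size))
    cov[0, years == 2010] = c2010
    cov[0, years == 2030] = c2030
    return TrajectoryState(
        years=years, cover_branching=cov, cover_massive=np.zeros_like(cov)
    )


@pytest.mark.parametrize(
    "c2010, c2030, expected",
    [(40.0, 30.0, 0.25), (30.0, 40.0, 0.0), (25.0, 25.0, 0.0), (0.0, 0.0, 0.0)],
)
def test_degradation_rate_definition(c2010, c2030, expected):
    assert degradation_rate(make_traj(c2010, c2030))[0] == pytest.approx(expected)


# ----------------------------------------------------------- downscaling


def grid_xy(n=6, cell=10.0):
    xs = (np.arange(n) + 0.5) * cell
    gx, gy = np.meshgrid(xs, xs, indexing="xy")
    return np.column_stack([gx.ravel(), gy.ravel()])


def square_forcing(values, valid=None):
    """2x2 coarse grid with centres at (15,15),(45,15),(15,45),(45,45)."""
    centres = np.array([[15.0, 15.0], [45.0, 15.0], [15.0, 45.0], [45.0, 45.0]])
    sst = np.full((4, 1, 3, 12), 27.0)
    f = make_forcing(sst, np.arange(2000, 2003), centres=centres, valid=valid)
    return f


def test_interpolation_constant_field():
    f = square_forcing(None)
    fine = interpolate_to_grid(np.full(4, 3.3), f, grid_xy())
    assert np.allclose(fine, 3.3)


def test_interpolation_reproduces_linear_ramp():
    f = square_forcing(None)
    field = f.centres[:, 0] * 0.1  # linear in x
    fine = interpolate_to_grid(field, f, f.centres)
    assert np.allclose(fine, field)


def test_interpolation_coastal_nearest_fill():
    valid = np.array([True, False, False, False])
    f = square_forcing(None, valid=valid)
    fine = interpolate_to_grid(np.array([7.0, 99.0, 99.0, 99.0]), f, grid_xy())
    assert np.allclose(fine, 7.0)  # everything falls back to the only valid cell


def test_interpolation_requires_valid_cells():
    f = square_forcing(None, valid=np.zeros(4, dtype=bool))
    with pytest.raises(ForcingError):
        interpolate_to_grid(np.ones(4), f, grid_xy())


# -------------------------------------------------------- habitat decline


def test_degrade_habitat_arithmetic(small_scape):
    import pandas as pd

    amounts = small_scape.habitat_amounts
    d0 = pd.Series(0.0, index=amounts.index)
    assert degrade_habitat(amounts, d0).equals(amounts)
    d1 = pd.Series(1.0, index=amounts.index)
    assert (degrade_habitat(amounts, d1)["coral_reef"] == 0).all()
    toy = pd.DataFrame(
        {"coral_reef": [8.0], "mangrove": [2.0]}, index=pd.Index([1], name="pu_id")
    )
    out = degrade_habitat(toy, pd.Series([0.25], index=toy.index))
    assert out.loc[1, "coral_reef"] == pytest.approx(6.0)
    assert out.loc[1, "mangrove"] == pytest.approx(2.0)
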