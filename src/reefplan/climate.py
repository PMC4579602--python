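"""Thermal-stress projection and coral-cover trajectory modelling.

The climate stage turns monthly sea-surface temperature (SST) ensembles and
an aragonite saturation (Omega_ar) trend on a coarse grid into per-planning-
unit habitat degradation rates:

1. *Degree heating months* (DHM): the annual maximum 4-month accumulation of
   monthly SST in excess of the warmest month of the 1985–2000 monthly
   climatology, a standard coral bleaching stress metric.
2. *Exceedance probabilities* ``P(DHM > x)`` for x = 1..8 °C·month per year,
   estimated over a 10-year moving window pooling all model runs.
3. A two-taxon coral-cover *trajectory*: branching (fast-growing, bleaching-
   sensitive) and massive (slow, tolerant) taxa share a logistic substrate
   limit; growth is modulated by aragonite saturation and warm-season
   temperature, mortality is the expected bleaching loss over DHM stress
   classes.  Cover starts at 30% in 1865 and is stepped annually to 2050.
4. The *proportional degradation* of cover from 2010 to 2030 is interpolated
   bilinearly from coarse-cell centres to the planning grid, with nearest-
   neighbour fill for coastal cells outside the valid coarse hull, and used
   to shrink present coral-reef habitat amounts to their projected 2030
   values.

Local stressors (fishing, nutrients, cyclones) are deliberately excluded:
the trajectories isolate warming and acidification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError

DHM_WINDOW_MONTHS = 4
DHM_X_VALUES = np.arange(1, 9)


class ForcingError(ValueError):
    """Raised for incomplete or inconsistent climate forcing."""


class TrajectoryConfigError(ValueError):
    """Raised for trajectory parameter sets violating model bounds."""


@dataclass
class ClimateForcing:
    """Gridded climate forcing on a coarse grid overlaying the planning grid.

    Attributes
    ----------
    sst : (n_coarse, n_runs, n_years, 12) array
        Monthly SST per coarse cell per model run, °C.
    years : (n_years,) int array
        Calendar years covered by ``sst`` (contiguous).
    aragonite : (n_coarse, n_ar_years) array
        Annual aragonite saturation state per coarse cell.
    ar_years : (n_ar_years,) int array
    coarse_shape : (rows, cols)
    factor : int
        Planning cells per coarse cell along each axis.
    centres : (n_coarse, 2) array
        Coarse-cell centre coordinates (x_km, y_km).
    valid : (n_coarse,) bool array
        Coarse cells resolved by the forcing model; invalid (coastal) cells
        are filled by nearest-neighbour during downscaling.
    cell_to_coarse : (n_units,) int array
        Coarse-cell index for each planning unit (row-major order).
    """

    sst: np.ndarray
    years: np.ndarray
    aragonite: np.ndarray
    ar_years: np.ndarray
    coarse_shape: tuple[int, int]
    factor: int
    centres: np.ndarray
    valid: np.ndarray
    cell_to_coarse: np.ndarray

    def validate(self) -> None:
        if self.sst.ndim != 4 or self.sst.shape[3] != 12:
            raise ForcingError("sst must be (cells, runs, years, 12)")
        if self.sst.shape[2] != self.years.size:
            raise ForcingError("sst year axis does not match years")
        if np.any(np.diff(self.years) != 1):
            raise ForcingError("years must be contiguous")
        if np.any(self.aragonite <= 0):
            raise ForcingError("aragonite saturation must be positive")
        if not np.isfinite(self.sst).all():
            raise ForcingError("sst contains non-finite values")

    @property
    def n_coarse(self) -> int:
        return self.sst.shape[0]

    @property
    def n_runs(self) -> int:
        return self.sst.shape[1]

    def year_index(self, year: int) -> int:
        idx = int(year - self.years[0])
        if not 0 <= idx < self.years.size:
            raise ForcingError(f"year {year} outside forcing span")
        return idx

    def aragonite_at(self, year: int) -> np.ndarray:
        idx = int(year - self.ar_years[0])
        if not 0 <= idx < self.ar_years.size:
            raise ForcingError(f"year {year} outside aragonite span")
        return self.aragonite[:, idx]


@dataclass(frozen=True)
class TaxonParams:
    """Growth and bleaching-mortality parameters for one coral growth form.

    ``mu`` gives the expected mortality fraction in each DHM stress class
    1..8 °C·month; entries must lie in [0, 1] so the expected annual
    bleaching mortality is a proper fraction.
    """

    name: str
    r: float  # intrinsic annual growth rate
    mu: tuple[float, ...]  # mortality per DHM class, len 8

    def __post_init__(self) -> None:
        if self.r < 0:
            raise TrajectoryConfigError(f"{self.name}: growth rate must be >= 0")
        if len(self.mu) != DHM_X_VALUES.size:
            raise TrajectoryConfigError(
                f"{self.name}: mu must have {DHM_X_VALUES.size} stress classes"
            )
        if any(not 0.0 <= m <= 1.0 for m in self.mu):
            raise TrajectoryConfigError(
                f"{self.name}: mortalities must lie in [0, 1]"
            )


@dataclass(frozen=True)
class TrajectoryParams:
    """Shared trajectory-model parameters plus the two taxa.

    Defaults give the branching taxon faster growth and higher bleaching
    mortality than the massive taxon; growth declines as aragonite
    saturation falls below ``omega_ref`` and as annual-mean SST exceeds
    ``t_opt``.
    """

    branching: TaxonParams = field(
        default_factory=lambda: TaxonParams(
            "branching",
            r=0.30,
            mu=(0.05, 0.10, 0.20, 0.32, 0.46, 0.62, 0.78, 0.92),
        )
    )
    massive: TaxonParams = field(
        default_factory=lambda: TaxonParams(
            "massive",
            r=0.12,
            mu=(0.02, 0.05, 0.10, 0.16, 0.24, 0.34, 0.46, 0.60),
        )
    )
    alpha: float = 0.30  # aragonite sensitivity of calcification
    omega_ref: float = 3.8  # saturation state with neutral growth effect
    beta: float = 0.15  # growth decline per °C above t_opt
    t_opt: float = 29.5  # annual-mean SST above which growth slows, °C
    g_max: float = 1.5  # cap on the aragonite growth multiplier
    initial_cover: float = 30.0  # total % cover at the start year
    carrying_capacity: float = 100.0

    @property
    def taxa(self) -> tuple[TaxonParams, TaxonParams]:
        return (self.branching, self.massive)


@dataclass
class TrajectoryState:
    """Per-cell annual cover of the branching and massive taxa (% substrate)."""

    years: np.ndarray
    cover_branching: np.ndarray  # (n_cells, n_years)
    cover_massive: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.cover_branching + self.cover_massive

    def at_year(self, year: int) -> np.ndarray:
        idx = int(year - self.years[0])
        if not 0 <= idx < self.years.size:
            raise ForcingError(f"year {year} outside trajectory span")
        return self.total[:, idx]


def monthly_climatology_max(
    forcing: ClimateForcing, ref_years: tuple[int, int] = (1985, 2000)
) -> np.ndarray:
    """Maximum of the 12 monthly climatological means per coarse cell.

    The climatology averages each calendar month over the reference years
    (inclusive) and over all model runs; the bleaching threshold is the
    warmest of those 12 means.
    """
    lo, hi = ref_years
    mask = (forcing.years >= lo) & (forcing.years <= hi)
    missing = set(range(lo, hi + 1)) - set(int(y) for y in forcing.years[mask])
    if missing:
        raise ForcingError(f"reference years missing from forcing: {sorted(missing)}")
    clim = forcing.sst[:, :, mask, :].mean(axis=(1, 2))  # (cells, 12)
    return clim.max(axis=1)


def compute_dhm(sst_year: np.ndarray, climatology_max: float) -> float:
    """Annual maximum degree-heating-month value for one cell-year.

    Over the nine 4-month windows within the calendar year, DHM is the
    largest accumulated positive SST excess over the climatology maximum
    (°C·month); never negative.
    """
    sst_year = np.asarray(sst_year, dtype=float)
    if sst_year.shape != (12,):
        raise ForcingError("a year of SST must have exactly 12 monthly values")
    excess = np.clip(sst_year - climatology_max, 0.0, None)
    window_sums = np.convolve(excess, np.ones(DHM_WINDOW_MONTHS), mode="valid")
    return float(window_sums.max())


def annual_max_dhm(
    forcing: ClimateForcing, climatology_max: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`compute_dhm` -> (n_coarse, n_runs, n_years)."""
    excess = np.clip(
        forcing.sst - climatology_max[:, None, None, None], 0.0, None
    )
    cum = np.concatenate(
        [np.zeros(excess.shape[:-1] + (1,)), np.cumsum(excess, axis=-1)], axis=-1
    )
    windows = cum[..., DHM_WINDOW_MONTHS:] - cum[..., :-DHM_WINDOW_MONTHS]
    return windows.max(axis=-1)


@dataclass
class ExceedanceResult:
    """P(DHM > x) per cell and year, pooled over runs in a moving window."""

    prob: np.ndarray  # (n_cells, n_years, n_x)
    x_values: np.ndarray
    n_samples: np.ndarray  # (n_years,) runs x window-years per estimate
    truncated: np.ndarray  # (n_years,) bool, True where the window is short


def dhm_exceedance(
    dhm: np.ndarray,
    x_values: np.ndarray = DHM_X_VALUES,
    window: int = 10,
) -> ExceedanceResult:
    """Empirical exceedance probabilities from a trailing moving window.

    For year ``t`` the window covers years ``t - window + 1 .. t`` over all
    runs, so with 8 runs each estimate pools n = 80 samples and with 2 runs
    n = 20.  Years too early for a full window use the available truncated
    window and are flagged.
    """
    dhm = np.asarray(dhm, dtype=float)
    if dhm.ndim != 3:
        raise ForcingError("dhm must be (cells, runs, years)")
    n_cells, n_runs, n_years = dhm.shape
    if n_years == 0:
        raise ForcingError("empty DHM series")
    x_values = np.asarray(x_values, dtype=float)
    prob = np.empty((n_cells, n_years, x_values.size))
    n_samples = np.empty(n_years, dtype=int)
    truncated = np.zeros(n_years, dtype=bool)
    for t in range(n_years):
        lo = max(0, t - window + 1)
        sample = dhm[:, :, lo : t + 1].reshape(n_cells, -1)
        n = sample.shape[1]
        n_samples[t] = n
        truncated[t] = (t - lo + 1) < window
        prob[:, t, :] = (sample[:, :, None] > x_values[None, None, :]).mean(axis=1)
    return ExceedanceResult(prob, x_values, n_samples, truncated)


def expected_bleaching_mortality(
    exceed_probs: np.ndarray, mu: np.ndarray
) -> np.ndarray:
    """Expected mortality over DHM stress classes.

    ``m = sum_x mu(x) * [P(DHM > x) - P(DHM > x + 1)]`` with
    ``P(DHM > x_max + 1) = 0``; class probabilities sum to ``P(DHM > 1)``
    <= 1, so ``m`` is a proper fraction whenever ``mu`` is.
    """
    probs = np.asarray(exceed_probs, dtype=float)
    upper = np.concatenate(
        [probs[..., 1:], np.zeros(probs.shape[:-1] + (1,))], axis=-1
    )
    class_prob = probs - upper
    return np.einsum("...x,x->...", class_prob, np.asarray(mu, dtype=float))


def step_trajectory(
    cover_branching: np.ndarray,
    cover_massive: np.ndarray,
    exceed_probs: np.ndarray,
    sst_annual: np.ndarray,
    aragonite: np.ndarray,
    params: TrajectoryParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance coral cover by one year.

    Per taxon k: ``C_k' = C_k + r_k * g * C_k * (1 - C/K) - m_k * C_k`` where
    the shared growth modifier is

    ``g = clamp(1 + alpha * (Omega - omega_ref), 0, g_max)
        * clamp(1 - beta * max(0, SST_annual - t_opt), 0, 1)``

    and ``m_k`` is the expected bleaching mortality over DHM stress classes.
    The result is clamped to non-negative cover with total <= the carrying
    capacity.
    """
    cp = np.asarray(cover_branching, dtype=float)
    cm = np.asarray(cover_massive, dtype=float)
    k_cap = params.carrying_capacity
    g = np.clip(
        1.0 + params.alpha * (np.asarray(aragonite) - params.omega_ref),
        0.0,
        params.g_max,
    ) * np.clip(
        1.0 - params.beta * np.clip(np.asarray(sst_annual) - params.t_opt, 0.0, None),
        0.0,
        1.0,
    )
    free = 1.0 - (cp + cm) / k_cap
    new = []
    for cov, taxon in ((cp, params.branching), (cm, params.massive)):
        m = expected_bleaching_mortality(exceed_probs, np.asarray(taxon.mu))
        nxt = cov + taxon.r * g * cov * free - m * cov
        new.append(np.clip(nxt, 0.0, k_cap))
    cp2, cm2 = new
    total = cp2 + cm2
    over = total > k_cap
    if np.any(over):
        scale = np.where(over, k_cap / np.where(total > 0, total, 1.0), 1.0)
        cp2 = cp2 * scale
        cm2 = cm2 * scale
    return cp2, cm2


def run_trajectory(
    forcing: ClimateForcing,
    params: TrajectoryParams | None = None,
    start_year: int = 1865,
    end_year: int = 2050,
    ref_years: tuple[int, int] = (1985, 2000),
) -> TrajectoryState:
    """Annual coral-cover trajectories for every coarse cell.

    Total cover starts at ``params.initial_cover`` (30% by default, split
    equally between the taxa) in ``start_year`` and is stepped annually to
    ``end_year`` using run-pooled DHM exceedance, run-mean annual SST, and
    the aragonite series.
    """
    params = params or TrajectoryParams()
    forcing.validate()
    if start_year < forcing.years[0] or end_year > forcing.years[-1]:
        raise ForcingError(
            f"forcing years {forcing.years[0]}–{forcing.years[-1]} do not cover "
            f"{start_year}–{end_year}"
        )
    clim_max = monthly_climatology_max(forcing, ref_years)
    dhm = annual_max_dhm(forcing, clim_max)
    exceed = dhm_exceedance(dhm)
    sst_annual = forcing.sst.mean(axis=(1, 3))  # (cells, years)

    years = np.arange(start_year, end_year + 1)
    n_cells = forcing.n_coarse
    cp = np.empty((n_cells, years.size))
    cm = np.empty((n_cells, years.size))
    cp[:, 0] = params.initial_cover / 2.0
    cm[:, 0] = params.initial_cover / 2.0
    for t, year in enumerate(years[:-1]):
        yi = forcing.year_index(int(year))
        cp[:, t + 1], cm[:, t + 1] = step_trajectory(
            cp[:, t],
            cm[:, t],
            exceed.prob[:, yi, :],
            sst_annual[:, yi],
            forcing.aragonite_at(int(year)),
            params,
        )
    return TrajectoryState(years=years, cover_branching=cp, cover_massive=cm)


def degradation_rate(
    trajectory: TrajectoryState, present_year: int = 2010, future_year: int = 2030
) -> np.ndarray:
    """Proportional decline of total cover from present to future, in [0, 1].

    ``d = clamp((C_present - C_future) / C_present, 0, 1)``; cells with zero
    present cover report 0 (nothing left to degrade).
    """
    c_now = trajectory.at_year(present_year)
    c_then = trajectory.at_year(future_year)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(c_now > 0, (c_now - c_then) / np.where(c_now > 0, c_now, 1.0), 0.0)
    return np.clip(d, 0.0, 1.0)


def interpolate_to_grid(
    coarse_field: np.ndarray,
    forcing: ClimateForcing,
    pu_xy: np.ndarray,
) -> np.ndarray:
    """Downscale a per-coarse-cell field to planning-unit centroids.

    Bilinear (piecewise-linear) interpolation from the centres of valid
    coarse cells; planning cells outside the convex hull of valid centres —
    the coastal fringe the coarse model does not resolve — take the value of
    the nearest valid coarse cell.
    """
    coarse_field = np.asarray(coarse_field, dtype=float)
    valid = np.asarray(forcing.valid, dtype=bool)
    if not valid.any():
        raise ForcingError("no valid coarse cells to interpolate from")
    pts = forcing.centres[valid]
    vals = coarse_field[valid]
    pu_xy = np.asarray(pu_xy, dtype=float)
    nearest = NearestNDInterpolator(pts, vals)
    if pts.shape[0] >= 3:
        try:
            linear = LinearNDInterpolator(pts, vals)
            fine = linear(pu_xy)
        except QhullError:  # collinear centres: fall back to nearest
            fine = np.full(pu_xy.shape[0], np.nan)
    else:
        fine = np.full(pu_xy.shape[0], np.nan)
    missing = ~np.isfinite(fine)
    if missing.any():
        fine[missing] = nearest(pu_xy[missing])
    return fine


def degrade_habitat(
    habitat_amounts: pd.DataFrame,
    rates: pd.Series,
    reef_column: str = "coral_reef",
) -> pd.DataFrame:
    """Projected habitat amounts after climate-driven reef decline.

    The coral-reef column is multiplied by ``1 - d`` per planning unit; all
    other habitats are left unchanged.
    """
    if reef_column not in habitat_amounts.columns:
        raise KeyError(f"no {reef_column!r} column in habitat table")
    d = rates.reindex(habitat_amounts.index)
    if d.isna().any():
        missing = habitat_amounts.index[d.isna()].tolist()
        raise ForcingError(f"degradation rates missing for planning units {missing[:5]}")
    out = habitat_amounts.copy()
    out[reef_column] = out[reef_column] * (1.0 - d.clip(0.0, 1.0))
    return out
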