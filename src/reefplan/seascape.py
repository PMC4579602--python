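"""Synthetic seascape generation.

Builds a fully self-consistent study region with the statistical structure
the downstream analysis assumes: a rectangular planning-unit grid carved
into contiguous provinces nested in countries; spatially autocorrelated
habitat amount fields (coral reef, mangrove, seagrass plus generic benthic
classes) and bioregions; small sub-cell and large multi-cell protected
areas; point fish-spawning-aggregation sites on reef; correlated-random-walk
turtle tracks from nesting to foraging grounds; reef cells clustered into
reef complexes with asymmetric, distance-decaying, current-biased larval
dispersal matrices for a long-dispersing and a short-dispersing species; and
monthly SST ensembles plus an aragonite saturation trend on a coarse grid
(one coarse cell per 5x5 planning cells, emulating the half-degree vs 10-km
scale gap).

Identical config + seed reproduces byte-identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.ndimage import gaussian_filter

from .climate import ClimateForcing
from .connectivity import TurtleTrack
from .lockin import MPARecord

REEF = "coral_reef"
MANGROVE = "mangrove"
SEAGRASS = "seagrass"
TURTLE_SPECIES = ("green", "hawksbill", "leatherback", "olive_ridley")
LARVAL_SPECIES = ("trout", "cucumber")


class SizingError(ValueError):
    """Config demands more MPAs/sites/complexes than eligible cells exist."""


def habitat_names(n_habitats: int) -> list[str]:
    base = [REEF, MANGROVE, SEAGRASS]
    if n_habitats <= len(base):
        return base[:n_habitats]
    return base + [f"benthic_{k}" for k in range(n_habitats - len(base))]


@dataclass(frozen=True)
class SeascapeConfig:
    """Sizes, rates and the seed controlling one synthetic seascape.

    Defaults are a scaled-down analogue of a large tropical planning region
    (20x20 grid of 10x10 km planning units, 6 provinces in 3 countries, 11
    habitat classes, 7 bioregions) chosen so a full six-objective analysis
    completes in minutes; full-scale counts remain reachable through the
    config.
    """

    grid_width: int = 20
    grid_height: int = 20
    cell_size_km: float = 10.0
    n_provinces: int = 6
    n_countries: int = 3
    n_habitats: int = 11
    n_bioregions: int = 7
    n_small_mpas: int = 8
    n_large_mpas: int = 3
    n_fsa_sites: int = 10
    n_turtle_tracks: int = 12
    n_reef_complexes: int = 8
    n_sst_runs: int = 2
    coarse_factor: int = 5  # planning cells per coarse forcing cell
    current_direction_deg: float = 15.0  # prevailing current bearing
    current_strength: float = 0.5  # directional bias of dispersal
    settlement_fraction: float = 0.8  # row sum of dispersal matrices
    trout_decay_km: float = 120.0  # long-dispersing species
    cucumber_decay_km: float = 30.0  # short-dispersing species
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "grid_width": self.grid_width,
            "grid_height": self.grid_height,
            "n_provinces": self.n_provinces,
            "n_countries": self.n_countries,
            "n_habitats": self.n_habitats,
            "n_bioregions": self.n_bioregions,
            "coarse_factor": self.coarse_factor,
        }
        for name, value in counts.items():
            if value < 1:
                raise SizingError(f"{name} must be strictly positive, got {value}")
        for name in (
            "n_small_mpas",
            "n_large_mpas",
            "n_fsa_sites",
            "n_turtle_tracks",
            "n_reef_complexes",
            "n_sst_runs",
        ):
            if getattr(self, name) < 0:
                raise SizingError(f"{name} must be non-negative")
        if self.n_provinces < self.n_countries:
            raise SizingError("need at least one province per country")
        if self.n_provinces > self.grid_height:
            raise SizingError("more provinces than grid rows; provinces are row bands")
        if self.cell_size_km <= 0:
            raise SizingError("cell_size_km must be positive")
        if self.trout_decay_km < 3.0 * self.cucumber_decay_km:
            raise SizingError(
                "species dispersal scales must contrast by at least a factor 3"
            )

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.grid_height, self.grid_width)

    @property
    def n_units(self) -> int:
        return self.grid_height * self.grid_width

    @property
    def cell_area(self) -> float:
        return self.cell_size_km**2


@dataclass
class Seascape:
    """One generated study region; container for every downstream input."""

    config: SeascapeConfig
    planning_units: pd.DataFrame
    habitat_amounts: pd.DataFrame
    mpas: list[MPARecord]
    fsa_sites: pd.DataFrame
    turtle_tracks: list[TurtleTrack]
    dispersal: dict[str, np.ndarray]
    forcing: ClimateForcing

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.config.grid_shape

    @property
    def n_units(self) -> int:
        return self.config.n_units

    def validate(self) -> None:
        pu = self.planning_units
        amounts = self.habitat_amounts
        if (amounts.to_numpy() < 0).any():
            raise ValueError("negative habitat amount")
        if (amounts.sum(axis=1) > self.config.cell_area + 1e-9).any():
            raise ValueError("per-cell habitat amount exceeds cell area")
        by_province = pu.groupby("province")["country"].nunique()
        if (by_province != 1).any():
            raise ValueError("a province maps to more than one country")
        reef = amounts[REEF] if REEF in amounts else amounts.iloc[:, 0]
        for _, site in self.fsa_sites.iterrows():
            if reef.loc[site["pu_id"]] <= 0:
                raise ValueError(f"FSA site {site['site_id']} is off-reef")
        nesting = set(pu.index[pu["nesting_zone"]])
        foraging = set(pu.index[pu["foraging_zone"]])
        ncols = self.config.grid_width
        for track in self.turtle_tracks:
            first = track.path[0][0] * ncols + track.path[0][1] + 1
            last = track.path[-1][0] * ncols + track.path[-1][1] + 1
            if first not in nesting:
                raise ValueError(f"track {track.individual_id} does not start on nesting")
            if last not in foraging:
                raise ValueError(f"track {track.individual_id} does not end on foraging")
        for species, mat in self.dispersal.items():
            if (mat < 0).any() or (mat > 1).any():
                raise ValueError(f"{species} dispersal entries outside [0, 1]")
            if (mat.sum(axis=1) > 1 + 1e-9).any():
                raise ValueError(f"{species} dispersal row sums exceed 1")
        self.forcing.validate()

    def checksum(self) -> str:
        """Deterministic digest of every generated table and array."""
        h = hashlib.md5()
        h.update(repr(sorted(asdict(self.config).items())).encode())
        for frame in (self.planning_units, self.habitat_amounts, self.fsa_sites):
            h.update(frame.round(9).to_csv().encode())
        for mpa in self.mpas:
            cover = sorted((int(k), round(v, 9)) for k, v in (mpa.cover or {}).items())
            h.update(repr((mpa.mpa_id, mpa.size_class, cover, mpa.members)).encode())
        for track in self.turtle_tracks:
            h.update(repr((track.individual_id, track.species, track.path)).encode())
        for species in sorted(self.dispersal):
            h.update(np.round(self.dispersal[species], 9).tobytes())
        h.update(np.round(self.forcing.sst, 6).tobytes())
        h.update(np.round(self.forcing.aragonite, 6).tobytes())
        return h.hexdigest()


def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], sigma: float
) -> np.ndarray:
    return gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")


def _pu_frame(config: SeascapeConfig) -> pd.DataFrame:
    h, w = config.grid_shape
    rows, cols = np.divmod(np.arange(config.n_units), w)
    province = (rows * config.n_provinces) // h
    country = (province * config.n_countries) // config.n_provinces
    coastal = (rows == 0) | (cols == 0) | (rows == h - 1) | (cols == w - 1)
    return pd.DataFrame(
        {
            "pu_id": np.arange(1, config.n_units + 1),
            "row": rows,
            "col": cols,
            "x_km": (cols + 0.5) * config.cell_size_km,
            "y_km": (rows + 0.5) * config.cell_size_km,
            "province": province,
            "country": country,
            "coastal": coastal,
        }
    ).set_index("pu_id")


def _habitats(
    config: SeascapeConfig, pu: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    shape = config.grid_shape
    sigma = max(1.2, min(shape) / 10.0)
    coastal = pu["coastal"].to_numpy().reshape(shape)
    names = habitat_names(config.n_habitats)
    amounts = {}
    for name in names:
        field = _smooth_field(rng, shape, sigma)
        thr = np.quantile(field, 0.65)
        amt = np.clip(field - thr, 0.0, None)
        if name == MANGROVE:
            amt = amt * coastal
        if amt.max() > 0:
            amt *= (0.35 * config.cell_area) / amt.max()
        amounts[name] = amt.ravel()
    frame = pd.DataFrame(amounts, index=pu.index)
    totals = frame.sum(axis=1)
    scale = max(1.0, float(totals.max()) / (0.9 * config.cell_area))
    return frame / scale


def _bioregions(
    config: SeascapeConfig, rng: np.random.Generator
) -> np.ndarray:
    field = _smooth_field(rng, config.grid_shape, max(1.5, min(config.grid_shape) / 8))
    return pd.qcut(field.ravel(), config.n_bioregions, labels=False).astype(int)


def _cost_surfaces(
    config: SeascapeConfig, pu: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    shape = config.grid_shape
    profit = np.exp(0.8 * _smooth_field(rng, shape, 2.0)).ravel()
    rows = pu["row"].to_numpy()
    cols = pu["col"].to_numpy()
    h, w = shape
    edge_dist = np.minimum.reduce([rows, cols, h - 1 - rows, w - 1 - cols])
    proximity = 1.0 / (1.0 + edge_dist)
    density = np.exp(0.8 * _smooth_field(rng, shape, 2.0)).ravel() * proximity
    return profit, density


def _small_mpas(
    config: SeascapeConfig, habitat_amounts: pd.DataFrame, rng: np.random.Generator
) -> list[MPARecord]:
    eligible = habitat_amounts.index[habitat_amounts.sum(axis=1) > 0].to_numpy()
    if config.n_small_mpas > 0 and eligible.size == 0:
        raise SizingError("no habitat-bearing cells to host small MPAs")
    records = []
    for k in range(config.n_small_mpas):
        pu_id = int(rng.choice(eligible))  # with replacement: coverage may stack
        frac = float(rng.uniform(0.15, 0.65))
        records.append(
            MPARecord(mpa_id=f"smpa_{k:03d}", size_class="small", cover={pu_id: frac})
        )
    return records


def _large_mpas(
    config: SeascapeConfig, pu: pd.DataFrame, rng: np.random.Generator
) -> list[MPARecord]:
    h, w = config.grid_shape
    if config.n_large_mpas > 0 and config.n_units < 2:
        raise SizingError("grid too small for large MPAs")
    records = []
    for k in range(config.n_large_mpas):
        size = int(rng.integers(5, 13))
        start = int(rng.integers(config.n_units))
        members = {start}
        frontier = [start]
        while len(members) < size and frontier:
            cell = frontier[int(rng.integers(len(frontier)))]
            r, c = divmod(cell, w)
            neighbours = [
                rr * w + cc
                for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                if 0 <= rr < h and 0 <= cc < w
            ]
            fresh = [n for n in neighbours if n not in members]
            if not fresh:
                frontier.remove(cell)
                continue
            nxt = fresh[int(rng.integers(len(fresh)))]
            members.add(nxt)
            frontier.append(nxt)
        records.append(
            MPARecord(
                mpa_id=f"lmpa_{k:03d}",
                size_class="large",
                members=tuple(sorted(m + 1 for m in members)),
            )
        )
    return records


def _fsa_sites(
    config: SeascapeConfig, habitat_amounts: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    reef_cells = habitat_amounts.index[habitat_amounts[REEF] > 0].to_numpy()
    if config.n_fsa_sites > reef_cells.size:
        raise SizingError(
            f"{config.n_fsa_sites} FSA sites requested but only "
            f"{reef_cells.size} reef cells exist"
        )
    chosen = np.sort(rng.choice(reef_cells, size=config.n_fsa_sites, replace=False))
    w = config.grid_width
    rows, cols = np.divmod(chosen - 1, w)
    return pd.DataFrame(
        {
            "site_id": [f"fsa_{k:03d}" for k in range(config.n_fsa_sites)],
            "pu_id": chosen.astype(int),
            "row": rows,
            "col": cols,
        }
    )


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.hypot(v[0], v[1])
    return v / norm if norm > 0 else v


def generate_tracks(
    planning_units: pd.DataFrame,
    grid_shape: tuple[int, int],
    n_tracks: int,
    seed: int,
    max_steps: int | None = None,
    max_retries: int = 8,
) -> list[TurtleTrack]:
    """Correlated random walks from a nesting cell to a foraging cell.

    Headings blend persistence, attraction toward a randomly chosen foraging
    target and noise; a walk succeeds when it enters the foraging zone.
    Walks that exhaust ``max_steps`` are resampled, with a hard error after
    ``max_retries`` failures.
    """
    if n_tracks == 0:
        return []
    h, w = grid_shape
    nesting = planning_units.index[planning_units["nesting_zone"]].to_numpy()
    foraging = planning_units.index[planning_units["foraging_zone"]].to_numpy()
    if nesting.size == 0 or foraging.size == 0:
        raise SizingError("turtle tracks need non-empty nesting and foraging zones")
    foraging_cells = {((p - 1) // w, (p - 1) % w) for p in foraging}
    rng = np.random.default_rng(seed)
    max_steps = max_steps or 6 * (h + w)
    tracks: list[TurtleTrack] = []
    for t in range(n_tracks):
        path = None
        for _ in range(max_retries):
            start_id = int(rng.choice(nesting))
            target_id = int(rng.choice(foraging))
            pos = np.array(divmod(start_id - 1, w), dtype=float)
            target = np.array(divmod(target_id - 1, w), dtype=float)
            heading = _unit(target - pos)
            walk = [(int(pos[0]), int(pos[1]))]
            for _step in range(max_steps):
                desired = _unit(
                    0.55 * heading + 0.45 * _unit(target - pos) + rng.normal(0, 0.4, 2)
                )
                best, best_dot = None, -np.inf
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == 0 and dc == 0:
                            continue
                        rr, cc = int(pos[0]) + dr, int(pos[1]) + dc
                        if not (0 <= rr < h and 0 <= cc < w):
                            continue
                        step = _unit(np.array([dr, dc], dtype=float))
                        d = float(step @ desired)
                        if d > best_dot:
                            best, best_dot = (rr, cc), d
                if best is None:
                    break
                pos = np.array(best, dtype=float)
                heading = _unit(0.6 * heading + 0.4 * _unit(pos - np.array(walk[-1])))
                walk.append(best)
                if best in foraging_cells:
                    path = walk
                    break
            if path is not None:
                break
        if path is None:
            raise RuntimeError(
                f"track {t}: no foraging cell reached within {max_steps} steps "
                f"after {max_retries} attempts"
            )
        species = TURTLE_SPECIES[int(rng.integers(len(TURTLE_SPECIES)))]
        tracks.append(TurtleTrack(individual_id=t, species=species, path=tuple(path)))
    return tracks


def _reef_complexes(
    config: SeascapeConfig,
    pu: pd.DataFrame,
    habitat_amounts: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    membership = np.full(config.n_units, -1, dtype=int)
    if config.n_reef_complexes == 0:
        return membership
    reef_idx = np.flatnonzero(habitat_amounts[REEF].to_numpy() > 0)
    if reef_idx.size < config.n_reef_complexes:
        raise SizingError(
            f"{config.n_reef_complexes} reef complexes requested but only "
            f"{reef_idx.size} reef cells exist"
        )
    xy = pu.iloc[reef_idx][["x_km", "y_km"]].to_numpy()
    k = config.n_reef_complexes
    try:
        _, labels = kmeans2(xy, k, minit="++", seed=int(rng.integers(2**31)), iter=25)
        if np.unique(labels).size < k:
            raise ValueError("empty cluster")
    except Exception:
        order = np.lexsort((xy[:, 1], xy[:, 0]))  # contiguous x-then-y strips
        labels = np.empty(reef_idx.size, dtype=int)
        labels[order] = (np.arange(reef_idx.size) * k) // reef_idx.size
    membership[reef_idx] = labels
    return membership


def _dispersal(
    config: SeascapeConfig,
    pu: pd.DataFrame,
    habitat_amounts: pd.DataFrame,
    membership: np.ndarray,
) -> dict[str, np.ndarray]:
    k = config.n_reef_complexes
    if k == 0:
        return {s: np.zeros((0, 0)) for s in LARVAL_SPECIES}
    reef = habitat_amounts[REEF].to_numpy()
    xy = pu[["x_km", "y_km"]].to_numpy()
    centres = np.zeros((k, 2))
    for c in range(k):
        idx = np.flatnonzero(membership == c)
        wts = reef[idx]
        centres[c] = (xy[idx] * wts[:, None]).sum(axis=0) / wts.sum()
    disp = centres[None, :, :] - centres[:, None, :]  # source -> target
    dist = np.hypot(disp[..., 0], disp[..., 1])
    theta = np.deg2rad(config.current_direction_deg)
    current = np.array([np.cos(theta), np.sin(theta)])
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(
            dist > 0, (disp @ current) / np.where(dist > 0, dist, 1.0), 0.0
        )
    out = {}
    for species, scale in (
        ("trout", config.trout_decay_km),
        ("cucumber", config.cucumber_decay_km),
    ):
        raw = np.exp(-dist / scale) * np.clip(
            1.0 + config.current_strength * cosang, 0.0, None
        )
        row_sums = raw.sum(axis=1, keepdims=True)
        out[species] = raw / row_sums * config.settlement_fraction
    return out


def _forcing(
    config: SeascapeConfig, pu: pd.DataFrame, rng: np.random.Generator
) -> ClimateForcing:
    h, w = config.grid_shape
    f = config.coarse_factor
    crows, ccols = -(-h // f), -(-w // f)
    n_coarse = crows * ccols
    rows = pu["row"].to_numpy()
    cols = pu["col"].to_numpy()
    cell_to_coarse = (rows // f) * ccols + cols // f
    centres = np.zeros((n_coarse, 2))
    valid = np.zeros(n_coarse, dtype=bool)
    coastal = pu["coastal"].to_numpy()
    xy = pu[["x_km", "y_km"]].to_numpy()
    for c in range(n_coarse):
        idx = np.flatnonzero(cell_to_coarse == c)
        centres[c] = xy[idx].mean(axis=0)
        valid[c] = not coastal[idx].any()  # coarse land mask analogue
    if not valid.any():
        valid[:] = True  # tiny grids: everything counts as open ocean

    years = np.arange(1865, 2051)
    n_years = years.size
    lat_norm = centres[:, 1] / (h * config.cell_size_km)
    base = 27.0 + 1.2 * (0.5 - lat_norm)
    months = np.arange(12)
    seasonal = 1.6 * np.cos(2 * np.pi * (months - 4) / 12.0)
    warming = 2.4 * ((years - years[0]) / (years[-1] - years[0])) ** 2
    sst = np.empty((n_coarse, config.n_sst_runs, n_years, 12))
    for run in range(config.n_sst_runs):
        anomaly = np.empty(n_years)
        a = 0.0
        for t in range(n_years):  # AR(1) regional interannual anomaly
            a = 0.6 * a + rng.normal(0.0, 0.35)
            anomaly[t] = a
        noise = rng.normal(0.0, 0.25, size=(n_coarse, n_years, 12))
        sst[:, run] = (
            base[:, None, None]
            + seasonal[None, None, :]
            + warming[None, :, None]
            + anomaly[None, :, None]
            + noise
        )

    ar_years = np.arange(1860, 2051)
    spatial = _smooth_field(rng, (crows, ccols), 1.0).ravel()
    spatial = 0.3 * (spatial - spatial.mean())
    decline = 1.2 * (ar_years - ar_years[0]) / (ar_years[-1] - ar_years[0])
    aragonite = 4.0 + spatial[:, None] - decline[None, :]

    return ClimateForcing(
        sst=sst,
        years=years,
        aragonite=aragonite,
        ar_years=ar_years,
        coarse_shape=(crows, ccols),
        factor=f,
        centres=centres,
        valid=valid,
        cell_to_coarse=cell_to_coarse,
    )


def generate_seascape(config: SeascapeConfig) -> Seascape:
    """Generate the complete synthetic study region for one config + seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (s_hab, s_bio, s_cost, s_smpa, s_lmpa, s_fsa, s_track, s_cplx, s_forc) = [
        np.random.default_rng(child) for child in ss.spawn(9)
    ]

    pu = _pu_frame(config)
    amounts = _habitats(config, pu, s_hab)
    pu["bioregion"] = _bioregions(config, s_bio)
    profit, density = _cost_surfaces(config, pu, s_cost)
    pu["fishing_profit"] = profit
    pu["population_density"] = density

    reef_present = amounts[REEF].to_numpy() > 0
    cols = pu["col"].to_numpy()
    w = config.grid_width
    pu["nesting_zone"] = reef_present & (cols < w / 3)
    pu["foraging_zone"] = reef_present & (cols >= 2 * w / 3)

    mpas = _small_mpas(config, amounts, s_smpa) + _large_mpas(config, pu, s_lmpa)
    fsa = _fsa_sites(config, amounts, s_fsa)
    tracks = generate_tracks(
        pu, config.grid_shape, config.n_turtle_tracks, int(s_track.integers(2**31))
    )
    membership = _reef_complexes(config, pu, amounts, s_cplx)
    pu["reef_complex"] = membership
    dispersal = _dispersal(config, pu, amounts, membership)
    forcing = _forcing(config, pu, s_forc)

    scape = Seascape(
        config=config,
        planning_units=pu,
        habitat_amounts=amounts,
        mpas=mpas,
        fsa_sites=fsa,
        turtle_tracks=tracks,
        dispersal=dispersal,
        forcing=forcing,
    )
    scape.validate()
    return scape
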