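"""Readers and writers for the Marxan-dialect tables and companion CSVs.

The reserve-selection problem round-trips through the community-standard
file triple plus one:

* ``pu.dat`` — ``id,cost,status`` (status 2 marks locked-in units, 0
  available);
* ``spec.dat`` — ``id,target,spf,name`` with absolute target amounts;
* ``puvspr.dat`` — ``species,pu,amount`` sorted by pu then species;
* ``bound.dat`` — ``id1,id2,boundary`` reused to carry the connectivity
  strengths CV_ij (directed matrices list both orientations).

All files are delimited text with a header row; the delimiter (comma by
default) is an argument everywhere.  Readers enforce referential integrity
and raise named validation errors for dangling ids, duplicates and negative
amounts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import ClimateForcing
from .connectivity import ConnMatrix, TurtleTrack
from .lockin import MPARecord
from .seascape import Seascape, SeascapeConfig

STATUS_AVAILABLE = 0
STATUS_LOCKED_IN = 2


class MarxanFormatError(ValueError):
    """Raised for malformed or referentially inconsistent Marxan inputs."""


# ---------------------------------------------------------------- pu.dat


def write_pu(path, costs: pd.Series, locked: set[int], sep: str = ",") -> None:
    status = [
        STATUS_LOCKED_IN if pu in locked else STATUS_AVAILABLE for pu in costs.index
    ]
    frame = pd.DataFrame({"id": costs.index, "cost": costs.to_numpy(), "status": status})
    frame.to_csv(path, sep=sep, index=False)


def read_pu(path, sep: str = ",") -> pd.DataFrame:
    frame = pd.read_csv(path, sep=sep)
    required = {"id", "cost", "status"}
    if not required.issubset(frame.columns):
        raise MarxanFormatError(f"pu.dat missing columns {required - set(frame.columns)}")
    if frame["id"].duplicated().any():
        dupes = frame.loc[frame["id"].duplicated(), "id"].tolist()
        raise MarxanFormatError(f"duplicate planning-unit ids in pu.dat: {dupes}")
    if (frame["cost"] < 0).any():
        raise MarxanFormatError("negative cost in pu.dat")
    return frame


# -------------------------------------------------------------- spec.dat


def write_spec(path, features: pd.DataFrame, sep: str = ",") -> None:
    frame = pd.DataFrame(
        {
            "id": features["feature_id"],
            "target": features["target_amount"],
            "spf": features["spf"],
            "name": features["name"],
        }
    )
    frame.to_csv(path, sep=sep, index=False)


def read_spec(path, sep: str = ",") -> pd.DataFrame:
    frame = pd.read_csv(path, sep=sep)
    required = {"id", "target", "spf", "name"}
    if not required.issubset(frame.columns):
        raise MarxanFormatError(
            f"spec.dat missing columns {required - set(frame.columns)}"
        )
    if frame["id"].duplicated().any():
        raise MarxanFormatError("duplicate feature ids in spec.dat")
    return frame


# ------------------------------------------------------------ puvspr.dat


def write_puvspr(path, features: pd.DataFrame, amounts, pu_ids, sep: str = ",") -> None:
    coo = amounts.tocoo()
    frame = pd.DataFrame(
        {
            "species": features["feature_id"].to_numpy()[coo.row],
            "pu": np.asarray(pu_ids)[coo.col],
            "amount": coo.data,
        }
    ).sort_values(["pu", "species"], kind="mergesort")
    frame.to_csv(path, sep=sep, index=False)


def read_puvspr(path, pu_ids=None, feature_ids=None, sep: str = ",") -> pd.DataFrame:
    frame = pd.read_csv(path, sep=sep)
    required = {"species", "pu", "amount"}
    if not required.issubset(frame.columns):
        raise MarxanFormatError(
            f"puvspr.dat missing columns {required - set(frame.columns)}"
        )
    dup = frame.duplicated(subset=["species", "pu"])
    if dup.any():
        row = frame[dup].iloc[0]
        raise MarxanFormatError(
            f"duplicate (species, pu) row in puvspr.dat: "
            f"({int(row['species'])}, {int(row['pu'])})"
        )
    if (frame["amount"] < 0).any():
        row = frame[frame["amount"] < 0].iloc[0]
        raise MarxanFormatError(
            f"negative amount in puvspr.dat at (species {int(row['species'])}, "
            f"pu {int(row['pu'])})"
        )
    if pu_ids is not None:
        dangling = set(frame["pu"]) - set(np.asarray(pu_ids).tolist())
        if dangling:
            raise MarxanFormatError(
                f"puvspr.dat references unknown planning units: {sorted(dangling)[:5]}"
            )
    if feature_ids is not None:
        dangling = set(frame["species"]) - set(np.asarray(feature_ids).tolist())
        if dangling:
            raise MarxanFormatError(
                f"puvspr.dat references unknown features: {sorted(dangling)[:5]}"
            )
    return frame


# ------------------------------------------------------------- bound.dat


def write_bound(path, conn: ConnMatrix, sep: str = ",") -> None:
    conn.to_frame().to_csv(path, sep=sep, index=False)


def read_bound(path, n_units: int, directed: bool, sep: str = ",") -> ConnMatrix:
    frame = pd.read_csv(path, sep=sep)
    required = {"id1", "id2", "boundary"}
    if not required.issubset(frame.columns):
        raise MarxanFormatError(
            f"bound.dat missing columns {required - set(frame.columns)}"
        )
    if (frame["boundary"] < 0).any():
        raise MarxanFormatError("negative connectivity strength in bound.dat")
    for col in ("id1", "id2"):
        bad = frame[(frame[col] < 1) | (frame[col] > n_units)]
        if len(bad):
            raise MarxanFormatError(
                f"bound.dat {col} outside 1..{n_units}: {bad[col].tolist()[:5]}"
            )
    return ConnMatrix.from_frame(frame, n_units, directed)


def read_marxan_inputs(directory, sep: str = ",") -> dict:
    """Read and cross-validate a Marxan input directory (pu.dat required)."""
    directory = Path(directory)
    pu_path = directory / "pu.dat"
    if not pu_path.exists():
        raise MarxanFormatError(f"pu.dat not found in {directory}")
    out: dict = {"pu": read_pu(pu_path, sep)}
    pu_ids = out["pu"]["id"].to_numpy()
    if (directory / "spec.dat").exists():
        out["spec"] = read_spec(directory / "spec.dat", sep)
    if (directory / "puvspr.dat").exists():
        feature_ids = out["spec"]["id"].to_numpy() if "spec" in out else None
        out["puvspr"] = read_puvspr(
            directory / "puvspr.dat", pu_ids, feature_ids, sep
        )
    if (directory / "bound.dat").exists():
        out["bound"] = pd.read_csv(directory / "bound.dat", sep=sep)
    return out


def write_scenario(scenario, directory, sep: str = ",") -> None:
    """Serialize one scenario to the Marxan triple plus a config block."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    locked_ids = set(scenario.pu_ids[scenario.locked].tolist())
    write_pu(
        directory / "pu.dat",
        pd.Series(scenario.costs, index=scenario.pu_ids),
        locked_ids,
        sep,
    )
    write_spec(directory / "spec.dat", scenario.features, sep)
    write_puvspr(
        directory / "puvspr.dat", scenario.features, scenario.amounts,
        scenario.pu_ids, sep,
    )
    if scenario.conn is not None:
        write_bound(directory / "bound.dat", scenario.conn, sep)
    block = {
        "objective": scenario.name,
        "connectivity_weight": scenario.conn_weight,
        "connectivity_directed": None
        if scenario.conn is None
        else scenario.conn.directed,
        "n_runs": scenario.n_runs,
        "seed": scenario.seed,
    }
    (directory / "scenario.json").write_text(json.dumps(block, indent=2))


# ------------------------------------------------- seascape serialization


def write_seascape(scape: Seascape, directory, sep: str = ",") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scape.planning_units.to_csv(directory / "planning_units.csv", sep=sep)
    scape.habitat_amounts.to_csv(directory / "habitat_amounts.csv", sep=sep)
    scape.fsa_sites.to_csv(directory / "fsa_sites.csv", sep=sep, index=False)
    mpa_rows = []
    for mpa in scape.mpas:
        if mpa.size_class == "small":
            for pu, frac in sorted(mpa.cover.items()):
                mpa_rows.append(
                    {"mpa_id": mpa.mpa_id, "size_class": "small",
                     "pu_id": pu, "fraction": frac, "no_take": mpa.no_take}
                )
        else:
            for pu in mpa.members:
                mpa_rows.append(
                    {"mpa_id": mpa.mpa_id, "size_class": "large",
                     "pu_id": pu, "fraction": np.nan, "no_take": mpa.no_take}
                )
    pd.DataFrame(
        mpa_rows, columns=["mpa_id", "size_class", "pu_id", "fraction", "no_take"]
    ).to_csv(directory / "mpas.csv", sep=sep, index=False)
    track_rows = [
        {"track_id": t.individual_id, "species": t.species, "step": k,
         "row": r, "col": c}
        for t in scape.turtle_tracks
        for k, (r, c) in enumerate(t.path)
    ]
    pd.DataFrame(
        track_rows, columns=["track_id", "species", "step", "row", "col"]
    ).to_csv(directory / "turtle_tracks.csv", sep=sep, index=False)
    for species, mat in scape.dispersal.items():
        k = mat.shape[0]
        src, dst = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
        pd.DataFrame(
            {"source": src.ravel(), "target": dst.ravel(), "flow": mat.ravel()}
        ).to_csv(directory / f"dispersal_{species}.csv", sep=sep, index=False)
    write_forcing(scape.forcing, directory, sep)
    meta = {"config": {k: (v if not isinstance(v, np.generic) else v.item())
                       for k, v in vars(scape.config).items()}}
    (directory / "seascape.json").write_text(json.dumps(meta, indent=2))


def write_forcing(forcing: ClimateForcing, directory, sep: str = ",") -> None:
    directory = Path(directory)
    n_coarse, n_runs, n_years, _ = forcing.sst.shape
    cell, run, year, month = np.meshgrid(
        np.arange(n_coarse), np.arange(n_runs), forcing.years, np.arange(1, 13),
        indexing="ij",
    )
    pd.DataFrame(
        {"cell": cell.ravel(), "run": run.ravel(), "year": year.ravel(),
         "month": month.ravel(), "sst": forcing.sst.ravel()}
    ).to_csv(directory / "forcing_sst.csv", sep=sep, index=False)
    cell, year = np.meshgrid(np.arange(n_coarse), forcing.ar_years, indexing="ij")
    pd.DataFrame(
        {"cell": cell.ravel(), "year": year.ravel(),
         "aragonite": forcing.aragonite.ravel()}
    ).to_csv(directory / "forcing_aragonite.csv", sep=sep, index=False)
    meta = {
        "coarse_shape": list(forcing.coarse_shape),
        "factor": int(forcing.factor),
        "centres": forcing.centres.tolist(),
        "valid": forcing.valid.astype(int).tolist(),
        "cell_to_coarse": forcing.cell_to_coarse.astype(int).tolist(),
        "years": [int(forcing.years[0]), int(forcing.years[-1])],
        "ar_years": [int(forcing.ar_years[0]), int(forcing.ar_years[-1])],
    }
    (directory / "forcing_meta.json").write_text(json.dumps(meta))


def read_forcing(directory, sep: str = ",") -> ClimateForcing:
    directory = Path(directory)
    meta = json.loads((directory / "forcing_meta.json").read_text())
    years = np.arange(meta["years"][0], meta["years"][1] + 1)
    ar_years = np.arange(meta["ar_years"][0], meta["ar_years"][1] + 1)
    sst_long = pd.read_csv(directory / "forcing_sst.csv", sep=sep)
    n_coarse = int(sst_long["cell"].max()) + 1
    n_runs = int(sst_long["run"].max()) + 1
    sst = np.empty((n_coarse, n_runs, years.size, 12))
    sst_long = sst_long.sort_values(["cell", "run", "year", "month"])
    sst[...] = sst_long["sst"].to_numpy().reshape(sst.shape)
    ar_long = pd.read_csv(directory / "forcing_aragonite.csv", sep=sep)
    ar_long = ar_long.sort_values(["cell", "year"])
    aragonite = ar_long["aragonite"].to_numpy().reshape(n_coarse, ar_years.size)
    return ClimateForcing(
        sst=sst,
        years=years,
        aragonite=aragonite,
        ar_years=ar_years,
        coarse_shape=tuple(meta["coarse_shape"]),
        factor=meta["factor"],
        centres=np.asarray(meta["centres"], dtype=float),
        valid=np.asarray(meta["valid"], dtype=bool),
        cell_to_coarse=np.asarray(meta["cell_to_coarse"], dtype=int),
    )


def read_seascape(directory, sep: str = ",") -> Seascape:
    directory = Path(directory)
    meta = json.loads((directory / "seascape.json").read_text())
    config = SeascapeConfig(**meta["config"])
    pu = pd.read_csv(directory / "planning_units.csv", sep=sep, index_col="pu_id")
    amounts = pd.read_csv(
        directory / "habitat_amounts.csv", sep=sep, index_col="pu_id"
    )
    fsa = pd.read_csv(directory / "fsa_sites.csv", sep=sep)
    mpa_long = pd.read_csv(directory / "mpas.csv", sep=sep)
    mpas = []
    for mpa_id, grp in mpa_long.groupby("mpa_id", sort=False):
        size_class = grp["size_class"].iloc[0]
        if size_class == "small":
            mpas.append(
                MPARecord(
                    mpa_id=mpa_id, size_class="small",
                    cover={int(r.pu_id): float(r.fraction) for r in grp.itertuples()},
                    no_take=bool(grp["no_take"].iloc[0]),
                )
            )
        else:
            mpas.append(
                MPARecord(
                    mpa_id=mpa_id, size_class="large",
                    members=tuple(int(p) for p in sorted(grp["pu_id"])),
                    no_take=bool(grp["no_take"].iloc[0]),
                )
            )
    track_long = pd.read_csv(directory / "turtle_tracks.csv", sep=sep)
    tracks = []
    for track_id, grp in track_long.groupby("track_id", sort=True):
        grp = grp.sort_values("step")
        tracks.append(
            TurtleTrack(
                individual_id=int(track_id),
                species=grp["species"].iloc[0],
                path=tuple((int(r), int(c)) for r, c in zip(grp["row"], grp["col"])),
            )
        )
    dispersal = {}
    for species in ("trout", "cucumber"):
        path = directory / f"dispersal_{species}.csv"
        if path.exists():
            frame = pd.read_csv(path, sep=sep).sort_values(["source", "target"])
            k = int(frame["source"].max()) + 1 if len(frame) else 0
            dispersal[species] = frame["flow"].to_numpy().reshape(k, k)
    forcing = read_forcing(directory, sep)
    return Seascape(
        config=config,
        planning_units=pu,
        habitat_amounts=amounts,
        mpas=mpas,
        fsa_sites=fsa,
        turtle_tracks=tracks,
        dispersal=dispersal,
        forcing=forcing,
    )
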