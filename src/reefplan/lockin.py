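"""Lock-in of existing marine protected areas.

Existing MPAs come in two flavours. Small, locally managed areas are often
smaller than a planning unit; each is described by the fraction of a cell's
habitat it protects, and a cell becomes locked into every reserve solution
once the cumulative protected fraction exceeds 50% of the cell's habitat.
Large multi-cell protected areas carry no zoning information, so a fixed 10%
of their member cells (at least one) is drawn at random and locked, a
mid-range stand-in for typical no-take proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

SMALL = "small"
LARGE = "large"

#: cumulative protected habitat fraction above which a cell is locked
LOCK_THRESHOLD = 0.5
#: fraction of a large MPA's member cells allocated as no-take
LARGE_NOTAKE_FRACTION = 0.10


class MPAValidationError(ValueError):
    """Raised when an MPA references impossible coverage."""


@dataclass(frozen=True)
class MPARecord:
    """One existing protected area, pre-rasterized onto planning units.

    Parameters
    ----------
    mpa_id : str
        Unique identifier.
    size_class : str
        ``"small"`` (sub-cell, habitat-fraction coverage) or ``"large"``
        (multi-cell membership, no zoning).
    cover : mapping, optional
        For small MPAs: planning-unit id -> fraction of that cell's habitat
        protected, each in [0, 1].
    members : tuple of int, optional
        For large MPAs: member planning-unit ids (at least one).
    no_take : bool
        Small MPAs are assumed entirely no-take.
    """

    mpa_id: str
    size_class: str
    cover: Mapping[int, float] | None = None
    members: tuple[int, ...] = field(default=())
    no_take: bool = True

    def __post_init__(self) -> None:
        if self.size_class not in (SMALL, LARGE):
            raise MPAValidationError(f"unknown size class {self.size_class!r}")
        if self.size_class == SMALL:
            if not self.cover:
                raise MPAValidationError(f"small MPA {self.mpa_id} has no coverage")
            for pu, frac in self.cover.items():
                if not 0.0 <= frac <= 1.0:
                    raise MPAValidationError(
                        f"MPA {self.mpa_id}: cover fraction {frac} for pu {pu} "
                        "outside [0, 1]"
                    )
        else:
            if len(self.members) < 1:
                raise MPAValidationError(f"large MPA {self.mpa_id} has no member cells")


def lock_small_mpas(
    mpas: list[MPARecord], habitat_amounts: pd.DataFrame
) -> set[int]:
    """Planning units locked by cumulative small-MPA coverage.

    A cell is locked iff the summed protected habitat fraction over all small
    MPAs strictly exceeds :data:`LOCK_THRESHOLD` of the cell's habitat.

    Raises
    ------
    MPAValidationError
        If a covered cell does not exist or holds no habitat at all while a
        positive protected amount is claimed for it.
    """
    totals = habitat_amounts.sum(axis=1)
    cumulative: dict[int, float] = {}
    for mpa in mpas:
        if mpa.size_class != SMALL:
            continue
        for pu, frac in mpa.cover.items():
            if pu not in totals.index:
                raise MPAValidationError(
                    f"MPA {mpa.mpa_id} covers unknown planning unit {pu}"
                )
            if frac > 0 and totals.loc[pu] <= 0:
                raise MPAValidationError(
                    f"MPA {mpa.mpa_id} claims protected habitat in planning unit "
                    f"{pu}, which holds no habitat"
                )
            cumulative[pu] = cumulative.get(pu, 0.0) + frac
    return {pu for pu, frac in cumulative.items() if frac > LOCK_THRESHOLD}


def lock_large_mpas(mpas: list[MPARecord], rng_seed: int) -> set[int]:
    """Planning units locked inside large MPAs.

    For each large MPA, ``round(0.10 * n_members)`` cells — never fewer than
    one — are drawn uniformly at random.  The half-up rounding and the draw
    order (MPAs sorted by id) make the result a pure function of the seed.
    """
    rng = np.random.default_rng(rng_seed)
    locked: set[int] = set()
    for mpa in sorted(
        (m for m in mpas if m.size_class == LARGE), key=lambda m: m.mpa_id
    ):
        n = len(mpa.members)
        k = max(1, int(np.floor(LARGE_NOTAKE_FRACTION * n + 0.5)))
        chosen = rng.choice(sorted(mpa.members), size=k, replace=False)
        locked.update(int(c) for c in chosen)
    return locked


def compute_protected_amounts(
    locked: set[int],
    habitat_amounts: pd.DataFrame,
    admin: pd.DataFrame,
) -> pd.DataFrame:
    """Currently protected amount and fraction per feature per admin unit.

    Parameters
    ----------
    locked : set of int
        Locked planning-unit ids (union of both lock-in rules).
    habitat_amounts : DataFrame
        Indexed by planning-unit id, one column per habitat feature.
    admin : DataFrame
        Indexed by planning-unit id with ``country`` and ``bioregion`` columns.

    Returns
    -------
    DataFrame
        Long table with columns ``admin_type`` ("country" | "bioregion"),
        ``admin_unit``, ``feature``, ``protected_amount``, ``total_amount``,
        ``fraction``.  Features with zero total amount report fraction 0 and
        raise a warning.
    """
    unknown = set(locked) - set(habitat_amounts.index)
    if unknown:
        raise MPAValidationError(f"locked units not in habitat table: {sorted(unknown)}")
    locked_mask = habitat_amounts.index.isin(locked)
    rows: list[dict] = []
    for admin_type in ("country", "bioregion"):
        groups = admin.loc[habitat_amounts.index, admin_type]
        for unit, idx in habitat_amounts.groupby(groups).groups.items():
            sub = habitat_amounts.loc[idx]
            sub_locked = sub[pd.Index(idx).isin(locked)]
            for feat in habitat_amounts.columns:
                total = float(sub[feat].sum())
                prot = float(sub_locked[feat].sum())
                if total <= 0:
                    if prot > 0:  # pragma: no cover - prevented upstream
                        raise MPAValidationError(
                            f"feature {feat} protected but absent in {unit}"
                        )
                    warnings.warn(
                        f"feature {feat!r} has zero total amount in "
                        f"{admin_type} {unit}; fraction reported as 0",
                        stacklevel=2,
                    )
                    frac = 0.0
                else:
                    frac = prot / total
                rows.append(
                    {
                        "admin_type": admin_type,
                        "admin_unit": unit,
                        "feature": feat,
                        "protected_amount": prot,
                        "total_amount": total,
                        "fraction": frac,
                    }
                )
    del locked_mask
    return pd.DataFrame(rows)


def locked_union(
    mpas: list[MPARecord], habitat_amounts: pd.DataFrame, rng_seed: int
) -> set[int]:
    """Union of both lock-in rules; the set passed to every scenario."""
    return lock_small_mpas(mpas, habitat_amounts) | lock_large_mpas(mpas, rng_seed)
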