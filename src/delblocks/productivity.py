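"""Building-block productivity statistics.

P(bind) of a building block at a position is the fraction of trisynthons
containing it there that are labeled binders.  Compatibility counts how many
distinct partners a building block forms binders with at another position,
and joint-probability tables give the binder fraction for pairs of
building-block groups (P(bind) bins or similarity clusters), flagging
combinations never observed in the data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_pbind",
    "bin_pbind",
    "compatibility_counts",
    "joint_probability",
]

#: Occurrence count at or below which a P(bind) estimate is flagged as
#: small-sample (flagged, never silently excluded).
LOW_N = 30


def _bb_col(position: int) -> str:
    if position not in (1, 2, 3):
        raise ValueError(f"position must be 1, 2 or 3, got {position}")
    return f"bb{position}"


def compute_pbind(records: pd.DataFrame, position: int) -> pd.DataFrame:
    """Per-building-block binder fraction at one position.

    Returns a DataFrame indexed by bb_id with columns ``pbind`` (fraction of
    the building block's trisynthons that bind), ``n`` (occurrence count)
    and ``low_n`` (True when n <= 30, a conventional small-sample cutoff).
    Building blocks that never occur are simply absent.
    """
    if "binder" not in records.columns:
        raise ValueError("records must be labeled (missing 'binder' column)")
    col = _bb_col(position)
    if len(records) == 0:
        return pd.DataFrame(columns=["pbind", "n", "low_n"])
    grouped = records.groupby(col)["binder"].agg(["mean", "size"])
    table = grouped.rename(columns={"mean": "pbind", "size": "n"})
    table["low_n"] = table["n"] <= LOW_N
    table.index.name = "bb_id"
    return table


def bin_pbind(table: pd.DataFrame, n_bins: int = 5) -> pd.DataFrame:
    """Assign interval bins to P(bind) values.

    Bin b covers [ (b-1)/n_bins, b/n_bins ) for b < n_bins; the top bin is
    closed at 1.0, so with the default 5 bins, bin 1 is [0.00, 0.20) and
    bin 5 is [0.80, 1.00].
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    out = table.copy()
    binned = np.floor(out["pbind"].to_numpy() * n_bins).astype(np.int64) + 1
    out["bin"] = np.minimum(binned, n_bins)
    return out


def compatibility_counts(
    records: pd.DataFrame, position_i: int, position_j: int
) -> pd.Series:
    """Number of compatible partners at ``position_j`` per building block at
    ``position_i``.

    Two building blocks are compatible when they co-occur in at least one
    binder, so the count is the number of distinct position-j building
    blocks among the binders containing the reference building block.
    Building blocks with no binders count 0.
    """
    if position_i == position_j:
        raise ValueError("reference and partner positions must differ")
    if "binder" not in records.columns:
        raise ValueError("records must be labeled (missing 'binder' column)")
    ci, cj = _bb_col(position_i), _bb_col(position_j)
    binders = records.loc[records["binder"] == 1]
    counts = binders.groupby(ci)[cj].nunique()
    all_bbs = pd.Index(records[ci].unique(), name="bb_id")
    return counts.reindex(all_bbs, fill_value=0).astype(np.int64)


def joint_probability(
    records: pd.DataFrame,
    position_i: int,
    position_j: int,
    grouping_i: pd.Series | dict,
    grouping_j: pd.Series | dict,
) -> pd.DataFrame:
    """Binder fraction for every pair of building-block groups.

    ``grouping_i``/``grouping_j`` map every bb_id at the respective position
    to a group label (a P(bind) bin index or a cluster ID).  The positions
    need not be adjacent — any disynthon pair (1,2), (1,3), (2,3) works.

    Returns a long-format DataFrame over the full cross product of group
    labels with columns ``group_i, group_j, n, n_bind, p, observed``.  Cells
    never observed in the data have ``observed=False`` and ``p=NaN`` —
    "never observed" is distinct from "low probability".
    """
    if position_i == position_j:
        raise ValueError("positions must differ")
    gi = pd.Series(grouping_i)
    gj = pd.Series(grouping_j)
    ci, cj = _bb_col(position_i), _bb_col(position_j)
    for col, mapping, pos in ((ci, gi, position_i), (cj, gj, position_j)):
        missing = set(records[col].unique()) - set(mapping.index)
        if missing:
            raise KeyError(
                f"building blocks at position {pos} lack a group assignment: "
                f"{sorted(missing)[:5]}"
            )
    df = pd.DataFrame(
        {
            "group_i": records[ci].map(gi).to_numpy(),
            "group_j": records[cj].map(gj).to_numpy(),
            "binder": records["binder"].to_numpy(),
        }
    )
    agg = df.groupby(["group_i", "group_j"])["binder"].agg(["size", "sum"])
    full = pd.MultiIndex.from_product(
        [np.sort(gi.unique()), np.sort(gj.unique())], names=["group_i", "group_j"]
    )
    agg = agg.reindex(full, fill_value=0).rename(columns={"size": "n", "sum": "n_bind"})
    agg = agg.reset_index()
    agg["observed"] = agg["n"] > 0
    agg["p"] = np.where(agg["observed"], agg["n_bind"] / agg["n"].where(agg["n"] > 0), np.nan)
    agg["n"] = agg["n"].astype(np.int64)
    agg["n_bind"] = agg["n_bind"].astype(np.int64)
    return agg
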