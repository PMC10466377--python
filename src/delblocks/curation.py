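"""Selection-table ingest, curation, and Poisson binder calling.

The raw input is one CSV row per trisynthon: the compound SMILES, its NGS
read count, and the SMILES of the three constituent building blocks
(position 1 is closest to the DNA tag, position 3 furthest).  Curation
removes duplicates, null rows, boron-containing building blocks and
unspecified-stereo duplicates, and strips protecting groups; labeling then
calls a compound a binder when its read count is inconsistent with a Poisson
background at the configured confidence level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.stats import poisson

from .smirks import DEFAULT_DEPROTECTION_SMIRKS, compile_smirks, deprotect_smiles

__all__ = [
    "REQUIRED_COLUMNS",
    "CSVFormatError",
    "CurationReport",
    "read_selection_csv",
    "curate",
    "poisson_binder_threshold",
    "label_binders",
    "threshold_sweep",
    "subsample",
]

#: Canonical input column names; ``read_selection_csv`` can rename from a
#: user-supplied mapping.
REQUIRED_COLUMNS = (
    "compound_smiles",
    "read_count",
    "bb1_smiles",
    "bb2_smiles",
    "bb3_smiles",
)

POSITIONS = (1, 2, 3)


class CSVFormatError(ValueError):
    """The selection CSV is missing a required column."""


@dataclass
class CurationReport:
    """Row-level accounting for one curation pass.

    Invariant: ``rows_out + sum(dropped.values()) == rows_in``.
    """

    rows_in: int = 0
    rows_out: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    deprotections: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.rows_out + sum(self.dropped.values()) != self.rows_in:
            raise AssertionError("curation accounting does not balance")

    def to_json(self) -> str:
        return json.dumps(
            {
                "rows_in": self.rows_in,
                "rows_out": self.rows_out,
                "dropped": self.dropped,
                "deprotections": self.deprotections,
            },
            indent=2,
        )


def read_selection_csv(path, columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a raw selection CSV into a DataFrame with canonical column names.

    Parameters
    ----------
    path : path-like
        CSV with one row per trisynthon.
    columns : dict, optional
        Mapping from canonical name (see ``REQUIRED_COLUMNS``) to the column
        name actually used in the file.

    Read counts are parsed as integers; unparsable entries become null and
    are dropped (and counted) by :func:`curate`.
    """
    df = pd.read_csv(path, dtype=str)
    rename = {}
    for canonical in REQUIRED_COLUMNS:
        source = (columns or {}).get(canonical, canonical)
        if source not in df.columns:
            raise CSVFormatError(f"selection CSV is missing required column {source!r}")
        rename[source] = canonical
    df = df.rename(columns=rename)[list(REQUIRED_COLUMNS)]
    df["read_count"] = pd.to_numeric(df["read_count"], errors="coerce").astype("Int64")
    return df


def _canonical(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def _stereo_stripped(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def _has_stereo(smiles: str) -> bool:
    return _stereo_stripped(smiles) != Chem.CanonSmiles(smiles)


def _contains_boron(smiles: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    return any(atom.GetAtomicNum() == 5 for atom in mol.GetAtoms())


def curate(
    raw: pd.DataFrame,
    smirks: tuple[tuple[str, str], ...] = DEFAULT_DEPROTECTION_SMIRKS,
) -> tuple[pd.DataFrame, dict[int, pd.DataFrame], CurationReport]:
    """Apply the curation rules to raw selection rows.

    Rules, in order: drop rows with null fields or unparsable read counts;
    drop duplicate compounds; deprotect every building-block SMILES
    (exhaustively, in SMIRKS list order); drop rows whose building blocks do
    not parse; drop compounds with boron-containing building blocks; for
    building blocks duplicated with and without stereochemistry, drop the
    compounds containing the unspecified form.

    Returns
    -------
    records : DataFrame
        Columns ``compound_smiles, read_count, bb1, bb2, bb3,
        bb{i}_smiles`` — building-block IDs are deterministic
        sorted-canonical-SMILES ranks within each position.
    bb_tables : dict position -> DataFrame(bb_id, smiles, stereo_specified)
    report : CurationReport
    """
    compiled = compile_smirks(smirks)
    report = CurationReport(rows_in=len(raw))
    df = raw.copy()

    # Null rows (including read counts that failed to parse).
    mask_null = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    report.dropped["nulls"] = int(mask_null.sum())
    df = df.loc[~mask_null]

    # Duplicate compounds.
    mask_dup = df.duplicated(subset="compound_smiles", keep="first")
    report.dropped["duplicates"] = int(mask_dup.sum())
    df = df.loc[~mask_dup]

    # Deprotect each distinct building-block SMILES once, then map.
    bb_cols = [f"bb{i}_smiles" for i in POSITIONS]
    unique_smiles = pd.unique(df[bb_cols].values.ravel())
    deprotected: dict[str, str | None] = {}
    for smi in unique_smiles:
        canon, applied = deprotect_smiles(smi, compiled)
        deprotected[smi] = canon
        for name, count in applied.items():
            report.deprotections[name] = report.deprotections.get(name, 0) + count
    for col in bb_cols:
        df[col] = df[col].map(deprotected)

    mask_bad = df[bb_cols].isna().any(axis=1)
    report.dropped["unparsable_bb"] = int(mask_bad.sum())
    df = df.loc[~mask_bad]

    # Boron-containing building blocks (conformer force fields cannot treat
    # them, and they dominate some raw libraries).
    boron = {smi for smi in set(df[bb_cols].values.ravel()) if _contains_boron(smi)}
    mask_boron = df[bb_cols].isin(boron).any(axis=1)
    report.dropped["boron"] = int(mask_boron.sum())
    df = df.loc[~mask_boron]

    # Stereo duplicates: where the same skeleton occurs both with and without
    # specified stereochemistry, drop compounds carrying the unspecified form.
    unspecified_forms: set[tuple[int, str]] = set()
    for pos in POSITIONS:
        col = f"bb{pos}_smiles"
        variants: dict[str, set[str]] = {}
        for smi in df[col].unique():
            variants.setdefault(_stereo_stripped(smi), set()).add(smi)
        for stripped, group in variants.items():
            if len(group) < 2:
                continue
            specified = {s for s in group if _has_stereo(s)}
            if specified and len(specified) < len(group):
                unspecified_forms.update((pos, s) for s in group - specified)
    if unspecified_forms:
        mask_stereo = pd.Series(False, index=df.index)
        for pos, smi in unspecified_forms:
            mask_stereo |= df[f"bb{pos}_smiles"] == smi
        report.dropped["unspecified_stereo"] = int(mask_stereo.sum())
        df = df.loc[~mask_stereo]
    else:
        report.dropped["unspecified_stereo"] = 0

    # Deterministic IDs: sorted-canonical-SMILES rank within each position.
    bb_tables: dict[int, pd.DataFrame] = {}
    for pos in POSITIONS:
        col = f"bb{pos}_smiles"
        ordered = sorted(df[col].unique())
        ids = {smi: f"p{pos}_{rank:05d}" for rank, smi in enumerate(ordered)}
        df[f"bb{pos}"] = df[col].map(ids)
        bb_tables[pos] = pd.DataFrame(
            {
                "bb_id": [ids[s] for s in ordered],
                "smiles": ordered,
                "stereo_specified": [_has_stereo(s) for s in ordered],
            }
        )

    records = df[
        ["compound_smiles", "read_count"]
        + [f"bb{i}" for i in POSITIONS]
        + bb_cols
    ].reset_index(drop=True)
    records["read_count"] = records["read_count"].astype(np.int64)
    report.rows_out = len(records)
    report.validate()
    return records, bb_tables, report


def poisson_binder_threshold(lambda0: float, alpha: float = 0.05) -> int:
    """Smallest integer read count k* with P(X >= k* | lambda0) < alpha.

    A read count at or above k* is inconsistent with the Poisson background
    at level ``alpha``.  ``alpha >= 1`` accepts everything (k* = 0).
    """
    if lambda0 <= 0:
        raise ValueError(f"lambda0 must be positive, got {lambda0}")
    if not 0 < alpha:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if alpha >= 1:
        return 0
    # P(X >= k) = sf(k - 1); start near the analytic inverse and walk.
    k = max(int(poisson.isf(alpha, lambda0)) - 2, 0)
    while poisson.sf(k - 1, lambda0) >= alpha:
        k += 1
    return k


def label_binders(
    records: pd.DataFrame,
    lambda0: float | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Attach a binary ``binder`` label from the Poisson background test.

    ``lambda0=None`` estimates the background rate as the mean read count of
    the input — the only dataset-intrinsic estimate available when the true
    sequencing background is unknown; pass an explicit rate when it is.

    The chosen rate and threshold are recorded in ``df.attrs``.
    """
    if lambda0 is None:
        lambda0 = float(records["read_count"].mean())
    if lambda0 == 0:
        # Limit of a vanishing background: any nonzero count is significant.
        threshold = 1
    else:
        threshold = poisson_binder_threshold(lambda0, alpha)
    out = records.copy()
    out["binder"] = (out["read_count"] >= threshold).astype(np.int64)
    out.attrs["lambda0"] = lambda0
    out.attrs["alpha"] = alpha
    out.attrs["binder_threshold"] = threshold
    return out


def threshold_sweep(records: pd.DataFrame, thresholds) -> pd.DataFrame:
    """Tabulate binder/nonbinder counts as the minimum read count varies.

    Useful when the binder/nonbinder delineation is less clear-cut than for
    a rich target: shows how sensitive the labeling is to the cutoff.
    """
    thresholds = sorted(int(t) for t in thresholds)
    if len(records) == 0:
        return pd.DataFrame(columns=["threshold", "n_binder", "n_nonbinder"])
    counts = records["read_count"].to_numpy()
    rows = []
    for t in thresholds:
        n_bind = int((counts >= t).sum())
        rows.append({"threshold": t, "n_binder": n_bind, "n_nonbinder": len(counts) - n_bind})
    return pd.DataFrame(rows)


def subsample(
    records: pd.DataFrame,
    n_binders: int,
    n_nonbinders: int,
    seed: int,
) -> pd.DataFrame:
    """Optional size management after labeling: keep the top ``n_binders``
    binders by read count and a random sample of ``n_nonbinders`` nonbinders.

    Off by default in every pipeline; it changes dataset composition, not the
    statistics' definitions.
    """
    if "binder" not in records.columns:
        raise ValueError("subsample requires labeled records")
    binders = records.loc[records["binder"] == 1]
    nonbinders = records.loc[records["binder"] == 0]
    top = binders.sort_values("read_count", ascending=False, kind="mergesort").head(n_binders)
    rng = np.random.default_rng(seed)
    take = min(n_nonbinders, len(nonbinders))
    picked = nonbinders.iloc[rng.choice(len(nonbinders), size=take, replace=False)]
    out = pd.concat([top, picked]).sort_index().reset_index(drop=True)
    out.attrs = dict(records.attrs)
    return out
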