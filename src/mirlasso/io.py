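"""Readers and writers for expression matrices, clinical tables and edge lists.

All on-disk formats are plain tab-separated UTF-8 text:

* **Expression matrix** — row 1 holds feature IDs, column 1 holds sample IDs,
  body is numeric.  One file per molecule class (miRNA or mRNA).
* **Clinical table** — columns ``sample_id``, ``survival_days``, ``er_status``,
  ``stage``; unknown columns are ignored, endpoint values may be absent.
* **Edge list** — columns ``node_a``, ``node_b``, ``class_a``, ``class_b``,
  one undirected edge per line in deterministic lexicographic order.

Missing expression entries are an error, never imputed.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MIRNA = "miRNA"
MRNA = "mRNA"
FEATURE_CLASSES = (MIRNA, MRNA)

ER_LEVELS = ("positive", "negative")
STAGE_LEVELS = ("I", "II", "III", "IV")


class ExpressionIOError(ValueError):
    """Raised for malformed expression / clinical / edge-list files."""


def _find_duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass
class ExpressionMatrix:
    """A samples x features expression matrix with per-feature class labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix; index = sample IDs, columns = feature IDs.
    feature_class : pandas.Series
        Maps each feature ID to ``"miRNA"`` or ``"mRNA"``.
    """

    values: pd.DataFrame
    feature_class: pd.Series

    def __post_init__(self) -> None:
        idx = list(self.values.index.astype(str))
        cols = list(self.values.columns.astype(str))
        dup_s = _find_duplicates(idx)
        if dup_s:
            raise ExpressionIOError(f"duplicate sample IDs: {dup_s}")
        dup_f = _find_duplicates(cols)
        if dup_f:
            raise ExpressionIOError(f"duplicate feature IDs: {dup_f}")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ExpressionIOError("empty expression matrix")
        if self.values.isna().any().any():
            where = np.argwhere(self.values.isna().to_numpy())
            r, c = where[0]
            raise ExpressionIOError(
                f"missing value at sample {idx[r]!r}, feature {cols[c]!r} "
                "(missing expression entries are not imputed)"
            )
        self.feature_class = self.feature_class.reindex(self.values.columns)
        if self.feature_class.isna().any():
            missing = list(self.feature_class.index[self.feature_class.isna()])
            raise ExpressionIOError(f"features without class label: {missing}")
        bad = set(self.feature_class.unique()) - set(FEATURE_CLASSES)
        if bad:
            raise ExpressionIOError(f"unknown feature classes: {sorted(bad)}")

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        unknown = [f for f in ids if f not in self.values.columns]
        if unknown:
            raise ExpressionIOError(f"unknown feature IDs: {unknown}")
        return ExpressionMatrix(self.values[ids].copy(), self.feature_class[ids].copy())

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        unknown = [s for s in ids if s not in self.values.index]
        if unknown:
            raise ExpressionIOError(f"unknown sample IDs: {unknown}")
        return ExpressionMatrix(self.values.loc[ids].copy(), self.feature_class.copy())


@dataclass
class ClinicalTable:
    """Per-sample clinical endpoints used for two-group assignment.

    ``data`` has index = sample IDs and columns ``survival_days`` (nonnegative
    float or NaN), ``er_status`` (``positive``/``negative`` or NaN) and
    ``stage`` (``I``..``IV`` or NaN).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        dup = _find_duplicates(list(self.data.index.astype(str)))
        if dup:
            raise ExpressionIOError(f"duplicate sample IDs in clinical table: {dup}")
        for col in ("survival_days", "er_status", "stage"):
            if col not in self.data.columns:
                self.data[col] = np.nan
        sd = pd.to_numeric(self.data["survival_days"], errors="coerce")
        bad = self.data["survival_days"].notna() & sd.isna()
        if bad.any():
            raise ExpressionIOError(
                f"non-numeric survival_days for samples: {list(self.data.index[bad])}"
            )
        if (sd.dropna() < 0).any():
            neg = list(sd.index[sd < 0])
            raise ExpressionIOError(f"negative survival_days for samples: {neg}")
        self.data["survival_days"] = sd
        for col, levels in (("er_status", ER_LEVELS), ("stage", STAGE_LEVELS)):
            vals = self.data[col]
            ok = vals.isna() | vals.isin(levels)
            if not ok.all():
                bad_vals = sorted(set(vals[~ok]))
                raise ExpressionIOError(f"invalid {col} values: {bad_vals}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


def read_expression(path: str | Path, class_label: str) -> ExpressionMatrix:
    """Read a TSV expression matrix and label every feature ``class_label``.

    The file orientation is rows = samples, columns = features.  Duplicate
    IDs, non-numeric or missing cells, and empty matrices raise
    :class:`ExpressionIOError` with the offending coordinates named.
    """
    if class_label not in FEATURE_CLASSES:
        raise ExpressionIOError(
            f"class_label must be one of {FEATURE_CLASSES}, got {class_label!r}"
        )
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if len(lines) < 2:
        raise ExpressionIOError(f"{path}: empty expression matrix")
    header = lines[0].split("\t")
    feature_ids = [h.strip() for h in header[1:]]
    if not feature_ids:
        raise ExpressionIOError(f"{path}: no feature columns")
    dup = _find_duplicates(feature_ids)
    if dup:
        raise ExpressionIOError(f"{path}: duplicate feature IDs: {dup}")

    raw = pd.read_csv(
        _stdio.StringIO(text), sep="\t", index_col=0, header=0, dtype=str,
        keep_default_na=False, na_values=[],
    )
    raw.columns = feature_ids
    raw.index = raw.index.astype(str)
    dup_s = _find_duplicates(list(raw.index))
    if dup_s:
        raise ExpressionIOError(f"{path}: duplicate sample IDs: {dup_s}")

    numeric = raw.apply(lambda col: pd.to_numeric(col.str.strip(), errors="coerce"))
    bad_mask = numeric.isna().to_numpy()
    if bad_mask.any():
        r, c = np.argwhere(bad_mask)[0]
        cell = raw.iat[r, c]
        kind = "missing" if cell.strip() == "" else f"non-numeric ({cell!r})"
        raise ExpressionIOError(
            f"{path}: {kind} value at row {raw.index[r]!r}, column {feature_ids[c]!r}"
        )
    numeric.index.name = None
    numeric.columns.name = None
    fclass = pd.Series(class_label, index=numeric.columns)
    return ExpressionMatrix(numeric.astype(float), fclass)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix in the TSV dialect read_expression expects."""
    expr.values.to_csv(Path(path), sep="\t", index_label="sample_id")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id / survival_days / er_status / stage."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ExpressionIOError(f"{path}: clinical table must have a sample_id column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index)
    for col in ("survival_days", "er_status", "stage"):
        if col in df.columns:
            vals = df[col].str.strip()
            out[col] = vals.where(vals.str.len() > 0, other=np.nan)
        else:
            out[col] = np.nan
    return ClinicalTable(out)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    df = clinical.data.copy()
    sd = df["survival_days"]
    df["survival_days"] = sd.map(lambda v: "" if pd.isna(v) else f"{int(v)}" if float(v).is_integer() else f"{v}")
    df = df.fillna("")
    df.to_csv(Path(path), sep="\t", index_label="sample_id")


def integrate(mirna: ExpressionMatrix, mrna: ExpressionMatrix) -> ExpressionMatrix:
    """Join miRNA (X, n x j) and mRNA (Y, n x k) profiles into Z (n x (j+k)).

    Samples are aligned by ID (the second argument may be permuted); the
    miRNA block comes first.  Mismatched sample sets or a shared feature ID
    raise :class:`ExpressionIOError`.
    """
    sx, sy = set(mirna.sample_ids), set(mrna.sample_ids)
    if sx != sy:
        only_x = sorted(sx - sy)
        only_y = sorted(sy - sx)
        raise ExpressionIOError(
            f"sample sets differ: only in first matrix {only_x}, only in second {only_y}"
        )
    shared = set(mirna.feature_ids) & set(mrna.feature_ids)
    if shared:
        raise ExpressionIOError(f"feature ID collision between matrices: {sorted(shared)}")
    y_aligned = mrna.values.loc[mirna.sample_ids]
    values = pd.concat([mirna.values, y_aligned], axis=1)
    fclass = pd.concat([mirna.feature_class, mrna.feature_class])
    return ExpressionMatrix(values, fclass)


EDGE_LIST_COLUMNS = ("node_a", "node_b", "class_a", "class_b")


def write_edge_list(network, path: str | Path) -> None:
    """Write an InteractionNetwork's edges as a sorted four-column TSV.

    Within each edge the lexicographically smaller node is ``node_a``; rows
    are sorted by (node_a, node_b).  An empty network yields a header-only
    file.
    """
    rows = []
    for u, v in network.edges:
        a, b = sorted((u, v))
        rows.append((a, b, network.node_class[a], network.node_class[b]))
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EDGE_LIST_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_edge_list(path: str | Path):
    """Read an edge-list TSV back into an InteractionNetwork."""
    from .network import InteractionNetwork  # local import: avoid cycle

    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    missing = [c for c in EDGE_LIST_COLUMNS if c not in df.columns]
    if missing:
        raise ExpressionIOError(f"{path}: edge list missing columns {missing}")
    node_class: dict[str, str] = {}
    edges = []
    for _, row in df.iterrows():
        for node, cls in ((row.node_a, row.class_a), (row.node_b, row.class_b)):
            if cls not in FEATURE_CLASSES:
                raise ExpressionIOError(f"{path}: unknown feature class {cls!r}")
            prev = node_class.setdefault(node, cls)
            if prev != cls:
                raise ExpressionIOError(f"{path}: conflicting class for node {node!r}")
        edges.append((row.node_a, row.node_b, 1.0))
    return InteractionNetwork.from_edges(node_class, edges)
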