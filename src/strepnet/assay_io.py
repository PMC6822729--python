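"""Reading, writing, and binarization of pairwise inhibition assays.

The raw data of an agar-overlay inhibition assay are zone-of-inhibition
measurements (mm) for ordered isolate pairs: each *source* isolate is grown,
killed, overlaid, and a *target* isolate is scored for growth inhibition.
Zones are measured twice at right angles per replicate, with three replicates
per pair. A directed edge source → target is called when the mean zone
exceeds a threshold (2 mm by default, strictly), yielding one binary
interaction matrix per sympatric community.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ZONE_COLUMNS = ("source", "target", "replicate", "zone_a_mm", "zone_b_mm")

DEFAULT_THRESHOLD_MM = 2.0


class ZoneTableError(ValueError):
    """Malformed or invalid zone-table content."""


class MatrixFormatError(ValueError):
    """Interaction matrix file is not a square labeled 0/1 table."""


@dataclass(frozen=True)
class InhibitionMatrix:
    """Binary interaction matrix for one community.

    ``cells[i, j] == 1`` iff the row isolate ``labels[i]`` inhibits the
    column isolate ``labels[j]``. The diagonal is ignored by all downstream
    computation and forced to zero on construction.
    """

    labels: tuple[str, ...]
    cells: np.ndarray
    community_id: str = ""

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        n = len(self.labels)
        if cells.shape != (n, n):
            raise MatrixFormatError(
                f"matrix shape {cells.shape} does not match {n} labels"
            )
        if not np.isin(cells, (0, 1)).all():
            raise MatrixFormatError("matrix cells must be 0 or 1")
        cells = cells.astype(np.int8).copy()
        np.fill_diagonal(cells, 0)
        cells.setflags(write=False)
        object.__setattr__(self, "cells", cells)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def n_isolates(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.cells.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InhibitionMatrix):
            return NotImplemented
        return (
            self.labels == other.labels
            and self.community_id == other.community_id
            and bool((self.cells == other.cells).all())
        )


@dataclass
class AssayTable:
    """Replicated zone measurements plus isolate/community bookkeeping."""

    measurements: pd.DataFrame
    isolates: list[str]
    community_of: dict[str, str] = field(default_factory=dict)

    def pair_means(self) -> pd.DataFrame:
        """Mean zone per ordered pair: perpendicular pair first, then replicates."""
        df = self.measurements.copy()
        df["zone_mm"] = (df["zone_a_mm"] + df["zone_b_mm"]) / 2.0
        per_rep = df.groupby(["source", "target", "replicate"], sort=False)[
            "zone_mm"
        ].mean()
        return (
            per_rep.groupby(["source", "target"]).mean().rename("mean_zone_mm").reset_index()
        )

    def missing_pairs(self) -> list[tuple[str, str]]:
        """Ordered distinct pairs of known isolates with no measurement at all."""
        seen = set(zip(self.measurements["source"], self.measurements["target"]))
        return [
            (s, t)
            for s in self.isolates
            for t in self.isolates
            if s != t and (s, t) not in seen
        ]


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_zone_table(
    path: str | Path,
    community_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    communities_from_prefix: bool = False,
) -> AssayTable:
    """Read a replicated zone table (columns ``source,target,replicate,zone_a_mm,zone_b_mm``).

    Community membership comes from ``community_map`` (an explicit label →
    community mapping); ``communities_from_prefix=True`` instead derives it
    from the label prefix before the first ``.`` (isolate naming such as
    ``1231.5`` encodes the soil core as ``1231``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), dtype=str)
    missing_cols = [c for c in ZONE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ZoneTableError(f"{path}: missing columns {missing_cols}")

    df = df[list(ZONE_COLUMNS)].copy()
    for col in ("replicate", "zone_a_mm", "zone_b_mm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] + 2  # 1-based + header
        if len(bad):
            raise ZoneTableError(
                f"{path}: malformed value in column {col!r} at line(s) {list(bad)}"
            )
        if coerced.isna().any():
            line = int(df.index[coerced.isna()][0]) + 2
            raise ZoneTableError(f"{path}: empty {col!r} at line {line}")
        df[col] = coerced
    for col in ("zone_a_mm", "zone_b_mm"):
        if (df[col] < 0).any() or not np.isfinite(df[col]).all():
            line = int(df.index[(df[col] < 0) | ~np.isfinite(df[col])][0]) + 2
            raise ZoneTableError(f"{path}: negative or non-finite zone at line {line}")
    df["replicate"] = df["replicate"].astype(int)

    isolates = list(dict.fromkeys(pd.concat([df["source"], df["target"]])))
    community_of: dict[str, str] = dict(community_map or {})
    if communities_from_prefix:
        for label in isolates:
            community_of.setdefault(label, label.split(".")[0])

    table = AssayTable(measurements=df, isolates=isolates, community_of=community_of)

    rep_counts = df.groupby(["source", "target"])["replicate"].nunique()
    if rep_counts.nunique() > 1:
        full = rep_counts.max()
        deficient = rep_counts[rep_counts < full]
        warnings.warn(
            "unequal replication; deficient pairs: "
            + ", ".join(f"{s}->{t} ({c}/{full})" for (s, t), c in deficient.items()),
            stacklevel=2,
        )
    absent = table.missing_pairs()
    if absent:
        warnings.warn(
            f"{len(absent)} ordered pair(s) have no measurements: {absent[:10]}",
            stacklevel=2,
        )
    return table


def binarize(
    assay: AssayTable, threshold: float = DEFAULT_THRESHOLD_MM
) -> dict[str, InhibitionMatrix]:
    """Binarize mean zones into one matrix per community.

    Per ordered pair, the two perpendicular measurements are averaged within
    each replicate and replicate means are averaged; a directed edge is
    written iff that grand mean is strictly greater than ``threshold`` mm.
    Only within-community (sympatric) pairs are considered; self-pairs are
    always excluded.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    unassigned = [x for x in assay.isolates if x not in assay.community_of]
    if unassigned:
        raise ZoneTableError(f"isolates without community assignment: {unassigned}")

    means = assay.pair_means()
    lookup = {
        (row.source, row.target): row.mean_zone_mm for row in means.itertuples()
    }
    out: dict[str, InhibitionMatrix] = {}
    for community in dict.fromkeys(assay.community_of[x] for x in assay.isolates):
        members = [x for x in assay.isolates if assay.community_of[x] == community]
        n = len(members)
        cells = np.zeros((n, n), dtype=np.int8)
        for i, s in enumerate(members):
            for j, t in enumerate(members):
                if i != j and lookup.get((s, t), 0.0) > threshold:
                    cells[i, j] = 1
        out[community] = InhibitionMatrix(
            labels=tuple(members), cells=cells, community_id=community
        )
    return out


def read_matrix(
    path: str | Path, community_id: str = "", delimiter: str | None = None
) -> InhibitionMatrix:
    """Read a square labeled 0/1 matrix (CSV/TSV, labels in header and first column)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), index_col=0)
    if df.shape[0] != df.shape[1]:
        raise MatrixFormatError(f"{path}: matrix is {df.shape}, not square")
    if list(map(str, df.index)) != list(map(str, df.columns)):
        raise MatrixFormatError(f"{path}: row labels differ from column labels")
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise MatrixFormatError(f"{path}: non-binary cells present")
    return InhibitionMatrix(
        labels=tuple(map(str, df.index)),
        cells=values.astype(np.int8),
        community_id=community_id or path.stem,
    )


def read_matrices_xlsx(path: str | Path) -> dict[str, InhibitionMatrix]:
    """Read a spreadsheet of interaction matrices, one sheet per community."""
    sheets = pd.read_excel(path, sheet_name=None, index_col=0)
    out = {}
    for name, df in sheets.items():
        if df.shape[0] != df.shape[1]:
            raise MatrixFormatError(f"{path}[{name}]: matrix is {df.shape}, not square")
        values = df.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise MatrixFormatError(f"{path}[{name}]: non-binary cells present")
        out[name] = InhibitionMatrix(
            labels=tuple(map(str, df.index)),
            cells=values.astype(np.int8),
            community_id=str(name),
        )
    return out


def write_matrix(matrix: InhibitionMatrix, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(matrix.cells, index=matrix.labels, columns=matrix.labels)
    df.to_csv(path, sep=_sep_for(path, delimiter))


def write_edge_list(matrix: InhibitionMatrix, path: str | Path) -> None:
    """Export directed edges as a two-column TSV (source<TAB>target)."""
    rows, cols = np.nonzero(matrix.cells)
    with open(path, "w") as fh:
        for i, j in zip(rows, cols):
            fh.write(f"{matrix.labels[i]}\t{matrix.labels[j]}\n")


def write_zone_table(table: AssayTable, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    table.measurements.to_csv(path, sep=_sep_for(path, delimiter), index=False)
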