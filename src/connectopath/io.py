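"""Reading, validation and writing of connectivity matrices, cohort metadata
and statistical result tables.

Connectivity matrices are square ROI-by-ROI tables of non-negative tract
counts, stored as plain CSV/TSV, optionally with a header row and an index
column of ROI labels.  Metadata tables are delimited files with one row per
subject.  All readers validate their input and raise subclasses of
:class:`ValidationError` with messages that name the offending row/column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("connectopath")

#: Ordered study groups: unexposed controls < trauma-exposed without PTSD < PTSD.
GROUPS: tuple[str, ...] = ("control", "exposed_noptsd", "ptsd")

#: Symptom-domain columns expected in metadata tables.
SYMPTOM_COLUMNS: tuple[str, ...] = (
    "re_experiencing",
    "avoidance",
    "hyperarousal",
    "negative_affect",
    "overall",
)

REQUIRED_METADATA_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "group",
    "mdd",
    "age",
    "sex",
    "education",
    "body_mass",
    "pcl_total",
) + SYMPTOM_COLUMNS


class ValidationError(ValueError):
    """Base class for all input-validation failures."""


class NonSquareError(ValidationError):
    pass


class NegativeEntryError(ValidationError):
    pass


class AsymmetryError(ValidationError):
    pass


class TooSmallError(ValidationError):
    pass


class MetadataError(ValidationError):
    pass


def _default_labels(n: int) -> list[str]:
    return [f"ROI_{i + 1:03d}" for i in range(n)]


@dataclass
class ConnectivityMatrix:
    """Symmetric non-negative tract-count adjacency with node labels.

    Parameters
    ----------
    nodes
        Ordered ROI label strings, one per row/column.
    weights
        ``(n, n)`` array of tract counts.  Fractional values are accepted;
        deterministic tractography typically yields integers.
    """

    nodes: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        validate_weights(self.weights, nodes=self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @classmethod
    def from_array(
        cls,
        weights: np.ndarray,
        nodes: Sequence[str] | None = None,
        tolerance: float = 1e-6,
    ) -> "ConnectivityMatrix":
        """Build a validated matrix, symmetrizing/zeroing within tolerance."""
        w = np.asarray(weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NonSquareError(f"matrix is not square: shape {w.shape}")
        w = _clean_weights(w, tolerance=tolerance)
        labels = list(nodes) if nodes is not None else _default_labels(w.shape[0])
        if len(labels) != w.shape[0]:
            raise ValidationError(
                f"{len(labels)} labels for a {w.shape[0]}-node matrix"
            )
        return cls(labels, w)

    def permuted(self, order: Sequence[int]) -> "ConnectivityMatrix":
        """Jointly permute rows and columns (relabels nodes accordingly)."""
        order = list(order)
        return ConnectivityMatrix(
            [self.nodes[i] for i in order], self.weights[np.ix_(order, order)]
        )


def validate_weights(w: np.ndarray, nodes: Sequence[str] | None = None) -> None:
    """Check ConnectivityMatrix invariants; raise a named error on violation."""
    labels = list(nodes) if nodes is not None else _default_labels(w.shape[0])
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise NonSquareError(f"matrix is not square: shape {w.shape}")
    if w.shape[0] < 2:
        raise TooSmallError("matrix must have at least 2 nodes")
    if not np.all(np.isfinite(w)):
        i, j = np.argwhere(~np.isfinite(w))[0]
        raise ValidationError(f"non-finite entry at ({labels[i]}, {labels[j]})")
    if np.any(w < 0):
        i, j = np.argwhere(w < 0)[0]
        raise NegativeEntryError(
            f"negative entry {w[i, j]} at ({labels[i]}, {labels[j]})"
        )
    if np.any(np.diag(w) != 0):
        i = int(np.argwhere(np.diag(w) != 0)[0][0])
        raise ValidationError(f"nonzero diagonal at node {labels[i]}")
    if not np.array_equal(w, w.T):
        i, j = np.argwhere(w != w.T)[0]
        raise AsymmetryError(
            f"asymmetric entries at ({labels[i]}, {labels[j]}): "
            f"{w[i, j]} vs {w[j, i]}"
        )


def _clean_weights(w: np.ndarray, tolerance: float) -> np.ndarray:
    """Symmetrize within tolerance and zero the diagonal, logging repairs."""
    if w.shape[0] < 2:
        raise TooSmallError("matrix must have at least 2 nodes")
    if np.any(w < 0):
        i, j = np.argwhere(w < 0)[0]
        raise NegativeEntryError(f"negative entry {w[i, j]} at row {i}, column {j}")
    scale = float(np.max(w)) if w.size else 0.0
    gap = float(np.max(np.abs(w - w.T))) if w.size else 0.0
    if gap > 0:
        if scale > 0 and gap > tolerance * scale:
            i, j = np.argwhere(np.abs(w - w.T) == np.abs(w - w.T).max())[0]
            raise AsymmetryError(
                f"asymmetry {gap:g} at row {i}, column {j} exceeds "
                f"tolerance {tolerance:g} * max weight {scale:g}"
            )
        logger.warning(
            "symmetrizing matrix by arithmetic mean (max asymmetry %g)", gap
        )
        w = (w + w.T) / 2.0
    if np.any(np.diag(w) != 0):
        logger.warning("zeroing nonzero diagonal entries (self-tracts ignored)")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
    return w


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        first_line = fh.readline()
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return r"\s+"


def read_matrix(path: str | Path, tolerance: float = 1e-6) -> ConnectivityMatrix:
    """Read a square connectivity matrix from a CSV/TSV file.

    A header row / label column is detected by the first cell being empty or
    non-numeric.  Asymmetries within ``tolerance * max(weight)`` are repaired
    by the arithmetic mean; a nonzero diagonal is zeroed (both logged).
    """
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, header=None, engine="python")
    first = raw.iloc[0, 0]
    labelled = pd.isna(first) or (
        isinstance(first, str) and not _is_number(first)
    )
    if labelled:
        df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
        nodes = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    else:
        nodes = None
        try:
            values = raw.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric entry in {path}: {exc}") from exc
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise NonSquareError(
            f"{path}: table is not square (shape {values.shape})"
        )
    return ConnectivityMatrix.from_array(values, nodes=nodes, tolerance=tolerance)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_matrix(conn: ConnectivityMatrix, path: str | Path) -> None:
    """Write a connectivity matrix as labelled CSV (round-trips via read_matrix)."""
    df = pd.DataFrame(conn.weights, index=conn.nodes, columns=conn.nodes)
    df.to_csv(path, float_format="%.12g")


@dataclass
class SubjectRecord:
    """One subject's group assignment, covariates and symptom scores."""

    subject_id: str
    group: str
    mdd: bool
    age: float
    sex: str
    education: str
    body_mass: float
    pcl_total: float
    re_experiencing: float
    avoidance: float
    hyperarousal: float
    negative_affect: float
    overall: float
    dementia: bool = False
    cortical_complexity: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise MetadataError(
                f"subject {self.subject_id}: unknown group {self.group!r} "
                f"(expected one of {GROUPS})"
            )
        for col in SYMPTOM_COLUMNS + ("pcl_total",):
            v = getattr(self, col)
            if v < 0:
                raise MetadataError(
                    f"subject {self.subject_id}: negative symptom score {col}={v}"
                )


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tabulate records with `group` as an ordered categorical."""
    df = pd.DataFrame([vars(r) for r in records])
    df["group"] = pd.Categorical(df["group"], categories=GROUPS, ordered=True)
    return df


def read_metadata(
    path: str | Path, group_aliases: Mapping[str, str] | None = None
) -> list[SubjectRecord]:
    """Read a subject metadata table into typed records.

    ``group_aliases`` maps external labels (e.g. ``"PTSD+"``) onto the
    canonical ordered groups.  Missing required columns, duplicate subject
    ids, unknown group labels and unparseable numerics all raise
    :class:`MetadataError`.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"{path}: missing required columns {missing}")
    ids = df["subject_id"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise MetadataError(f"{path}: duplicate subject_id {dup.iloc[0]!r}")
    aliases = dict(group_aliases or {})
    records: list[SubjectRecord] = []
    known = {f.name for f in dc_fields(SubjectRecord)}
    for _, row in df.iterrows():
        group = str(row["group"])
        group = aliases.get(group, group)
        numeric = {}
        for col in ("age", "body_mass", "pcl_total") + SYMPTOM_COLUMNS:
            try:
                numeric[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise MetadataError(
                    f"{path}: subject {row['subject_id']}: unparseable "
                    f"numeric in column {col!r}: {row[col]!r}"
                ) from exc
        cc = row.get("cortical_complexity", np.nan)
        extra = {}
        if "dementia" in df.columns:
            extra["dementia"] = _parse_bool(row["dementia"])
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=group,
                mdd=_parse_bool(row["mdd"]),
                sex=str(row["sex"]),
                education=str(row["education"]),
                cortical_complexity=None if pd.isna(cc) else float(cc),
                **numeric,
                **extra,
            )
        )
    return records


def _parse_bool(v: object) -> bool:
    if isinstance(v, str):
        s = v.strip().lower()
        if s in {"true", "t", "yes", "1"}:
            return True
        if s in {"false", "f", "no", "0"}:
            return False
        raise MetadataError(f"unparseable boolean {v!r}")
    return bool(v)


def write_metadata(records: Sequence[SubjectRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.12g")


@dataclass
class CohortTable:
    """Subject records plus their connectivity matrices."""

    records: list[SubjectRecord]
    matrices: dict[str, ConnectivityMatrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise MetadataError("duplicate subject ids in cohort")
        if self.matrices:
            missing = [i for i in ids if i not in self.matrices]
            if missing:
                raise MetadataError(f"subjects without a matrix: {missing[:5]}")
            node_sets = {tuple(m.nodes) for m in self.matrices.values()}
            if len(node_sets) > 1:
                raise ValidationError("matrices do not share a common node set")

    @property
    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, subject_ids: Sequence[str]) -> "CohortTable":
        keep = set(subject_ids)
        recs = [r for r in self.records if r.subject_id in keep]
        mats = {r.subject_id: self.matrices[r.subject_id] for r in recs}
        return CohortTable(recs, mats)


RESULT_COLUMNS = (
    "method",
    "contrast",
    "estimate",
    "effect_size",
    "statistic",
    "df",
    "p",
    "p_adjusted",
    "n",
)


def results_to_frame(results: Sequence) -> pd.DataFrame:
    """Tabulate StatResult-like objects into the standard result schema."""
    if not results:
        raise ValidationError("no results to tabulate")
    rows = []
    for r in results:
        d = vars(r).copy() if not isinstance(r, dict) else dict(r)
        rows.append({c: d.get(c) for c in RESULT_COLUMNS})
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results(results: Sequence, path: str | Path) -> pd.DataFrame:
    """Write a results table as CSV; values round-trip to 12 significant digits."""
    df = results_to_frame(results)
    df.to_csv(path, index=False, float_format="%.12g")
    return df


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
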