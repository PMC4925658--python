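"""Reading, validating and assembling regional morphometry tables.

Input dialect: one UTF-8 tab-separated table per (hemisphere, measure) in the
layout of standard surface-stats exporters — header row, first column
``subject``, remaining columns region names; values in each measure's native
units (mm^2, mm^3, mm, mm, mm^-1).  The ``Area`` table may additionally carry
a ``WhiteSurfArea`` column and the ``Thickness`` table a ``MeanThickness``
column; these become the per-hemisphere global features.  Subject metadata
live in one TSV with columns id, group, sex, age_months, nviq.

Parsing is strict by default: the analysis is invalid with silently missing
features, so unknown columns and missing cells abort unless ``lenient`` is
requested (which warns and drops unknown columns instead).  Units are trusted
as-is; no conversion is performed.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dkt import (
    DKT_REGIONS,
    GLOBAL_ENTRIES,
    HEMISPHERES,
    MEASURES,
    FeatureIndex,
    feature_name,
)

#: NVIQ threshold below which a control is labelled developmentally delayed.
DD_NVIQ_THRESHOLD = 70.0

GROUP_LABELS = {"case": 1, "control": -1}


class MorphometryIOError(ValueError):
    """Malformed or incomplete morphometry input."""


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MorphometryIOError(f"file not found: {path}")
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise MorphometryIOError(f"empty file: {path}") from exc
    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise MorphometryIOError(f"no data rows in {path}")
    return frame


def read_measure_table(
    path: str | Path,
    hemisphere: str,
    measure: str,
    regions: tuple[str, ...] = DKT_REGIONS,
    lenient: bool = False,
) -> pd.DataFrame:
    """Read one (hemisphere, measure) stats table.

    Returns a DataFrame indexed by subject id whose columns are region names
    (plus the global pseudo-region of this measure, if present in the file).
    """
    if hemisphere not in HEMISPHERES:
        raise MorphometryIOError(f"unknown hemisphere {hemisphere!r}")
    if measure not in MEASURES:
        raise MorphometryIOError(f"unknown measure {measure!r}")
    frame = _read_tsv(path)
    header = list(frame.columns)
    if header[0] != "subject":
        raise MorphometryIOError(
            f"{path}: first column must be 'subject', found {header[0]!r}"
        )
    allowed = set(regions)
    allowed.update(g for g, m in GLOBAL_ENTRIES if m == measure)
    unknown = [c for c in header[1:] if c not in allowed]
    if unknown:
        if lenient:
            warnings.warn(
                f"{path}: ignoring unknown column(s) {unknown}", stacklevel=2
            )
            frame = frame.drop(columns=unknown)
        else:
            raise MorphometryIOError(f"{path}: unknown region column(s) {unknown}")
    frame = frame.set_index("subject")
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise MorphometryIOError(f"{path}: duplicate subject id(s) {dupes}")
    values = pd.DataFrame(index=frame.index)
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise MorphometryIOError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                f"{frame.loc[row, col]!r}"
            )
        if converted.isna().any():
            row = converted.index[converted.isna()][0]
            raise MorphometryIOError(f"{path}: missing value at row {row!r}, column {col!r}")
        # exact parse: numpy's float conversion round-trips %.17g text
        values[col] = frame[col].astype(float)
    return values


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the subject metadata table.

    Returns a DataFrame indexed by subject id with columns group, y (+1 case /
    -1 control), sex, age_months, nviq and the derived dd flag (nviq < 70).
    """
    frame = _read_tsv(path)
    required = ["id", "group", "sex", "age_months", "nviq"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise MorphometryIOError(f"{path}: missing metadata column(s) {missing}")
    if frame["id"].duplicated().any():
        dupes = frame.loc[frame["id"].duplicated(), "id"].tolist()
        raise MorphometryIOError(f"{path}: duplicate subject id(s) {dupes}")
    bad_groups = sorted(set(frame["group"]) - set(GROUP_LABELS))
    if bad_groups:
        raise MorphometryIOError(
            f"{path}: unknown group label(s) {bad_groups}; expected 'case' or 'control'"
        )
    bad_sex = sorted(set(frame["sex"]) - {"M", "F"})
    if bad_sex:
        raise MorphometryIOError(f"{path}: unknown sex label(s) {bad_sex}")
    table = frame.set_index("id")
    for col in ("age_months", "nviq"):
        table[col] = pd.to_numeric(table[col], errors="coerce")
        if table[col].isna().any() or not np.isfinite(table[col]).all():
            raise MorphometryIOError(f"{path}: non-numeric or missing {col}")
        if (table[col] <= 0).any():
            raise MorphometryIOError(f"{path}: {col} must be positive")
    table["y"] = table["group"].map(GROUP_LABELS)
    table["dd"] = table["nviq"] < DD_NVIQ_THRESHOLD
    return table[["group", "y", "sex", "age_months", "nviq", "dd"]]


def assemble_feature_matrix(
    partials: Mapping[tuple[str, str], pd.DataFrame],
    subjects: pd.DataFrame,
    index: FeatureIndex | None = None,
) -> pd.DataFrame:
    """Assemble per-(hemisphere, measure) tables into the canonical matrix.

    ``partials`` maps (hemisphere, measure) to the frame returned by
    :func:`read_measure_table`.  Fails loudly if any (subject, feature) cell
    is absent.
    """
    if index is None:
        regions = sorted(
            {
                c
                for frame in partials.values()
                for c in frame.columns
                if c not in {g for g, _ in GLOBAL_ENTRIES}
            }
        )
        measures = sorted({m for _, m in partials}, key=MEASURES.index)
        has_global = any(
            g in frame.columns for frame in partials.values() for g, _ in GLOBAL_ENTRIES
        )
        index = FeatureIndex.build(regions=regions, measures=measures, include_global=has_global)
    subject_ids = list(subjects.index)
    matrix = pd.DataFrame(index=pd.Index(subject_ids, name="subject"), columns=index.names, dtype=float)
    for hemi, region, measure in index:
        key = (hemi, measure)
        if key not in partials:
            raise MorphometryIOError(f"no table provided for hemisphere {hemi!r}, measure {measure!r}")
        frame = partials[key]
        if region not in frame.columns:
            raise MorphometryIOError(
                f"feature {feature_name(hemi, region, measure)} absent from the "
                f"({hemi}, {measure}) table"
            )
        missing = [s for s in subject_ids if s not in frame.index]
        if missing:
            raise MorphometryIOError(
                f"subject(s) {missing} missing from the ({hemi}, {measure}) table"
            )
        matrix[feature_name(hemi, region, measure)] = frame.loc[subject_ids, region].to_numpy()
    if matrix.isna().any().any():
        raise MorphometryIOError("assembled matrix contains missing cells")
    matrix.attrs["feature_index"] = index
    return matrix


def split_feature_matrix(matrix: pd.DataFrame, index: FeatureIndex) -> dict[tuple[str, str], pd.DataFrame]:
    """Inverse of :func:`assemble_feature_matrix` (assemble o split = identity)."""
    partials: dict[tuple[str, str], pd.DataFrame] = {}
    for hemi, region, measure in index:
        key = (hemi, measure)
        frame = partials.setdefault(key, pd.DataFrame(index=matrix.index))
        frame[region] = matrix[feature_name(hemi, region, measure)].to_numpy()
    return partials


def measure_table_path(directory: str | Path, hemisphere: str, measure: str) -> Path:
    return Path(directory) / f"{hemisphere}.{measure}.tsv"


def subject_table_path(directory: str | Path) -> Path:
    return Path(directory) / "subjects.tsv"


def write_measure_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = frame.copy()
    out.insert(0, "subject", frame.index)
    # %.17g guarantees bit-exact float round-trip through the text table
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def write_subject_table(subjects: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = subjects.reset_index()
    cols = [c for c in ("id", "group", "sex", "age_months", "nviq") if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_cohort(
    directory: str | Path,
    index: FeatureIndex | None = None,
    lenient: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort directory (per-measure TSVs + subjects.tsv).

    Returns (feature matrix, subject table).
    """
    directory = Path(directory)
    subjects = read_subject_table(subject_table_path(directory))
    if index is None:
        index = FeatureIndex.default()
    measures = sorted({m for _, _, m in index}, key=MEASURES.index)
    regions = tuple(sorted({r for _, r, _ in index if r not in {g for g, _ in GLOBAL_ENTRIES}}))
    partials = {
        (hemi, measure): read_measure_table(
            measure_table_path(directory, hemi, measure), hemi, measure, regions=regions, lenient=lenient
        )
        for hemi in HEMISPHERES
        for measure in measures
    }
    matrix = assemble_feature_matrix(partials, subjects, index=index)
    return matrix, subjects
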