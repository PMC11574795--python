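"""On-disk artifacts of a cohort: manifest, time series, phenotypes, FC matrices.

A cohort lives in a directory holding a manifest CSV (``subject_id,state,file``),
a phenotype CSV (one row per subject) and one plain-text table per scan.  Time
series are written as TSV with timepoints as rows and one column per region of
interest (ROI); connectivity matrices as square TSV with an ROI-label header.
Missing behavioral values stay missing (NaN) and are excluded pairwise by the
downstream statistics — they are never silently imputed as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateEntryError,
    FormatError,
    ParseError,
    ShapeError,
)

#: Valid scan states.  Each subject has one resting scan and one or two task runs.
STATES = ("rest", "task_run1", "task_run2")
TASK_STATES = ("task_run1", "task_run2")

GROUPS = ("ASD", "TD")
SUBGROUPS = ("TP-ASD", "LP-ASD", "TDs", "excluded", "unassigned")

#: Columns a phenotype table must provide; the remaining columns are optional.
REQUIRED_PHENOTYPE_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "rmsd_rest",
    "rmsd_task",
    "acc_sw",
    "acc_aw",
)

OPTIONAL_PHENOTYPE_COLUMNS = ("acc_pw", "rt_sw", "rt_aw", "brief_gec", "celf_wc")

_FLOAT_FMT = "%.10g"


def default_roi_labels(n_rois: int) -> list[str]:
    """Placeholder ROI names used when a table carries no header."""
    return [f"ROI{i + 1:02d}" for i in range(n_rois)]


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass
class SubjectRecord:
    """Phenotype row for one participant.

    Accuracies are proportions correct in [0, 1] for single words (sw),
    abstract words (aw) and pseudo-words (pw, a response-inhibition
    condition without reaction times).  ``rmsd_*`` is in-scanner head motion
    (root-mean-square displacement, mm) per state.  ``brief_gec`` is an
    executive-function composite T-score; ``celf_wc`` a language subtest
    scaled score.  ``subgroup`` stays "unassigned" until subgrouping runs.
    """

    subject_id: str
    group: str
    age: float
    rmsd_rest: float
    rmsd_task: float
    acc_sw: float
    acc_aw: float
    acc_pw: float = math.nan
    rt_sw: float = math.nan
    rt_aw: float = math.nan
    brief_gec: float = math.nan
    celf_wc: float = math.nan
    subgroup: str = "unassigned"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"unknown subgroup {self.subgroup!r}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        for name in ("rmsd_rest", "rmsd_task"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        for name in ("acc_sw", "acc_aw", "acc_pw"):
            v = getattr(self, name)
            if not math.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class TimeSeriesSet:
    """ROI-averaged BOLD time series for one subject in one scan state."""

    subject_id: str
    state: str
    data: np.ndarray  # T x R
    tr: float  # repetition time, seconds
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ShapeError("time series must be a 2-D (timepoints x ROIs) table")
        t, r = self.data.shape
        if t < 10 or r < 2:
            raise ShapeError(f"need at least 10 timepoints and 2 ROIs, got {t}x{r}")
        if not np.all(np.isfinite(self.data)):
            raise ParseError("time series contains non-finite values")
        if not self.roi_labels:
            self.roi_labels = default_roi_labels(r)
        elif len(self.roi_labels) != r:
            raise ShapeError("roi_labels length does not match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class CohortManifest:
    """Index of all scan files of a cohort, with resolved absolute paths."""

    entries: pd.DataFrame  # columns subject_id, state, file
    root: Path
    phenotype_path: Path | None = None

    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.entries["subject_id"]))

    def files_for(self, subject_id: str) -> dict[str, Path]:
        sub = self.entries[self.entries["subject_id"] == subject_id]
        return {row.state: Path(row.file) for row in sub.itertuples()}


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path, check_files: bool = True) -> CohortManifest:
    """Read and validate a cohort manifest CSV.

    Completeness is enforced here, before any statistics can run: every
    subject must have exactly one rest entry and one or two task runs, state
    labels must be known, (subject, state) pairs unique, and every referenced
    file must exist (relative paths are resolved against the manifest's
    directory).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = {"subject_id", "state", "file"} - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} is missing columns: {sorted(missing)}")
    bad_states = sorted(set(df["state"]) - set(STATES))
    if bad_states:
        raise ValueError(
            f"manifest {path} has unknown state labels {bad_states}; "
            f"expected one of {STATES}"
        )
    dup = df.duplicated(subset=["subject_id", "state"])
    if dup.any():
        pairs = df.loc[dup, ["subject_id", "state"]].to_records(index=False).tolist()
        raise DuplicateEntryError(f"duplicate (subject, state) entries: {pairs}")

    root = path.parent.resolve()
    resolved = [
        str(p if (p := Path(f)).is_absolute() else root / f) for f in df["file"]
    ]
    df = df.assign(file=resolved)

    for sid, sub in df.groupby("subject_id", sort=False):
        n_rest = int((sub["state"] == "rest").sum())
        n_task = int(sub["state"].isin(TASK_STATES).sum())
        if n_rest != 1:
            raise FormatError(f"subject {sid} has {n_rest} rest entries; need exactly 1")
        if n_task not in (1, 2):
            raise FormatError(f"subject {sid} has {n_task} task entries; need 1 or 2")
    if check_files:
        for f in df["file"]:
            if not Path(f).exists():
                raise FileNotFoundError(f"manifest references missing file: {f}")
    return CohortManifest(entries=df.reset_index(drop=True), root=root)


def write_manifest(
    manifest: CohortManifest | pd.DataFrame, path: str | Path
) -> Path:
    """Write a manifest CSV; file paths are stored relative to the CSV when possible."""
    path = Path(path)
    df = manifest.entries if isinstance(manifest, CohortManifest) else manifest
    out = df.copy()
    rel = []
    base = path.parent.resolve()
    for f in out["file"]:
        p = Path(f)
        if not p.is_absolute():
            p = p.resolve()
        try:
            rel.append(str(p.relative_to(base)))
        except ValueError:
            rel.append(str(p))
    out["file"] = rel
    out.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# time-series tables
# ---------------------------------------------------------------------------


def _looks_like_header(tokens: list[str]) -> bool:
    for tok in tokens:
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_timeseries(
    path: str | Path, expected_R: int | None = None
) -> tuple[np.ndarray, list[str]]:
    """Read a T x R plain-text numeric table (TSV; optional ROI-label header).

    Returns ``(data, roi_labels)``.  Rejects ragged rows, non-numeric cells
    and non-finite values; if ``expected_R`` is given, a column-count mismatch
    raises :class:`ShapeError`.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path} is empty")
    first = lines[0].split("\t")
    if _looks_like_header(first):
        labels = [t.strip() for t in first]
        body = lines[1:]
    else:
        labels = []
        body = lines
    rows = []
    width = len(labels) or len(first)
    for i, ln in enumerate(body):
        toks = ln.split("\t")
        if len(toks) != width:
            raise ShapeError(
                f"{path}: row {i + 1} has {len(toks)} columns, expected {width}"
            )
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric cell in row {i + 1}: {exc}") from exc
    data = np.asarray(rows, dtype=float)
    if data.size == 0:
        raise ParseError(f"{path} has a header but no data rows")
    if not np.all(np.isfinite(data)):
        raise ParseError(f"{path} contains non-finite values")
    if expected_R is not None and data.shape[1] != expected_R:
        raise ShapeError(
            f"{path} has {data.shape[1]} columns, expected {expected_R} ROIs"
        )
    if not labels:
        labels = default_roi_labels(data.shape[1])
    return data, labels


def write_timeseries(
    data: np.ndarray, path: str | Path, roi_labels: list[str] | None = None
) -> Path:
    path = Path(path)
    data = np.asarray(data, dtype=float)
    labels = roi_labels or default_roi_labels(data.shape[1])
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        for row in data:
            fh.write("\t".join(_FLOAT_FMT % v for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# FC matrices (square TSV, diagonal written as nan)
# ---------------------------------------------------------------------------


def write_fc_matrix(values: np.ndarray, path: str | Path, roi_labels=None) -> Path:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ShapeError("FC matrix must be square")
    labels = roi_labels or default_roi_labels(values.shape[0])
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        for row in values:
            fh.write("\t".join(_FLOAT_FMT % v for v in row) + "\n")
    return Path(path)


def read_fc_matrix(
    path: str | Path, expected_R: int | None = None
) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    labels = [t.strip() for t in lines[0].split("\t")]
    rows = []
    for ln in lines[1:]:
        rows.append([float(t) for t in ln.split("\t")])
    values = np.asarray(rows, dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ShapeError(f"{path}: matrix is not square ({values.shape})")
    if expected_R is not None and values.shape[0] != expected_R:
        raise ShapeError(f"{path}: expected {expected_R} ROIs, got {values.shape[0]}")
    off = ~np.eye(values.shape[0], dtype=bool)
    if not np.all(np.isfinite(values[off])):
        raise ParseError(f"{path}: non-finite off-diagonal entries")
    return values, labels


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> list[SubjectRecord]:
    """Parse a phenotype CSV into validated :class:`SubjectRecord` objects.

    Empty cells become NaN ("missing"), never zeros.  Out-of-range values
    (e.g. an accuracy of 1.2) raise ``ValueError`` via record validation.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(REQUIRED_PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"phenotype table {path} is missing columns: {sorted(missing)}")
    records = []
    numeric = [
        f.name
        for f in fields(SubjectRecord)
        if f.name not in ("subject_id", "group", "subgroup")
    ]
    for _, row in df.iterrows():
        kwargs = {"subject_id": str(row["subject_id"]), "group": str(row["group"])}
        for name in numeric:
            if name in df.columns and pd.notna(row[name]):
                kwargs[name] = float(row[name])
            elif name in REQUIRED_PHENOTYPE_COLUMNS:
                if name not in df.columns or pd.isna(row[name]):
                    raise FormatError(
                        f"subject {kwargs['subject_id']}: required field {name} is empty"
                    )
            else:
                kwargs[name] = math.nan
        records.append(SubjectRecord(**kwargs))
    return records


def write_phenotypes(records: list[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    cols = [f.name for f in fields(SubjectRecord) if f.name != "subgroup"]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Phenotypes as a DataFrame indexed by subject_id (includes subgroup)."""
    cols = [f.name for f in fields(SubjectRecord)]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])
    return df.set_index("subject_id", drop=False)


# ---------------------------------------------------------------------------
# optional volumetric ingestion
# ---------------------------------------------------------------------------


def extract_roi_timeseries(image_path: str | Path, mask_path: str | Path):
    """Mean time series per integer mask label from a 4-D NIfTI image.

    Optional convenience for users whose data are still volumetric; the
    tested pipeline path starts from plain-text ROI tables.  Requires
    ``nibabel``.
    """
    import nibabel as nib  # deferred: not needed on the standard path

    img = nib.load(str(image_path))
    mask = nib.load(str(mask_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    lab = np.asanyarray(mask.dataobj).astype(int)
    if data.ndim != 4:
        raise ShapeError("expected a 4-D functional image")
    if lab.shape != data.shape[:3]:
        raise ShapeError("label mask shape does not match image grid")
    labels = sorted(int(v) for v in np.unique(lab) if v > 0)
    if not labels:
        raise ValueError("label mask contains no positive labels")
    out = np.column_stack([data[lab == v, :].mean(axis=0) for v in labels])
    return out, [f"ROI{v:02d}" for v in labels]
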