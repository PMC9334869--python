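"""Reading and writing of cohort data, ROI name lists and result reports.

The on-disk conventions are deliberately plain: a phenotype manifest is a CSV
with header ``subject_id,label,file``; each referenced file holds one subject's
ROI-averaged BOLD matrix as a delimited text table, timepoints in rows and ROIs
in columns (the common ``T x R`` export orientation, e.g. 170 x 116 for an AAL
parcellation of a standard resting-state run). Reports are written as a CSV
plus a JSON sidecar carrying the full configuration and per-fold values so a
run can be reconstructed exactly.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("sagcn")

DEFAULT_LABEL_MAP = {"ASD": 1, "NC": 0}


@dataclass
class SubjectRecord:
    """One subject's ROI time-series matrix with diagnostic label."""

    subject_id: str
    label: int  # 1 = positive (patient), 0 = negative (control)
    series: np.ndarray  # shape (T, R)
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError(f"subject {self.subject_id}: series must be 2-D")
        t, r = self.series.shape
        if t < 2 or r < 2:
            raise ValueError(
                f"subject {self.subject_id}: need T >= 2 and R >= 2, got {t}x{r}"
            )
        if np.isnan(self.series).any():
            i, j = np.argwhere(np.isnan(self.series))[0]
            raise ValueError(
                f"subject {self.subject_id}: missing value at row {i}, column {j}"
            )
        if self.roi_names is not None and len(self.roi_names) != r:
            raise ValueError(
                f"subject {self.subject_id}: {len(self.roi_names)} ROI names for {r} ROIs"
            )

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[0]

    @property
    def n_rois(self) -> int:
        return self.series.shape[1]


@dataclass
class CohortManifest:
    entries: list[tuple[str, int, str]]

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids in manifest: {dupes}")

    @property
    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for _, lab, _ in self.entries:
            counts[lab] = counts.get(lab, 0) + 1
        return counts


@dataclass
class RunConfig:
    """Pipeline hyperparameters: windowing, graph thresholding, CV and seeding."""

    window_length: int = 130
    stride: int = 5
    threshold: float = 0.6
    binary_edges: bool = False
    folds: int = 5
    repeats: int = 10
    seed: int = 0
    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    transpose_input: bool = False  # set when files are stored ROIs-in-rows

    def validate(self, n_timepoints: int | None = None) -> None:
        if self.stride < 1 or self.window_length < self.stride:
            raise ValueError("need 1 <= stride <= window_length")
        if n_timepoints is not None and self.window_length > n_timepoints:
            raise ValueError(
                f"window_length {self.window_length} exceeds series length {n_timepoints}"
            )
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0, 1]")


def _read_matrix(path: Path) -> np.ndarray:
    """Load a delimited numeric matrix, sniffing comma/tab/whitespace."""
    text = path.read_text()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if "," in first:
        delim: str | None = ","
    elif "\t" in first:
        delim = "\t"
    else:
        delim = None  # any whitespace
    try:
        mat = np.loadtxt(path.open(), delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if np.isnan(mat).any():
        i, j = np.argwhere(np.isnan(mat))[0]
        raise ValueError(f"{path}: missing/NaN value at row {i}, column {j}")
    return mat


def read_manifest(manifest_path: str | Path, label_map: dict[str, int] | None = None) -> CohortManifest:
    label_map = label_map or DEFAULT_LABEL_MAP
    entries: list[tuple[str, int, str]] = []
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"subject_id", "label", "file"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"manifest must have header columns {sorted(required)}, got {reader.fieldnames}"
            )
        for row in reader:
            raw = row["label"].strip()
            if raw in label_map:
                lab = label_map[raw]
            elif raw in {"0", "1"}:
                lab = int(raw)
            else:
                raise ValueError(f"unknown label {raw!r} for subject {row['subject_id']}")
            entries.append((row["subject_id"].strip(), lab, row["file"].strip()))
    return CohortManifest(entries)


def load_cohort(
    manifest_path: str | Path,
    data_dir: str | Path | None = None,
    label_map: dict[str, int] | None = None,
    transpose: bool = False,
    roi_names: list[str] | None = None,
) -> list[SubjectRecord]:
    """Load every subject listed in a phenotype manifest.

    All subjects must share the same ROI count; label strings are mapped to
    binary classes via ``label_map`` (default ASD=1, NC=0).
    """
    manifest_path = Path(manifest_path)
    base = Path(data_dir) if data_dir is not None else manifest_path.parent
    manifest = read_manifest(manifest_path, label_map)
    records: list[SubjectRecord] = []
    for sid, lab, rel in manifest.entries:
        fpath = Path(rel) if Path(rel).is_absolute() else base / rel
        if not fpath.exists():
            raise FileNotFoundError(f"subject {sid}: time-series file {fpath} not found")
        try:
            mat = _read_matrix(fpath)
        except ValueError as exc:
            raise ValueError(f"subject {sid}: {exc}") from exc
        if transpose:
            mat = mat.T
        records.append(SubjectRecord(sid, lab, mat, roi_names))
    r_counts = {rec.n_rois for rec in records}
    if len(r_counts) > 1:
        raise ValueError(f"inconsistent ROI counts across subjects: {sorted(r_counts)}")
    return records


def load_roi_names(path: str | Path, expected_r: int) -> list[str]:
    """Read one ROI name per line; the count must match the data."""
    names = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(names) != expected_r:
        raise ValueError(f"{path}: {len(names)} ROI names, expected {expected_r}")
    if len(set(names)) != len(names):
        logger.warning("%s: duplicate ROI names present (display-only, accepted)", path)
    return names


def save_cohort(records: list[SubjectRecord], out_dir: str | Path) -> Path:
    """Write subjects as per-subject CSV matrices plus a manifest (inverse of load_cohort)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inv = {1: "ASD", 0: "NC"}
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "label", "file"])
        for rec in records:
            fname = f"{rec.subject_id}.csv"
            np.savetxt(out_dir / fname, rec.series, delimiter=",", fmt="%.10g")
            writer.writerow([rec.subject_id, inv[rec.label], fname])
    if records and records[0].roi_names:
        (out_dir / "roi_names.txt").write_text("\n".join(records[0].roi_names) + "\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_report(report, path: str | Path) -> None:
    """Write a report as CSV plus a JSON sidecar with config and per-row values.

    Accepts any object with a ``to_frame() -> DataFrame`` method and a
    ``meta`` dict (MetricsReport and ImportanceTable both qualify).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame()
    frame.to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    payload = {
        "kind": type(report).__name__,
        "meta": _jsonable(getattr(report, "meta", {})),
        "rows": _jsonable(frame.to_dict(orient="list")),
    }
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_report_frame(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Round-trip companion to save_report: full-precision rows from the sidecar."""
    sidecar = Path(path).with_suffix(".json")
    payload = json.loads(sidecar.read_text())
    return pd.DataFrame(payload["rows"]), payload["meta"]


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
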