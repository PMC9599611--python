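"""Reading and writing ROI time-series files and cohort manifests.

On-disk formats are plain delimited text:

* one file per scan, N rows (ROIs) x T columns (timepoints), no header,
  tab- or comma-delimited (auto-detected);
* one manifest per cohort with columns
  ``subject_id, scan_id, path, label, has_baseline``.

Labels are stored as strings in the manifest and mapped to contiguous
integer ids in manifest order, stably across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BoldRecording",
    "CohortManifest",
    "ManifestEntry",
    "read_recording",
    "write_recording",
    "read_manifest",
    "write_manifest",
]


class FormatError(ValueError):
    """Raised when an on-disk table violates the expected layout."""


@dataclass
class BoldRecording:
    """One scan's ROI-by-timepoint BOLD signal matrix with identifiers.

    ``signal`` has N rows (ROIs) and T columns (timepoints); ``label`` is the
    integer class id assigned by the manifest's label ordering.
    """

    subject_id: str
    scan_id: str
    signal: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise FormatError(f"scan {self.scan_id}: signal must be 2-D")
        if self.signal.shape[0] < 2:
            raise FormatError(f"scan {self.scan_id}: need at least 2 ROIs")
        if not np.all(np.isfinite(self.signal)):
            raise FormatError(f"scan {self.scan_id}: non-finite values in signal")

    @property
    def n_rois(self) -> int:
        return self.signal.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class ManifestEntry:
    subject_id: str
    scan_id: str
    path: str
    label: str
    has_baseline: bool


@dataclass
class CohortManifest:
    """Subject/scan registry; the unit of cross-validation is the subject."""

    entries: list[ManifestEntry]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.classes:
            seen: list[str] = []
            for e in self.entries:
                if e.label not in seen:
                    seen.append(e.label)
            self.classes = seen
        self.validate()

    def validate(self) -> None:
        scan_ids = [e.scan_id for e in self.entries]
        if len(scan_ids) != len(set(scan_ids)):
            dup = sorted({s for s in scan_ids if scan_ids.count(s) > 1})
            raise FormatError(f"duplicate scan_id(s): {dup}")
        known = set(self.classes)
        for e in self.entries:
            if e.label not in known:
                raise FormatError(
                    f"scan {e.scan_id}: unknown label {e.label!r} "
                    f"(classes: {self.classes})"
                )
        by_subject: dict[str, set[bool]] = {}
        for e in self.entries:
            by_subject.setdefault(e.subject_id, set()).add(e.has_baseline)
        bad = [s for s, flags in by_subject.items() if len(flags) > 1]
        if bad:
            raise FormatError(f"has_baseline not constant within subject(s): {bad}")

    @property
    def label_ids(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.classes)}

    @property
    def subjects(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.subject_id not in seen:
                seen.append(e.subject_id)
        return seen

    def subject_label(self, subject_id: str) -> str:
        for e in self.entries:
            if e.subject_id == subject_id:
                return e.label
        raise KeyError(subject_id)

    def scans_of(self, subject_ids) -> list[ManifestEntry]:
        wanted = set(subject_ids)
        return [e for e in self.entries if e.subject_id in wanted]

    def subset_by_classes(self, class_names) -> "CohortManifest":
        """Restrict to the named classes (binary tasks subset before splitting)."""
        names = list(class_names)
        missing = [c for c in names if c not in self.classes]
        if missing:
            raise KeyError(f"classes not in manifest: {missing}")
        entries = [e for e in self.entries if e.label in names]
        return CohortManifest(entries=entries, classes=names)


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_recording(path: str | Path, manifest_entry: ManifestEntry | None = None,
                   label_ids: dict[str, int] | None = None) -> BoldRecording:
    """Read one scan's N x T matrix from delimited text.

    The delimiter is sniffed from the first line. Errors name the offending
    cell; ragged rows are a format error.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    rows: list[list[float]] = []
    width = None
    for i, ln in enumerate(lines):
        cells = ln.split(delim)
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise FormatError(
                f"{path}: ragged row {i} ({len(cells)} cells, expected {width})"
            )
        parsed = []
        for j, c in enumerate(cells):
            try:
                parsed.append(float(c))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at row {i}, column {j}: {c!r}"
                ) from None
        rows.append(parsed)
    signal = np.array(rows, dtype=float)
    if manifest_entry is None:
        return BoldRecording("", path.stem, signal, 0)
    if label_ids is None:
        raise ValueError("label_ids required when manifest_entry is given")
    return BoldRecording(
        subject_id=manifest_entry.subject_id,
        scan_id=manifest_entry.scan_id,
        signal=signal,
        label=label_ids[manifest_entry.label],
    )


def write_recording(path: str | Path, signal: np.ndarray) -> None:
    """Write an N x T matrix as headerless TSV with full float precision."""
    signal = np.asarray(signal, dtype=float)
    np.savetxt(path, signal, delimiter="\t", fmt="%.17g")


_MANIFEST_COLUMNS = ["subject_id", "scan_id", "path", "label", "has_baseline"]


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest (CSV/TSV with the 5 named columns)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    delim = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=delim, dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing column(s) {missing}")
    entries = [
        ManifestEntry(
            subject_id=row.subject_id,
            scan_id=row.scan_id,
            path=row.path,
            label=row.label,
            has_baseline=str(row.has_baseline).strip().lower() in ("1", "true", "yes"),
        )
        for row in df.itertuples()
    ]
    return CohortManifest(entries=entries)


def write_manifest(path: str | Path, manifest: CohortManifest) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": e.subject_id,
                "scan_id": e.scan_id,
                "path": e.path,
                "label": e.label,
                "has_baseline": int(e.has_baseline),
            }
            for e in manifest.entries
        ],
        columns=_MANIFEST_COLUMNS,
    )
    df.to_csv(path, index=False)


def load_cohort(manifest_path: str | Path) -> tuple[CohortManifest, list[BoldRecording]]:
    """Read a manifest and every scan it references.

    Relative scan paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    ids = manifest.label_ids
    recs = []
    for e in manifest.entries:
        p = Path(e.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        recs.append(read_recording(p, e, ids))
    return manifest, recs
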