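"""Reading and writing pulling traces and dataset manifests.

The native on-disk format is a headered TSV: a block of ``#key: value``
metadata lines followed by a header row and three numeric columns
``time  extension  force``.  Units are declared in the metadata and default
to (s, nm, pN) for AFM traces and (ns, nm, pN) for steered-MD traces.
Values are stored and returned in the declared units; unit conversions
happen only in the energetics layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "DatasetManifest",
    "ManifestEntry",
    "read_trace",
    "write_trace",
    "read_manifest",
    "write_manifest",
    "align_smd_channels",
]

VALID_KINDS = ("afm", "smd")

#: significant digits used when writing numeric columns; 17 guarantees an
#: exact float64 round-trip
_WRITE_DIGITS = 17


@dataclass
class Trace:
    """One pulling trace: equal-length (time, extension, force) series.

    ``time`` is in s (AFM) or ns (SMD) and must be strictly increasing;
    ``extension`` in nm; ``force`` in pN.  ``metadata`` carries instrument
    parameters such as ``spring_constant_pN_per_nm``, ``pulling_speed`` and
    ``sampling_interval`` plus a ``source_id``.
    """

    kind: str
    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = len(self.time)
        if n == 0:
            raise ValueError("trace series must be non-empty")
        if len(self.extension) != n or len(self.force) != n:
            raise ValueError(
                f"series length mismatch: time={n}, "
                f"extension={len(self.extension)}, force={len(self.force)}"
            )
        for name, arr in (("time", self.time), ("extension", self.extension),
                          ("force", self.force)):
            bad = ~np.isfinite(arr)
            if np.any(bad):
                idx = int(np.argmax(bad))
                raise ValueError(f"non-finite value in {name} at row {idx}")
        if np.any(np.diff(self.time) <= 0):
            idx = int(np.argmax(np.diff(self.time) <= 0))
            raise ValueError(f"time must be strictly increasing (violated at row {idx + 1})")

    def __len__(self) -> int:
        return len(self.time)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Trace):
            return NotImplemented
        return (
            self.kind == other.kind
            and np.array_equal(self.time, other.time)
            and np.array_equal(self.extension, other.extension)
            and np.array_equal(self.force, other.force)
            and self.metadata == other.metadata
        )


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    kind: str
    metadata_overrides: dict = field(default_factory=dict)


@dataclass
class DatasetManifest:
    """List of trace files with kinds and optional metadata overrides."""

    entries: list[ManifestEntry]
    notes: str = ""

    def __post_init__(self) -> None:
        paths = [e.path for e in self.entries]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest paths must be unique")
        for e in self.entries:
            if e.kind not in VALID_KINDS:
                raise ValueError(f"invalid kind {e.kind!r} for {e.path}")


def _parse_meta_value(raw: str):
    try:
        return json.loads(raw)
    except (json.JSONDecodeError, ValueError):
        return raw


def read_trace(path, kind: str | None = None, metadata_overrides: dict | None = None) -> Trace:
    """Read a headered-TSV trace file.

    Columns are mapped by header names (``time``, ``extension``, ``force``);
    metadata comes from the ``#key: value`` header block, overridable with
    ``metadata_overrides``.  ``kind`` falls back to the header's ``kind``.
    """
    path = Path(path)
    metadata: dict = {}
    header_lines = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                metadata[key.strip()] = _parse_meta_value(val.strip())

    df = pd.read_csv(path, sep="\t", skiprows=header_lines, float_precision="round_trip")
    for col in ("time", "extension", "force"):
        if col not in df.columns:
            raise ValueError(f"trace file {path} is missing required column {col!r}")

    if metadata_overrides:
        metadata.update(metadata_overrides)
    file_kind = metadata.pop("kind", None)
    kind = kind or file_kind
    if kind is None:
        raise ValueError(f"trace file {path} declares no kind and none was given")
    metadata.setdefault("source_id", path.stem)
    return Trace(
        kind=kind,
        time=df["time"].to_numpy(float),
        extension=df["extension"].to_numpy(float),
        force=df["force"].to_numpy(float),
        metadata=metadata,
    )


def write_trace(trace: Trace, path) -> None:
    """Write a trace as headered TSV with deterministic %.10g formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = f"%.{_WRITE_DIGITS}g"
    with path.open("w") as fh:
        fh.write(f"#kind: {trace.kind}\n")
        for key in sorted(trace.metadata):
            val = trace.metadata[key]
            if isinstance(val, str):
                fh.write(f"#{key}: {val}\n")
            else:
                fh.write(f"#{key}: {json.dumps(val)}\n")
        fh.write("time\textension\tforce\n")
        for t, x, f in zip(trace.time, trace.extension, trace.force):
            fh.write(f"{fmt % t}\t{fmt % x}\t{fmt % f}\n")


def write_manifest(manifest: DatasetManifest, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "notes": manifest.notes,
        "traces": [
            {"path": e.path, "kind": e.kind, "metadata_overrides": e.metadata_overrides}
            for e in manifest.entries
        ],
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")


def read_manifest(path) -> DatasetManifest:
    payload = json.loads(Path(path).read_text())
    entries = [
        ManifestEntry(t["path"], t["kind"], t.get("metadata_overrides", {}))
        for t in payload.get("traces", [])
    ]
    return DatasetManifest(entries=entries, notes=payload.get("notes", ""))


def align_smd_channels(
    force_time: np.ndarray,
    force: np.ndarray,
    extension_time: np.ndarray,
    extension: np.ndarray,
    metadata: dict | None = None,
) -> Trace:
    """Block-average a fast force channel onto a slower extension time base.

    Steered-MD runs commonly record the pulling force every integration step
    but the end-to-end extension only every Nth step.  The force samples are
    averaged in consecutive blocks of N so both series share the extension
    time base.
    """
    force_time = np.asarray(force_time, float)
    force = np.asarray(force, float)
    extension_time = np.asarray(extension_time, float)
    extension = np.asarray(extension, float)
    if len(force) != len(force_time) or len(extension) != len(extension_time):
        raise ValueError("channel series and time bases must have equal lengths")
    if len(force) % len(extension) != 0:
        raise ValueError(
            f"force sampling ({len(force)}) must be an integer multiple of "
            f"extension sampling ({len(extension)})"
        )
    ratio = len(force) // len(extension)
    force_blocked = force.reshape(len(extension), ratio).mean(axis=1)
    return Trace(
        kind="smd",
        time=extension_time,
        extension=extension,
        force=force_blocked,
        metadata=dict(metadata or {}),
    )
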