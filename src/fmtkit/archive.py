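"""UUID-keyed molecule archives with JSON persistence.

A :class:`MoleculeRecord` bundles everything known about one tethered
molecule: the tracked trajectory, derived scalar parameters (force,
length, compaction slope, ...), free-form tags ("coilable", "accepted",
...), change-point segment tables, and an append-only processing log.
Records live in a :class:`MoleculeArchive` keyed by UUID.

Archives serialize to a single UTF-8 JSON container (schema
``fmtkit-archive/1``) whose trailing ``index`` object maps each uid to
the byte span of that record's JSON text.  :meth:`MoleculeArchive.open`
reads only the header and index, so any single record can be fetched
from disk without parsing the rest of the file — archives far larger
than memory remain addressable record-by-record.
"""

from __future__ import annotations

import json
import os
import uuid as _uuid
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Iterator

import numpy as np
import pandas as pd

SCHEMA = "fmtkit-archive/1"

TRAJECTORY_COLUMNS = ["frame", "t_s", "x_um", "y_um"]
SEGMENT_COLUMNS = ["t_start", "t_end", "slope", "intercept", "resid_sd"]


class ArchiveError(ValueError):
    """Raised on archive contract violations (duplicate uids, bad files)."""


def new_uid(rng: np.random.Generator | None = None) -> str:
    """A random RFC-4122 v4 uid; deterministic when an rng is supplied."""
    if rng is None:
        return str(_uuid.uuid4())
    raw = bytearray(rng.bytes(16))
    raw[6] = (raw[6] & 0x0F) | 0x40  # version 4
    raw[8] = (raw[8] & 0x3F) | 0x80  # RFC 4122 variant
    return str(_uuid.UUID(bytes=bytes(raw)))


def make_segment_table(rows: Iterable[tuple] | pd.DataFrame) -> pd.DataFrame:
    """Build a validated segment table (ordered, non-overlapping)."""
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS) if not isinstance(rows, pd.DataFrame) else rows[SEGMENT_COLUMNS].copy()
    if len(df):
        if (df["t_start"] >= df["t_end"]).any():
            raise ArchiveError("segment rows require t_start < t_end")
        starts = df["t_start"].to_numpy()
        ends = df["t_end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ArchiveError("segments must be ordered and non-overlapping")
    return df.reset_index(drop=True)


@dataclass
class MoleculeRecord:
    """One molecule: trajectory, parameters, tags, segments, log."""

    uid: str
    trajectory: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TRAJECTORY_COLUMNS))
    parameters: dict[str, float] = field(default_factory=dict)
    tags: set[str] = field(default_factory=set)
    segments: list[pd.DataFrame] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _uuid.UUID(self.uid)  # raises on malformed uid
        self.trajectory = self._validate_trajectory(self.trajectory)

    @staticmethod
    def _validate_trajectory(traj: pd.DataFrame) -> pd.DataFrame:
        traj = traj[TRAJECTORY_COLUMNS].copy() if len(traj) else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
        if len(traj):
            t = traj["t_s"].to_numpy(float)
            if not np.all(np.diff(t) > 0):
                raise ArchiveError("trajectory time must be strictly increasing")
            fr = traj["frame"].to_numpy()
            if (fr < 0).any() or not np.allclose(fr, np.round(fr)):
                raise ArchiveError("frame indices must be non-negative integers")
        return traj.reset_index(drop=True)

    # ------------------------------------------------------------------
    # mutation helpers — every mutation appends a log entry
    def set_parameter(self, name: str, value: float) -> None:
        self.parameters[name] = float(value)
        self.log.append(f"set parameter {name}={value!r}")

    def add_tag(self, tag: str) -> None:
        self.tags.add(tag)
        self.log.append(f"added tag {tag}")

    def remove_tag(self, tag: str) -> None:
        self.tags.discard(tag)
        self.log.append(f"removed tag {tag}")

    def add_segments(self, table: pd.DataFrame, note: str = "") -> None:
        self.segments.append(make_segment_table(table))
        self.log.append(f"added segment table ({len(table)} rows){': ' + note if note else ''}")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "uid": self.uid,
            "trajectory": {c: self.trajectory[c].tolist() for c in TRAJECTORY_COLUMNS},
            "parameters": dict(self.parameters),
            "tags": sorted(self.tags),
            "segments": [{c: seg[c].tolist() for c in SEGMENT_COLUMNS} for seg in self.segments],
            "log": list(self.log),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MoleculeRecord":
        traj = pd.DataFrame({c: d["trajectory"].get(c, []) for c in TRAJECTORY_COLUMNS})
        segs = [pd.DataFrame({c: s.get(c, []) for c in SEGMENT_COLUMNS}) for s in d.get("segments", [])]
        return cls(
            uid=d["uid"],
            trajectory=traj,
            parameters={k: float(v) for k, v in d.get("parameters", {}).items()},
            tags=set(d.get("tags", [])),
            segments=segs,
            log=list(d.get("log", [])),
        )

    def equals(self, other: "MoleculeRecord") -> bool:
        return (
            self.uid == other.uid
            and self.trajectory.equals(other.trajectory)
            and self.parameters == other.parameters
            and self.tags == other.tags
            and len(self.segments) == len(other.segments)
            and all(a.equals(b) for a, b in zip(self.segments, other.segments))
            and self.log == other.log
        )


class MoleculeArchive:
    """In-memory collection of molecule records plus experiment metadata."""

    def __init__(self, metadata: dict[str, Any] | None = None):
        self.metadata: dict[str, Any] = metadata or {}
        self._records: dict[str, MoleculeRecord] = {}

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, uid: str) -> bool:
        return uid in self._records

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self._records.values())

    @property
    def uids(self) -> list[str]:
        return list(self._records)

    def add_record(self, rec: MoleculeRecord) -> None:
        if rec.uid in self._records:
            raise ArchiveError(f"duplicate uid {rec.uid}")
        self._records[rec.uid] = rec

    def get_record(self, uid: str) -> MoleculeRecord:
        try:
            return self._records[uid]
        except KeyError:
            raise ArchiveError(f"no record with uid {uid}") from None

    def query(self, predicate: Callable[[MoleculeRecord], bool]) -> list[str]:
        """uids of records satisfying the predicate, in insertion order.

        Predicates should treat missing tags/parameters as False; the
        convenience helpers :func:`tag_is` and :func:`parameter_gt` do.
        """
        return [uid for uid, rec in self._records.items() if predicate(rec)]

    def merge(self, other: "MoleculeArchive") -> "MoleculeArchive":
        """Union of two archives; uid sets must be disjoint.

        Metadata of both inputs is retained keyed per source experiment;
        processing logs travel with their records.
        """
        collisions = sorted(set(self._records) & set(other._records))
        if collisions:
            raise ArchiveError(f"uid collision on merge: {collisions}")
        merged = MoleculeArchive()
        sources: dict[str, Any] = {}
        for arch in (self, other):
            incoming = arch.metadata.get("sources")
            if incoming is None:
                incoming = {"experiment": arch.metadata} if arch.metadata else {}
            for name, meta in incoming.items():
                key, k = name, 1
                while key in sources:
                    key = f"{name}_{k}"
                    k += 1
                sources[key] = meta
        merged.metadata = {"sources": sources}
        for rec in self:
            merged.add_record(rec)
        for rec in other:
            merged.add_record(rec)
        return merged

    # ------------------------------------------------------------------
    # persistence
    def save(self, path: str | os.PathLike) -> None:
        """Write the ``fmtkit-archive/1`` JSON container with a byte index."""
        with open(path, "wb") as fh:
            fh.write(b'{"schema": %s,\n' % json.dumps(SCHEMA).encode())
            fh.write(b'"metadata": %s,\n' % json.dumps(self.metadata, sort_keys=True).encode())
            fh.write(b'"records": [\n')
            index: dict[str, list[int]] = {}
            pos = fh.tell()
            for i, (uid, rec) in enumerate(self._records.items()):
                if i:
                    fh.write(b",\n")
                    pos += 2
                blob = json.dumps(rec.to_dict()).encode("utf-8")
                fh.write(blob)
                index[uid] = [pos, len(blob)]
                pos += len(blob)
            fh.write(b'\n],\n')
            fh.write(b'"index": %s}\n' % json.dumps(index).encode())

    @classmethod
    def load(cls, path: str | os.PathLike) -> "MoleculeArchive":
        """Eagerly load a whole archive file into memory."""
        with open(path, "r", encoding="utf-8") as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ArchiveError(f"malformed archive file {path}: {exc}") from exc
        if data.get("schema") != SCHEMA:
            raise ArchiveError(f"unexpected schema {data.get('schema')!r} in {path}")
        arch = cls(metadata=data.get("metadata", {}))
        for rd in data.get("records", []):
            try:
                arch.add_record(MoleculeRecord.from_dict(rd))
            except (KeyError, ArchiveError, ValueError) as exc:
                raise ArchiveError(
                    f"malformed record {rd.get('uid', '<no uid>')}: {exc}"
                ) from exc
        return arch

    @staticmethod
    def open(path: str | os.PathLike) -> "FileBackedArchive":
        """Open for on-demand record retrieval without a full parse."""
        return FileBackedArchive(path)

    def equals(self, other: "MoleculeArchive") -> bool:
        return (
            self.metadata == other.metadata
            and set(self._records) == set(other._records)
            and all(rec.equals(other.get_record(uid)) for uid, rec in self._records.items())
        )

    # CSV trajectory interchange -----------------------------------------
    def export_trajectories(self, path: str | os.PathLike) -> None:
        frames = []
        for uid, rec in self._records.items():
            df = rec.trajectory.copy()
            df.insert(0, "uid", uid)
            frames.append(df)
        out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=["uid", *TRAJECTORY_COLUMNS])
        out.to_csv(path, index=False, columns=["uid", "frame", "t_s", "x_um", "y_um"])

    @classmethod
    def import_trajectories(cls, path: str | os.PathLike) -> "MoleculeArchive":
        df = pd.read_csv(path)
        arch = cls()
        for uid, grp in df.groupby("uid", sort=False):
            arch.add_record(MoleculeRecord(uid=str(uid), trajectory=grp[TRAJECTORY_COLUMNS]))
        return arch


class FileBackedArchive:
    """Read-only archive view that fetches single records by byte offset.

    Only the header (schema, metadata) and the trailing index are parsed
    on open; each :meth:`get_record` seeks directly to that record's JSON
    span.  ``bytes_read`` counts payload bytes actually read, so the
    virtual-storage contract is checkable.
    """

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        self.bytes_read = 0
        self._size = os.path.getsize(self.path)
        self._index = self._read_index()
        self._metadata = self._read_header_metadata()

    def _read_index(self) -> dict[str, list[int]]:
        # The index object is the final top-level key; scan back from EOF.
        chunk = 1 << 16
        with open(self.path, "rb") as fh:
            buf = b""
            pos = self._size
            marker = b'"index": '
            while pos > 0:
                step = min(chunk, pos)
                pos -= step
                fh.seek(pos)
                buf = fh.read(step) + buf
                self.bytes_read += step
                k = buf.rfind(marker)
                if k != -1:
                    tail = buf[k + len(marker):].decode("utf-8").rstrip()
                    if tail.endswith("}"):  # the container's closing brace
                        tail = tail[:-1]
                    try:
                        return json.loads(tail)
                    except json.JSONDecodeError as exc:
                        raise ArchiveError(f"malformed archive index in {self.path}: {exc}") from exc
        raise ArchiveError(f"no index found in {self.path}")

    def _read_header_metadata(self) -> dict[str, Any]:
        if not self._index:
            with open(self.path, "r", encoding="utf-8") as fh:
                data = json.load(fh)
            self.bytes_read += self._size
            if data.get("schema") != SCHEMA:
                raise ArchiveError(f"unexpected schema {data.get('schema')!r}")
            return data.get("metadata", {})
        first = min(start for start, _ in self._index.values())
        head_end = min(first, self._size)
        with open(self.path, "rb") as fh:
            head = fh.read(head_end).decode("utf-8")
        self.bytes_read += head_end
        # header is '{"schema": ..., "metadata": ..., "records": [' — close it
        head = head.rstrip().rstrip("[").rstrip().rstrip(",").rstrip()
        head = head[:-len('"records":')].rstrip().rstrip(",")
        try:
            data = json.loads(head + "}")
        except json.JSONDecodeError as exc:
            raise ArchiveError(f"malformed archive header in {self.path}: {exc}") from exc
        if data.get("schema") != SCHEMA:
            raise ArchiveError(f"unexpected schema {data.get('schema')!r}")
        return data.get("metadata", {})

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, uid: str) -> bool:
        return uid in self._index

    @property
    def uids(self) -> list[str]:
        return list(self._index)

    @property
    def metadata(self) -> dict[str, Any]:
        return self._metadata

    def get_record(self, uid: str) -> MoleculeRecord:
        try:
            start, length = self._index[uid]
        except KeyError:
            raise ArchiveError(f"no record with uid {uid}") from None
        with open(self.path, "rb") as fh:
            fh.seek(start)
            raw = fh.read(length)
        self.bytes_read += length
        try:
            return MoleculeRecord.from_dict(json.loads(raw.decode("utf-8")))
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise ArchiveError(f"malformed record {uid}: {exc}") from exc


# ----------------------------------------------------------------------
# predicate helpers for MoleculeArchive.query
def tag_is(tag: str) -> Callable[[MoleculeRecord], bool]:
    return lambda rec: tag in rec.tags


def parameter_gt(name: str, value: float) -> Callable[[MoleculeRecord], bool]:
    return lambda rec: name in rec.parameters and rec.parameters[name] > value
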