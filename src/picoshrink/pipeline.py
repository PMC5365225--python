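"""Composition of the techniques into the three compression modes.

* ``lossless``      — GZIP level 9 repack + minimal-width retyping. Output
  remains readable by any FAST5-aware tool.
* ``deep_lossless`` — lossless, plus event-table deduplication and structure
  collapsing. Best reversible ratio; most tools need a revert first.
* ``raw``           — lossless, plus irreversible removal of event-level
  intermediates (raw signal and FASTQ are retained).

Technique order within a mode is shrink → dedup-index → collapse for deep
(dedup links therefore reference original paths), and shrink → strip for raw.
Every output carries a provenance marker; reversible modes store full
reversal metadata.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .errors import PicoshrinkError
from .model import (
    COMPRESS_POLICY,
    Fast5Snapshot,
    FilterPolicy,
    ONT_DEFAULT_POLICY,
    load_snapshot,
    write_snapshot,
)
from .transforms import (
    ProvenanceRecord,
    attach_provenance,
    collapse_structure,
    index_duplicates,
    read_provenance,
    revert_snapshot,
    shrink_types,
    strip_intermediate,
)

log = logging.getLogger(__name__)

MODES = ("lossless", "deep_lossless", "raw")

__all__ = ["MODES", "RunConfig", "FileReport", "apply_mode", "compress_file",
           "revert_file", "process_file", "output_path_for"]


@dataclass(frozen=True)
class RunConfig:
    """User options for a compression run."""

    mode: str = "lossless"
    revert: bool = False
    realtime: bool = False
    prefix: Optional[str] = None
    group: Optional[str] = None
    threads: int = 1
    inputs: tuple = ()
    stability_window: float = 5.0
    filter_policy: FilterPolicy = COMPRESS_POLICY

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


@dataclass
class FileReport:
    """Per-file outcome of one compression or reversion."""

    input_path: str
    output_path: str
    mode: str
    bytes_before: int
    bytes_after: int
    status: str            # "compressed" | "reverted" | "skipped_already_compressed" | "skipped_error"
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status in ("compressed", "reverted", "skipped_already_compressed")


def _has_group(snapshot: Fast5Snapshot, suffix: str) -> bool:
    import re
    pat = re.compile(r"/Analyses/\w+_" + re.escape(suffix) + r"(/|$)")
    return any(pat.search(g) for g in snapshot.groups)


def apply_mode(snapshot: Fast5Snapshot, mode: str,
               group_selector: Optional[str] = None) -> Fast5Snapshot:
    """Run one mode's technique pipeline and attach provenance."""
    record = ProvenanceRecord(mode=mode)
    out, shrink_delta = shrink_types(snapshot)
    record.original_dtypes = shrink_delta
    if mode == "deep_lossless":
        out, links = index_duplicates(out)
        record.dedup_links = links
        out, collapse_delta = collapse_structure(out)
        record.original_paths = collapse_delta["original_paths"]
        record.original_attr_owners = collapse_delta["original_attr_owners"]
        record.original_groups = collapse_delta["original_groups"]
    elif mode == "raw":
        if group_selector is not None and not _has_group(out, group_selector):
            log.warning("no analysis group with suffix _%s; keeping all groups",
                        group_selector)
            group_selector = None
        out = strip_intermediate(out, group_selector=group_selector)
        # raw is irreversible: keep only the marker, not reversal metadata
        record = ProvenanceRecord(mode="raw")
    return attach_provenance(out, record)


def output_path_for(path, prefix: Optional[str]) -> Path:
    path = Path(path)
    return path if prefix is None else path.with_name(f"{prefix}.{path.name}")


def _write_atomic(snapshot: Fast5Snapshot, destination: Path,
                  policy: FilterPolicy) -> int:
    """Write to a temp file in the destination directory, then rename over.
    The original is never removed before the replacement is durable."""
    fd, tmp = tempfile.mkstemp(prefix=f".{destination.name}.", suffix=".tmp",
                               dir=destination.parent)
    os.close(fd)
    try:
        size = write_snapshot(snapshot, tmp, policy)
        os.replace(tmp, destination)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return size


def compress_file(path, config: RunConfig) -> FileReport:
    """Compress one FAST5 file in the configured mode.

    Output replaces the input atomically, or goes to ``<prefix>.<name>`` in
    the same directory when a prefix is configured. Files already carrying a
    picoshrink provenance marker are skipped. Errors are reported, never
    raised, so batch runs keep going.
    """
    path = Path(path)
    destination = output_path_for(path, config.prefix)
    try:
        before = os.path.getsize(path)
        snapshot = load_snapshot(path)
        existing = read_provenance(snapshot)
        if existing is not None:
            note = ("already compressed in this mode" if existing.mode == config.mode
                    else f"already compressed in mode {existing.mode!r}; revert first")
            return FileReport(str(path), str(path), config.mode, before, before,
                              "skipped_already_compressed", note)
        out = apply_mode(snapshot, config.mode, group_selector=config.group)
        after = _write_atomic(out, destination, config.filter_policy)
        log.info("%s: %s %d -> %d bytes", config.mode, path, before, after)
        return FileReport(str(path), str(destination), config.mode, before, after,
                          "compressed")
    except PicoshrinkError as exc:
        return FileReport(str(path), "", config.mode, _size_or_zero(path), 0,
                          "skipped_error", str(exc))
    except OSError as exc:
        return FileReport(str(path), "", config.mode, _size_or_zero(path), 0,
                          "skipped_error", f"I/O error: {exc}")


def revert_file(path, config: RunConfig) -> FileReport:
    """Restore a losslessly compressed file to its original form."""
    path = Path(path)
    destination = output_path_for(path, config.prefix)
    try:
        before = os.path.getsize(path)
        snapshot = load_snapshot(path)
        restored = revert_snapshot(snapshot)
        after = _write_atomic(restored, destination, ONT_DEFAULT_POLICY)
        log.info("revert: %s %d -> %d bytes", path, before, after)
        return FileReport(str(path), str(destination), "revert", before, after,
                          "reverted")
    except PicoshrinkError as exc:
        return FileReport(str(path), "", "revert", _size_or_zero(path), 0,
                          "skipped_error", str(exc))
    except OSError as exc:
        return FileReport(str(path), "", "revert", _size_or_zero(path), 0,
                          "skipped_error", f"I/O error: {exc}")


def process_file(path, config: RunConfig) -> FileReport:
    return revert_file(path, config) if config.revert else compress_file(path, config)


def _size_or_zero(path) -> int:
    try:
        return os.path.getsize(path)
    except OSError:
        return 0
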