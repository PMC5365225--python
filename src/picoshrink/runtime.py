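"""Batch execution: input discovery, parallel runs, real-time watching.

Parallelism is per file (a process pool); one worker compresses one file
end-to-end, so results are independent of thread count and arrival order.
The real-time watcher is a polling loop: a newly created ``.fast5`` file is
processed once its size has been stable for a configurable window, since the
acquisition software writes files in bursts and gives no completion signal.
"""

from __future__ import annotations

import logging
import threading
import time
from concurrent.futures import ProcessPoolExecutor
from pathlib import Path
from typing import Iterator, Optional, Sequence

from .pipeline import FileReport, RunConfig, process_file
from .errors import ParameterError

log = logging.getLogger(__name__)

__all__ = ["discover_inputs", "run_batch", "watch_realtime", "summarize",
           "RunConfig", "FileReport"]


def discover_inputs(paths: Sequence) -> list:
    """Resolve files and directories to a sorted, deduplicated list of FAST5
    files. Directories are searched recursively for the ``.fast5`` extension
    (case-insensitive); explicitly named files are taken as given."""
    found = set()
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise ParameterError(f"input path does not exist: {p}")
        if p.is_dir():
            hits = [f for f in p.rglob("*") if f.is_file()
                    and f.suffix.lower() == ".fast5"]
            if not hits:
                log.warning("no FAST5 files found under %s", p)
            found.update(hits)
        else:
            found.add(p)
    return sorted(found, key=str)


def _process_one(args) -> FileReport:
    path, config = args
    return process_file(path, config)


def run_batch(config: RunConfig) -> tuple:
    """Process every discovered input; returns ``(reports, exit_code)``.

    Up to ``config.threads`` files are in flight concurrently. Failures are
    isolated per file: the batch always runs to completion and the exit code
    is 0 iff no file failed.
    """
    files = discover_inputs(config.inputs)
    jobs = [(f, config) for f in files]
    if config.threads == 1 or len(files) <= 1:
        reports = [_process_one(j) for j in jobs]
    else:
        with ProcessPoolExecutor(max_workers=config.threads) as pool:
            reports = list(pool.map(_process_one, jobs))
    for r in reports:
        log.info("%s: %s (%d -> %d bytes) %s", r.status, r.input_path,
                 r.bytes_before, r.bytes_after, r.message)
    failures = sum(1 for r in reports if r.status == "skipped_error")
    return reports, (0 if failures == 0 else 1)


def summarize(reports: Sequence) -> dict:
    """Aggregate a batch: totals equal the sum of the per-file counts."""
    done = [r for r in reports if r.status in ("compressed", "reverted")]
    return {
        "files": len(reports),
        "processed": len(done),
        "skipped": sum(1 for r in reports if r.status == "skipped_already_compressed"),
        "failed": sum(1 for r in reports if r.status == "skipped_error"),
        "bytes_before": sum(r.bytes_before for r in done),
        "bytes_after": sum(r.bytes_after for r in done),
    }


def _candidate_files(dirs, prefix: Optional[str]) -> list:
    out = []
    for d in dirs:
        if not d.exists():
            continue
        for f in d.rglob("*"):
            if not f.is_file() or f.suffix.lower() != ".fast5":
                continue
            if f.name.startswith("."):
                continue  # temp files from atomic writes
            if prefix is not None and f.name.startswith(f"{prefix}."):
                continue  # our own prefixed outputs are never re-inputs
            out.append(f)
    return sorted(out, key=str)


def watch_realtime(config: RunConfig, stop_event: Optional[threading.Event] = None,
                   poll_interval: float = 0.5) -> Iterator[FileReport]:
    """Watch the input directories and compress each new FAST5 file once its
    size has been unchanged for ``config.stability_window`` seconds. Files
    already present at start are processed in a catch-up pass. Yields one
    report per completed file; returns when ``stop_event`` is set or every
    watched directory has disappeared.
    """
    dirs = [Path(p) for p in config.inputs]
    for d in dirs:
        if not d.is_dir():
            raise ParameterError(f"realtime mode watches directories; {d} is not one")
    stop_event = stop_event or threading.Event()
    processed: set = set()
    pending: dict = {}  # path -> (size, time first seen at this size)
    while not stop_event.is_set():
        if all(not d.exists() for d in dirs):
            log.info("watched director%s deleted; shutting down",
                     "y" if len(dirs) == 1 else "ies")
            return
        now = time.monotonic()
        for f in _candidate_files(dirs, config.prefix):
            if f in processed:
                continue
            try:
                size = f.stat().st_size
            except OSError:
                continue
            prev = pending.get(f)
            if prev is None or prev[0] != size:
                pending[f] = (size, now)
                continue
            if now - prev[1] >= config.stability_window:
                processed.add(f)
                del pending[f]
                yield process_file(f, config)
        stop_event.wait(poll_interval)
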