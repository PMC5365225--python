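"""Corpus-level evaluation of the compression modes.

Measures what a practitioner would: the size of a (deterministic, POSIX pax)
tarball of the corpus after each treatment arm — no compression, external
gzip of the tarball, and each picoshrink mode — normalised per megabase of
called sequence, with percent reductions and a dependent-sample t-test on
per-file sizes between successive arms.
"""

from __future__ import annotations

import gzip
import io
import json
import math
import os
import shutil
import tarfile
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ParameterError
from .model import extract_fastq, load_snapshot
from .pipeline import MODES, RunConfig
from .runtime import discover_inputs, run_batch

__all__ = ["SizeReport", "count_bases", "percent_reduction", "paired_t_test",
           "measure_corpus", "deterministic_tar_size"]

_GZIP_LEVEL = 6  # the gzip command-line default; applied after tarring


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def count_bases(records: Sequence) -> int:
    """Total called bases: the sum of sequence lengths over FASTQ records."""
    return sum(len(r.sequence) for r in records)


def percent_reduction(bytes_before: float, bytes_after: float) -> float:
    """Headline size-reduction metric, 100 * (1 - after/before)."""
    if bytes_before <= 0:
        raise ParameterError("percent reduction undefined for zero original size")
    return 100.0 * (1.0 - bytes_after / bytes_before)


def paired_t_test(sizes_a: Sequence, sizes_b: Sequence):
    """Dependent-sample t-test on paired observations.

    With d = a - b elementwise: t = mean(d) / (sd(d)/sqrt(n)) using the
    sample standard deviation (n-1 denominator), df = n-1, and a two-sided
    p-value from the t distribution. Positive t means the first sample is
    larger on average. Returns ``(t, p, df)``.
    """
    a = np.asarray(sizes_a, dtype=float)
    b = np.asarray(sizes_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("paired samples must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ParameterError("paired t-test requires at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateDataError("zero variance of paired differences")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


# ---------------------------------------------------------------------------
# Corpus measurement
# ---------------------------------------------------------------------------

def deterministic_tar_size(files: Sequence, gzip_after: bool = False) -> int:
    """Size of a reproducible POSIX pax tarball of the given files: members
    sorted by name, zeroed mtimes and ownership. Optionally gzip the tarball
    afterwards (the conventional tar-then-gzip arm)."""
    buf = io.BytesIO()
    with tarfile.open(fileobj=buf, mode="w", format=tarfile.PAX_FORMAT) as tar:
        for f in sorted(Path(p) for p in files):
            info = tar.gettarinfo(f, arcname=f.name)
            info.mtime = 0
            info.uid = info.gid = 0
            info.uname = info.gname = ""
            with open(f, "rb") as fh:
                tar.addfile(info, fh)
    raw = buf.getvalue()
    if gzip_after:
        return len(gzip.compress(raw, compresslevel=_GZIP_LEVEL, mtime=0))
    return len(raw)


@dataclass
class SizeReport:
    """Per-file and per-corpus size accounting for each treatment arm."""

    n_files: int = 0
    total_bases: int = 0
    per_file: list = field(default_factory=list)   # dicts: path, mode, bytes_*
    tar_bytes: dict = field(default_factory=dict)          # arm -> tarball size
    file_bytes: dict = field(default_factory=dict)         # arm -> summed file sizes
    tar_reduction_pct: dict = field(default_factory=dict)  # vs uncompressed tar
    file_reduction_pct: dict = field(default_factory=dict)
    bytes_per_megabase: dict = field(default_factory=dict)
    t_tests: dict = field(default_factory=dict)    # "arm1_vs_arm2" -> {t, p, df}

    def per_file_sizes(self, arm: str) -> list:
        return [r["bytes"] for r in self.per_file if r["arm"] == arm]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)

    def to_tsv(self) -> str:
        lines = ["arm\ttar_bytes\tfile_bytes\ttar_reduction_pct"
                 "\tfile_reduction_pct\tbytes_per_megabase"]
        for arm in self.tar_bytes:
            lines.append("\t".join([
                arm, str(self.tar_bytes[arm]), str(self.file_bytes[arm]),
                f"{self.tar_reduction_pct[arm]:.2f}",
                f"{self.file_reduction_pct[arm]:.2f}",
                f"{self.bytes_per_megabase[arm]:.1f}",
            ]))
        return "\n".join(lines) + "\n"


def measure_corpus(directory, modes: Sequence = MODES, threads: int = 1,
                   include_gzip_arm: bool = True,
                   workdir: Optional[Path] = None) -> SizeReport:
    """Run the full evaluation on one corpus directory.

    Each mode works on its own copy of the corpus, so arms are independent.
    Reductions are reported both on tarball sizes and on summed per-file
    sizes; normalisation divides by the corpus' called megabases.
    """
    files = discover_inputs([directory])
    if not files:
        raise ParameterError(f"no FAST5 files in {directory}")
    report = SizeReport(n_files=len(files))
    report.total_bases = sum(count_bases(extract_fastq(load_snapshot(f)))
                             for f in files)

    def record_arm(arm: str, arm_files: Sequence, gzip_after: bool = False) -> None:
        report.tar_bytes[arm] = deterministic_tar_size(arm_files, gzip_after=gzip_after)
        sizes = [os.path.getsize(f) for f in sorted(arm_files, key=lambda p: Path(p).name)]
        report.file_bytes[arm] = sum(sizes)
        for f, s in zip(sorted(arm_files, key=lambda p: Path(p).name), sizes):
            report.per_file.append({"path": str(f), "arm": arm, "bytes": s})

    record_arm("uncompressed", files)
    if include_gzip_arm:
        record_arm("gzip", files, gzip_after=True)

    ctx = tempfile.TemporaryDirectory(prefix="picoshrink-bench-") if workdir is None else None
    base = Path(ctx.name) if ctx else Path(workdir)
    try:
        for mode in modes:
            arm_dir = base / mode
            arm_dir.mkdir(parents=True, exist_ok=True)
            copies = []
            for f in files:
                dst = arm_dir / Path(f).name
                shutil.copyfile(f, dst)
                copies.append(dst)
            reports, code = run_batch(RunConfig(mode=mode, threads=threads,
                                                inputs=(str(arm_dir),)))
            if code != 0:
                bad = [r for r in reports if r.status == "skipped_error"]
                raise ParameterError(f"{len(bad)} file(s) failed in mode {mode}: "
                                     f"{bad[0].message}")
            record_arm(mode, copies)
    finally:
        if ctx:
            ctx.cleanup()

    base_tar = report.tar_bytes["uncompressed"]
    base_files = report.file_bytes["uncompressed"]
    mb = report.total_bases / 1e6
    for arm in report.tar_bytes:
        report.tar_reduction_pct[arm] = percent_reduction(base_tar, report.tar_bytes[arm])
        report.file_reduction_pct[arm] = percent_reduction(base_files,
                                                           report.file_bytes[arm])
        report.bytes_per_megabase[arm] = (report.tar_bytes[arm] / mb
                                          if mb > 0 else float("nan"))

    chain = ["uncompressed"] + [m for m in modes]
    for arm1, arm2 in zip(chain, chain[1:]):
        a = report.per_file_sizes(arm1)
        b = report.per_file_sizes(arm2)
        if len(a) == len(b) >= 2:
            try:
                t, p, df = paired_t_test(a, b)
                report.t_tests[f"{arm1}_vs_{arm2}"] = {"t": t, "p": p, "df": df}
            except DegenerateDataError:
                pass
    return report
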