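"""Deterministic synthetic FAST5 files with ONT-era storage pathologies.

Real FAST5 read files from the R7–R9.4 MinION era share a set of storage
inefficiencies: every numeric column is written as a 64-bit type, strings are
variable-length, datasets are GZIP-compressed only at level 1, the group tree
is deep, and the basecalled event tables duplicate the mean/stdv/start/length
columns of the event-detection table verbatim. This module builds small
in-memory snapshots (and on-disk corpora) exhibiting exactly those
pathologies, together with a manifest describing the embedded content so that
every transform has an oracle to test against.

The signal itself is a clipped Gaussian random walk and the sequence is
uniform random DNA — content realism is not the point, structural fidelity
is. Event means/stdvs are computed from the signal segments so the tables
are internally consistent, and the FASTQ sequence is derived from the
model_state/move columns so sequence length and event annotation agree.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ParameterError
from .model import (
    DatasetNode,
    Fast5Snapshot,
    FastqRecord,
    FilterPolicy,
    ONT_DEFAULT_POLICY,
    TypeDescriptor,
    write_snapshot,
)

__all__ = ["FixtureParams", "FixtureManifest", "generate_read_snapshot", "generate_corpus"]

_SAMPLING_RATE = 4000.0  # Hz, typical MinKNOW acquisition rate
_BASES = np.array(list("ACGT"))

_I8 = TypeDescriptor("sint", 8)
_F8 = TypeDescriptor("float", 8)
_VS = TypeDescriptor("var_string")


@dataclass(frozen=True)
class FixtureParams:
    """Knobs of the generator. Defaults emulate a small R9-era 2D read."""

    seed: int = 0
    n_events: int = 2000
    read_variant: str = "2d"                  # "1d" | "2d"
    kmer_k: int = 5
    signal_samples_per_event: int = 10
    include_basecall: bool = True
    analysis_suffixes: tuple = ("000",)
    time_unit: str = "sample_index"           # "sample_index" | "seconds"

    def __post_init__(self):
        if self.read_variant not in ("1d", "2d"):
            raise ParameterError(f"read_variant must be 1d or 2d, got {self.read_variant!r}")
        if self.time_unit not in ("sample_index", "seconds"):
            raise ParameterError(f"unknown time_unit {self.time_unit!r}")
        if self.n_events < self.kmer_k:
            raise ParameterError("n_events must be at least kmer_k")


@dataclass
class FixtureManifest:
    """What the generator put into the snapshot (the test oracle)."""

    read_id: str = ""
    read_number: int = 0
    fastq_records: list = field(default_factory=list)      # list[FastqRecord]
    event_counts: dict = field(default_factory=dict)       # events path -> rows
    dedup_slices: dict = field(default_factory=dict)       # basecall path -> (ed path, start, count)
    group_paths: list = field(default_factory=list)
    n_bases: int = 0

    def to_json(self) -> dict:
        d = asdict(self)
        d["fastq_records"] = [asdict(r) for r in self.fastq_records]
        return d

    @classmethod
    def from_json(cls, d: dict) -> "FixtureManifest":
        m = cls(**{**d, "fastq_records": [FastqRecord(**r) for r in d["fastq_records"]]})
        m.dedup_slices = {k: tuple(v) for k, v in m.dedup_slices.items()}
        return m


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _random_quality(rng: np.random.Generator, length: int) -> str:
    # Phred+33 in '!'..'I'
    return "".join(chr(c) for c in rng.integers(ord("!"), ord("I") + 1, size=length))


def _event_detection_table(rng, params, signal):
    """Segment the signal into events; all columns 64-bit (the ONT default)."""
    n = params.n_events
    spe = params.signal_samples_per_event
    lengths = rng.integers(max(2, spe // 2), 2 * spe + 1, size=n)
    lengths = lengths[: n]
    total = int(lengths.sum())
    if total > signal.size:
        raise ParameterError("signal too short for requested events")
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    mean = np.empty(n)
    stdv = np.empty(n)
    for i, (s, ln) in enumerate(zip(starts, lengths)):
        seg = signal[s:s + ln].astype(np.float64)
        mean[i] = seg.mean()
        stdv[i] = seg.std()
    if params.time_unit == "sample_index":
        start_col, len_col, ttd = starts.astype("<i8"), lengths.astype("<i8"), _I8
    else:
        start_col = starts.astype("<f8") / _SAMPLING_RATE
        len_col = lengths.astype("<f8") / _SAMPLING_RATE
        ttd = _F8
    td = TypeDescriptor("compound", None, (
        ("mean", _F8), ("stdv", _F8), ("start", ttd), ("length", ttd)))
    table = np.empty(n, dtype=td.to_numpy())
    table["mean"], table["stdv"] = mean, stdv
    table["start"], table["length"] = start_col, len_col
    return table, td


def _basecall_table(rng, params, ed_table, sl: slice):
    """Basecall event table duplicating a contiguous event-detection slice."""
    k = params.kmer_k
    rows = ed_table[sl]
    n = len(rows)
    moves = np.zeros(n, dtype="<i8")
    moves[1:] = rng.integers(0, 3, size=n - 1)
    seq = _random_dna(rng, k + int(moves.sum()))
    pos = np.concatenate([[0], np.cumsum(moves[1:])]) if n > 1 else np.zeros(1, "<i8")
    states = np.array([seq[p:p + k].encode("ascii") for p in pos], dtype=f"S{k}")
    ed_td = TypeDescriptor.from_numpy(ed_table.dtype)
    td = TypeDescriptor("compound", None, ed_td.fields + (
        ("model_state", TypeDescriptor("fixed_string", k)),
        ("move", _I8),
        ("p_model_state", _F8),
    ))
    table = np.empty(n, dtype=td.to_numpy())
    for name in ed_table.dtype.names:
        table[name] = rows[name]
    table["model_state"] = states
    table["move"] = moves
    table["p_model_state"] = rng.random(n)
    return table, td, seq


def _vs_attr(value: str):
    return (np.array(value, dtype=object), _VS)


def generate_read_snapshot(params: FixtureParams):
    """Build one synthetic single-read FAST5 snapshot plus its manifest.

    The snapshot mirrors the ONT on-disk defaults: int16 raw signal,
    event tables with 64-bit columns, variable-length string attributes and
    a level-1 GZIP expectation when written with the default policy. With
    ``include_basecall=False`` the file resembles a pre-basecalled
    acquisition (raw signal and run metadata only, no ``/Analyses`` group).
    """
    rng = np.random.default_rng(params.seed)
    snap = Fast5Snapshot()
    manifest = FixtureManifest()

    n_samples = params.n_events * 2 * params.signal_samples_per_event + 16
    steps = rng.normal(0.0, 4.0, size=n_samples)
    signal = np.clip(500 + np.cumsum(steps), 50, 1800).astype("<i2")

    read_number = int(params.seed % 10000)
    read_id = f"{params.seed:08x}-0000-4000-8000-{params.seed % 2**32:012x}"
    manifest.read_id, manifest.read_number = read_id, read_number

    read_group = f"/Raw/Reads/Read_{read_number}"
    for g in ("/Raw", "/Raw/Reads", read_group, "/UniqueGlobalKey",
              "/UniqueGlobalKey/tracking_id", "/UniqueGlobalKey/channel_id"):
        snap.groups.add(g)

    sig_path = f"{read_group}/Signal"
    snap.datasets[sig_path] = DatasetNode(sig_path, signal, TypeDescriptor("sint", 2))

    snap.attrs_for("/")["file_version"] = _vs_attr("1.0")
    snap.attrs_for(read_group).update({
        "read_id": _vs_attr(read_id),
        "read_number": (np.int64(read_number), _I8),
        "start_time": (np.int64(rng.integers(0, 10**7)), _I8),
        "duration": (np.int64(signal.size), _I8),
        "median_before": (np.float64(rng.normal(250, 10)), _F8),
    })
    snap.attrs_for("/UniqueGlobalKey/tracking_id").update({
        "run_id": _vs_attr(f"{rng.integers(0, 2**32):08x}run"),
        "device_id": _vs_attr("MN17324"),
        "flow_cell_id": _vs_attr("FAD00000"),
        "exp_start_time": _vs_attr("1970-01-01T00:00:00Z"),
    })
    snap.attrs_for("/UniqueGlobalKey/channel_id").update({
        "channel_number": _vs_attr(str(int(rng.integers(1, 513)))),
        "digitisation": (np.float64(8192.0), _F8),
        "offset": (np.float64(rng.integers(-10, 10)), _F8),
        "range": (np.float64(1400.0), _F8),
        "sampling_rate": (np.float64(_SAMPLING_RATE), _F8),
    })

    if not params.include_basecall:
        manifest.group_paths = sorted(snap.groups)
        return snap, manifest

    suffix = params.analysis_suffixes[0]
    ed_group = f"/Analyses/EventDetection_{suffix}"
    ed_reads = f"{ed_group}/Reads/Read_{read_number}"
    for g in ("/Analyses", ed_group, f"{ed_group}/Reads", ed_reads):
        snap.groups.add(g)
    ed_table, ed_td = _event_detection_table(rng, params, signal)
    ed_path = f"{ed_reads}/Events"
    snap.datasets[ed_path] = DatasetNode(
        ed_path, ed_table, ed_td, compression="gzip", compression_level=1, chunked=True)
    manifest.event_counts[ed_path] = len(ed_table)
    snap.attrs_for(ed_group)["name"] = _vs_attr("synthetic event detection")
    snap.attrs_for(ed_reads).update({
        "read_number": (np.int64(read_number), _I8),
        "start_time": (np.int64(0), _I8),
    })

    n = params.n_events
    if params.read_variant == "2d":
        bc_group = f"/Analyses/Basecall_2D_{suffix}"
        n_template = int(rng.integers(n // 2, max(n // 2 + 1, n - params.kmer_k)))
        slices = {
            "template": slice(0, n_template),
            "complement": slice(n_template, n),
        }
        s2 = int(rng.integers(0, n // 4 + 1))
        m2 = int(rng.integers(n // 2, n - s2 + 1))
        slices["2D"] = slice(s2, s2 + m2)
        fastq_section = "2D"
    else:
        bc_group = f"/Analyses/Basecall_1D_{suffix}"
        a = int(rng.integers(0, max(1, n // 10)))
        slices = {"template": slice(a, n - int(rng.integers(0, max(1, n // 10))))}
        fastq_section = "template"

    snap.groups.add(bc_group)
    snap.attrs_for(bc_group).update({
        "name": _vs_attr("synthetic basecaller"),
        "version": _vs_attr("0.1.0"),
        "time_stamp": _vs_attr("1970-01-01T00:00:00Z"),
    })
    summary = f"{bc_group}/Summary"
    snap.groups.add(summary)
    snap.attrs_for(summary).update({
        "num_events": (np.int64(n), _I8),
        "mean_qscore": (np.float64(rng.uniform(6, 14)), _F8),
    })

    for section, sl in slices.items():
        sec_group = f"{bc_group}/BaseCalled_{section}"
        snap.groups.add(sec_group)
        table, td, seq = _basecall_table(rng, params, ed_table, sl)
        ev_path = f"{sec_group}/Events"
        snap.datasets[ev_path] = DatasetNode(
            ev_path, table, td, compression="gzip", compression_level=1, chunked=True)
        manifest.event_counts[ev_path] = len(table)
        manifest.dedup_slices[ev_path] = (ed_path, sl.start, sl.stop - sl.start)
        if section == fastq_section:
            qual = _random_quality(rng, len(seq))
            rec = FastqRecord(f"{read_id}_{section}", seq, qual)
            fq_path = f"{sec_group}/Fastq"
            snap.datasets[fq_path] = DatasetNode(
                fq_path, np.array(rec.to_text(), dtype=object), _VS)
            manifest.fastq_records.append(rec)
            manifest.n_bases += len(seq)

    manifest.group_paths = sorted(snap.groups)
    return snap, manifest


def generate_corpus(directory, n_files: int, base_seed: int = 0,
                    params: Optional[FixtureParams] = None,
                    filter_policy: FilterPolicy = ONT_DEFAULT_POLICY,
                    overwrite: bool = False) -> list:
    """Write ``n_files`` synthetic FAST5 files (seeds ``base_seed..+n-1``)
    into ``directory`` plus a ``manifest.json`` describing all of them.
    Returns the file paths in creation order. Refuses to clobber existing
    files unless ``overwrite`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = params or FixtureParams()
    paths, manifests = [], {}
    names = [f"read_{base_seed + i:05d}.fast5" for i in range(n_files)]
    if not overwrite:
        clashes = [n for n in names if (directory / n).exists()]
        if clashes:
            raise FileExistsError(
                f"{len(clashes)} file(s) already exist in {directory} "
                f"(e.g. {clashes[0]}); pass overwrite=True to replace them")
    for i, name in enumerate(names):
        p = FixtureParams(**{**asdict(base), "seed": base_seed + i})
        snap, manifest = generate_read_snapshot(p)
        out = directory / name
        write_snapshot(snap, out, filter_policy)
        paths.append(out)
        manifests[name] = manifest.to_json()
    if n_files:
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifests, fh, indent=1, sort_keys=True)
    return paths


def load_corpus_manifests(directory) -> dict:
    """Read back the manifests written by :func:`generate_corpus`."""
    with open(Path(directory) / "manifest.json") as fh:
        raw = json.load(fh)
    return {name: FixtureManifest.from_json(d) for name, d in raw.items()}
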