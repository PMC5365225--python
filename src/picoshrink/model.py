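"""Semantic model of a FAST5 (HDF5) read file.

A FAST5 file is an ordinary HDF5 container laid out by Oxford Nanopore's
acquisition and basecalling software: raw current signal under
``/Raw/Reads/Read_<n>/Signal``, event-detection tables under
``/Analyses/EventDetection_<ggg>/...``, basecall outputs (event tables and
FASTQ text) under ``/Analyses/Basecall_{1D,2D}_<ggg>/...`` and run metadata
as attributes under ``/UniqueGlobalKey``.

This module loads such a file into a :class:`Fast5Snapshot` — a plain
in-memory tree of groups, datasets and attributes with explicit element-type
descriptors — and writes a snapshot back out as a freshly packed file
(equivalent to ``h5repack``: no unreclaimed free space, new filter settings
applied). All compression transforms in :mod:`picoshrink.transforms` are pure
functions on snapshots, so the file I/O lives here and nowhere else.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace
from typing import Optional

import h5py
import numpy as np

from .errors import CorruptFileError, EncodingError, FastqParseError, FormatError

__all__ = [
    "TypeDescriptor",
    "DatasetNode",
    "AttributeMap",
    "Fast5Snapshot",
    "FilterPolicy",
    "FastqRecord",
    "RESERVED_GROUP",
    "load_snapshot",
    "write_snapshot",
    "semantic_equal",
    "extract_fastq",
]

#: Reserved namespace for picoshrink's own reversal metadata. Content under
#: this group is tool bookkeeping, not sequencing data, and is therefore
#: ignored by :func:`semantic_equal`.
RESERVED_GROUP = "/.picoshrink"

_INT_WIDTHS = (1, 2, 4, 8)
_FLOAT_WIDTHS = (4, 8)


# ---------------------------------------------------------------------------
# Type descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TypeDescriptor:
    """Element type of a dataset or attribute.

    ``kind`` is one of ``sint``, ``uint``, ``float``, ``fixed_string``,
    ``var_string``, ``compound``. ``width_bytes`` is the per-element byte
    width (``None`` for variable-length strings and compounds). ``fields``
    is the ordered tuple of ``(name, TypeDescriptor)`` pairs for compounds.
    """

    kind: str
    width_bytes: Optional[int] = None
    fields: tuple = ()

    def __post_init__(self) -> None:
        if self.kind in ("sint", "uint") and self.width_bytes not in _INT_WIDTHS:
            raise ValueError(f"integer width must be one of {_INT_WIDTHS}")
        if self.kind == "float" and self.width_bytes not in _FLOAT_WIDTHS:
            raise ValueError(f"float width must be one of {_FLOAT_WIDTHS}")
        if self.kind == "fixed_string" and (self.width_bytes is None or self.width_bytes < 1):
            raise ValueError("fixed_string requires a positive width")
        if self.kind == "compound":
            names = [n for n, _ in self.fields]
            if len(set(names)) != len(names):
                raise ValueError("compound field names must be unique")

    # -- numpy/h5py interop -------------------------------------------------

    def to_numpy(self) -> np.dtype:
        if self.kind == "sint":
            return np.dtype(f"<i{self.width_bytes}")
        if self.kind == "uint":
            return np.dtype(f"<u{self.width_bytes}")
        if self.kind == "float":
            return np.dtype(f"<f{self.width_bytes}")
        if self.kind == "fixed_string":
            return np.dtype(f"S{self.width_bytes}")
        if self.kind == "var_string":
            return h5py.string_dtype(encoding="utf-8")
        if self.kind == "compound":
            return np.dtype([(n, td.to_numpy()) for n, td in self.fields])
        raise ValueError(f"unknown kind {self.kind!r}")

    @classmethod
    def from_numpy(cls, dt: np.dtype) -> "TypeDescriptor":
        dt = np.dtype(dt)
        if dt.names:
            return cls("compound", None,
                       tuple((n, cls.from_numpy(dt[n])) for n in dt.names))
        sinfo = h5py.check_string_dtype(dt)
        if sinfo is not None:
            if sinfo.length is None:
                return cls("var_string")
            return cls("fixed_string", sinfo.length)
        if dt.kind == "i":
            return cls("sint", dt.itemsize)
        if dt.kind == "u":
            return cls("uint", dt.itemsize)
        if dt.kind == "f":
            return cls("float", dt.itemsize)
        if dt.kind == "S":
            return cls("fixed_string", dt.itemsize)
        raise ValueError(f"unsupported element type {dt!r}")

    # -- compact JSON encoding for provenance records -------------------------
    # scalars are numpy-style codes ("i8", "u1", "f4", "S5", "vlen");
    # compounds are [[name, code], ...]

    def to_json(self):
        if self.kind == "compound":
            return [[n, td.to_json()] for n, td in self.fields]
        if self.kind == "var_string":
            return "vlen"
        code = {"sint": "i", "uint": "u", "float": "f", "fixed_string": "S"}[self.kind]
        return f"{code}{self.width_bytes}"

    @classmethod
    def from_json(cls, obj) -> "TypeDescriptor":
        if isinstance(obj, list):
            return cls("compound", None,
                       tuple((n, cls.from_json(td)) for n, td in obj))
        if obj == "vlen":
            return cls("var_string")
        kind = {"i": "sint", "u": "uint", "f": "float", "S": "fixed_string"}[obj[0]]
        return cls(kind, int(obj[1:]))


@dataclass
class DatasetNode:
    """One HDF5 dataset: values plus element type and stored filter settings.

    Filter settings (``compression``, ``compression_level``, ``chunked``) are
    recorded at load time for inspection; the writer applies its own
    :class:`FilterPolicy` instead, mirroring ``h5repack``.
    """

    path: str
    values: np.ndarray
    dtype: TypeDescriptor
    compression: str = "none"  # "none" | "gzip"
    compression_level: int = 0
    chunked: bool = False

    def __post_init__(self) -> None:
        if self.compression == "gzip" and not self.chunked:
            raise ValueError("gzip-filtered datasets must be chunked")

    @property
    def name(self) -> str:
        return self.path.rsplit("/", 1)[-1]


class AttributeMap(dict):
    """Ordered map of attribute name -> (value, TypeDescriptor)."""


@dataclass
class Fast5Snapshot:
    """Full semantic content of one FAST5 file."""

    groups: set = field(default_factory=lambda: {"/"})
    datasets: dict = field(default_factory=dict)      # path -> DatasetNode
    attributes: dict = field(default_factory=dict)    # owner path -> AttributeMap

    def copy(self) -> "Fast5Snapshot":
        return Fast5Snapshot(
            groups=set(self.groups),
            datasets={p: replace(n, values=n.values) for p, n in self.datasets.items()},
            attributes={p: AttributeMap(a) for p, a in self.attributes.items()},
        )

    def dataset_paths(self) -> list:
        return sorted(self.datasets)

    def attrs_for(self, owner: str) -> AttributeMap:
        return self.attributes.setdefault(owner, AttributeMap())


@dataclass(frozen=True)
class FilterPolicy:
    """How the writer stores datasets.

    Datasets whose payload exceeds ``min_bytes_to_compress`` are chunked and
    GZIP-filtered at ``level``; smaller ones (and scalar datasets, which HDF5
    cannot chunk) are stored contiguous. ONT's acquisition software writes at
    level 1; compression rewrites at level 9. The byte-shuffle filter is off
    by default since only the GZIP level is part of the established behaviour.
    """

    level: int = 1
    min_bytes_to_compress: int = 512
    shuffle: bool = False

    #: single chunk below this size; above it, split on the leading axis
    single_chunk_limit: int = 4 * 1024 * 1024


#: ONT-like defaults (GZIP level 1) used by the fixture generator.
ONT_DEFAULT_POLICY = FilterPolicy(level=1)
#: Policy applied by all picoshrink compression modes.
COMPRESS_POLICY = FilterPolicy(level=9)


@dataclass(frozen=True)
class FastqRecord:
    id: str
    sequence: str
    quality: str

    def to_text(self) -> str:
        return f"@{self.id}\n{self.sequence}\n+\n{self.quality}\n"


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _attr_descriptor(obj, name: str) -> TypeDescriptor:
    aid = h5py.h5a.open(obj.id, name.encode("utf-8"))
    sinfo = h5py.check_string_dtype(aid.dtype)
    if sinfo is not None and sinfo.length is None:
        return TypeDescriptor("var_string")
    return TypeDescriptor.from_numpy(aid.dtype)


def _normalise_strings(values: np.ndarray, td: TypeDescriptor) -> np.ndarray:
    """Variable-length string payloads are held in memory as Python str."""
    if td.kind != "var_string":
        return values
    decode = lambda v: v.decode("utf-8") if isinstance(v, bytes) else str(v)
    if np.ndim(values) == 0:
        out = np.empty((), dtype=object)
        out[()] = decode(values[()] if isinstance(values, np.ndarray) else values)
        return out
    flat = np.array([decode(v) for v in np.asarray(values).ravel()], dtype=object)
    return flat.reshape(np.shape(values))


def load_snapshot(path) -> Fast5Snapshot:
    """Read an entire FAST5/HDF5 file into memory. Side-effect free."""
    path = os.fspath(path)
    if not h5py.is_hdf5(path):
        raise FormatError(f"not an HDF5 (FAST5) file: {path}")
    snap = Fast5Snapshot()
    try:
        with h5py.File(path, "r") as f:
            def record_attrs(owner: str, obj) -> None:
                amap = AttributeMap()
                for name in sorted(obj.attrs):
                    td = _attr_descriptor(obj, name)
                    amap[name] = (_normalise_strings(np.asarray(obj.attrs[name], dtype=object)
                                                     if td.kind == "var_string"
                                                     else obj.attrs[name], td), td)
                if amap:
                    snap.attributes[owner] = amap

            record_attrs("/", f)
            paths = []
            f.visit(paths.append)
            for rel in sorted(paths):
                abspath = "/" + rel
                obj = f[rel]
                if isinstance(obj, h5py.Group):
                    snap.groups.add(abspath)
                else:
                    td = TypeDescriptor.from_numpy(obj.dtype)
                    node = DatasetNode(
                        path=abspath,
                        values=_normalise_strings(obj[()], td),
                        dtype=td,
                        compression="gzip" if obj.compression == "gzip" else "none",
                        compression_level=obj.compression_opts or 0
                        if obj.compression == "gzip" else 0,
                        chunked=obj.chunks is not None,
                    )
                    snap.datasets[abspath] = node
                record_attrs(abspath, obj)
    except (OSError, RuntimeError) as exc:
        raise CorruptFileError(f"cannot read {path}: {exc}") from exc
    return snap


# ---------------------------------------------------------------------------
# Writing (repack)
# ---------------------------------------------------------------------------

def _check_representable(values: np.ndarray, td: TypeDescriptor, where: str) -> None:
    if td.kind in ("sint", "uint") and values.size:
        info = np.iinfo(td.to_numpy())
        vmin, vmax = values.min(), values.max()
        if vmin < info.min or vmax > info.max:
            raise EncodingError(
                f"{where}: values [{vmin}, {vmax}] do not fit {td.kind}{td.width_bytes * 8}")
    if td.kind == "fixed_string":
        arr = np.asarray(values)
        for v in arr.ravel() if arr.ndim else [arr[()]]:
            b = v if isinstance(v, bytes) else str(v).encode("utf-8")
            if len(b) > td.width_bytes:
                raise EncodingError(f"{where}: string longer than S{td.width_bytes}")


def _encode_values(values, td: TypeDescriptor) -> np.ndarray:
    arr = np.asarray(values)
    if td.kind == "compound":
        out = np.empty(arr.shape, dtype=td.to_numpy())
        for name, sub in td.fields:
            out[name] = _encode_values(arr[name], sub)
        return out
    if td.kind == "var_string":
        return arr  # object array of str; h5py handles vlen encoding
    if td.kind == "fixed_string":
        if arr.dtype.kind in ("O", "U"):
            conv = np.array(
                [s.encode("utf-8") if isinstance(s, str) else s for s in arr.ravel()]
                if arr.ndim else
                [arr[()].encode("utf-8") if isinstance(arr[()], str) else arr[()]],
                dtype=f"S{td.width_bytes}")
            return conv.reshape(arr.shape)
        return arr.astype(f"S{td.width_bytes}")
    return arr.astype(td.to_numpy())


def _payload_nbytes(node: DatasetNode) -> int:
    if node.dtype.kind == "var_string":
        arr = np.asarray(node.values)
        items = arr.ravel() if arr.ndim else [arr[()]]
        return sum(len(str(v).encode("utf-8")) for v in items)
    return _encode_values(node.values, node.dtype).nbytes


def _chunk_shape(shape: tuple, itemsize: int, policy: FilterPolicy) -> tuple:
    nbytes = itemsize * int(np.prod(shape))
    if nbytes <= policy.single_chunk_limit or shape[0] <= 1:
        return shape
    rows = max(1, policy.single_chunk_limit // max(1, nbytes // shape[0]))
    return (min(shape[0], rows),) + shape[1:]


def write_snapshot(snapshot: Fast5Snapshot, path,
                   filter_policy: FilterPolicy = ONT_DEFAULT_POLICY) -> int:
    """Write a snapshot as a fresh file; returns bytes written.

    Every non-scalar dataset whose payload exceeds the policy threshold is
    stored chunked with GZIP at the policy level. Writing is deterministic:
    objects are created in lexicographic path order and HDF5 object
    timestamps are disabled.
    """
    path = os.fspath(path)
    with h5py.File(path, "w", track_order=False) as f:
        for gpath in sorted(snapshot.groups):
            if gpath != "/":
                f.require_group(gpath)
        for dpath in sorted(snapshot.datasets):
            node = snapshot.datasets[dpath]
            _check_representable(np.asarray(node.values), node.dtype, dpath)
            data = _encode_values(node.values, node.dtype)
            kwargs = {"track_times": False}
            payload = _payload_nbytes(node)
            compressible = (np.ndim(data) >= 1 and data.size > 0
                            and node.dtype.kind != "var_string")
            if (compressible and filter_policy.level > 0
                    and payload > filter_policy.min_bytes_to_compress):
                kwargs.update(
                    chunks=_chunk_shape(data.shape, data.dtype.itemsize, filter_policy),
                    compression="gzip",
                    compression_opts=filter_policy.level,
                    shuffle=filter_policy.shuffle,
                )
            dt = node.dtype.to_numpy()
            f.create_dataset(dpath, data=data, dtype=dt, **kwargs)
        for owner in sorted(snapshot.attributes):
            amap = snapshot.attributes[owner]
            if owner not in snapshot.groups and owner not in snapshot.datasets:
                raise EncodingError(f"attribute owner {owner} has no object")
            obj = f["/"] if owner == "/" else f[owner]
            for name, (value, td) in amap.items():
                _check_representable(np.asarray(value), td, f"{owner}@{name}")
                enc = _encode_values(value, td)
                if td.kind == "var_string" and np.ndim(enc) == 0:
                    enc = enc[()]
                obj.attrs.create(name, enc, dtype=td.to_numpy())
    return os.path.getsize(path)


# ---------------------------------------------------------------------------
# Semantic equality
# ---------------------------------------------------------------------------

def _decoded(arr: np.ndarray) -> np.ndarray:
    flat = [v.decode("utf-8") if isinstance(v, bytes) else str(v)
            for v in (arr.ravel() if arr.ndim else [arr[()]])]
    return np.array(flat, dtype=object).reshape(arr.shape)


def _values_equal(a, b) -> bool:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    if a.dtype.names or b.dtype.names:
        if a.dtype.names != b.dtype.names:
            return False
        return all(_values_equal(a[n], b[n]) for n in a.dtype.names)
    if a.dtype.kind in "SOU" or b.dtype.kind in "SOU":
        return bool(np.array_equal(_decoded(a), _decoded(b)))
    if a.dtype.kind == "f" or b.dtype.kind == "f":
        return bool(np.array_equal(a.astype("<f8"), b.astype("<f8"), equal_nan=True))
    return bool(np.array_equal(a, b))


def _is_reserved(path: str) -> bool:
    return path == RESERVED_GROUP or path.startswith(RESERVED_GROUP + "/")


def semantic_equal(a: Fast5Snapshot, b: Fast5Snapshot, strict_types: bool = False) -> bool:
    """True iff two snapshots carry the same groups, dataset values and
    attribute values. ``strict_types`` additionally requires identical type
    descriptors; filter settings are never compared. The reserved provenance
    group is tool metadata and is excluded on both sides.
    """
    ga = {g for g in a.groups if not _is_reserved(g)}
    gb = {g for g in b.groups if not _is_reserved(g)}
    if ga != gb:
        return False
    da = {p: n for p, n in a.datasets.items() if not _is_reserved(p)}
    db = {p: n for p, n in b.datasets.items() if not _is_reserved(p)}
    if set(da) != set(db):
        return False
    for p, na in da.items():
        nb = db[p]
        if strict_types and na.dtype != nb.dtype:
            return False
        if not _values_equal(na.values, nb.values):
            return False
    aa = {o: m for o, m in a.attributes.items() if m and not _is_reserved(o)}
    ab = {o: m for o, m in b.attributes.items() if m and not _is_reserved(o)}
    if set(aa) != set(ab):
        return False
    for owner, ma in aa.items():
        mb = ab[owner]
        if set(ma) != set(mb):
            return False
        for name, (va, ta) in ma.items():
            vb, tb = mb[name]
            if strict_types and ta != tb:
                return False
            if not _values_equal(va, vb):
                return False
    return True


# ---------------------------------------------------------------------------
# FASTQ extraction
# ---------------------------------------------------------------------------

def _string_payload(node: DatasetNode) -> str:
    arr = np.asarray(node.values)
    items = arr.ravel() if arr.ndim else [arr[()]]
    parts = [v.decode("utf-8") if isinstance(v, bytes) else str(v) for v in items]
    return "".join(parts)


def parse_fastq_text(text: str, where: str = "<string>") -> list:
    """Parse 4-line FASTQ blocks into records."""
    lines = text.strip("\n").split("\n") if text.strip("\n") else []
    if len(lines) % 4 != 0:
        raise FastqParseError(f"{where}: {len(lines)} lines is not a multiple of 4")
    records = []
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i:i + 4]
        if not header.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
            raise FastqParseError(f"{where}: malformed record at line {i + 1}")
        records.append(FastqRecord(header[1:], seq, qual))
    return records


def _path_components(path: str) -> list:
    """Split an HDF5 path into semantic components, understanding the flat
    names produced by structure collapsing ('/' encoded as '.', literal dots
    escaped as '\\.')."""
    parts = []
    for seg in path.strip("/").split("/"):
        parts.extend(p.replace("\x00", ".") for p in
                     seg.replace("\\.", "\x00").split("."))
    return parts


def _matches_group(path: str, suffix: str) -> bool:
    return any(re.fullmatch(r"(EventDetection|Basecall_\w+)_" + re.escape(suffix), c)
               for c in _path_components(path))


def _has_analysis_group(path: str) -> bool:
    return any(re.fullmatch(r"(EventDetection|Basecall_\w+)_\d+", c)
               for c in _path_components(path))


def extract_fastq(snapshot: Fast5Snapshot, group_selector: Optional[str] = None) -> list:
    """Collect FASTQ records from every ``Fastq`` dataset in the snapshot.

    Works both on the native layout and on collapsed (flat-named) files.
    ``group_selector`` restricts extraction to the analysis group with that
    3-digit suffix. Returns ``[]`` when no FASTQ dataset exists.
    """
    records = []
    for path in sorted(snapshot.datasets):
        if _is_reserved(path):
            continue
        if _path_components(path)[-1] != "Fastq":
            continue
        if group_selector is not None and not _matches_group(path, group_selector):
            continue
        records.extend(parse_fastq_text(_string_payload(snapshot.datasets[path]), path))
    return records
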