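"""The compression techniques and their exact reversal.

Four techniques operate on :class:`~picoshrink.model.Fast5Snapshot` objects
as pure functions (the fifth, GZIP level 9, is applied by the writer's
filter policy):

* :func:`shrink_types` — retype every integer, float and string to the
  smallest width that represents the values exactly (ONT writes everything
  as 64-bit or variable-length);
* :func:`index_duplicates` — drop the mean/stdv/start/length columns from
  basecalled event tables whose rows duplicate a contiguous slice of the
  event-detection table, keeping only an index into that table;
* :func:`collapse_structure` — move every dataset to the root group under a
  flat name, freeing the per-group metadata slots HDF5 allocates;
* :func:`strip_intermediate` — irreversibly delete event-level intermediates,
  keeping raw signal, FASTQ and run metadata.

Reversible transforms record what they changed in a :class:`ProvenanceRecord`
which is serialised into the output file under the reserved group
``/.picoshrink``, so a compressed file is self-describing and
:func:`revert_snapshot` can reconstruct the original exactly.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import __version__
from .errors import IrreversibleModeError, ProvenanceError, StripRefusedError
from .model import (
    AttributeMap,
    DatasetNode,
    Fast5Snapshot,
    RESERVED_GROUP,
    TypeDescriptor,
)

log = logging.getLogger(__name__)

__all__ = [
    "ProvenanceRecord",
    "shrink_types",
    "collapse_structure",
    "index_duplicates",
    "strip_intermediate",
    "revert_snapshot",
    "attach_provenance",
    "read_provenance",
]

TOOL_MARKER = "picoshrink"
FORMAT_VERSION = 1
DEDUP_COLUMNS = ("mean", "stdv", "start", "length")

_PROV_DATASET = RESERVED_GROUP + "/provenance"


@dataclass
class ProvenanceRecord:
    """Everything needed to reverse a lossless or deep-lossless compression."""

    mode: str = "lossless"
    #: "datasets": path -> TypeDescriptor json; "attributes": owner -> {name: td json}
    original_dtypes: dict = field(default_factory=lambda: {"datasets": {}, "attributes": {}})
    #: flat path -> original path (deep mode only)
    original_paths: dict = field(default_factory=dict)
    #: flat attribute-owner token -> original owner group path (deep mode only)
    original_attr_owners: dict = field(default_factory=dict)
    #: full pre-collapse group list (deep mode only; restores empty groups)
    original_groups: list = field(default_factory=list)
    #: one entry per deduplicated basecall table
    dedup_links: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "tool": TOOL_MARKER,
            "version": __version__,
            "format_version": FORMAT_VERSION,
            "mode": self.mode,
            "original_dtypes": self.original_dtypes,
            "original_paths": self.original_paths,
            "original_attr_owners": self.original_attr_owners,
            "original_groups": self.original_groups,
            "dedup_links": self.dedup_links,
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ProvenanceRecord":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ProvenanceError(f"corrupt provenance record: {exc}") from exc
        if d.get("tool") != TOOL_MARKER:
            raise ProvenanceError("provenance record written by a different tool")
        if d.get("format_version") != FORMAT_VERSION:
            raise ProvenanceError(
                f"unknown provenance format version {d.get('format_version')!r}")
        return cls(
            mode=d["mode"],
            original_dtypes=d.get("original_dtypes", {"datasets": {}, "attributes": {}}),
            original_paths=d.get("original_paths", {}),
            original_attr_owners=d.get("original_attr_owners", {}),
            original_groups=d.get("original_groups", []),
            dedup_links=d.get("dedup_links", []),
        )


_ATTR_PAYLOAD_LIMIT = 16000  # HDF5 compact attributes must stay well below 64 KiB


def attach_provenance(snapshot: Fast5Snapshot, record: ProvenanceRecord) -> Fast5Snapshot:
    """Store the record inside the snapshot under the reserved group.

    The JSON payload normally lives in a fixed-string attribute of the
    reserved group (cheapest HDF5 representation for a few KiB, readable by
    any HDF5 tool); very large records fall back to a uint8 dataset, which
    the writer's GZIP filter then compresses.
    """
    snapshot.groups.add(RESERVED_GROUP)
    payload = record.to_json().encode("utf-8")
    if len(payload) <= _ATTR_PAYLOAD_LIMIT:
        snapshot.attrs_for(RESERVED_GROUP)["provenance"] = (
            np.bytes_(payload), TypeDescriptor("fixed_string", len(payload)))
    else:
        snapshot.datasets[_PROV_DATASET] = DatasetNode(
            _PROV_DATASET, np.frombuffer(payload, dtype="<u1").copy(),
            TypeDescriptor("uint", 1))
    return snapshot


def read_provenance(snapshot: Fast5Snapshot) -> Optional[ProvenanceRecord]:
    """Return the stored record, or None for a file this tool never touched."""
    amap = snapshot.attributes.get(RESERVED_GROUP)
    if amap and "provenance" in amap:
        raw, _ = amap["provenance"]
        raw = np.asarray(raw)[()] if np.ndim(raw) == 0 else raw
        text = raw.decode("utf-8") if isinstance(raw, bytes) else str(raw)
        return ProvenanceRecord.from_json(text)
    node = snapshot.datasets.get(_PROV_DATASET)
    if node is None:
        return None
    return ProvenanceRecord.from_json(
        np.asarray(node.values).astype("<u1").tobytes().decode("utf-8"))


def strip_provenance(snapshot: Fast5Snapshot) -> None:
    snapshot.groups.discard(RESERVED_GROUP)
    for p in [p for p in snapshot.datasets if p.startswith(RESERVED_GROUP)]:
        del snapshot.datasets[p]
    for o in [o for o in snapshot.attributes if o.startswith(RESERVED_GROUP)]:
        del snapshot.attributes[o]


# ---------------------------------------------------------------------------
# Dynamic memory allocation: minimal-width retyping
# ---------------------------------------------------------------------------

def _min_int_descriptor(values: np.ndarray) -> TypeDescriptor:
    vmin = int(values.min()) if values.size else 0
    vmax = int(values.max()) if values.size else 0
    kind = "uint" if vmin >= 0 else "sint"
    for width in (1, 2, 4, 8):
        info = np.iinfo(f"{'u' if kind == 'uint' else 'i'}{width}")
        if info.min <= vmin and vmax <= info.max:
            return TypeDescriptor(kind, width)
    return TypeDescriptor(kind, 8)


def _float_survives_f4(values: np.ndarray) -> bool:
    v = np.asarray(values, dtype="<f8")
    back = v.astype("<f4").astype("<f8")
    with np.errstate(invalid="ignore"):
        return bool(np.all((back == v) | (np.isnan(v) & np.isnan(back))))


def _max_string_bytes(values: np.ndarray) -> int:
    arr = np.asarray(values)
    items = arr.ravel() if arr.ndim else [arr[()]]
    longest = 0
    for v in items:
        b = v if isinstance(v, bytes) else str(v).encode("utf-8")
        longest = max(longest, len(b))
    return max(1, longest)


def _shrunk_descriptor(values, td: TypeDescriptor) -> TypeDescriptor:
    arr = np.asarray(values)
    if td.kind in ("sint", "uint"):
        return _min_int_descriptor(arr)
    if td.kind == "float":
        if td.width_bytes == 8 and _float_survives_f4(arr):
            return TypeDescriptor("float", 4)
        return td
    if td.kind in ("var_string", "fixed_string"):
        return TypeDescriptor("fixed_string", _max_string_bytes(arr))
    if td.kind == "compound":
        return TypeDescriptor("compound", None, tuple(
            (name, _shrunk_descriptor(arr[name], sub)) for name, sub in td.fields))
    return td


def _retype_values(values, old: TypeDescriptor, new: TypeDescriptor) -> np.ndarray:
    if new == old:
        return np.asarray(values)
    arr = np.asarray(values)
    if new.kind == "compound":
        out = np.empty(arr.shape, dtype=new.to_numpy())
        for (name, sub_new), (_, sub_old) in zip(new.fields, old.fields):
            out[name] = _retype_values(arr[name], sub_old, sub_new)
        return out
    if new.kind == "fixed_string":
        if arr.dtype.kind in ("O", "U"):
            items = arr.ravel() if arr.ndim else [arr[()]]
            enc = np.array([v.encode("utf-8") if isinstance(v, str) else v for v in items],
                           dtype=f"S{new.width_bytes}")
            return enc.reshape(arr.shape)
        return arr.astype(f"S{new.width_bytes}")
    if new.kind == "var_string":
        items = arr.ravel() if arr.ndim else [arr[()]]
        dec = np.array([v.decode("utf-8") if isinstance(v, bytes) else str(v)
                        for v in items], dtype=object)
        return dec.reshape(arr.shape)
    return arr.astype(new.to_numpy())


def shrink_types(snapshot: Fast5Snapshot):
    """Retype every dataset, attribute and compound field to minimal width.

    Integers move to the narrowest of 1/2/4/8 bytes covering their range
    (unsigned when the minimum is non-negative); 64-bit floats become 32-bit
    only when every value survives an exact 8→4→8 round trip; variable and
    fixed strings become fixed strings of the maximum encoded byte length.
    Values are never changed. Returns ``(snapshot', record_delta)`` where the
    delta maps each changed path to its original descriptor.
    """
    out = snapshot.copy()
    delta = {"datasets": {}, "attributes": {}}
    for path, node in out.datasets.items():
        if path.startswith(RESERVED_GROUP):
            continue
        new_td = _shrunk_descriptor(node.values, node.dtype)
        if new_td != node.dtype:
            delta["datasets"][path] = node.dtype.to_json()
            node.values = _retype_values(node.values, node.dtype, new_td)
            node.dtype = new_td
    for owner, amap in out.attributes.items():
        if owner.startswith(RESERVED_GROUP):
            continue
        for name in list(amap):
            value, td = amap[name]
            new_td = _shrunk_descriptor(value, td)
            if new_td != td:
                delta["attributes"].setdefault(owner, {})[name] = td.to_json()
                amap[name] = (_retype_values(value, td, new_td), new_td)
    return out, delta


def _unshrink(snapshot: Fast5Snapshot, delta: dict) -> None:
    for path, td_json in delta.get("datasets", {}).items():
        node = snapshot.datasets.get(path)
        if node is None:
            raise ProvenanceError(f"provenance names missing dataset {path}")
        orig = TypeDescriptor.from_json(td_json)
        node.values = _retype_values(node.values, node.dtype, orig)
        node.dtype = orig
    for owner, names in delta.get("attributes", {}).items():
        amap = snapshot.attributes.get(owner)
        if amap is None:
            raise ProvenanceError(f"provenance names missing attribute owner {owner}")
        for name, td_json in names.items():
            value, td = amap[name]
            orig = TypeDescriptor.from_json(td_json)
            amap[name] = (_retype_values(value, td, orig), orig)


# ---------------------------------------------------------------------------
# Collapsing of file structure
# ---------------------------------------------------------------------------

def flat_name(path: str) -> str:
    """Encode an absolute HDF5 path as a single flat component: literal dots
    are escaped as ``\\.`` and separators become dots."""
    return ".".join(seg.replace(".", "\\.") for seg in path.strip("/").split("/"))


def collapse_structure(snapshot: Fast5Snapshot):
    """Relocate every dataset (and group-owned attribute) to the root group.

    Groups cost HDF5 metadata slots; a collapsed file keeps only the root
    (plus the reserved provenance group). Dataset attributes travel with
    their dataset; attributes owned by non-root groups are re-attached to the
    root under ``<flat-owner>:<name>``. Name collisions get deterministic
    ``#<n>`` suffixes. Returns ``(snapshot', delta)`` with the flat→original
    path mappings.
    """
    out = Fast5Snapshot()
    original_paths: dict = {}
    original_attr_owners: dict = {}
    taken: set = set()

    def unique(flat: str) -> str:
        cand, n = flat, 1
        while cand in taken:
            n += 1
            cand = f"{flat}#{n}"
        taken.add(cand)
        return cand

    rename: dict = {}
    for path in sorted(snapshot.datasets):
        if path.startswith(RESERVED_GROUP):
            continue
        new_path = "/" + unique(flat_name(path))
        rename[path] = new_path
        node = snapshot.datasets[path]
        out.datasets[new_path] = DatasetNode(new_path, node.values, node.dtype,
                                             node.compression, node.compression_level,
                                             node.chunked)
        original_paths[new_path] = path

    root_attrs = AttributeMap(snapshot.attributes.get("/", AttributeMap()))
    for owner in sorted(snapshot.attributes):
        if owner == "/" or owner.startswith(RESERVED_GROUP):
            continue
        amap = snapshot.attributes[owner]
        if not amap:
            continue
        if owner in rename:  # dataset attributes move with the dataset
            out.attributes[rename[owner]] = AttributeMap(amap)
        else:  # group attributes land on the root with a prefixed name
            token = unique(flat_name(owner))
            original_attr_owners[token] = owner
            for name, entry in amap.items():
                root_attrs[f"{token}:{name}"] = entry
    if root_attrs:
        out.attributes["/"] = root_attrs
    return out, {"original_paths": original_paths,
                 "original_attr_owners": original_attr_owners,
                 "original_groups": sorted(g for g in snapshot.groups
                                           if not g.startswith(RESERVED_GROUP))}


def _uncollapse(snapshot: Fast5Snapshot, record: ProvenanceRecord) -> Fast5Snapshot:
    out = Fast5Snapshot()
    out.groups |= set(record.original_groups)

    def ensure_groups(path: str) -> None:
        parts = path.strip("/").split("/")
        for i in range(1, len(parts)):
            out.groups.add("/" + "/".join(parts[:i]))

    for flat_path, orig in sorted(record.original_paths.items()):
        node = snapshot.datasets.get(flat_path)
        if node is None:
            raise ProvenanceError(f"collapsed dataset {flat_path} missing")
        ensure_groups(orig)
        out.datasets[orig] = DatasetNode(orig, node.values, node.dtype,
                                         node.compression, node.compression_level,
                                         node.chunked)
        if flat_path in snapshot.attributes:
            out.attributes[orig] = AttributeMap(snapshot.attributes[flat_path])

    root = snapshot.attributes.get("/", AttributeMap())
    restored_root = AttributeMap()
    for name, entry in root.items():
        if ":" in name:
            token, attr_name = name.split(":", 1)
            owner = record.original_attr_owners.get(token)
            if owner is not None:
                out.groups.add(owner)
                ensure_groups(owner)
                out.attrs_for(owner)[attr_name] = entry
                continue
        restored_root[name] = entry
    if restored_root:
        out.attributes["/"] = restored_root
    # carry over anything outside the collapse mapping (e.g. reserved group)
    for path, node in snapshot.datasets.items():
        if path not in record.original_paths and path not in out.datasets:
            out.datasets[path] = node
            ensure_groups(path)
            out.groups.add(path.rsplit("/", 1)[0] or "/")
    for owner, amap in snapshot.attributes.items():
        if owner != "/" and owner not in record.original_paths and owner not in out.attributes:
            out.attributes[owner] = amap
            out.groups.add(owner) if owner not in out.datasets else None
    out.groups.discard("")
    return out


# ---------------------------------------------------------------------------
# Indexing of duplicated data
# ---------------------------------------------------------------------------

def _is_event_detection_table(path: str, node: DatasetNode) -> bool:
    if node.dtype.kind != "compound" or node.name != "Events":
        return False
    names = {n for n, _ in node.dtype.fields}
    return "EventDetection" in path and set(DEDUP_COLUMNS) <= names


def _is_basecall_table(path: str, node: DatasetNode) -> bool:
    if node.dtype.kind != "compound" or node.name != "Events":
        return False
    names = {n for n, _ in node.dtype.fields}
    return "Basecall" in path and set(DEDUP_COLUMNS) <= names and len(names) > 4


def find_duplicate_slice(ed_table: np.ndarray, bc_table: np.ndarray) -> Optional[int]:
    """Earliest start index s such that ed_table[s:s+len(bc)] equals bc_table
    on all four shared columns, element for element; None when no contiguous
    slice matches exactly."""
    m, n = len(bc_table), len(ed_table)
    if m == 0 or m > n:
        return None
    first = np.ones(n - m + 1, dtype=bool)
    for col in DEDUP_COLUMNS:
        first &= ed_table[col][: n - m + 1] == bc_table[col][0]
    for s in np.nonzero(first)[0]:
        if all(np.array_equal(ed_table[col][s:s + m], bc_table[col])
               for col in DEDUP_COLUMNS):
            return int(s)
    return None


def index_duplicates(snapshot: Fast5Snapshot):
    """Replace duplicated basecall-table columns with an index link.

    For every basecalled event table whose mean/stdv/start/length rows exactly
    duplicate one contiguous slice of the (unique) event-detection table,
    those four columns are dropped and a ``(slice start, row count)`` link is
    recorded; remaining columns (model_state, move, ...) stay. Tables with no
    exact match — or files with zero or several event-detection tables — are
    left untouched. Matching requires bit-exact value equality; approximate or
    rescaled duplicates are never indexed.
    """
    out = snapshot.copy()
    links: list = []
    ed_paths = [p for p, n in out.datasets.items() if _is_event_detection_table(p, n)]
    if len(ed_paths) != 1:
        if ed_paths:
            log.info("dedup skipped: %d event-detection tables", len(ed_paths))
        return out, links
    ed_path = ed_paths[0]
    ed_values = np.asarray(out.datasets[ed_path].values)
    for path in sorted(out.datasets):
        node = out.datasets[path]
        if not _is_basecall_table(path, node):
            continue
        table = np.asarray(node.values)
        start = find_duplicate_slice(ed_values, table)
        if start is None:
            log.info("dedup skipped for %s: no exact contiguous match", path)
            continue
        kept = tuple((n, td) for n, td in node.dtype.fields if n not in DEDUP_COLUMNS)
        new_td = TypeDescriptor("compound", None, kept)
        reduced = np.empty(len(table), dtype=new_td.to_numpy())
        for name, _ in kept:
            reduced[name] = table[name]
        links.append({
            "basecall_path": path,
            "event_detection_path": ed_path,
            "slice_start": start,
            "row_count": len(table),
            "removed_columns": list(DEDUP_COLUMNS),
            "table_dtype": node.dtype.to_json(),
        })
        node.values = reduced
        node.dtype = new_td
    return out, links


def _undedup(snapshot: Fast5Snapshot, links: list) -> None:
    for link in links:
        node = snapshot.datasets.get(link["basecall_path"])
        ed = snapshot.datasets.get(link["event_detection_path"])
        if node is None or ed is None:
            raise ProvenanceError("dedup link references a missing table")
        full_td = TypeDescriptor.from_json(link["table_dtype"])
        s, m = link["slice_start"], link["row_count"]
        ed_values = np.asarray(ed.values)[s:s + m]
        ed_td = dict(ed.dtype.fields)
        stored = np.asarray(node.values)
        full = np.empty(m, dtype=full_td.to_numpy())
        for name, sub in full_td.fields:
            if name in link["removed_columns"]:
                full[name] = _retype_values(ed_values[name], ed_td[name], sub)
            else:
                full[name] = stored[name]
        node.values = full
        node.dtype = full_td


# ---------------------------------------------------------------------------
# Removal of intermediate data (irreversible)
# ---------------------------------------------------------------------------

_ANALYSIS_GROUP_RE = re.compile(r"/Analyses/(?P<kind>\w+?)_(?P<suffix>\d{3})(?=/|$)")

#: dataset leaf names retained by raw mode (configurable)
DEFAULT_KEEP_DATASETS = ("Signal", "Fastq")


def strip_intermediate(snapshot: Fast5Snapshot, group_selector: Optional[str] = None,
                       keep_datasets: tuple = DEFAULT_KEEP_DATASETS):
    """Delete event-level intermediates, keeping signal, FASTQ and metadata.

    Retains the ``/Raw`` and ``/UniqueGlobalKey`` subtrees, root attributes,
    FASTQ datasets (restricted to the selected analysis group when a
    selector is given) and basecall summary attributes; deletes
    event-detection subtrees, per-event basecall tables and any other
    intermediate dataset, then prunes empty groups. Irreversible: no
    provenance is recorded for deleted data.
    """
    has_signal = any(p.startswith("/Raw/") and n.name == "Signal"
                     for p, n in snapshot.datasets.items())
    if not has_signal:
        raise StripRefusedError("no raw signal dataset; stripping would orphan the read")

    def analysis_info(path: str):
        m = _ANALYSIS_GROUP_RE.search(path)
        return (m.group("kind"), m.group("suffix")) if m else None

    def keep_dataset(path: str, node: DatasetNode) -> bool:
        if path.startswith(RESERVED_GROUP):
            return True
        if path.startswith("/Raw/") or path.startswith("/UniqueGlobalKey/"):
            return True
        info = analysis_info(path)
        if info is not None:
            kind, suffix = info
            if kind.startswith("EventDetection"):
                return False
            if group_selector is not None and suffix != group_selector:
                return False
            return node.name in keep_datasets and node.name != "Signal"
        return node.name in keep_datasets

    def keep_attr_owner(owner: str) -> bool:
        if owner == "/" or owner.startswith(RESERVED_GROUP):
            return True
        if owner == "/Raw" or owner.startswith("/Raw/"):
            return True
        if owner == "/UniqueGlobalKey" or owner.startswith("/UniqueGlobalKey/"):
            return True
        info = analysis_info(owner)
        if info is not None:
            kind, suffix = info
            if kind.startswith("EventDetection"):
                return False
            if group_selector is not None and suffix != group_selector:
                return False
            return True  # basecall group / summary attributes: small, kept
        return owner in snapshot.datasets  # attrs on kept datasets handled below

    out = Fast5Snapshot()
    for path, node in snapshot.datasets.items():
        if keep_dataset(path, node):
            out.datasets[path] = node
    for owner, amap in snapshot.attributes.items():
        if not amap:
            continue
        if owner in snapshot.datasets:
            if owner in out.datasets:
                out.attributes[owner] = AttributeMap(amap)
        elif keep_attr_owner(owner):
            out.attributes[owner] = AttributeMap(amap)

    needed = set()
    def add_ancestors(path: str) -> None:
        parts = path.strip("/").split("/")
        for i in range(1, len(parts) + 1):
            needed.add("/" + "/".join(parts[:i]))
    for path in out.datasets:
        add_ancestors(path.rsplit("/", 1)[0]) if "/" in path.strip("/") else None
    for owner in out.attributes:
        if owner != "/" and owner not in out.datasets:
            add_ancestors(owner)
    out.groups = {"/"} | {g for g in snapshot.groups if g in needed}
    # groups needed by kept datasets but absent from the original set (defensive)
    out.groups |= {g for g in needed if g not in out.datasets}
    return out


# ---------------------------------------------------------------------------
# Reversal
# ---------------------------------------------------------------------------

def revert_snapshot(snapshot: Fast5Snapshot) -> Fast5Snapshot:
    """Reconstruct the pre-compression snapshot exactly (strict type
    equality) from its embedded provenance; refuses on raw-mode files and on
    files this tool never produced."""
    record = read_provenance(snapshot)
    if record is None:
        raise ProvenanceError("no picoshrink provenance record; nothing to revert")
    if record.mode == "raw":
        raise IrreversibleModeError(
            "file was compressed with the irreversible raw mode; deleted "
            "intermediate data can be regenerated using basecalling software")
    out = snapshot.copy()
    if record.original_paths or record.original_attr_owners:
        out = _uncollapse(out, record)
    if record.dedup_links:
        _undedup(out, record.dedup_links)
    _unshrink(out, record.original_dtypes)
    strip_provenance(out)
    return out
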