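"""The compression techniques and their exact reversal."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import picoshrink.transforms as tr
from picoshrink.errors import IrreversibleModeError, ProvenanceError, StripRefusedError
from picoshrink.fixtures import generate_read_snapshot
from picoshrink.model import (
    DatasetNode,
    Fast5Snapshot,
    TypeDescriptor,
    extract_fastq,
    semantic_equal,
)
from tests.conftest import make_params


def _single_dataset(values, td):
    snap = Fast5Snapshot()
    snap.datasets["/x"] = DatasetNode("/x", np.asarray(values), td)
    return snap


# ---------------------------------------------------------------------------
# shrink_types
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("values,td,expected", [
    ([0, 100, 255], TypeDescriptor("sint", 8), TypeDescriptor("uint", 1)),
    ([-1, 127], TypeDescriptor("sint", 8), TypeDescriptor("sint", 1)),
    ([0, 65535], TypeDescriptor("sint", 8), TypeDescriptor("uint", 2)),
    ([-129, 0], TypeDescriptor("sint", 8), TypeDescriptor("sint", 2)),
    ([0, 2**32], TypeDescriptor("sint", 8), TypeDescriptor("uint", 8)),
    ([0.5, 1.25], TypeDescriptor("float", 8), TypeDescriptor("float", 4)),
    ([0.5, 0.1], TypeDescriptor("float", 8), TypeDescriptor("float", 8)),
])
def test_shrink_picks_minimal_numeric_width(values, td, expected):
    dtype = np.dtype(f"<f{td.width_bytes}") if td.kind == "float" else np.dtype("<i8")
    snap = _single_dataset(np.array(values, dtype=dtype), td)
    out, delta = tr.shrink_types(snap)
    assert out.datasets["/x"].dtype == expected
    assert semantic_equal(snap, out, strict_types=False)
    assert ("/x" in delta["datasets"]) == (expected != td)


def test_shrink_var_string_to_fixed_of_max_length():
    snap = _single_dataset(np.array(["ACGTT", "AC"], dtype=object),
                           TypeDescriptor("var_string"))
    out, _ = tr.shrink_types(snap)
    assert out.datasets["/x"].dtype == TypeDescriptor("fixed_string", 5)
    assert semantic_equal(snap, out)


def test_shrink_compound_fields_independently(fresh_2d):
    snap, _ = fresh_2d
    out, delta = tr.shrink_types(snap)
    ed_path = [p for p in out.datasets if "EventDetection" in p][0]
    fields = dict(out.datasets[ed_path].dtype.fields)
    # event means are generally not float32-exact; sample indices are small ints
    assert fields["mean"] == TypeDescriptor("float", 8)
    assert fields["start"].kind == "uint" and fields["start"].width_bytes <= 4
    assert semantic_equal(snap, out, strict_types=False)
    # reversal restores the exact original types
    restored = out.copy()
    tr._unshrink(restored, delta)
    assert semantic_equal(snap, restored, strict_types=True)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=-2**62, max_value=2**62), min_size=1, max_size=30))
def test_shrink_unshrink_integer_round_trip(values):
    snap = _single_dataset(np.array(values, dtype="<i8"), TypeDescriptor("sint", 8))
    out, delta = tr.shrink_types(snap)
    assert semantic_equal(snap, out, strict_types=False)
    info = np.iinfo(out.datasets["/x"].dtype.to_numpy())
    assert info.min <= min(values) and max(values) <= info.max
    tr._unshrink(out, delta)
    assert semantic_equal(snap, out, strict_types=True)


# ---------------------------------------------------------------------------
# collapse_structure
# ---------------------------------------------------------------------------

def test_collapse_flattens_and_records_paths(fresh_2d):
    snap, _ = fresh_2d
    out, delta = tr.collapse_structure(snap)
    assert out.groups == {"/"}
    fq_orig = "/Analyses/Basecall_2D_000/BaseCalled_2D/Fastq"
    fq_flat = "/" + tr.flat_name(fq_orig)
    assert fq_flat in out.datasets
    assert delta["original_paths"][fq_flat] == fq_orig
    assert set(delta["original_groups"]) == snap.groups


def test_collapse_identity_on_root_only():
    snap = Fast5Snapshot()
    snap.attrs_for("/")["a"] = (np.int64(1), TypeDescriptor("sint", 8))
    out, delta = tr.collapse_structure(snap)
    assert out.groups == {"/"} and not out.datasets
    assert dict(out.attributes["/"]) == dict(snap.attributes["/"])
    assert delta["original_paths"] == {}


def test_collapse_resolves_name_collisions_deterministically():
    snap = Fast5Snapshot()
    td = TypeDescriptor("sint", 8)
    # "/a.b" escapes to flat "a\.b"; the two-segment path "/a\" + "/b" joins
    # to the same byte sequence, forcing the deterministic "#n" suffix
    snap.groups.add("/a\\")
    snap.datasets["/a.b"] = DatasetNode("/a.b", np.array([1]), td)
    snap.datasets["/a\\/b"] = DatasetNode("/a\\/b", np.array([2]), td)
    assert tr.flat_name("/a.b") == tr.flat_name("/a\\") + "." + tr.flat_name("b")
    out, delta = tr.collapse_structure(snap)
    assert len(out.datasets) == 2
    assert set(delta["original_paths"].values()) == {"/a.b", "/a\\/b"}
    assert any(p.endswith("#2") for p in out.datasets)
    rec = tr.ProvenanceRecord(mode="deep_lossless", **delta)
    restored = tr._uncollapse(out, rec)
    assert semantic_equal(restored, snap, strict_types=True)


def test_collapsed_file_is_smaller_on_disk(tmp_path):
    from picoshrink.model import FilterPolicy, write_snapshot
    policy = FilterPolicy(level=9)
    total_nested = total_flat = 0
    for seed in range(3):
        snap, _ = generate_read_snapshot(make_params(seed=seed))
        flat, _ = tr.collapse_structure(snap)
        total_nested += write_snapshot(snap, tmp_path / f"n{seed}.fast5", policy)
        total_flat += write_snapshot(flat, tmp_path / f"f{seed}.fast5", policy)
    assert total_flat <= total_nested


def test_collapse_round_trip_strict(fresh_2d):
    snap, _ = fresh_2d
    out, delta = tr.collapse_structure(snap)
    rec = tr.ProvenanceRecord(mode="deep_lossless", **delta)
    assert semantic_equal(tr._uncollapse(out, rec), snap, strict_types=True)


# ---------------------------------------------------------------------------
# index_duplicates
# ---------------------------------------------------------------------------

def brute_force_slice(ed, bc):
    """Independent oracle: exhaustive scan over all contiguous slices,
    comparing rows as Python tuples."""
    cols = ("mean", "stdv", "start", "length")
    m, n = len(bc), len(ed)
    for s in range(n - m + 1):
        if all(tuple(ed[c][s + i] for c in cols) == tuple(bc[c][i] for c in cols)
               for i in range(m)):
            return s
    return None


def test_dedup_reduces_all_basecall_tables(fresh_2d):
    snap, manifest = fresh_2d
    out, links = tr.index_duplicates(snap)
    assert len(links) == len(manifest.dedup_slices) == 3
    for link in links:
        node = out.datasets[link["basecall_path"]]
        names = {n for n, _ in node.dtype.fields}
        assert names.isdisjoint(tr.DEDUP_COLUMNS)
        ed_path, start, count = manifest.dedup_slices[link["basecall_path"]]
        assert (link["event_detection_path"], link["slice_start"],
                link["row_count"]) == (ed_path, start, count)


def test_dedup_requires_exact_match(fresh_2d):
    snap, manifest = fresh_2d
    bc_path = sorted(manifest.dedup_slices)[0]
    node = snap.datasets[bc_path]
    perturbed = np.asarray(node.values).copy()
    perturbed["stdv"][len(perturbed) // 2] += 1e-9
    node.values = perturbed
    out, links = tr.index_duplicates(snap)
    assert bc_path not in {l["basecall_path"] for l in links}
    assert len(links) == 2  # the untouched tables still deduplicate
    assert dict(out.datasets[bc_path].dtype.fields)["stdv"]  # columns kept


def test_dedup_matches_brute_force_oracle(fresh_2d):
    snap, manifest = fresh_2d
    ed_path = next(iter(manifest.dedup_slices.values()))[0]
    ed = np.asarray(snap.datasets[ed_path].values)
    assert len(ed) <= 200
    for bc_path in manifest.dedup_slices:
        bc = np.asarray(snap.datasets[bc_path].values)
        assert tr.find_duplicate_slice(ed, bc) == brute_force_slice(ed, bc)
    # and on tables that do NOT match: shuffled rows
    bc = np.asarray(snap.datasets[sorted(manifest.dedup_slices)[0]].values).copy()
    rng = np.random.default_rng(0)
    rng.shuffle(bc)
    assert tr.find_duplicate_slice(ed, bc) == brute_force_slice(ed, bc)


def test_dedup_picks_earliest_of_ambiguous_matches():
    cols = [("mean", "<f8"), ("stdv", "<f8"), ("start", "<i8"), ("length", "<i8")]
    ed = np.zeros(10, dtype=cols)  # constant table: every slice matches
    bc = np.zeros(4, dtype=cols + [("model_state", "S5"), ("move", "<i8")])
    assert tr.find_duplicate_slice(ed, bc) == 0 == brute_force_slice(ed, bc)


def test_dedup_revert_rematerialises_tables(fresh_2d):
    snap, _ = fresh_2d
    out, links = tr.index_duplicates(snap)
    restored = out.copy()
    tr._undedup(restored, links)
    assert semantic_equal(restored, snap, strict_types=True)


# ---------------------------------------------------------------------------
# strip_intermediate
# ---------------------------------------------------------------------------

def test_strip_keeps_signal_and_fastq_only(fresh_2d):
    snap, _ = fresh_2d
    out = tr.strip_intermediate(snap)
    names = {node.name for node in out.datasets.values()}
    assert "Signal" in names and "Fastq" in names
    assert "Events" not in names
    assert extract_fastq(out) == extract_fastq(snap)
    # raw signal is untouched
    sig = [p for p in snap.datasets if p.endswith("/Signal")][0]
    assert np.array_equal(out.datasets[sig].values, snap.datasets[sig].values)
    # run metadata survives
    assert "/UniqueGlobalKey/tracking_id" in out.attributes
    # no empty analysis debris
    assert not any("EventDetection" in g for g in out.groups)


def test_strip_is_identity_on_pre_basecalled_file():
    snap, _ = generate_read_snapshot(make_params(include_basecall=False))
    out = tr.strip_intermediate(snap)
    assert semantic_equal(out, snap, strict_types=True)


def test_strip_refuses_without_signal(fresh_2d):
    snap, _ = fresh_2d
    sig = [p for p in snap.datasets if p.endswith("/Signal")][0]
    del snap.datasets[sig]
    with pytest.raises(StripRefusedError):
        tr.strip_intermediate(snap)


def test_strip_group_selector_drops_other_groups(fresh_2d):
    snap, _ = fresh_2d
    kept = tr.strip_intermediate(snap, group_selector="000")
    assert extract_fastq(kept) == extract_fastq(snap)
    dropped = tr.strip_intermediate(snap, group_selector="001")
    assert extract_fastq(dropped) == []
    assert not any("Basecall" in g for g in dropped.groups)


# ---------------------------------------------------------------------------
# revert_snapshot
# ---------------------------------------------------------------------------

def test_revert_refuses_untouched_file(fresh_2d):
    snap, _ = fresh_2d
    with pytest.raises(ProvenanceError):
        tr.revert_snapshot(snap)


def test_revert_refuses_raw_mode(fresh_2d):
    from picoshrink.pipeline import apply_mode
    snap, _ = fresh_2d
    raw = apply_mode(snap, "raw")
    with pytest.raises(IrreversibleModeError, match="basecalling"):
        tr.revert_snapshot(raw)


def test_revert_refuses_unknown_format_version(fresh_2d):
    from picoshrink.pipeline import apply_mode
    snap, _ = fresh_2d
    out = apply_mode(snap, "lossless")
    value, td = out.attributes[tr.RESERVED_GROUP]["provenance"]
    doctored = value.replace(b'"format_version": 1', b'"format_version": 99')
    out.attributes[tr.RESERVED_GROUP]["provenance"] = (np.bytes_(doctored), td)
    with pytest.raises(ProvenanceError, match="version"):
        tr.revert_snapshot(out)


@pytest.mark.parametrize("mode", ["lossless", "deep_lossless"])
def test_mode_round_trips_strictly(fresh_2d, mode):
    from picoshrink.pipeline import apply_mode
    snap, _ = fresh_2d
    compressed = apply_mode(snap, mode)
    restored = tr.revert_snapshot(compressed)
    assert semantic_equal(restored, snap, strict_types=True)
    assert extract_fastq(restored) == extract_fastq(snap)
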