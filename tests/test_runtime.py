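"""Input discovery, batch execution, real-time watching."""

import threading
import time

import pytest

from picoshrink.errors import ParameterError
from picoshrink.fixtures import generate_corpus, generate_read_snapshot
from picoshrink.model import ONT_DEFAULT_POLICY, load_snapshot, semantic_equal, write_snapshot
from picoshrink.pipeline import RunConfig
from picoshrink.runtime import discover_inputs, run_batch, summarize, watch_realtime
from tests.conftest import make_params


def test_discover_recursive_sorted_deduplicated(tmp_path):
    (tmp_path / "a" / "b").mkdir(parents=True)
    for rel in ("a/b/x.fast5", "a/y.fast5", "a/z.FAST5", "a/notes.fastq", "a/b/.hidden"):
        (tmp_path / rel).write_bytes(b"")
    found = discover_inputs([tmp_path / "a", tmp_path / "a" / "y.fast5"])
    assert [f.name for f in found] == ["x.fast5", "y.fast5", "z.FAST5"]


def test_discover_single_file_and_missing_path(tmp_path):
    f = tmp_path / "only.fast5"
    f.write_bytes(b"")
    assert discover_inputs([f]) == [f]
    with pytest.raises(ParameterError, match="nope"):
        discover_inputs([tmp_path / "nope"])


def _make_corpus(directory, n):
    return generate_corpus(directory, n, base_seed=50, params=make_params())


def test_batch_isolation_and_exit_code(tmp_path):
    paths = _make_corpus(tmp_path, 3)
    (tmp_path / "broken.fast5").write_bytes(b"\x89HDFgarbage")
    reports, code = run_batch(RunConfig(mode="lossless", inputs=(str(tmp_path),)))
    assert code == 1
    by_status = {r.status for r in reports}
    assert by_status == {"compressed", "skipped_error"}
    assert sum(r.status == "compressed" for r in reports) == 3
    s = summarize(reports)
    assert s["failed"] == 1 and s["processed"] == 3
    assert s["bytes_before"] == sum(r.bytes_before for r in reports
                                    if r.status == "compressed")


def test_thread_count_does_not_change_results(tmp_path):
    out = {}
    for threads in (1, 2):
        d = tmp_path / f"t{threads}"
        _make_corpus(d, 4)
        reports, code = run_batch(RunConfig(mode="deep_lossless", threads=threads,
                                            inputs=(str(d),)))
        assert code == 0
        out[threads] = {r.input_path.rsplit("/", 1)[-1]:
                        (r.bytes_before, r.bytes_after) for r in reports}
    assert out[1] == out[2]
    for name in out[1]:
        a = load_snapshot(tmp_path / "t1" / name)
        b = load_snapshot(tmp_path / "t2" / name)
        assert semantic_equal(a, b, strict_types=True)


def test_batch_prefix_outputs(tmp_path):
    paths = _make_corpus(tmp_path, 2)
    reports, code = run_batch(RunConfig(mode="lossless", prefix="shrunk",
                                        inputs=(str(tmp_path),)))
    assert code == 0
    for p in paths:
        assert (tmp_path / f"shrunk.{p.name}").exists()
        assert p.exists()


def _drain_watcher(config, stop, results, errors):
    try:
        for report in watch_realtime(config, stop_event=stop, poll_interval=0.05):
            results.append(report)
    except Exception as exc:  # pragma: no cover - surfaced in the test body
        errors.append(exc)


def test_realtime_catchup_new_files_and_no_feedback(tmp_path):
    _make_corpus(tmp_path, 1)  # present before start: catch-up pass
    config = RunConfig(mode="lossless", prefix="rt", inputs=(str(tmp_path),),
                       stability_window=0.15)
    stop, results, errors = threading.Event(), [], []
    t = threading.Thread(target=_drain_watcher, args=(config, stop, results, errors))
    t.start()
    try:
        snap, _ = generate_read_snapshot(make_params(seed=99))
        write_snapshot(snap, tmp_path / "new.fast5", ONT_DEFAULT_POLICY)
        deadline = time.monotonic() + 20
        while len(results) < 2 and time.monotonic() < deadline:
            time.sleep(0.05)
    finally:
        stop.set()
        t.join(timeout=10)
    assert not errors
    names = sorted(r.input_path.rsplit("/", 1)[-1] for r in results)
    assert names == ["new.fast5", "read_00050.fast5"]
    assert all(r.status == "compressed" for r in results)
    # prefixed outputs exist but were never re-processed as inputs
    assert (tmp_path / "rt.new.fast5").exists()
    assert not any(r.input_path.endswith("rt.new.fast5") for r in results)


def test_realtime_waits_for_stable_size(tmp_path):
    config = RunConfig(mode="lossless", prefix="rt", inputs=(str(tmp_path),),
                       stability_window=0.4)
    stop, results, errors = threading.Event(), [], []
    t = threading.Thread(target=_drain_watcher, args=(config, stop, results, errors))
    t.start()
    try:
        growing = tmp_path / "grow.fast5"
        growing.write_bytes(b"x")
        for _ in range(4):  # keep the file growing inside the window
            time.sleep(0.1)
            growing.write_bytes(growing.read_bytes() + b"x")
            assert results == []
    finally:
        stop.set()
        t.join(timeout=10)
    assert not errors
    assert results == []  # never became stable for a full window


def test_realtime_requires_directories(tmp_path):
    f = tmp_path / "x.fast5"
    f.write_bytes(b"")
    config = RunConfig(mode="lossless", realtime=True, inputs=(str(f),))
    with pytest.raises(ParameterError):
        next(iter(watch_realtime(config)))
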