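# Methods

## The file model

A FAST5 read file is loaded in full into a `Fast5Snapshot`: the set of group
paths, every dataset (values, element-type descriptor, filter settings) and
every attribute. All transforms are pure functions on snapshots; the only
I/O is `load_snapshot` / `write_snapshot`. Writing always produces a fresh
file in lexicographic path order with HDF5 object timestamps disabled, so a
given snapshot and filter policy yield a reproducible file and no
unreclaimed free space survives a rewrite.

Two snapshots are *semantically equal* when they have the same groups, the
same dataset paths with element-wise equal values, and the same attributes;
`strict_types=True` additionally requires identical type descriptors. Filter
settings are never compared — compression level is storage, not content.
Variable-length and fixed-length strings holding the same text compare equal
under the relaxed mode. The reserved provenance group `/.picoshrink` is
excluded from the comparison on both sides: it is tool bookkeeping, and
excluding it is what lets "lossless compression changes nothing" be stated
as a semantic-equality invariant even though the compressed file carries a
marker.

## Filter policy

Datasets whose payload exceeds `min_bytes_to_compress` (default 512 B) are
chunked and GZIP-filtered; smaller ones are stored contiguous, because chunk
and filter overhead inflates tiny datasets. Scalar datasets cannot be
chunked in HDF5 and are always contiguous. Chunk shape is the full dataset
below 4 MiB (single chunk maximises the GZIP context; single-read files are
small), else split on the leading axis. The generator writes at level 1 —
the acquisition software's default — and all compression modes write at
level 9. Byte-shuffle is available behind a flag but off by default: only
the GZIP level is part of the established behaviour, and shuffle changes the
on-disk bytes without reliably helping on these tables.

## Type shrinking

Integers are retyped to the narrowest of {1,2,4,8} bytes covering
`[min, max]`, unsigned when `min ≥ 0`. Doubles become floats only when every
value survives an exact 8→4→8 round trip, so the operation is lossless by
construction rather than by tolerance; a value like 0.1 keeps its column at
8 bytes. Variable-length strings become fixed strings of the maximum encoded
byte length (width 1 when all are empty) — fixed strings participate in
dataset-level GZIP, variable-length ones do not. Compound (table) fields are
shrunk independently. Empty datasets pass through unchanged. Every change is
recorded as `path → original descriptor` so reversal restores exact types,
not merely exact values.

## Duplicate indexing

Only tables that structurally qualify are considered: the event-detection
candidate is the unique compound `Events` dataset under an `EventDetection`
group (files with zero or several candidates are left alone), and basecall
candidates are compound `Events` datasets under `Basecall` groups carrying
the four shared columns plus at least one more. A basecall table is reduced
only when its `mean`/`stdv`/`start`/`length` rows equal a contiguous slice
of the event-detection table **bit-exactly**; approximate or unit-rescaled
matches (seconds vs sample counts) are never indexed — correctness is
preferred over ratio. Ambiguous matches (possible in constant tables) take
the earliest slice, deterministically. The stored link records the slice,
the removed column names and the full pre-reduction compound descriptor, so
reversal rebuilds the table even when the two tables' columns shrank to
different widths. The matcher is verified in the test suite against an
independent brute-force scan over all contiguous slices.

## Structure collapse

Flat names encode the original path with `/` → `.` and literal dots escaped
as `\.`; the rare residual collisions (possible when names contain
backslashes) get deterministic `#n` suffixes. Dataset attributes travel with
their dataset; attributes owned by non-root groups are re-attached to the
root as `<flat-owner>:<name>`. The full original group list, path map and
attribute-owner map go into provenance, so reversal restores the exact tree
including groups that owned nothing. Dedup runs before collapse, so dedup
links reference original paths; reversal un-collapses first, then
re-materialises columns, then restores types.

## Provenance

Reversal metadata is serialised as JSON and stored as a fixed-string
attribute named `provenance` on the reserved group `/.picoshrink` — the
cheapest faithful HDF5 representation at the few-kilobyte scale (an
attribute costs its payload plus a header message; a chunked dataset costs
kilobytes of B-tree and heap). Records larger than 16 kB fall back to a
uint8 dataset, which the GZIP filter then compresses; HDF5 compact
attributes must stay below 64 KiB. Type descriptors use compact numpy-style
codes (`u1`, `f8`, `S5`, `vlen`). The record carries a format version;
reverting refuses on unknown versions, on files with no record, and — with
a pointer to re-basecalling — on `raw`-mode files, which store only the
marker and mode. Files that already carry a marker are skipped by
compression regardless of mode; changing mode requires an explicit revert
first, since merging provenance across modes is deliberately unsupported.

## Intermediate removal (`raw`)

The keep-list is: the `/Raw` and `/UniqueGlobalKey` subtrees, root
attributes, `Fastq` datasets, and the attributes of basecall groups
(summaries are cheap and useful); `EventDetection` subtrees and all
per-event datasets are deleted and empty groups pruned. The leaf names kept
are configurable (`keep_datasets`). A file without a raw-signal dataset is
refused — stripping it would orphan the read. With `--group GGG` only the
selected analysis group's FASTQ is retained; if no group matches the
selector the file is stripped without group filtering and a warning is
logged, so a mistyped selector cannot silently delete the only FASTQ.

## Execution model

Batch runs discover `.fast5` files case-insensitively and recursively,
deduplicate, and process them in lexicographic order, one file per process
worker (`--threads`); per-file isolation means one corrupt file yields a
`skipped_error` report and a nonzero exit code but never aborts the batch.
In-place replacement writes to a temporary file in the same directory and
`os.replace`s it, so a crash never leaves a half-written file in place of
the original.

The real-time watcher polls the watched directories (default 0.5 s) and
processes a file once its size has been unchanged for the stability window
(default 5 s) — the acquisition software writes in bursts and offers no
completion signal, so size stability is the only portable criterion. Files
present at startup are handled by the same mechanism as a catch-up pass, and
prefixed outputs are excluded from discovery to prevent feedback loops.
Watcher outputs are identical to batch outputs for the same file set because
each file's processing is independent and deterministic.

## Synthetic data

The generator emulates the *storage* shape of an R7–R9.4-era single read:
int16 raw signal under `/Raw/Reads/Read_n/Signal`, an event-detection table
with float64 `mean`/`stdv` and 64-bit `start`/`length` (either integer
sample indices or float seconds — both conventions occur in real archives
and both are exercised), basecall groups (`1d`: template; `2d`: template,
complement and 2D) whose tables copy contiguous slices of the
event-detection table verbatim, a FASTQ whose sequence length equals
`k + Σ move` so annotation and sequence agree, variable-length string
attributes, and level-1 GZIP throughout. Defaults (2 000 events, 10 samples
per event, 5-mers) give files in the 120–230 kB range, the scale of real
reads of that era, so per-object HDF5 overhead plays the same minor role it
does in practice.

What it does **not** emulate: realistic pore-signal autocorrelation and
basecall error structure, the full attribute inventory of each chemistry
era, alignment/hairpin datasets of 2D basecalls, or multi-read FAST5. The
signal is a clipped Gaussian random walk and sequences are uniform random
DNA, which makes synthetic files *less* GZIP-compressible than real ones —
reduction percentages measured here are conservative relative to real data.
Passing tests therefore demonstrate exact reversibility, the retention
contracts, determinism and the relative ordering of the modes; they do not
certify absolute ratios on real runs.

## Evaluation

`benchmark.measure_corpus` copies the corpus per arm, compresses, and
records both the size of a deterministic POSIX-pax tarball (sorted members,
zeroed mtimes) and the summed per-file sizes; reductions are reported on
both, since the two aggregations can differ by tar padding. The external
gzip arm compresses the tarball at level 6, the gzip command-line default.
Per-megabase normalisation divides by total called bases extracted from the
files' FASTQ records. The dependent-sample t-test uses the closed form
`t = mean(d)/(sd(d)/√n)` with the n−1 sample standard deviation and n−1
degrees of freedom, two-sided p from the t distribution; zero-variance
differences are reported as a degenerate-data error rather than ±∞. The
test suite checks it against an independent reference implementation to
1e−10. Average reduction across corpora is the unweighted mean of
per-corpus tarball reductions.

`scripts/acceptance.py` runs this evaluation on four generated 40-file
corpora (1D/2D × both time conventions) plus round-trip checks on a mixed
20-file corpus with ≤200-row tables; the whole script completes in well
under a minute on one CPU, which is why these problem sizes were chosen.
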