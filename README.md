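# picoshrink

Storage compression for Oxford Nanopore FAST5 read files.

MinION-era sequencing writes one HDF5 container (`.fast5`) per read, and the
format is highly redundant: every numeric column is stored as a 64-bit type,
datasets are GZIP-compressed only at level 1, the group tree costs metadata
on disk, and the basecalled event tables duplicate the `mean`, `stdv`,
`start` and `length` columns of the event-detection table row for row. A run
of hundreds of thousands of reads therefore occupies far more disk than its
information content requires — a problem both on the acquisition laptop
during a run and on the lab file server afterwards.

picoshrink is for people who sit on directories of R7–R9.4-era single-read
FAST5 files: it shrinks them in place (or side by side), keeps them valid
HDF5, and — for the reversible modes — can reconstruct the original file
bit-exactly from metadata embedded in the compressed file.

## Modes

| mode | techniques | reversible |
|---|---|---|
| `lossless` | GZIP 1→9 repack + minimal-width retyping | yes, exactly |
| `deep-lossless` | lossless + event-table dedup + structure collapse | yes, exactly |
| `raw` | lossless + removal of event-level intermediates | no (re-basecall to regenerate) |

The core operations, in the field's usual terms:

* **Repack at GZIP 9.** Every dataset above a small threshold is rewritten
  chunked with the GZIP filter at level 9 (ONT writes level 1); the file is
  written fresh, so freed space is reclaimed, as `h5repack` would.
* **Minimal-width retyping.** An integer column with values in
  `[min, max]` is stored in the narrowest of 1/2/4/8 bytes whose range
  covers it (unsigned when `min ≥ 0`); a float64 column becomes float32 only
  when every value `x` satisfies `float64(float32(x)) == x`; variable-length
  strings become fixed strings of the maximum byte length. Values never
  change.
* **Duplicate indexing.** If the rows of a basecalled event table equal a
  contiguous slice `ed[s : s+m]` of the event-detection table on all four
  shared columns (bit-exact, earliest `s` on ties), those columns are
  dropped and `(s, m)` is stored instead; reversal re-materialises them.
* **Structure collapse.** All datasets move to the root group under flat
  names (`/Analyses/Basecall_2D_000/BaseCalled_2D/Fastq` →
  `Analyses.Basecall_2D_000.BaseCalled_2D.Fastq`), freeing per-group
  metadata. The original tree is recorded and restored on revert.
* **Intermediate removal** (`raw`). Event-detection and basecall event
  tables are deleted; the raw signal, the FASTQ and run metadata are kept
  byte for byte.

Reversal metadata lives inside the compressed file under the reserved group
`/.picoshrink` as a JSON attribute readable by any HDF5 tool; `--revert`
refuses politely on files produced by `raw` or by nothing at all.

## Worked example

No real data at hand? The package ships a generator for synthetic single-read
FAST5 files that reproduce the format's storage pathologies (64-bit columns,
level-1 GZIP, duplicated event columns, variable-length strings):

```sh
picoshrink fixtures --out corpus --n-files 4 --seed 7
picoshrink bench --corpus corpus
```

```text
arm	tar_bytes	file_bytes	tar_reduction_pct	file_reduction_pct	bytes_per_megabase
uncompressed	716800	702668	0.00	0.00	119148936.2
gzip	574847	702668	19.80	0.00	95553025.3
lossless	655360	648727	8.57	7.68	108936170.2
deep_lossless	450560	441714	37.14	37.14	74893617.0
raw	194560	190019	72.86	72.96	32340425.5
t[uncompressed_vs_lossless] = 6.87, p = 0.00631, df = 3
t[lossless_vs_deep_lossless] = 5.67, p = 0.0108, df = 3
t[deep_lossless_vs_raw] = 11.91, p = 0.00127, df = 3
```

Each `arm` is one treatment of the corpus: `tar_bytes` is the size of a
deterministic POSIX tarball of the treated files (`gzip` is the conventional
tar-then-gzip baseline, which does not compress individual files),
`*_reduction_pct` is `100·(1 − after/before)` against the untreated corpus,
and `bytes_per_megabase` normalises by the called bases so corpora of
different yield are comparable. The `t[...]` lines are dependent-sample
t-tests on per-file sizes between successive modes — positive `t` means the
first arm is larger.

Compressing for real, keeping the originals via a filename prefix:

```sh
picoshrink --mode deep-lossless --prefix shrunk corpus
```

```text
compressed	corpus/read_00007.fast5	145726 -> 90686 bytes
compressed	corpus/read_00008.fast5	224383 -> 135647 bytes
compressed	corpus/read_00009.fast5	207065 -> 129877 bytes
compressed	corpus/read_00010.fast5	125494 -> 85504 bytes
4/4 files processed (0 skipped, 0 failed): 702668 -> 441714 bytes
```

`picoshrink --revert shrunk.files...` restores the originals exactly.
`--threads N` processes N files in parallel; `--realtime` watches the input
directories and compresses each new file once its size has been stable for a
few seconds, so a sequencing run can be compressed as it happens.

The same operations are available as a library:

```python
from picoshrink import load_snapshot, compress_file, revert_file, RunConfig

report = compress_file("read.fast5", RunConfig(mode="deep_lossless"))
print(report.bytes_before, "->", report.bytes_after)
revert_file("read.fast5", RunConfig(revert=True))
```

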