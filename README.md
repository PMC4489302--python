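# rlfscan

Prediction and analysis of **R-loop forming sequences (RLFS)** in DNA or RNA.

R-loops are three-stranded nucleic acid structures that form
co-transcriptionally: a nascent G-rich RNA segment hybridizes with the DNA
template strand, displacing the non-template strand. They participate in
transcription regulation, class-switch recombination, DNA damage and genome
instability. `rlfscan` predicts where R-loops can initiate and elongate from
sequence alone, using a quantitative structural model of the non-template
strand, and is aimed at genomicists who want to annotate loci, whole genes or
chromosomes with candidate R-loop regions and compare them with experimental
data such as DRIP-seq.

## The structural model

An RLFS is a **RIZ–linker–REZ** configuration on the strand whose transcript
would form the hybrid:

```
m1:   G{n1} N{x} G{n1} N{x} G{n1}   N{y}     N{z}      RIZ >= 50% G
      \________ RIZ ________/      linker    REZ       REZ >= 40% G

m2:   G{n2} N{x} G{n2}             N{y}     N{z}
      \_____ RIZ _____/
```

* **RIZ** (R-loop initiation zone): G-clusters of `n1 >= 3` contiguous G
  (three clusters, model *m1*) or `n2 >= 4` contiguous G (two clusters, model
  *m2*), separated by spacers of `1 <= x <= 10` nt of any composition; the
  whole RIZ must be at least 50% guanine.
* **linker**: `0 <= y <= 50` nt, unconstrained composition.
* **REZ** (R-loop elongation zone): a window of `100 <= z <= 2000` nt with at
  least 40% guanine; it may itself contain further G-clusters.

For every RIZ the scanner enumerates all linker/window combinations and keeps
only the **longest** qualifying REZ, so each RIZ yields at most one RLFS.
Both strands are scanned (the minus strand via the reverse complement) and
hits are reported in forward-strand coordinates. All coordinates in every
output are **0-based, half-open** (the BED convention).

Overlapping predictions (>= 1 shared base) are grouped into **RLFS clusters**
(>= 2 connected members); a larger cluster suggests a higher propensity for
R-loop formation at the locus.

## Worked example

Generate a synthetic sequence with one planted RIZ–linker–REZ construct and
scan it, anchoring the local sequence at hg19-style chromosome coordinates:

```sh
python - <<'EOF'
from rlfscan import make_background, plant_rlfs
bg = make_background(1500, 0.2, seed=21)
s, _ = plant_rlfs(bg, 400, ("m1", (3, 4, 3), (2, 1)), linker_length=4,
                  rez_length=150, rez_g_target=0.42, strand="+", seed=6)
open("example.fasta", "w").write(f">demo\n{s}\n")
EOF
rlfscan scan --input example.fasta --out-dir demo_out \
             --chrom chr8 --chrom-start 128748315
```

prints the validation status, a per-sequence per-strand summary and a cluster
count:

```
demo    PASS
demo    1 RLFS (+: 1, -: 0)
total   1 RLFS in 0 cluster(s)
```

and writes four files to `demo_out/`: `rlfs_table.tsv` (per-record detail),
`rlfs.fasta` (the RLFS sequences), `rlfs.bed` (BED6 features) and
`rlfs_track.txt` (UCSC custom track). The table row for the planted record
(first columns):

```
seq_name  model  strand  rlfs_start  rlfs_end   riz_start  riz_end  riz_length  riz_g_pct  n_g_clusters
chr8      m1     +       128748714   128748907  128748714  128748727  13        76.92      3
```

The RIZ was planted at local position 400 (= chr8:128748714 in 0-based
coordinates after anchoring at 1-based start 128748315) with three G-tracts
(13 nt, 76.9% G); the scanner extended the planted 150-nt, 42%-G REZ into
flanking sequence to the longest window still above the 40% threshold
(175 nt at exactly 40.00% G), which is the model's defined behaviour.

Evaluating the model against curated experimental R-loop calls at 22 gene
loci (detected by R-loop foot-printing, electron microscopy, DRIP-qPCR,
DRIP-seq and RNase H assays; bundled in `rlfscan/data/`):

```sh
rlfscan evaluate --calls src/rlfscan/data/experimental_rloop_calls.tsv
```

```
calls   22
TP      17
FP      1
TN      3
FN      1
accuracy        91%     (0.909091)
sensitivity     94%     (0.944444)
specificity     75%     (0.750000)
```

## Library use

```python
from rlfscan import InputSequence, SearchParams, assemble_rlfs, cluster_records

records = assemble_rlfs(InputSequence("myc", residues), SearchParams())
clusters = cluster_records(records)
```

`SearchParams` exposes every model parameter (tract lengths, cluster counts,
gap/linker/REZ bounds, G-content thresholds, model and strand selection).
The `annotate` module adds coordinate remapping, region-overlap counting
against reference interval sets, confusion-matrix metrics from present/absent
call tables, and seeded sampling of signal-free negative regions for
specificity estimation. A flat `key = value` config file can preset any
parameter on the command line (`--config`); explicit flags take precedence
over the config file, which takes precedence over defaults.

## Scope

`rlfscan` is a sequence-pattern model: it does not model thermodynamics,
RNA secondary structure or supercoiling, and it performs no peak calling or
statistical enrichment testing on experimental data.
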