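# annodepth

A fully synthetic, end-to-end testable pipeline for studying how
**transcriptome annotation depth** (how many transcripts a species'
reference annotates) distorts **tpm** values, and how a **TMM**
(trimmed mean of M-values) correction restores cross-sample
comparability.

Everything runs on forged data — no downloads, no aligners. Reads are
abstract `(origin transcript, block)` pairs: blocks are shared sequence
segments, and a read's compatibility set against any annotation is the
set of annotated transcripts containing its block. That is enough to
reproduce the mechanisms of interest:

* **Denominator inflation** — removing annotated transcripts shrinks
  `S = Σ xᵢ/yᵢ`, inflating every surviving transcript's
  `tpmᵢ = 10⁶ (xᵢ/yᵢ)/S`.
* **Read competition** — dropping a paralog or isoform hands its
  ambiguous reads to the survivors (multi-modal tpm across annotation
  replicates; inflated low-expression genes in "pre-clinicalized"
  annotations).
* **Gene-length drift** — padding a gene's annotated length with
  unexpressed sequence deflates its tpm by a closed-form amount.
* **Depth disparity** — thinning a sample's reads shifts the
  reported-gene tpm comparison; TMM on the orthologous, `tpm > 1`
  gene set recenters the log-difference distributions at ~0.

## Layout

| module | contents |
| --- | --- |
| `annodepth.synthetic_data` | transcriptome forging (isoform counts, paralog families, shared blocks), expression truth, read simulation, depth thinning, species profiles |
| `annodepth.quantify` | EM read assignment over compatibility classes, tpm computation, gene-level summaries |
| `annodepth.annotation_ops` | subsampling sweep (1–99% × reps with a re-inserted control set), paralog removal, pre-clinicalization, gene-length variation |
| `annodepth.normalize` | TMM from its defining formulas, cross-species correction, housekeeping-panel check |
| `annodepth.stats` | stratified control-gene selection, sweep log-difference tables, Kruskal–Wallis + Dunn + Benjamini–Hochberg, denominator diagnostics, inflated-gene characterisation with permutation nulls |
| `annodepth.tableio` / `config` / `experiments` / `cli` | TSV/FASTA dialects, YAML configs with explicit seeds and hashes, the five named experiments, the `annodepth` CLI |

## CLI

```bash
annodepth forge --seed 1 --out results/forge        # transcriptome + truth + reads
annodepth run sweep --seed 1 --out results          # depth sweep + significance
annodepth run preclinicalize --seed 1 --out results # per-gene transcript reduction
annodepth run correction --seed 1 --out results     # thinning + TMM rescue
annodepth run paralogs --seed 1 --out results
annodepth run history --seed 1 --out results
annodepth run sweep --scale paper ...               # full 9,900-annotation protocol
```

`--scale desk` (default) runs a CI-sized protocol (500 genes,
10 fractions × 20 reps, 10⁵ reads); `--scale paper` uses the full
protocol (1–99% × 100 reps; 4 species × 100 reps). A YAML config
(`--config`) overrides any parameter; every output table is stamped with
the config hash and seed, and identical config + seed reproduce
byte-identical tables.

There are also single-stage commands (`annodepth quantify`,
`annodepth normalize`, `annodepth stats`) operating on the TSV dialects.

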