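# cellver

Local version control for engineered cell lines, with chromosomal DNA
barcodes that physically link a living sample to its digital history.

Strain engineering produces a long trail of digital information — genotypes,
protocols, sequencing results, storage locations — that is rarely organized,
and almost never attached to the physical sample in the freezer. `cellver`
treats a cell-line project like a software project: a **repository** of
**commits** on **branches**, where each commit records one engineering step.
Milestone commits additionally receive a short, synthesizable **DNA barcode**
whose payload is the commit's unique identifier. Insert that barcode into a
stable chromosomal locus, and any later PCR + sequencing of the barcode
region identifies the exact commit — and with it the complete record of what
the strain is.

The package is a library (no command-line tool); `examples/` contains one
short runnable script per capability.

## What it provides

* **`cellver.repo`** — a file-backed store of repositories, branches and
  commits (canonical JSON on disk; 40-bit Crockford base-32 identifiers;
  keyword and error-tolerant DNA search; public/team/private visibility).
* **`cellver.codec`** — a deterministic, invertible mapping between commit
  identifiers and DNA inserts. Layout: an 8-bit whitening-seed header
  (homopolymer-free base-3 encoding) followed by the 40-bit payload and a
  CRC-16/CCITT checksum, XOR-whitened and written 2 bits/base. Seeds are
  searched in order until the insert satisfies GC bounds (0.40–0.60),
  maximal homopolymer run (3) and a both-strand restriction-site screen.
  Decoding corrects up to 2 substitutions and refuses to guess on ties.
* **`cellver.sites`** — insertion-site selection from GFF3 + FASTA: intergenic
  gaps flanked by essential genes (adjacency mode) or inside clusters of
  near-adjacent essential genes (cluster mode), screened for annotated
  features and for presence in other laboratory strains, then ranked;
  homology-arm cassette design.
* **`cellver.recovery`** — paired-read merging, flank-anchored barcode
  extraction, majority-vote commit recovery, and a per-position variant
  table over the barcode amplicon with an inclusive minimum variant
  frequency of 0.5 and the per-read change fraction
  `n_reads_with_any_change / n_reads`.
* **`cellver.simulate`** — seeded generators: annotated genomes with a
  planted insertion site, barcoded strains, exponential PCR with lineage
  tracking (a forced mutation in cycle *c* reaches exactly 2^-c of the final
  pool), Wright-Fisher passaging, and FASTQ read sampling with an error
  model.

## Worked example

`python examples/05_stability_analysis.py` prints:

```
jackpot control: 49.71% of reads changed (model predicts 50% = 2^-1); top variant frequency 0.4971
after passaging: 0.0000% of reads changed (barcode sequence stable)
```

The first line is the classic PCR-jackpot signature: a single polymerase
error in the first amplification cycle is inherited by half of all product
molecules, so ~50% of reads differ from the reference even though every cell
in the culture is unmutated. The second line shows a passaged population
(70 generations at a realistic per-base mutation rate) whose barcode reads
back essentially unchanged. `examples/04_recover_identity.py` closes the
loop end to end:

```
merged 50/50 pairs (0 unmerged)
recovered commit CMK9W39Q with support 50/50, mean decode distance 0.06
matches committed uid: True
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch through the public API, the two simulation-scale
headline numbers: **t1**, the percentage of amplicon reads changed after a
forced cycle-1 mutation in a 20-cycle PCR (10,000 sampled reads), and
**t2**, the percentage of merged reads showing any change when 100,000 reads
of an unmutated 150 nt amplicon carry a residual per-base error of 1e-6.
Results are written as JSON with the problem size used for each target.

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
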