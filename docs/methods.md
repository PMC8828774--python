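# Methods

This note documents the models, numerical choices and open design decisions
behind `cellver`, in the spirit of a package's methods appendix. It states
nothing the test suite or `scripts/acceptance.py` does not itself compute.

## Version-control model

A store is a directory of repositories; each repository holds named branches,
and each branch an append-only list of commits. A commit has exactly one
parent (the branch tip at creation time, or the branch's origin commit for
the first commit on a non-root branch); the graph is therefore a tree and
merging is deliberately unsupported — laboratory strain histories fork, they
do not merge. Acyclicity and single-parenthood are re-verified on every
store load.

Identifiers are 40-bit random values rendered as 8 Crockford base-32
characters (no I/L/O/U, so a uid can be read off a tube label without
ambiguity) and collision-checked against the store. 40 bits gives a
birthday-collision probability of ~5·10⁻³ only after a million commits,
far beyond a laboratory's scale, while staying short enough to fit the
barcode payload.

All on-disk JSON is canonical (sorted keys, two-space indent, UTF-8, LF,
trailing newline) so a save/load/save cycle is byte-identical and content
digests are stable. Visibility (public/team/private) is enforced against a
caller identity passed to `search`; in a local store this is advisory —
access control backed by authentication is a hosted-service concern and out
of scope.

## Barcode codec

The insert layout is `seed ‖ payload ‖ CRC-16(seed ‖ payload)` with the
payload+checksum bits XOR-whitened by a pad derived from the seed
(SHA-256 of a fixed label plus the seed, extended counter-mode as needed)
and written 2 bits/base. The 8-bit seed header is encoded base-3 with the
digit selecting among the three bases that differ from the previous base,
so the header itself can never form a homopolymer.

Whitening turns constraint satisfaction into a bounded deterministic search:
seeds are tried in ascending order and the first insert that passes all
composition constraints wins, so `encode` is a pure function of
`(uid, spec)`. Constraints checked on the insert: GC fraction within
[0.40, 0.60]; homopolymer runs ≤ 3; none of a configurable set of common
restriction-enzyme recognition sites on either strand. Across the
flank–insert junctions of the full cassette, the run-length and motif rules
are re-checked (GC is a composition property of the insert and is not
applied to the fixed flanks). The default 20-nt flanks satisfy the same
constraints and double as priming anchors for amplicon recovery. With the
default widths the insert is 34 nt and the cassette 74 nt.

**Decoding and the canonical-codeword rule.** A sequence is accepted as a
codeword only if (a) its header parses, (b) the CRC verifies, and (c)
re-encoding the decoded uid reproduces the sequence exactly. Rule (c) is
stronger than CRC validity alone and exists for a concrete reason: a
substitution inside the seed header changes the whitening pad wholesale, so
the un-whitened payload behind a corrupted header is effectively random and
would pass the CRC with probability 2⁻¹⁶. Restricting validity to the image
of `encode` removes that failure mode; the exhaustive audit in the test
suite (16-bit payload spec, all 65,536 uids × all 66 single substitutions)
finds zero mis-decodes. Error correction enumerates the Hamming ball
(substitutions only) up to `max_correct` (default 2) and reports two valid
codewords at the minimal distance as undecodable rather than guessing.
Indel-bearing reads are handled upstream by alignment, keeping the codeword
space analyzable.

CRC-16/CCITT-FALSE (poly 0x1021, init 0xFFFF) was chosen as a standard,
easily re-implementable checksum; the implementation is verified against the
published check value 0x29B1.

## Insertion-site selection

Coordinates are GFF3 1-based inclusive at every interface; internal
arithmetic is 0-based half-open; BED export is 0-based half-open. Genes are
features of configurable type (default `gene`); everything else is retained
for the feature-overlap screen.

Adjacency mode emits the gap `[left.end+1, right.start−1]` for every
consecutive essential pair; cluster mode does the same for every gap inside
a run of genes bounded by an essential pair and containing only
non-essential genes (at most `max_intervening`, default 3). A gap is
discarded if it intersects any gene body (closed intervals), or if its
length falls outside [50, 1000] nt — the lower bound fits a default cassette
without touching either gene, the upper bound keeps the locus tight; the
quantitative bounds are this package's choice, as is the cluster-size limit.
In cluster mode the reported flanking pair is the *bounding essential pair*,
since the selective rationale (deleting the region removes an essential
neighbourhood) attaches to the cluster, not to the immediate neighbours of
one gap.

Gene-name curation runs exact-id → exact-name → case-insensitive name →
synonym, reports every unmatched raw name, and excludes names that match
two or more genes as ambiguous. The matching order is a design choice; the
principle is only that curation must be explicit and lossless.

The conservation screen is a local nucleotide presence check: exact 15-mer
seeding on both strands followed by full-diagonal (ungapped) evaluation;
a strain counts as present at coverage ≥ 0.9 and identity ≥ 0.9. This
replaces a remote protein-level database search with an offline check that
has the same decision semantics (present/absent per strain) and needs no
network. It will miss homologs that are conserved only at the protein level
or rearranged — a stated limitation, not a target.

Ranking is deterministic: no feature overlap, then fewer intervening
non-essential genes, then more strains conserved, then length closest to a
200 nt target, with (contig, coordinate) tie-breaks; the weights are
configurable but default to a strict lexicographic-like hierarchy.
Orientations of the flanking genes are reported, not filtered on.

## Amplicon analysis

Pair merging reverse-complements mate 2 and scans all suffix–prefix overlaps
of length ≥ 20, scoring matches − mismatches and requiring ≥ 0.75 identity
within the overlap (random unrelated mates have expected identity 0.25, so
this cleanly separates genuine overlaps from noise; the exact threshold is a
package choice). Disagreements resolve to the higher-quality base, ties to
mate 1, and are counted per merged read.

Reads are aligned to the reference amplicon with an exact global affine-gap
DP (match +1, mismatch −1, gap open −2, gap extend −1) — amplicons are short,
so a heuristic mapper would add nondeterminism for no speed benefit.
Identical read sequences are aligned once and weighted by multiplicity.
Per-position counts satisfy `A+C+G+T+del = coverage ≤ n_reads` at every
position; insertions are keyed to the reference position they follow and do
not consume coverage, which keeps that conservation law checkable. A read
counts as changed iff its alignment contains at least one mismatch or gap;
the analyzer counts the aligned barcode region only. Variants are called at
frequency ≥ 0.5, *inclusive* — a 5/10 alternative is called, a 4/10 one is
not. Where a one-base indel sits in a homopolymer the gap placement within
the run is alignment-convention-dependent; counts and the per-read change
indicator are unaffected.

Commit recovery is per-read (flank location within ≤ 2 mismatches per flank
on either strand, then decode with correction, then store lookup) aggregated
by majority vote; tied support is flagged ambiguous and broken toward the
lexicographically smallest identifier, and identifiers that decode but are
unknown to the store are reported distinctly rather than dropped.

## Simulators and what a green test establishes

PCR is modelled at perfect per-cycle efficiency: every molecule is copied
once per cycle and originals never retro-mutate. Under this minimal model a
forced mutation in one copy event of cycle *c* is inherited by exactly
2^−c of the final pool — the "jackpot" arithmetic behind the 50% read-change
control — and the multiplicity ledger sums to exactly 2^cycles. Stochastic
mode applies one substitution per mutated copy, a good approximation at
per-copy error rates ≪ 1/length; cycle counts and polymerase error rates
are package defaults (20 cycles), as no canonical values exist at desk
scale. Passaging is Wright-Fisher resampling with per-offspring mutation
(substitutions only by default; indels are an opt-in stressor). Read
sampling is multiplicity-weighted and uniform — no GC, length or position
bias, no chimeras, no realistic quality profiles. Green tests therefore
establish the *accounting* (lineage fractions, thresholds, round trips,
coordinate arithmetic) on an idealized sequencer, not performance on real
instrument noise.

All generators are pure functions of (parameters, seed); fixtures used in
tests are regenerated at run time, never stored.

## Acceptance targets

`scripts/acceptance.py` recomputes two headline numbers end to end:

* **t1** — forced cycle-1 substitution, 20 cycles, 10,000 error-free reads
  of the cassette amplicon; reports `100 × read_mutation_fraction`. The
  model predicts 50% exactly in the pool; the sampled value carries binomial
  noise of ±~1 point at n = 10⁴.
* **t2** — 100,000 reads of an unmutated 150 nt amplicon at a residual
  per-base substitution rate of 10⁻⁶; expected changed-read fraction
  `1 − (1−10⁻⁶)¹⁵⁰ ≈ 0.015%`, comfortably below the 0.05% bound.

Both derive every input from `--seed` and touch nothing outside the
repository.

## Known limitations

* No merge/rebase semantics; no authentication; visibility is advisory.
* The codec corrects substitutions only; indels must be resolved upstream.
* The conservation screen is nucleotide-level and ungapped.
* Simulators omit instrument error profiles, coverage bias and chimeras.
* `min_variant_frequency` interacts with sampling noise near the boundary:
  a true 50% variant is called in only about half of finite samples — the
  read-change fraction, not the call, is the stable statistic there.
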