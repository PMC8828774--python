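"""Recover commit identity from sequencing reads and quantify barcode stability.

The pipeline mirrors a standard amplicon workflow: merge read pairs on their
overlap, anchor the barcode between its known flanks, decode it back to a
commit identifier, and — for stability analysis — align every merged read to
the reference amplicon and tabulate per-position variant frequencies plus the
fraction of reads carrying any change.

Alignment is an exact global affine-gap dynamic program (Biopython's
PairwiseAligner); amplicons are short, so there is no need for a heuristic
mapper and results are fully deterministic.  Variant calling uses an
inclusive minimum-variant-frequency threshold (default 0.5): an alternative
observed in exactly half the reads *is* called.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, SeqIO

from . import codec
from .util import revcomp, uid_to_str

__all__ = [
    "AnalyzerConfig",
    "Read",
    "ReadSet",
    "MergedRead",
    "VariantTable",
    "RecoveryResult",
    "AnalysisError",
    "FlankNotFoundError",
    "merge_pairs",
    "locate_barcode",
    "recover_commit",
    "variant_table",
    "sanger_verify",
    "read_fastq",
    "read_paired_fastq",
    "read_fasta",
]


class AnalysisError(ValueError):
    pass


class FlankNotFoundError(AnalysisError):
    pass


@dataclass(frozen=True)
class AnalyzerConfig:
    min_variant_frequency: float = 0.5
    min_overlap: int = 20
    max_flank_mismatch: int = 2
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    #: minimum fractional identity within the read-pair overlap for a merge
    #: to qualify (random unrelated mates sit near 0.25)
    min_overlap_identity: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.min_variant_frequency <= 1:
            raise ValueError("min_variant_frequency must be in (0, 1]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = self.match_score
        aligner.mismatch_score = self.mismatch_score
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        return aligner


@dataclass
class Read:
    read_id: str
    sequence: str
    quality: list[int] | None = None
    mate: "Read | None" = None


@dataclass
class ReadSet:
    reads: list[Read]

    def __iter__(self):
        return iter(self.reads)

    def __len__(self):
        return len(self.reads)


@dataclass
class MergedRead:
    read_id: str
    sequence: str
    overlap_len: int
    disagreements_resolved: int


# ---------------------------------------------------------------------------
# FASTQ / FASTA input

def _open_text(path: str | Path):
    path = Path(path)
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path)


def _strip_mate_suffix(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def read_fastq(path: str | Path) -> list[Read]:
    with _open_text(path) as fh:
        return [
            Read(
                read_id=_strip_mate_suffix(rec.id),
                sequence=str(rec.seq).upper(),
                quality=list(rec.letter_annotations.get("phred_quality", [])) or None,
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def read_paired_fastq(path_r1: str | Path, path_r2: str | Path) -> ReadSet:
    """Pair two FASTQ files one-to-one by read id (``/1``/``/2`` stripped)."""
    r1 = read_fastq(path_r1)
    r2 = {r.read_id: r for r in read_fastq(path_r2)}
    if len(r2) != len(r1) or any(r.read_id not in r2 for r in r1):
        raise AnalysisError("read1/read2 ids do not pair one-to-one")
    for r in r1:
        r.mate = r2[r.read_id]
    return ReadSet(reads=r1)


def read_fasta(path: str | Path) -> list[Read]:
    with _open_text(path) as fh:
        return [
            Read(read_id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(fh, "fasta")
        ]


# ---------------------------------------------------------------------------
# pair merging

def merge_pairs(
    readset: ReadSet | Sequence[Read], config: AnalyzerConfig | None = None
) -> tuple[list[MergedRead], list[str]]:
    """Merge mate pairs on their best ungapped overlap.

    Mate 2 is reverse-complemented; the maximal-scoring suffix/prefix overlap
    of length >= ``min_overlap`` is taken (score = matches − mismatches, ties
    to the longer overlap).  Overlap disagreements are resolved toward the
    higher-quality base (ties, or missing qualities, toward mate 1) and
    counted.  Pairs with no overlap reaching ``min_overlap_identity`` are
    returned in the unmerged report.
    """
    config = config or AnalyzerConfig()
    merged: list[MergedRead] = []
    unmerged: list[str] = []
    for read in readset:
        if read.mate is None:
            raise AnalysisError(f"read {read.read_id} has no mate")
        s1, q1 = read.sequence, read.quality
        s2 = revcomp(read.mate.sequence)
        q2 = list(reversed(read.mate.quality)) if read.mate.quality else None
        best: tuple[float, int] | None = None  # (score, overlap)
        max_o = min(len(s1), len(s2))
        for o in range(config.min_overlap, max_o + 1):
            a, b = s1[-o:], s2[:o]
            matches = sum(x == y for x, y in zip(a, b))
            if matches / o < config.min_overlap_identity:
                continue
            score = 2 * matches - o  # matches - mismatches
            if best is None or (score, o) > best:
                best = (score, o)
        if best is None:
            unmerged.append(read.read_id)
            continue
        o = best[1]
        head, tail = s1[:-o] if o < len(s1) else "", s2[o:]
        overlap = []
        disagreements = 0
        for i in range(o):
            b1, b2 = s1[len(s1) - o + i], s2[i]
            if b1 == b2:
                overlap.append(b1)
                continue
            disagreements += 1
            p1 = q1[len(s1) - o + i] if q1 else None
            p2 = q2[i] if q2 else None
            if p1 is not None and p2 is not None and p2 > p1:
                overlap.append(b2)
            else:
                overlap.append(b1)  # tie or missing quality -> mate 1
        merged.append(
            MergedRead(
                read_id=read.read_id,
                sequence=head + "".join(overlap) + tail,
                overlap_len=o,
                disagreements_resolved=disagreements,
            )
        )
    return merged, unmerged


# ---------------------------------------------------------------------------
# flank-anchored barcode extraction

def _best_flank_match(seq: str, flank: str, start_from: int = 0) -> tuple[int, int]:
    """(position, mismatches) of the best ungapped flank match at/after start_from."""
    n, m = len(seq), len(flank)
    if n - start_from < m:
        return -1, m + 1
    arr = np.frombuffer(seq[start_from:].encode(), dtype=np.uint8)
    fl = np.frombuffer(flank.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    mismatches = (windows != fl).sum(axis=1)
    pos = int(mismatches.argmin())
    return start_from + pos, int(mismatches[pos])


def locate_barcode(
    sequence: str,
    spec: codec.BarcodeSpec | None = None,
    max_flank_mismatch: int = 2,
) -> tuple[str, dict]:
    """Extract the barcode insert between its anchor flanks.

    Both strands are tried; if the cassette lies on the reverse strand the
    whole sequence is reverse-complemented first.  Each flank may carry up to
    ``max_flank_mismatch`` substitutions.  Raises
    :class:`FlankNotFoundError` when no orientation shows both flanks in the
    correct order.
    """
    spec = spec or codec.BarcodeSpec()
    s = sequence.upper()
    if len(s) < spec.cassette_len - max_flank_mismatch:
        raise FlankNotFoundError(
            f"sequence of length {len(s)} shorter than the cassette ({spec.cassette_len} nt)"
        )
    candidates = []
    for strand, oriented in (("+", s), ("-", revcomp(s))):
        p5, mm5 = _best_flank_match(oriented, spec.flank_5p)
        if p5 < 0 or mm5 > max_flank_mismatch:
            continue
        p3, mm3 = _best_flank_match(oriented, spec.flank_3p, p5 + len(spec.flank_5p))
        if p3 < 0 or mm3 > max_flank_mismatch:
            continue
        insert = oriented[p5 + len(spec.flank_5p) : p3]
        candidates.append((mm5 + mm3, strand, insert, p5, p3, mm5, mm3))
    if not candidates:
        raise FlankNotFoundError(
            "anchor flanks not found on either strand within "
            f"{max_flank_mismatch} mismatches"
        )
    mm, strand, insert, p5, p3, mm5, mm3 = min(candidates)
    return insert, {
        "strand": strand,
        "flank_5p_mismatches": mm5,
        "flank_3p_mismatches": mm3,
        "insert_start": p5 + len(spec.flank_5p),
        "insert_end": p3,
    }


# ---------------------------------------------------------------------------
# commit recovery

@dataclass
class RecoveryResult:
    matches: list[dict]  # [{uid, support, mean_distance, in_store}] ranked
    n_reads: int
    n_decoded: int
    n_failed: int
    ambiguous: bool

    @property
    def best(self) -> dict | None:
        return self.matches[0] if self.matches else None


def recover_commit(
    reads: Iterable[Read | MergedRead | str],
    store=None,
    spec: codec.BarcodeSpec | None = None,
    config: AnalyzerConfig | None = None,
) -> RecoveryResult:
    """Per-read barcode extraction + decode, aggregated by majority vote.

    Each read is searched for the flanked cassette, the insert decoded with
    error correction, and the identifier looked up in ``store`` (when given).
    Ties in read support are broken toward the lexicographically smallest
    identifier and flagged ``ambiguous``.  Identifiers that decode cleanly
    but are absent from the store are reported with ``in_store = False``.
    """
    config = config or AnalyzerConfig()
    if spec is None:
        spec = store.barcode_spec if store is not None else codec.BarcodeSpec()
    support: Counter[str] = Counter()
    distances: dict[str, list[int]] = {}
    n_reads = n_failed = 0
    for read in reads:
        n_reads += 1
        seq = read if isinstance(read, str) else read.sequence
        try:
            insert, _ = locate_barcode(seq, spec, config.max_flank_mismatch)
            uid_int, report = codec.decode(insert, spec, allow_correction=True)
        except (codec.DecodeError, FlankNotFoundError):
            n_failed += 1
            continue
        uid = uid_to_str(uid_int, spec.payload_bits)
        support[uid] += 1
        distances.setdefault(uid, []).append(report.distance)
    if n_reads == 0:
        raise AnalysisError("no reads supplied")
    if not support:
        raise AnalysisError("no read yielded a decodable barcode")
    ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    matches = []
    for uid, n in ranked:
        in_store = True
        if store is not None:
            try:
                store.get_commit(uid)
            except Exception:
                in_store = False
        matches.append(
            {
                "uid": uid,
                "support": n,
                "mean_distance": sum(distances[uid]) / n,
                "in_store": in_store,
            }
        )
    ambiguous = len(ranked) > 1 and ranked[0][1] == ranked[1][1]
    return RecoveryResult(
        matches=matches,
        n_reads=n_reads,
        n_decoded=n_reads - n_failed,
        n_failed=n_failed,
        ambiguous=ambiguous,
    )


# ---------------------------------------------------------------------------
# variant-frequency analysis

_BASES = "ACGT"


@dataclass
class VariantTable:
    reference: str
    counts: dict[str, np.ndarray]  # keys A C G T del -> per-position counts
    ins_after: Counter  # ref position (0-based, -1 = before start) -> count
    coverage: np.ndarray
    n_reads: int
    n_reads_with_any_change: int
    called_variants: list[dict] = field(default_factory=list)

    @property
    def read_mutation_fraction(self) -> float:
        return self.n_reads_with_any_change / self.n_reads if self.n_reads else 0.0

    def summary(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_reads_with_any_change": self.n_reads_with_any_change,
            "read_mutation_fraction": self.read_mutation_fraction,
            "called_variants": self.called_variants,
        }

    def to_frame(self):
        """Per-position table: position (1-based), ref, base/del counts, coverage."""
        import pandas as pd

        L = len(self.reference)
        return pd.DataFrame(
            {
                "position": np.arange(1, L + 1),
                "ref": list(self.reference),
                **{b: self.counts[b] for b in _BASES},
                "del": self.counts["del"],
                "ins_after": [self.ins_after.get(i, 0) for i in range(L)],
                "coverage": self.coverage,
            }
        )


def _aligned_events(aligner: Align.PairwiseAligner, reference: str, seq: str):
    """Yield per-read events from a global alignment.

    Returns (matched: list of (ref_pos, read_base), deleted_ref_positions,
    insertions: list of (ref_pos_after, length)).
    """
    alignment = aligner.align(reference, seq)[0]
    blocks = alignment.aligned
    matched: list[tuple[int, str]] = []
    deleted: list[int] = []
    insertions: list[tuple[int, int]] = []
    prev_r = prev_q = 0
    for (rs, re_), (qs, qe) in zip(blocks[0], blocks[1]):
        if rs > prev_r:
            deleted.extend(range(prev_r, rs))
        if qs > prev_q:
            insertions.append((prev_r - 1, qs - prev_q))
        for i in range(re_ - rs):
            matched.append((rs + i, seq[qs + i]))
        prev_r, prev_q = re_, qe
    if prev_r < len(reference):
        deleted.extend(range(prev_r, len(reference)))
    if prev_q < len(seq):
        insertions.append((prev_r - 1, len(seq) - prev_q))
    return matched, deleted, insertions


def variant_table(
    merged_reads: Iterable[MergedRead | Read | str],
    reference: str,
    config: AnalyzerConfig | None = None,
) -> VariantTable:
    """Align reads to the reference amplicon and tabulate variants.

    Identical read sequences are aligned once and counted with their
    multiplicity.  A read counts toward ``n_reads_with_any_change`` iff its
    alignment contains at least one mismatch or gap.  A variant is called at
    a position when an alternative's frequency is >= ``min_variant_frequency``
    (inclusive).  Insertions are keyed to the reference position they follow
    and do not consume per-position coverage.
    """
    config = config or AnalyzerConfig()
    if not reference:
        raise AnalysisError("reference must be non-empty")
    reference = reference.upper()
    L = len(reference)
    seq_counts = Counter(
        (r if isinstance(r, str) else r.sequence).upper() for r in merged_reads
    )
    n_reads = sum(seq_counts.values())
    if n_reads == 0:
        raise AnalysisError("no reads supplied")

    counts = {b: np.zeros(L, dtype=np.int64) for b in _BASES}
    counts["del"] = np.zeros(L, dtype=np.int64)
    ins_after: Counter = Counter()
    n_changed = 0
    aligner = config.aligner()

    for seq, mult in seq_counts.items():
        if seq == reference:  # exact match fast path
            for i, b in enumerate(reference):
                counts[b][i] += mult
            continue
        matched, deleted, insertions = _aligned_events(aligner, reference, seq)
        for pos, base in matched:
            if base in counts:
                counts[base][pos] += mult
        for pos in deleted:
            counts["del"][pos] += mult
        for pos, _length in insertions:
            ins_after[pos] += mult
        has_change = bool(deleted or insertions) or any(
            base != reference[pos] for pos, base in matched
        )
        if has_change:
            n_changed += mult

    coverage = sum(counts[b] for b in _BASES) + counts["del"]
    called: list[dict] = []
    for pos in range(L):
        cov = int(coverage[pos])
        if cov == 0:
            continue
        for alt in list(_BASES) + ["del"]:
            if alt == reference[pos]:
                continue
            freq = counts[alt][pos] / cov
            if freq >= config.min_variant_frequency:
                called.append(
                    {"position": pos + 1, "ref": reference[pos], "alt": alt,
                     "frequency": float(freq)}
                )
    for pos, cnt in sorted(ins_after.items()):
        freq = cnt / n_reads
        if freq >= config.min_variant_frequency:
            called.append(
                {"position": pos + 1, "ref": reference[pos] if pos >= 0 else "",
                 "alt": "ins", "frequency": float(freq)}
            )
    return VariantTable(
        reference=reference,
        counts=counts,
        ins_after=ins_after,
        coverage=coverage,
        n_reads=n_reads,
        n_reads_with_any_change=n_changed,
        called_variants=sorted(called, key=lambda v: (v["position"], v["alt"])),
    )


# ---------------------------------------------------------------------------
# Sanger-style single-sequence verification

def sanger_verify(
    single_sequence: str, reference: str, config: AnalyzerConfig | None = None
) -> dict:
    """Global pairwise comparison of one (Sanger-like) sequence to the
    reference barcode region.

    The better-scoring orientation is chosen automatically; the result lists
    every mismatch and indel with 1-based reference positions.
    """
    config = config or AnalyzerConfig()
    if not single_sequence or not reference:
        raise AnalysisError("sequences must be non-empty")
    reference = reference.upper()
    aligner = config.aligner()
    best_seq, best_score, orientation = None, None, "+"
    for strand, seq in (("+", single_sequence.upper()),
                        ("-", revcomp(single_sequence.upper()))):
        score = aligner.score(reference, seq)
        if best_score is None or score > best_score:
            best_seq, best_score, orientation = seq, score, strand
    matched, deleted, insertions = _aligned_events(aligner, reference, best_seq)
    differences = []
    for pos, base in matched:
        if base != reference[pos]:
            differences.append(
                {"type": "mismatch", "position": pos + 1,
                 "ref": reference[pos], "alt": base}
            )
    for pos in deleted:
        differences.append(
            {"type": "deletion", "position": pos + 1, "ref": reference[pos], "alt": "-"}
        )
    for pos, length in insertions:
        differences.append(
            {"type": "insertion", "position": pos + 1, "ref": "-", "alt": f"+{length}nt"}
        )
    differences.sort(key=lambda d: (d["position"], d["type"]))
    return {
        "identical": not differences,
        "orientation": orientation,
        "score": float(best_score),
        "differences": differences,
    }
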