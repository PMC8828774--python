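"""Seeded generators for every input the rest of the package consumes.

Annotated genomes with a planted insertion site, barcoded strain sequences,
PCR lineage pools (including the "jackpot" scenario where an early-cycle
polymerase error is inherited by ``2**-cycle`` of the final molecules),
Wright-Fisher passaging with per-base mutation, and FASTQ read sampling with
a configurable error model.  Every generator is a pure function of its
parameters and seed: identical inputs give byte-identical outputs.

PCR is modelled with perfect per-cycle efficiency — every molecule is copied
exactly once per cycle, originals never retro-mutate — which is the minimal
model under which a cycle-1 jackpot mutation ends up in exactly half the
product molecules.  Mutated copies in the stochastic modes carry a single
substitution per mutation event, a good approximation at realistic per-copy
error rates.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .recovery import Read, ReadSet
from .sites import CandidateSite, CassetteDesign, Gene, GenomeAnnotation
from .util import revcomp

__all__ = [
    "ErrorModel",
    "FixtureGenome",
    "MoleculePool",
    "BarcodedStrain",
    "make_genome",
    "write_genome_files",
    "barcode_strain",
    "simulate_pcr",
    "simulate_passaging",
    "sample_reads",
    "write_fastq",
    "write_paired_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ErrorModel:
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    quality: int = 30  # constant Phred score written to FASTQ

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must be in [0, 1]")


@dataclass
class MoleculePool:
    """Lineage-resolved molecule population: sequence -> multiplicity."""

    molecules: dict[str, int]
    history: list[tuple[int, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.molecules.values())

    def fraction(self, sequence: str) -> float:
        return self.molecules.get(sequence, 0) / self.total

    def as_list(self) -> list[dict]:
        return [
            {"sequence": s, "multiplicity": m}
            for s, m in sorted(self.molecules.items())
        ]


@dataclass
class FixtureGenome:
    annotation: GenomeAnnotation
    essential_names: list[str]
    planted_site: CandidateSite | None
    seed: int


@dataclass
class BarcodedStrain:
    contig: str
    sequence: str
    insertion_point: int  # 1-based base after which the cassette sits
    cassette: str
    shifted_genes: list[Gene]


# ---------------------------------------------------------------------------
# genome fixtures

def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def make_genome(
    n_genes: int = 40,
    essential_fraction: float = 0.3,
    intergenic_len_range: tuple[int, int] = (20, 400),
    seed: int = 0,
    plant_site: bool = True,
    planted_gap_len: int = 200,
    gene_len_range: tuple[int, int] = (300, 900),
    n_other_features: int = 0,
    contig_name: str = "chr1",
) -> FixtureGenome:
    """Random single-contig genome with (optionally) one planted barcode site.

    The planted site is an adjacent essential pair with a ``planted_gap_len``
    gap; essentiality of the remaining genes is assigned so that no *other*
    adjacent pair is fully essential, making the planted site the unique
    adjacency-mode candidate and the deterministic rank-1 hit.
    """
    if n_genes < 2:
        raise ValueError("need at least two genes")
    if plant_site and n_genes < 2:
        raise ValueError("planting a site needs two genes")
    rng = np.random.default_rng(seed)
    lo, hi = intergenic_len_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid intergenic_len_range")

    plant_idx = int(rng.integers(0, n_genes - 1)) if plant_site else -1
    essential = np.zeros(n_genes, dtype=bool)
    if plant_site:
        essential[plant_idx] = essential[plant_idx + 1] = True
    n_extra = int(round(essential_fraction * n_genes)) - int(essential.sum())
    # forbid slots adjacent to an already-essential gene so the planted pair
    # stays the only essential adjacency
    order = rng.permutation(n_genes)
    for idx in order:
        if n_extra <= 0:
            break
        idx = int(idx)
        if essential[idx]:
            continue
        if any(0 <= j < n_genes and essential[j] for j in (idx - 1, idx + 1)):
            continue
        essential[idx] = True
        n_extra -= 1

    parts: list[str] = []
    genes: list[Gene] = []
    pos = 0  # 0-based running coordinate
    leading = int(rng.integers(lo, hi + 1))
    parts.append(_random_dna(rng, leading))
    pos += leading
    gaps_after: list[tuple[int, int]] = []  # (gap_start0, gap_len) after each gene
    for i in range(n_genes):
        glen = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
        parts.append(_random_dna(rng, glen))
        genes.append(
            Gene(
                gene_id=f"G{i:04d}",
                names=(f"gene{i}",),
                synonyms=(f"syn{i}",),
                contig=contig_name,
                start=pos + 1,
                end=pos + glen,
                strand="+" if rng.random() < 0.5 else "-",
                type="gene",
            )
        )
        pos += glen
        if i < n_genes - 1:
            gap = planted_gap_len if i == plant_idx else int(rng.integers(lo, hi + 1))
            gaps_after.append((pos, gap))
            parts.append(_random_dna(rng, gap))
            pos += gap
    parts.append(_random_dna(rng, int(rng.integers(lo, hi + 1))))
    contig = "".join(parts)

    other_features: list[Gene] = []
    for f in range(n_other_features):
        # features land in random non-planted gaps
        choices = [g for i, g in enumerate(gaps_after) if i != plant_idx and g[1] >= 10]
        if not choices:
            break
        gstart, glen_ = choices[int(rng.integers(0, len(choices)))]
        flen = int(rng.integers(5, min(glen_, 50) + 1))
        fstart = gstart + int(rng.integers(0, glen_ - flen + 1)) + 1
        other_features.append(
            Gene(
                gene_id=f"F{f:03d}",
                names=(),
                synonyms=(),
                contig=contig_name,
                start=fstart,
                end=fstart + flen - 1,
                strand="+",
                type="regulatory_region",
            )
        )

    annotation = GenomeAnnotation(
        contigs={contig_name: contig}, genes=genes, other_features=other_features
    )
    planted = None
    if plant_site:
        left, right = genes[plant_idx], genes[plant_idx + 1]
        planted = CandidateSite(
            left_gene=left.gene_id,
            right_gene=right.gene_id,
            orientations=(left.strand, right.strand),
            contig=contig_name,
            start=left.end + 1,
            end=right.start - 1,
            sequence=contig[left.end : right.start - 1],
        )
    essential_names = [genes[i].names[0] for i in range(n_genes) if essential[i]]
    return FixtureGenome(
        annotation=annotation,
        essential_names=essential_names,
        planted_site=planted,
        seed=seed,
    )


def write_genome_files(fixture: FixtureGenome, out_dir: str | Path) -> dict[str, Path]:
    """Emit genome.fasta, genome.gff3, essential.txt and truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ann = fixture.annotation
    fasta = out_dir / "genome.fasta"
    with open(fasta, "w", newline="\n") as fh:
        for name, seq in sorted(ann.contigs.items()):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    gff = out_dir / "genome.gff3"
    with open(gff, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in sorted(ann.contigs.items()):
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in ann.genes + ann.other_features:
            attrs = f"ID={g.gene_id}"
            if g.names:
                attrs += f";Name={g.names[0]}"
            if g.synonyms:
                attrs += f";Alias={','.join(g.synonyms)}"
            fh.write(
                f"{g.contig}\tcellver\t{g.type}\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
    ess = out_dir / "essential.txt"
    with open(ess, "w", newline="\n") as fh:
        fh.write("# fixture essential gene list\n")
        for name in fixture.essential_names:
            fh.write(name + "\n")
    truth = out_dir / "truth.json"
    payload = {
        "seed": fixture.seed,
        "planted_site": None
        if fixture.planted_site is None
        else {
            "contig": fixture.planted_site.contig,
            "start": fixture.planted_site.start,
            "end": fixture.planted_site.end,
            "left_gene": fixture.planted_site.left_gene,
            "right_gene": fixture.planted_site.right_gene,
        },
    }
    with open(truth, "w", newline="\n") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return {"fasta": fasta, "gff3": gff, "essential": ess, "truth": truth}


def barcode_strain(fixture: FixtureGenome, design: CassetteDesign) -> BarcodedStrain:
    """Insert an assembled cassette's payload at its designed genome position.

    Verifies that the design's homology arms still match the fixture contig
    (coordinate mismatch otherwise) and returns the mutated contig together
    with a shifted-coordinate gene report.
    """
    contig = design.site.contig
    seq = fixture.annotation.contigs[contig]
    p = design.insertion_point  # 1-based; insert after this base
    arm_len = len(design.arm_5p)
    if seq[p - arm_len : p] != design.arm_5p or seq[p : p + arm_len] != design.arm_3p:
        raise ValueError("cassette design does not match this genome (coordinate mismatch)")
    new_seq = seq[:p] + design.payload + seq[p:]
    shift = len(design.payload)
    shifted = [
        g if g.start <= p else Gene(
            gene_id=g.gene_id, names=g.names, synonyms=g.synonyms, contig=g.contig,
            start=g.start + shift, end=g.end + shift, strand=g.strand, type=g.type,
        )
        for g in fixture.annotation.genes
        if g.contig == contig
    ]
    return BarcodedStrain(
        contig=contig,
        sequence=new_seq,
        insertion_point=p,
        cassette=design.payload,
        shifted_genes=shifted,
    )


# ---------------------------------------------------------------------------
# PCR and passaging

def simulate_pcr(
    template: str,
    cycles: int,
    forced: tuple[int, int, str] | None = None,
    substitution_rate: float = 0.0,
    seed: int = 0,
) -> MoleculePool:
    """Exponential amplification from one template molecule.

    Every molecule is copied once per cycle; copies may mutate, originals
    never do.  ``forced = (cycle, position, alt)`` mutates exactly one copy
    event at that cycle (position 0-based), so the mutant fraction in the
    final pool is exactly ``2**-cycle``.  ``substitution_rate`` is the
    per-base, per-copy polymerase error probability for the stochastic mode.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    template = template.upper()
    L = len(template)
    if forced is not None:
        fc, fpos, falt = forced
        if not 1 <= fc <= cycles:
            raise ValueError(f"forced cycle {fc} outside 1..{cycles}")
        if not 0 <= fpos < L:
            raise ValueError(f"forced position {fpos} outside template")
        falt = falt.upper()
        if falt == template[fpos]:
            raise ValueError("forced alt equals the template base")
    rng = np.random.default_rng(seed)
    pool: dict[str, int] = {template: 1}
    history: list[tuple[int, str]] = [(0, "template")]
    p_copy_mut = 1.0 - (1.0 - substitution_rate) ** L
    for cycle in range(1, cycles + 1):
        additions: dict[str, int] = {}
        for seq, mult in pool.items():
            n_mut = int(rng.binomial(mult, p_copy_mut)) if p_copy_mut > 0 else 0
            additions[seq] = additions.get(seq, 0) + (mult - n_mut)
            for _ in range(n_mut):
                pos = int(rng.integers(0, L))
                alt = "ACGT".replace(seq[pos], "")[int(rng.integers(0, 3))]
                mutant = seq[:pos] + alt + seq[pos + 1 :]
                additions[mutant] = additions.get(mutant, 0) + 1
                history.append((cycle, f"substitution {seq[pos]}{pos}{alt}"))
        if forced is not None and cycle == forced[0]:
            fc, fpos, falt = forced
            additions[template] -= 1
            mutant = template[:fpos] + falt.upper() + template[fpos + 1 :]
            additions[mutant] = additions.get(mutant, 0) + 1
            history.append((cycle, f"forced substitution {template[fpos]}{fpos}{falt}"))
        for seq, mult in additions.items():
            pool[seq] = pool.get(seq, 0) + mult
        pool = {s: m for s, m in pool.items() if m > 0}
    return MoleculePool(molecules=pool, history=history)


def simulate_passaging(
    sequence: str,
    generations: int,
    mu_per_base_per_generation: float,
    population_size: int = 1000,
    seed: int = 0,
) -> MoleculePool:
    """Wright-Fisher resampling with per-base substitution of offspring.

    Each generation, ``population_size`` offspring are drawn multinomially
    from the current population; each offspring mutates with probability
    ``1 - (1-mu)**L`` (one substitution per mutation event).
    """
    if generations < 0 or population_size < 1:
        raise ValueError("generations must be >= 0 and population_size >= 1")
    sequence = sequence.upper()
    L = len(sequence)
    rng = np.random.default_rng(seed)
    pool: dict[str, int] = {sequence: population_size}
    history: list[tuple[int, str]] = []
    p_mut = 1.0 - (1.0 - mu_per_base_per_generation) ** L
    for gen in range(1, generations + 1):
        seqs = sorted(pool)
        weights = np.array([pool[s] for s in seqs], dtype=float)
        counts = rng.multinomial(population_size, weights / weights.sum())
        nxt: dict[str, int] = {}
        for s, n in zip(seqs, counts):
            if n == 0:
                continue
            n_mut = int(rng.binomial(n, p_mut)) if p_mut > 0 else 0
            if n - n_mut:
                nxt[s] = nxt.get(s, 0) + int(n - n_mut)
            for _ in range(n_mut):
                pos = int(rng.integers(0, L))
                alt = "ACGT".replace(s[pos], "")[int(rng.integers(0, 3))]
                mutant = s[:pos] + alt + s[pos + 1 :]
                nxt[mutant] = nxt.get(mutant, 0) + 1
                history.append((gen, f"substitution {s[pos]}{pos}{alt}"))
        pool = nxt
    return MoleculePool(molecules=pool, history=history)


# ---------------------------------------------------------------------------
# read sampling

def _apply_substitutions(
    arr: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent per-base substitutions on a (n, L) uint8 base-index array."""
    if rate <= 0 or arr.size == 0:
        return arr
    n_err = int(rng.binomial(arr.size, rate))
    if n_err == 0:
        return arr
    flat = arr.reshape(-1)
    idx = rng.choice(arr.size, size=n_err, replace=False)
    flat[idx] = (flat[idx] + rng.integers(1, 4, size=n_err)) % 4
    return arr


_LUT = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i


def sample_reads(
    pool: MoleculePool | Sequence[str],
    n_reads: int,
    read_len: int,
    paired: bool = False,
    error_model: ErrorModel | None = None,
    seed: int = 0,
) -> ReadSet:
    """Draw reads from a molecule pool, multiplicity-weighted.

    Single mode returns the first ``read_len`` bases of each sampled
    molecule (the whole molecule when shorter).  Paired mode emits mate 1
    from the 5' end and mate 2 as the reverse complement of the 3' end —
    the 2 x ``read_len`` amplicon geometry — and requires
    ``2*read_len >= template length >= read_len`` so the mates overlap.
    Substitutions/indels follow the error model; deterministic under seed.
    """
    error_model = error_model or ErrorModel()
    if isinstance(pool, MoleculePool):
        classes = sorted(pool.molecules)
        weights = np.array([pool.molecules[s] for s in classes], dtype=float)
    else:
        counter: dict[str, int] = {}
        for s in pool:
            counter[s] = counter.get(s, 0) + 1
        classes = sorted(counter)
        weights = np.array([counter[s] for s in classes], dtype=float)
    if not classes:
        raise ValueError("empty molecule pool")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, weights / weights.sum())

    reads: list[Read] = []
    serial = 0
    for cls, n in zip(classes, counts):
        if n == 0:
            continue
        L = len(cls)
        if read_len > L:
            raise ValueError(f"read_len {read_len} exceeds template length {L}")
        if paired and 2 * read_len < L:
            raise ValueError(
                f"paired geometry infeasible: 2*{read_len} < template length {L}"
            )
        tmpl = _LUT[np.frombuffer(cls.encode(), dtype=np.uint8)]
        r1 = np.tile(tmpl[:read_len], (n, 1))
        r1 = _apply_substitutions(r1, error_model.substitution_rate, rng)
        if paired:
            r2t = _LUT[np.frombuffer(revcomp(cls).encode(), dtype=np.uint8)][:read_len]
            r2 = np.tile(r2t, (n, 1))
            r2 = _apply_substitutions(r2, error_model.substitution_rate, rng)
        for i in range(n):
            rid = f"read{serial:06d}"
            serial += 1
            seq1 = _indels(
                _BASES[r1[i]].tobytes().decode(), error_model.indel_rate, rng
            )
            read = Read(
                read_id=rid, sequence=seq1,
                quality=[error_model.quality] * len(seq1),
            )
            if paired:
                seq2 = _indels(
                    _BASES[r2[i]].tobytes().decode(), error_model.indel_rate, rng
                )
                read.mate = Read(
                    read_id=rid, sequence=seq2,
                    quality=[error_model.quality] * len(seq2),
                )
            reads.append(read)
    order = rng.permutation(len(reads))
    return ReadSet(reads=[reads[i] for i in order])


def _indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n = int(rng.binomial(len(seq), rate))
    for _ in range(n):
        pos = int(rng.integers(0, len(seq)))
        if rng.random() < 0.5 and len(seq) > 1:
            seq = seq[:pos] + seq[pos + 1 :]
        else:
            seq = seq[:pos] + "ACGT"[int(rng.integers(0, 4))] + seq[pos:]
    return seq


def write_fastq(reads: Sequence[Read], path: str | Path) -> Path:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr((q if q <= 93 else 93) + 33) for q in (r.quality or [30] * len(r.sequence)))
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
    return path


def write_paired_fastq(
    reads: Sequence[Read], path_r1: str | Path, path_r2: str | Path
) -> tuple[Path, Path]:
    mates = []
    for r in reads:
        if r.mate is None:
            raise ValueError(f"read {r.read_id} has no mate")
        mates.append(r.mate)
    return write_fastq(reads, path_r1), write_fastq(mates, path_r2)
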