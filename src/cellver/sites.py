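"""Chromosomal barcode insertion-site selection.

A good barcode locus is an intergenic interval flanked by *essential* genes:
a cell that deletes the inserted region together with its neighbourhood dies,
so the barcode is selected for passively.  Two search modes are provided:

* **adjacency** — consecutive gene pairs where both genes are essential and
  the gap between them is long enough for a cassette;
* **cluster** — essential gene pairs separated by up to ``max_intervening``
  non-essential genes (useful for genomes where truly adjacent essential
  pairs are rare); every intergenic gap inside such a cluster is a candidate.

Candidates are screened against annotated features (regulatory elements the
annotation knows about must not be disrupted) and for presence in other
laboratory strains of the species, then ranked deterministically.

Coordinates follow GFF3 at the boundary: 1-based, inclusive.  Internal
arithmetic is 0-based half-open; every reported interval is 1-based inclusive
again.  BED export is 0-based half-open, per that format.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO

from .util import revcomp

__all__ = [
    "Gene",
    "GenomeAnnotation",
    "EssentialSet",
    "CandidateSite",
    "CassetteDesign",
    "AnnotationError",
    "load_annotation",
    "read_essential_list",
    "normalize_names",
    "find_adjacent_essential_pairs",
    "find_essential_clusters",
    "check_conservation",
    "flag_feature_overlap",
    "rank_candidates",
    "design_cassette",
    "sites_to_table",
    "sites_to_bed",
]

DEFAULT_MIN_LEN = 50
DEFAULT_MAX_LEN = 1000

_NAME_ATTRS = ("Name", "gene", "gene_name", "locus_tag")
_SYNONYM_ATTRS = ("Alias", "gene_synonym", "synonym")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Gene:
    gene_id: str
    names: tuple[str, ...]  # primary names; gene_id excluded
    synonyms: tuple[str, ...]
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"
    type: str


@dataclass
class GenomeAnnotation:
    contigs: dict[str, str]
    genes: list[Gene]
    other_features: list[Gene]

    def genes_on(self, contig: str) -> list[Gene]:
        return sorted(
            (g for g in self.genes if g.contig == contig),
            key=lambda g: (g.start, g.end, g.gene_id),
        )


@dataclass
class EssentialSet:
    raw_names: list[str]
    normalized: set[str]  # canonical gene_ids
    mapping_report: dict[str, str]  # raw -> gene_id | "unmatched" | "ambiguous"


@dataclass
class CandidateSite:
    left_gene: str
    right_gene: str
    orientations: tuple[str, str]
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    sequence: str
    intervening_nonessential: int = 0
    overlaps_feature: bool = False
    overlapping_features: list[str] = field(default_factory=list)
    conservation: dict[str, dict] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CassetteDesign:
    site: CandidateSite
    arm_5p: str
    arm_3p: str
    payload: str
    assembled: str
    insertion_point: int  # 1-based; cassette goes between this base and the next


# ---------------------------------------------------------------------------
# input parsing

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def load_annotation(
    gff3_path: str | Path,
    fasta_path: str | Path,
    gene_types: Sequence[str] = ("gene",),
) -> GenomeAnnotation:
    """Parse a GFF3 + FASTA pair into a :class:`GenomeAnnotation`.

    Features whose type is in ``gene_types`` become genes; every other
    feature (except contig-spanning ``region`` records) is kept as an
    annotation feature for the overlap screen.  Both files may be gzipped.
    """
    contigs: dict[str, str] = {}
    with _open_text(fasta_path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise AnnotationError(f"no sequences in {fasta_path}")

    with _open_text(gff3_path) as fh:
        text = fh.read()
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils wraps many causes
        raise AnnotationError(f"malformed GFF3 {gff3_path}: {exc}") from exc

    genes: list[Gene] = []
    other: list[Gene] = []
    for feat in db.all_features():
        if feat.featuretype == "region":
            continue
        if feat.seqid not in contigs:
            raise AnnotationError(
                f"feature {feat.id} references unknown contig {feat.seqid!r}"
            )
        if not 1 <= feat.start <= feat.end <= len(contigs[feat.seqid]):
            raise AnnotationError(
                f"feature {feat.id} coordinates [{feat.start}, {feat.end}] outside "
                f"contig {feat.seqid} (length {len(contigs[feat.seqid])})"
            )
        names = tuple(
            v for attr in _NAME_ATTRS for v in feat.attributes.get(attr, [])
        )
        synonyms = tuple(
            v for attr in _SYNONYM_ATTRS for v in feat.attributes.get(attr, [])
        )
        gene = Gene(
            gene_id=feat.id,
            names=names,
            synonyms=synonyms,
            contig=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
            type=feat.featuretype,
        )
        (genes if feat.featuretype in gene_types else other).append(gene)
    return GenomeAnnotation(contigs=contigs, genes=genes, other_features=other)


def read_essential_list(path: str | Path) -> list[str]:
    """One gene name per line; blank lines and ``#`` comments ignored."""
    names = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                names.append(line)
    return names


# ---------------------------------------------------------------------------
# name curation

def normalize_names(
    annotation: GenomeAnnotation,
    raw_names: Iterable[str],
    rules: Mapping[str, str] | None = None,
) -> EssentialSet:
    """Map externally curated gene names onto annotation gene_ids.

    Matching pipeline, in order: explicit ``rules`` → exact gene_id → exact
    name → case-insensitive name → synonym list.  A raw name matching two or
    more genes is flagged ``"ambiguous"`` and excluded; unmatched names are
    reported, never silently dropped.
    """
    rules = dict(rules or {})
    by_id = {g.gene_id: g for g in annotation.genes}
    by_name: dict[str, list[str]] = {}
    by_name_ci: dict[str, list[str]] = {}
    by_syn: dict[str, list[str]] = {}
    for g in annotation.genes:
        for n in g.names:
            by_name.setdefault(n, []).append(g.gene_id)
            by_name_ci.setdefault(n.lower(), []).append(g.gene_id)
        for s in g.synonyms:
            by_syn.setdefault(s.lower(), []).append(g.gene_id)

    raw_names = list(raw_names)
    normalized: set[str] = set()
    report: dict[str, str] = {}
    for raw in raw_names:
        name = rules.get(raw, raw)
        matches: list[str]
        if name in by_id:
            matches = [name]
        elif name in by_name:
            matches = by_name[name]
        elif name.lower() in by_name_ci:
            matches = by_name_ci[name.lower()]
        elif name.lower() in by_syn:
            matches = by_syn[name.lower()]
        else:
            matches = []
        unique = sorted(set(matches))
        if not unique:
            report[raw] = "unmatched"
        elif len(unique) > 1:
            report[raw] = "ambiguous"
        else:
            report[raw] = unique[0]
            normalized.add(unique[0])
    return EssentialSet(raw_names=raw_names, normalized=normalized, mapping_report=report)


# ---------------------------------------------------------------------------
# candidate search

def _gap_site(
    annotation: GenomeAnnotation,
    contig_genes: list[Gene],
    left: Gene,
    right: Gene,
    bound_left: Gene,
    bound_right: Gene,
    min_len: int,
    max_len: int,
    intervening: int,
) -> CandidateSite | None:
    start, end = left.end + 1, right.start - 1  # 1-based inclusive gap
    length = end - start + 1
    if length < max(min_len, 1) or length > max_len:
        return None
    # the interval must not intersect any gene body (nested/overlapping genes)
    for g in contig_genes:
        if g.start <= end and g.end >= start:
            return None
    seq = annotation.contigs[left.contig][start - 1 : end]
    return CandidateSite(
        left_gene=bound_left.gene_id,
        right_gene=bound_right.gene_id,
        orientations=(bound_left.strand, bound_right.strand),
        contig=left.contig,
        start=start,
        end=end,
        sequence=seq,
        intervening_nonessential=intervening,
    )


def find_adjacent_essential_pairs(
    annotation: GenomeAnnotation,
    essential: EssentialSet | set[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[CandidateSite]:
    """Intergenic gaps between consecutive essential genes, length-bounded.

    Overlapping or abutting gene pairs (gap length <= 0) yield no candidate.
    """
    ess = essential.normalized if isinstance(essential, EssentialSet) else set(essential)
    out: list[CandidateSite] = []
    for contig in sorted(annotation.contigs):
        genes = annotation.genes_on(contig)
        for left, right in zip(genes, genes[1:]):
            if left.gene_id in ess and right.gene_id in ess:
                site = _gap_site(
                    annotation, genes, left, right, left, right, min_len, max_len, 0
                )
                if site is not None:
                    out.append(site)
    return out


def find_essential_clusters(
    annotation: GenomeAnnotation,
    essential: EssentialSet | set[str],
    max_intervening: int = 3,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[CandidateSite]:
    """Intergenic gaps inside clusters of nearby essential genes.

    A cluster is an essential pair separated by 1..``max_intervening``
    non-essential genes; every gap between consecutive genes of the cluster
    that is gene-free and length-bounded is emitted, tagged with the number
    of intervening non-essential genes and flanked (left_gene/right_gene) by
    the bounding essential pair.
    """
    ess = essential.normalized if isinstance(essential, EssentialSet) else set(essential)
    out: list[CandidateSite] = []
    for contig in sorted(annotation.contigs):
        genes = annotation.genes_on(contig)
        n = len(genes)
        for i in range(n):
            if genes[i].gene_id not in ess:
                continue
            for j in range(i + 2, min(n, i + max_intervening + 2)):
                if genes[j].gene_id not in ess:
                    continue
                between = genes[i + 1 : j]
                if any(g.gene_id in ess for g in between):
                    break  # nearer essential gene closes the cluster
                k = len(between)
                if 1 <= k <= max_intervening:
                    for left, right in zip(genes[i:j], genes[i + 1 : j + 1]):
                        site = _gap_site(
                            annotation, genes, left, right,
                            genes[i], genes[j], min_len, max_len, k,
                        )
                        if site is not None:
                            out.append(site)
                break
    return out


# ---------------------------------------------------------------------------
# screening

def flag_feature_overlap(
    site: CandidateSite, other_features: Iterable[Gene]
) -> CandidateSite:
    """Mark the site if any annotated feature intersects it (closed intervals)."""
    overlapping = [
        f.gene_id
        for f in other_features
        if f.contig == site.contig and f.start <= site.end and f.end >= site.start
    ]
    site.overlaps_feature = bool(overlapping)
    site.overlapping_features = sorted(overlapping)
    return site


def check_conservation(
    site: CandidateSite,
    other_genomes: Mapping[str, str],
    k: int = 15,
    cov_min: float = 0.9,
    id_min: float = 0.9,
) -> dict[str, dict]:
    """Presence screen of the site sequence in other strains' genomes.

    Exact ``k``-mer seeding on both strands followed by ungapped (diagonal)
    evaluation of the full site against the implied genome window.  A strain
    counts as ``present`` when the best diagonal covers at least ``cov_min``
    of the site at identity at least ``id_min``.  Genome values may be raw
    sequences or FASTA paths.
    """
    query = site.sequence.upper()
    if len(query) < k:
        raise ValueError(f"site length {len(query)} shorter than seed size k={k}")
    result: dict[str, dict] = {}
    for name, genome in other_genomes.items():
        seq = _genome_sequence(genome)
        if len(seq) < k:
            raise ValueError(f"genome {name!r} shorter than seed size k={k}")
        best_cov, best_id = 0.0, 0.0
        for oriented in (query, revcomp(query)):
            index: dict[str, list[int]] = {}
            for i in range(len(oriented) - k + 1):
                index.setdefault(oriented[i : i + k], []).append(i)
            offsets: set[int] = set()
            for j in range(len(seq) - k + 1):
                for i in index.get(seq[j : j + k], ()):
                    offsets.add(j - i)
            for off in offsets:
                lo = max(0, -off)
                hi = min(len(oriented), len(seq) - off)
                window = seq[off + lo : off + hi]
                matches = sum(1 for a, b in zip(oriented[lo:hi], window) if a == b)
                cov = (hi - lo) / len(oriented)
                ident = matches / (hi - lo) if hi > lo else 0.0
                if (cov, ident) > (best_cov, best_id):
                    best_cov, best_id = cov, ident
        result[name] = {
            "present": best_cov >= cov_min and best_id >= id_min,
            "identity": round(best_id, 4),
            "coverage": round(best_cov, 4),
        }
    site.conservation = result
    return result


def _genome_sequence(genome: str | Path) -> str:
    looks_like_path = isinstance(genome, Path) or str(genome).endswith(
        (".fa", ".fasta", ".fna", ".fa.gz", ".fasta.gz")
    )
    if looks_like_path:
        with _open_text(genome) as fh:
            return "".join(str(r.seq) for r in SeqIO.parse(fh, "fasta")).upper()
    return str(genome).upper()


# ---------------------------------------------------------------------------
# ranking and cassette design

DEFAULT_RANK_WEIGHTS = {
    "feature_overlap": 1000.0,
    "intervening": 100.0,
    "conserved": 10.0,
    "length": 1.0,
}


def rank_candidates(
    sites: Sequence[CandidateSite],
    weights: Mapping[str, float] | None = None,
    target_len: int = 200,
) -> list[CandidateSite]:
    """Deterministic ranking: clean before flagged, tighter clusters before
    looser, more conserved before less, length closest to ``target_len``;
    exact ties fall back to (contig, coordinate) order."""
    w = dict(DEFAULT_RANK_WEIGHTS)
    w.update(weights or {})

    def score(site: CandidateSite) -> float:
        n_present = sum(1 for v in site.conservation.values() if v.get("present"))
        return (
            w["feature_overlap"] * site.overlaps_feature
            + w["intervening"] * site.intervening_nonessential
            - w["conserved"] * n_present
            + w["length"] * abs(site.length - target_len) / max(target_len, 1)
        )

    return sorted(sites, key=lambda s: (score(s), s.contig, s.start, s.end))


def design_cassette(
    site: CandidateSite,
    cassette_dna: str,
    annotation: GenomeAnnotation,
    arm_len: int = 40,
    insertion_offset: int | None = None,
) -> CassetteDesign:
    """Homology-arm design around an insertion point inside the site.

    ``insertion_offset`` is 1-based within the site (default: midpoint); the
    cassette is inserted *after* the resulting genome coordinate.  Arms are
    exact genome substrings of ``arm_len`` nt immediately 5' and 3' of the
    insertion point.
    """
    contig_seq = annotation.contigs[site.contig]
    offset = insertion_offset if insertion_offset is not None else (site.length + 1) // 2
    if not 1 <= offset <= site.length:
        raise ValueError(f"insertion_offset {offset} outside site of length {site.length}")
    point = site.start + offset - 1  # 1-based; insert between point and point+1
    if point - arm_len + 1 < 1 or point + arm_len > len(contig_seq):
        raise ValueError("homology arm would run off the contig end")
    arm_5p = contig_seq[point - arm_len : point]
    arm_3p = contig_seq[point : point + arm_len]
    return CassetteDesign(
        site=site,
        arm_5p=arm_5p,
        arm_3p=arm_3p,
        payload=cassette_dna.upper(),
        assembled=arm_5p + cassette_dna.upper() + arm_3p,
        insertion_point=point,
    )


# ---------------------------------------------------------------------------
# reports

def sites_to_table(sites: Sequence[CandidateSite]):
    """Candidate sites as a pandas DataFrame (one row per site)."""
    import pandas as pd

    rows = []
    for s in sites:
        rows.append(
            {
                "contig": s.contig,
                "start": s.start,
                "end": s.end,
                "length": s.length,
                "left_gene": s.left_gene,
                "right_gene": s.right_gene,
                "left_strand": s.orientations[0],
                "right_strand": s.orientations[1],
                "intervening_nonessential": s.intervening_nonessential,
                "overlaps_feature": s.overlaps_feature,
                "overlapping_features": ",".join(s.overlapping_features),
                "conserved_in": ",".join(
                    sorted(n for n, v in s.conservation.items() if v.get("present"))
                ),
                "sequence": s.sequence,
            }
        )
    return pd.DataFrame(rows)


def sites_to_bed(sites: Sequence[CandidateSite]) -> str:
    """BED (0-based half-open) lines for the candidate intervals."""
    lines = [
        f"{s.contig}\t{s.start - 1}\t{s.end}\t{s.left_gene}|{s.right_gene}\t0\t+"
        for s in sites
    ]
    return "\n".join(lines) + ("\n" if lines else "")
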