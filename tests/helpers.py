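"""Independent oracles used across test modules.

Everything here is deliberately written with a different approach from the
library code (regex scans, O(n^2) enumeration, explicit lineage trees) so the
tests cross-check rather than echo the implementation.
"""

import re

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def independent_constraint_violations(seq, gc_min, gc_max, max_homopolymer, motifs):
    """Constraint checker independent of cellver.codec.validate."""
    problems = []
    gc = sum(seq.count(b) for b in "GC") / len(seq)
    if gc < gc_min or gc > gc_max:
        problems.append("gc")
    if re.search(r"(.)\1{%d,}" % max_homopolymer, seq):
        problems.append("homopolymer")
    for m in motifs:
        if m in seq or rc(m) in seq:
            problems.append(f"motif:{m}")
    return problems


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def brute_force_adjacent_sites(genes, essential, min_len, max_len):
    """O(n^2) enumeration of adjacent-essential intergenic gaps.

    genes: list of (gene_id, start, end) sorted arbitrarily; returns a set of
    (left_id, right_id, gap_start, gap_end) tuples (1-based inclusive).
    """
    ordered = sorted(genes, key=lambda g: (g[1], g[2], g[0]))
    out = set()
    for i in range(len(ordered) - 1):
        left, right = ordered[i], ordered[i + 1]
        if left[0] not in essential or right[0] not in essential:
            continue
        gs, ge = left[2] + 1, right[1] - 1
        if not (min_len <= ge - gs + 1 <= max_len):
            continue
        if any(g[1] <= ge and g[2] >= gs for g in ordered):
            continue
        out.add((left[0], right[0], gs, ge))
    return out


def brute_force_cluster_sites(genes, essential, max_intervening, min_len, max_len):
    """All essential pairs separated by 1..max_intervening non-essential genes;
    every clean intergenic gap inside the cluster is reported with the
    bounding pair and the intervening count."""
    ordered = sorted(genes, key=lambda g: (g[1], g[2], g[0]))
    out = set()
    n = len(ordered)
    for i in range(n):
        if ordered[i][0] not in essential:
            continue
        for j in range(i + 2, n):
            if ordered[j][0] not in essential:
                continue
            between = ordered[i + 1 : j]
            if any(g[0] in essential for g in between):
                break
            k = len(between)
            if 1 <= k <= max_intervening:
                for a, b in zip(ordered[i:j], ordered[i + 1 : j + 1]):
                    gs, ge = a[2] + 1, b[1] - 1
                    if not (min_len <= ge - gs + 1 <= max_len):
                        continue
                    if any(g[1] <= ge and g[2] >= gs for g in ordered):
                        continue
                    out.add((ordered[i][0], ordered[j][0], gs, ge, k))
            break
    return out


def enumerate_pcr_lineage(template: str, cycles: int, forced):
    """Explicit lineage-tree enumeration of perfect-efficiency PCR.

    Tracks every molecule individually; only feasible for a handful of
    cycles.  forced = (cycle, position, alt) mutates exactly one copy event.
    """
    molecules = [template]
    for cycle in range(1, cycles + 1):
        copies = []
        forced_done = False
        for mol in molecules:
            copy = mol
            if forced and cycle == forced[0] and not forced_done and mol == template:
                _, pos, alt = forced
                copy = mol[:pos] + alt + mol[pos + 1 :]
                forced_done = True
            copies.append(copy)
        molecules.extend(copies)
    return molecules
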