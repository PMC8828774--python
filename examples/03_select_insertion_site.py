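"""Choose a chromosomal insertion site flanked by essential genes.

Generates an annotated fixture genome with a known good locus, curates the
essential-gene list against the annotation, finds candidate intergenic sites
in adjacency and cluster modes, screens them, and designs homology arms.
"""

from cellver import (
    check_conservation,
    design_cassette,
    find_adjacent_essential_pairs,
    find_essential_clusters,
    flag_feature_overlap,
    make_genome,
    normalize_names,
    rank_candidates,
)
from cellver.sites import sites_to_table

fx = make_genome(n_genes=50, essential_fraction=0.3, seed=4, n_other_features=4)
essential = normalize_names(fx.annotation, fx.essential_names)
print(f"{len(essential.normalized)} essential genes curated, "
      f"{sum(v == 'unmatched' for v in essential.mapping_report.values())} unmatched")

adjacent = find_adjacent_essential_pairs(fx.annotation, essential)
clusters = find_essential_clusters(fx.annotation, essential, max_intervening=2)
print(f"adjacency mode: {len(adjacent)} candidate site(s); "
      f"cluster mode: {len(clusters)} additional gap(s)")

for site in adjacent:
    flag_feature_overlap(site, fx.annotation.other_features)
    # presence screen against another lab strain (here: the same genome)
    check_conservation(site, {"labstrain": fx.annotation.contigs[site.contig]})

ranked = rank_candidates(adjacent)
best = ranked[0]
print(sites_to_table([best]).drop(columns="sequence").to_string(index=False))
print("conserved in labstrain:", best.conservation["labstrain"])

design = design_cassette(best, "N" * 74, fx.annotation, arm_len=40)
print(f"insertion point {design.insertion_point}; assembled construct "
      f"{len(design.assembled)} nt = 40 + 74 + 40")
# The top-ranked site sits between two essential genes, overlaps no annotated
# feature, and its homology arms are exact genome substrings around the
# insertion point — ready for recombination-based delivery.
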