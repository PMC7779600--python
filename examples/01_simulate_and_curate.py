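"""Simulate a two-population inbred panel and run the marker-curation chain.

Builds a small landrace-like / modern-like panel, then applies the stepwise
curation used for SNP-array data: drop markers whose minor allele has fewer
than three carriers, drop markers with MAF <= 5%, and merge redundant
markers in near-perfect LD (r2 >= 0.99) into one representative call.
"""

from durumpanel import (
    default_config,
    filter_maf,
    filter_min_carriers,
    ld_prune,
    simulate_panel,
)

panel = simulate_panel(default_config("tiny", seed=1))
G, M, meta = panel
print(f"simulated panel: {G.n_accessions} accessions x {G.n_markers} markers")

G1 = filter_min_carriers(G, min_carriers=3)
print(f"after carrier filter (>= 3 carriers of the minor allele): {G1.n_markers}")

G2 = filter_maf(G1, threshold=0.05)
print(f"after MAF > 5% filter: {G2.n_markers}")

M2 = M.subset(G2.marker_ids)
G3, merge_report = ld_prune(G2, M2, r2_cut=0.99, mode="merge")
print(f"after LD merge at r2 >= 0.99: {G3.n_markers} "
      f"({len(merge_report)} merged groups)")

# Each removed marker was either uninformative (rare/monomorphic) or
# statistically redundant with a retained neighbour; the retained set carries
# the same information with fewer columns.
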