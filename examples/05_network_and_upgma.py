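"""Median-joining network and UPGMA dendrogram of simulated haplotypes.

The median-joining algorithm augments the observed haplotypes with inferred
median vectors (unsampled intermediates); MP pruning keeps only links on
minimum-length spanning trees of the observed haplotypes.
"""

from pathlib import Path

from ylineage import (
    SimConfig,
    collapse_haplotypes,
    export_network,
    hamming_matrix,
    mjn,
    mp_prune,
    simulate,
    upgma,
)

sim = simulate(SimConfig(seed=5, n_samples=150))
haps = collapse_haplotypes(sim.records, sim.panel)
vectors = {h.name: h.call_vector for h in haps}

net = mp_prune(mjn(vectors, counts={h.name: h.count for h in haps},
                   site_labels=[l.locus_id for l in sim.panel]))
print(f"{len(haps)} observed haplotypes, {len(net.medians)} median vectors, "
      f"{net.graph.number_of_edges()} links, total length {net.total_length:g}")

out = Path("scratch/example_net")
out.parent.mkdir(exist_ok=True)
edges, gml = export_network(net, out)
print(f"edge list -> {edges}\nGML -> {gml}")

tree = upgma(hamming_matrix(vectors))
print("\nUPGMA dendrogram (ultrametric, site-difference distances):")
print(tree.to_newick())
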