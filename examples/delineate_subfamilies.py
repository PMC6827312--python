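"""Call subfamilies from the network at one threshold and sample representatives.

Materializes the similarity network at E = 1e-55, takes its connected
components, and applies the subfamily rules: at least 20 members and at least
two distinct taxonomic classes (clusters failing the rules become
nonclassified). Each called subfamily then contributes up to 30 random member
sequences, the down-sampled set a phylogenetic tree would be built from.
"""

from ssnfam import network, pairwise, subfamily, synth

records, truth = synth.generate_families(synth.preset_config("five_families_small", seed=11))
hits = pairwise.all_vs_all(records)

graph = network.build_graph(hits, [r.id for r in records], threshold=1e-55)
partition = network.connected_components(graph)
result = subfamily.delineate(partition, records, min_size=20)

print(f"at E = 1e-55: {len(result.subfamilies)} subfamilies, "
      f"{len(result.nonclassified)} nonclassified "
      f"(classified fraction {result.classified_fraction:.3f})\n")
print("number  size  classes  representatives")
for sf in result.subfamilies:
    reps = subfamily.sample_representatives(sf, n=30, seed=1)
    print(f"  SF{sf.number}   {sf.size:>4d}  {sf.distinct_at('class'):>7d}  {len(reps)}")
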