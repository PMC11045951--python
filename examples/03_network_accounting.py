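"""Build the reference four-area hierarchy and print its accounting.

784/400/225 representation+error triplets, a 64-unit top area and 16 gist
units give 4,307 neurons; the three tied inter-areal matrices hold the
418,000 plastic synapses.
"""

from spikepc import build_network, synapse_counts, unit_count

sizes, n_gist = [784, 400, 225, 64], 16
net = build_network(sizes, n_gist=n_gist, P_c=0.05, seed=0)

print(f"areas: {sizes}, gist units: {n_gist}")
print(f"total units: {unit_count(sizes, n_gist)}")
for k, v in synapse_counts(sizes, n_gist, 0.05).items():
    print(f"  {k}: {v}")
print("\ncounted_total = plastic + one-to-one R->E links + dense gist->R links;")
print("the sparse input->gist synapses are random (expected count above) and")
print("the one-to-one E->R feedback links are reported separately.")
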