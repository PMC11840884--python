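"""Dispersal-cost-weighted spatial networks on random and clustered landscapes.

Links connect patch pairs within a species' maximum dispersal distance;
weights give the fraction of available energy left on arrival. Connectance
(share of linked pairs) and weighted connectance (mean link weight)
summarize how well each species can move through the landscape: the large
mammal out-connects the small one everywhere.
"""

from dispersalenergy import (
    AnimalProfile,
    build_network,
    generate_clustered_landscape,
    generate_random_landscape,
)

EXTENT_M = 1.5e6  # a 1500 x 1500 km region
landscapes = {
    "random": generate_random_landscape(40, extent=EXTENT_M, seed=23),
    "clustered": generate_clustered_landscape(40, 5, spread=7e4, extent=EXTENT_M, seed=23),
}

for name, scape in landscapes.items():
    print(f"{name} landscape ({len(scape)} patches over {EXTENT_M / 1e3:.0f} km):")
    for mass in (4.5, 4000.0):
        net = build_network(AnimalProfile.mammal(mass), scape)
        print(f"  {mass:6g} kg running mammal: Dmax {net.d_max / 1e3:7.0f} km, "
              f"connectance {net.connectance():.2f}, "
              f"weighted {net.weighted_connectance():.2f}, "
              f"{len(net.to_edge_frame())} links")
    print()
print("weighted <= unweighted always: weak links count fractionally.")
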