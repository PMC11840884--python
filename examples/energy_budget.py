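"""Energy cost of a fixed dispersal bout, small versus large running mammal.

Larger animals pay more joules per metre in absolute terms, yet spend a
smaller share of their (much larger) fat reserve on the same journey —
they disperse less efficiently per joule but more efficiently per reserve.
"""

from dispersalenergy import AnimalProfile, cost_per_metre, energy_cost, relative_depletion

DISTANCE_M = 100_000  # a 100 km crossing

for mass in (4.5, 4000.0):
    animal = AnimalProfile.mammal(mass)
    outcome = energy_cost(animal, DISTANCE_M)
    print(f"running mammal, {mass:g} kg:")
    print(f"  cost per metre      {cost_per_metre(animal):10.2f} J/m")
    print(f"  cost over 100 km    {outcome.energy_cost:12.3e} J")
    print(f"  energy remaining    {outcome.energy_remaining:12.3e} J "
          f"(feasible: {outcome.feasible})")
    print(f"  share of available  {100 * relative_depletion(animal, DISTANCE_M):10.1f} %"
          "   (of the 90% of storage spendable at lambda = 0.1)")
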