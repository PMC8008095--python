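"""Expand the ganglioside biosynthetic network from bare ceramide.

Ten glycosyltransferase activities are applied iteratively: every pass
feeds each newly made glycolipid to every enzyme, until no new product
appears.  The run prints the network totals and the first few reactions.
"""

from gangliosim import SimulationConfig, expand_network, systematic_svennerholm

net = expand_network(SimulationConfig())

print(f"products:   {net.n_products}")    # unique structures made from ceramide
print(f"reactions:  {net.n_reactions}")   # (substrate, enzyme, product) edges
print(f"iterations: {net.iterations_run}")  # passes that yielded something new

print("\nfirst reactions (substrate --enzyme--> product = name):")
for ev in sorted(net.events(),
                 key=lambda e: net.generation(e.product.abbreviated))[:6]:
    pid = ev.product.abbreviated
    try:
        name = str(systematic_svennerholm(pid))
    except Exception:
        name = "(unnamed precursor)"
    print(f"  {ev.substrate.abbreviated:>6} --{ev.enzyme_number}--> "
          f"{pid:<12} = {name}")

# The deepest product sits eleven enzymatic steps from ceramide: the
# septa-sialylated GS1cα.
deepest = max(net.products, key=net.generation)
print(f"\ndeepest product: {deepest} "
      f"({systematic_svennerholm(deepest)}, generation {net.generation(deepest)})")
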