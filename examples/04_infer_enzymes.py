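"""Which enzymes are required to synthesize a given ganglioside?

Backward inference strips the last-added residue by inverting enzyme
rewrites until ceramide is reached, returning the enzyme set and a
witness biosynthetic path.  Re-simulating with exactly that enzyme
subset regenerates the target.
"""

from gangliosim import (SimulationConfig, UnreachableTargetError,
                        expand_network, infer_required_enzymes)

target = "L3Vb4[S3]L4GT"  # GM1a
result = infer_required_enzymes(target)
print(f"target {target} requires enzymes {sorted(result.enzymes)}")
for ev in result.path:
    print(f"  {ev.substrate.abbreviated:>12} --[{ev.enzyme_number}]--> "
          f"{ev.product.abbreviated}")

cfg = SimulationConfig(knockouts=frozenset(set(range(1, 11)) - result.enzymes))
print("regenerated with only those enzymes:",
      target in expand_network(cfg))

# A sialic acid written linearly on lactosylceramide is not a branch
# decoration — no enzyme of the model makes it:
try:
    infer_required_enzymes("S3L4GT")
except UnreachableTargetError as err:
    print(f"\nS3L4GT is unreachable (blocked at {err.blocked})")
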