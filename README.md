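# gangliosim

Rule-based simulation of the ganglioside biosynthetic network.

Gangliosides are sialylated glycosphingolipids — oligosaccharides built on a
ceramide anchor — that dominate the neuronal cell surface; congenital defects
in their biosynthesis cause severe neuropathies, and individual species act as
tumour markers. Their biosynthesis is combinatorial: a small set of Golgi
glycosyltransferases acts stepwise on ceramide-linked acceptors, and which
products exist follows from which activities are present.

`gangliosim` models this as a string-rewriting system. A glycan is a compact
linear *structure identifier* read right to left from the ceramide end
(G = Glc, L = Gal, S = Neu5Ac, V = GalNAc, T = ceramide; brackets delimit
branches), e.g. ganglioside GM1a is

```
L3Vb4[S3]L4GT   ≡   Galb1-3GalNAcb1-4[Neu5Aca2-3]Galb1-4GlcCer
```

Each of the ten enzyme activities of the model transfers one sugar from a
nucleotide donor, following the reaction scheme `Ax + yB = xyB + A` (chain
extension) or `Ax + yB = [x]yB + A` (branch decoration), encoded as anchored
rewrite patterns with a `*` wildcard for the unrecognized part of the
acceptor. Iterating all activities from bare ceramide to a fixed point yields
the ganglioside network: **41 structures in 49 reactions after 11 iterations**,
partitioned into the Gala arm and the 0-, a-, b- and c-series (0–3 sialic
acids on the inner galactose).

The package also:

- assigns **systematic Svennerholm names** ("G" + sialic-count letter + core
  number + series letter + α, e.g. `GP1cα`) and **IUPAC names**
  (`IV3Neu5Ac,III6Neu5Ac,II3(Neu5Ac)3-Gg4Cer`), maps the four divergent
  legacy names, and inverts names back to structures;
- converts identifiers to/from **IUPAC condensed** strings and to
  **Linear Code**;
- simulates **enzyme knockouts** (congenital deficiencies) and diffs networks;
- **infers the enzymes required** for a target glycan by backward rewriting;
- exports networks as **CSV, SBML Level 3, Graphviz DOT and edge lists**.

## Worked example

```python
>>> from gangliosim import (SimulationConfig, expand_network,
...                         systematic_svennerholm, knockout_scan)
>>> net = expand_network(SimulationConfig())
>>> net.n_products, net.n_reactions, net.iterations_run
(41, 49, 11)
>>> str(systematic_svennerholm("S3L3[S6]Vb4[S8S8S3]L4GT"))
'GP1cα'
>>> nets = knockout_scan(SimulationConfig())
>>> [nets[i].n_reactions for i in (1, 3, 7)]
[4, 5, 9]
```

The first line regenerates the full wild-type network from ceramide: 41
product structures, 49 enzymatic reactions, fixed point after 11 productive
passes. The naming call decomposes the penta-sialylated identifier — 5 sialic
acids → letter P, fully extended core → core 1, three sialic acids on position
II → c-series, α2,6-Neu5Ac on the GalNAc → α. The knockout scan shows the
three core-building transferases (glucosylceramide synthase, LacCer synthase,
GM2/GD2 synthase) each collapse the network below ten reactions.

The same functionality is available from a shell:

```sh
$ gangliosim simulate --format dot --out network.dot
41 structures, 49 reactions, 11 iterations -> network.dot (dot)
$ gangliosim name 'S3L3[S6]Vb4[S8S8S3]L4GT'
identifier: S3L3[S6]Vb4[S8S8S3]L4GT
ssn:        GP1cα
iupac:      IV3Neu5Ac,III6Neu5Ac,II3(Neu5Ac)3-Gg4Cer
legacy:     GP1cα
$ gangliosim infer 'L3Vb4[S3]L4GT'
required enzymes: 1, 3, 4, 7, 8
...
```

Narrative scripts in `examples/` walk through each capability (simulation,
nomenclature, knockouts, enzyme inference, export formats).

## Documentation

`docs/methods.md` describes the model, the pattern-matching semantics, the
naming algorithms, numerical/formatting conventions and known limitations.
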