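# Methods

## Model

Ganglioside biosynthesis is modelled as an untimed rewriting system over
linear structure identifiers. A glycan is a rooted tree of residues on a
ceramide anchor; its canonical identifier is read right to left from the
ceramide end, with square brackets delimiting every branch that is not the
continuation of the main chain, branches ordered by ascending linkage
position (lowest written nearest its parent). Brackets carry meaning beyond
the tree of linkages: a bracketed sialic acid is a *decoration* of an inner
residue (`[S3]L4GT`, GM3), while an unbracketed one is a terminal chain
extension (`S3L3…`, the 0-series route); the two are distinct acceptors and
only the first arises on position II. Parsing preserves bracketing,
canonicalization only orders siblings, and parse∘serialize is the identity in
both dialects (the full dialect writes every anomer; the abbreviated one
drops default anomers — Glc, Gal β; Neu5Ac α — but always writes GalNAc's
non-default β).

Each enzyme activity is a donor plus one or more anchored rewrite patterns
over canonical abbreviated identifiers:

- **prefix** patterns anchor at the non-reducing end and run through the
  terminal T; `*` matches any bracket-balanced substring. A pattern without
  a wildcard (e.g. `L4GT` for the first sialylation) therefore matches only
  that exact acceptor.
- **internal** patterns are bracket-delimited literals matching any
  occurrence; because brackets must align literally, `[S8S3]` cannot match
  inside `[S8S8S3]`, which is what caps every sialyl chain at three.

Matching on canonical strings is equivalent to subtree matching for every
acceptor this rule set generates; the string form makes the published
patterns directly executable.

## The enzyme set

The ten activities (glucosyl-, galactosyl-, N-acetylgalactosaminyl- and
sialyltransferases; see `default_ruleset()` for EC numbers and names) follow
two reaction shapes — linear insertion (`Ax + yB = xyB + A`) and bracketed
insertion (`Ax + yB = [x]yB + A`) — and are classified as extension
(1, 2, 3, 5, 7, 8), decoration with extension (4), decoration (10),
termination with extension (9) and termination (6). `classify_activity`
validates each rewrite shape against the declared category (a decoration must
create exactly one new bracket pair; every rewrite must add exactly one
residue equal to the donor sugar).

Three deliberate generalizations beyond the minimal literature patterns are
part of the default set, each required for a documented product family:

1. activity 6 also initiates the α2,8 extension of a terminal α2,3 sialic
   acid (`S3*T → S8S3*T`), without which the 0-series GD1/GT1 and every
   IV-disialyl species would be unreachable;
2. activity 5 also acts on sialyl-galactosylceramide (`[S3]LT → [S8S3]LT`),
   giving the Gala arm products GD4 (and, via 6, GT4);
3. activity 7 (GM2/GD2 synthase) accepts the di- and tri-sialylated inner
   branches (`[S8S3]`, `[S8S8S3]`), giving GD2 and GT2.

Prefix anchoring of activity 5 encodes the biological ordering assumption
that GD3 synthesis precedes core extension with GalNAc: once `Vb4…` heads the
identifier, the pattern can no longer match. Conversely activity 6's
bracketed pattern is anchored internally, so every b-series branch can
convert to its c-series counterpart at any core stage — this single choice
reproduces the full 41-structure/49-reaction network, and it, rather than a
second application of activity 5, is what carries GD4 → GT4.

Rule sets serialize to a one-record-per-line text format
(`ruleset_to_text`/`ruleset_from_text`) so custom "wild-type" sets can be
defined, stored and replayed.

## Network expansion

`expand_network` performs synchronous breadth-first expansion: pass *k*
applies every active enzyme to every structure first seen in pass *k−1*,
records **all** discovered reactions (including edges into already-known
products — several products have multiple producers, and those edges are part
of the 49), and promotes novel products to the next frontier.
`iterations_run` counts passes yielding at least one novel structure; the
final pass that merely confirms the fixed point is not counted. Under this
convention the default run gives 11 iterations — the depth of the longest
biosynthetic path, T → … → GS1cα. Expansion is order-independent (set
semantics; asserted by a shuffled-rule-order test), and `truncated` flags a
run stopped by the pass limit (default 20) while still productive.

Knockouts remove whole activities; `knockout_scan` regenerates the network
once per enzyme (wild type under key 0). Because rules only produce and never
consume, knockout networks are monotone: any enlargement of the knockout set
shrinks nodes and edges, which the tests assert for all ten single knockouts.

`infer_required_enzymes` runs the rules backward: each inverse rewrite strips
one residue, every candidate precursor is confirmed by the forward rule, and
depth-first search ordered by (precursor identifier, enzyme number) returns a
deterministic witness path from ceramide plus the enzyme set along it.
Underivable targets raise an error naming the first intermediate with no
admissible precursor.

`reference_enumeration` builds the expected wild-type network *without* the
pattern engine, from the closed-form parameterization of the product
families: the Gala arm (GalCer + chain of 1–3 sialic acids), the Glc-arm
intermediates, and the fully-extended-core grid — position II branch
(0–3) × position IV terminal chain (0–3) × optional α2,6 Neu5Ac on position
III (only with a sialylated IV), 4 × (1 + 3×2) = 28 structures — with edges
written per rule. Engine and enumeration are compared as labelled graphs in
the tests; they agree node for node and edge for edge.

## Nomenclature

The systematic Svennerholm name is assembled as
`"G" + count letter + core number + series letter + α` with count letters
A M D T Q P H S (0–7; the grammar's maximum is 7, realized by GS1cα),
core number 5 − n for a Glc-based backbone of n residues and 4 for
galactosylceramide cores, series letter a/b/c only on the fully extended
core (position II branch 1–3; the 0-series takes no letter), and α marking
the α2,6 Neu5Ac on position III. Bare ceramide and glucosylceramide precede
the system's cores and raise `NoNameError`; exporters render them by
identifier. `parse_ssn` inverts the name (series → II, α → III, remainder →
IV chain) and rejects internally inconsistent names such as "GM1b" read
systematically.

Conventions fixed here because no authority pins them down:

- Greek `α` is the only alpha marker; a trailing ASCII `a` is always the
  series letter (otherwise GD1a and GD1α would collide).
- IUPAC names are rendered in plain text by default
  (`II3(Neu5Ac)2-Gg4Cer`), with `markup=True` producing the
  caret/underscore form `II^3^(Neu5Ac)_2_-Gg_4_Cer`; plain text keeps CSV
  output bit-stable.
- Shorter Glc-based cores keep the `Gg_n` descriptor with their actual core
  length (GM3 → `II3Neu5Ac-Gg2Cer`); Gal-based cores use `GalCer` with the
  lone galactose as position I (GM4 → `I3Neu5Ac-GalCer`). The rescinded
  `GgOse_n`-style descriptor is never emitted.
- Linear Code export uses the fixed map Gal→A, Glc→G, GalNAc→GN, Neu5Ac→NN
  with a `Cer` suffix and parenthesized branches; since no authoritative
  example of the dialect was available for these lipids it is export-only
  (no importer), to avoid committing to an unverifiable reading.

Only four traditional names differ from the systematic system (GM1b↔GM1,
GM1↔GM1a, GD1c↔GD1, GD1aα↔GD1α); `legacy_mapping` applies exactly those rows
and warns on the ambiguous traditional "GM1", returning both candidates.

## Export

CSV (RFC 4180, one row per product, ordered by generation then identifier),
SBML Level 3 Version 1 (single `golgi` compartment — the model has no
compartmentation; one species per glycan plus the four nucleotide-sugar
donors and two nucleotides, static ChEBI annotations from a hard-coded
table; one irreversible reaction per edge, all stoichiometries 1; glycan ids
escape brackets reversibly as `_b_`/`_e_`), Graphviz DOT (edges colored by
transferred sugar: galactosyl gold, glucosyl blue, GalNAc brown, sialyl
magenta) and a tab-separated edge list. All writers are deterministic and
timestamp-free, so repeated exports are byte-identical; `read_sbml_edges`
re-imports an SBML file to the reaction-triple set for round-trip checking.

## Testing and problem sizes

The network is small (42 nodes, 49 edges) and every computation is exact and
deterministic, so the full suite — including the exhaustive per-node
inference-and-regeneration property and SSN bijection over all 40 nameable
products — runs in a few seconds. Property tests additionally exercise 100
randomized grammar-valid trees per round-trip property (hypothesis,
derandomized profile); these trees cover arbitrary valid bracketing and
linkages, not just rule-reachable structures, so parser/serializer guarantees
do not depend on the enzyme grammar.

## Limitations

Activities are binary (present/absent): no kinetics, donor concentrations,
reversibility, transport or lysosomal recycling. Sialic acid variants
(Neu5Gc, KDN), O-acetylation and other modifications are out of scope, as are
GlycoCT import/export and 2-D structure drawing. The simulator treats the
rule set as ground truth; structures outside its grammar are reported as
unclassifiable or unreachable rather than guessed at.
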