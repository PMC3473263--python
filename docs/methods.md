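# Methods

## The regulation model and its assumptions

The model is *qualitative* and *declarative*: each regulatory interaction
is one record with a class, a regulator entity, a regulated entity and a
sign, not a mechanistic reaction chain. No quantitative parameters
(affinities, rates) and no combinatorial logic of co-acting regulators are
represented; when a gene has both an activator and an inhibitor the model
makes no claim about the combined outcome. Post-translational control
(covalent modification, sequestration) is represented as ordinary reaction
records rather than regulation records, so the full set of influences on a
protein is the union of the regulations touching it and the reactions it
participates in. Regulation of protein degradation is reserved in the
class vocabulary but rejected by validation as unsupported, and
environmental regulators (temperature, pH) cannot be expressed: a
regulator is always a product or a compound.

Gene order inside a transcription unit is authoritative: a terminator's
`site_index` counts the genes upstream of it, so attenuation semantics
need no genomic coordinates. Identifiers are case-sensitive opaque
strings, globally unique across entity kinds; all list outputs are sorted
for determinism.

Where a translational regulation targets a whole TU, every TU gene is
taken as regulated. The alternative — only genes downstream of the
regulator's mRNA site — would need binding-site-to-gene mapping that the
qualitative model does not carry.

## Gene network construction

Edges run from each gene encoding the regulator (polypeptides/RNAs to
their genes, modified forms through their base form, complexes through the
union of product components; compounds encode nothing) to each regulated
gene. Enzyme modulation never contributes edges; sigma-factor recognition
contributes activation edges when requested. Conflicting signs on one
ordered pair merge to `dual` under the lattice
`unknown < activation/inhibition < dual`: `dual` is strictly more
informative than ignoring the conflict, and `unknown` is absorbed by any
informative label. Compound regulators such as riboswitch ligands are out
of this gene-to-gene graph by construction; they are handled by the signed
entity graph instead.

Layout operations are coordinate computations only. The elliptical layout
places sigma-factor genes, other regulators, and pure targets on three
concentric ellipses (axes ratio 2:1, semi-minor radii 1, 2, 4 — concrete
values are this package's choice); a gene that is both sigma factor and TF
sits in the inner ring. The layered layout gives each regulator the layer
1 + (longest path through regulators), computed on the condensation so
mutually regulating genes share a layer; non-regulators form layer 0,
ordered contiguously by regulator-set cluster. "Regulator" means
out-degree > 0 in the built network, so translational regulators land in
the regulator ring/layers too.

## Influence ranking

Parameters: `normalization` (`regulator-count` default, or `none`),
`damping` α (default 0.001), `tolerance` (default 1e-12, L1 change per
iteration; 0 demands an exact floating-point fixed point) and
`max_iterations` (default 100 000). The iteration is
s ← (1−α)(M+I)s + αu with L1 renormalization; the +I shift removes
period-2 oscillation on bipartite/cyclic structures without changing
eigenvectors, and the damping term makes the dominant eigenvector unique
on disconnected graphs. The adjacency is sign-blind: repressors are as
influential as activators, and autoregulatory self-loops are kept.

Two numerical details matter. The final rescale divides by the maximum
*before* multiplying by 100 so that exactly equal entries give exactly
100.0. And because the per-iteration change underestimates the remaining
error when the spectral gap is small, the loop keeps polishing after the
tolerance is reached until the change stops improving (the floating-point
noise floor); on 20–50-node graphs this holds the L1 gap to a dense
eigendecomposition below 1e-8 after rescaling.

Printed scores follow the two-significant-figure convention below 10 and
integers above.

## Regulation enrichment

The test is the one-sided hypergeometric upper tail (Fisher exact in the
enrichment direction), computed by `scipy.stats.hypergeom`; it agrees with
exhaustive subset enumeration to better than 1e-12 on universes up to 20
genes. The candidate family is every gene with at least one target in the
universe under the chosen mode (direct, or reachability-bounded indirect),
so the multiple-testing family is model-dependent; its size is reported.
Correction is Benjamini–Hochberg at α = 0.05 by default (Bonferroni and
none available). Operon expansion is *not* applied implicitly: membership
is decided by network edges only, and callers who want operon-mates
expand the group first.

## Signed influence inference

The parity graph unifies a gene with its primary polypeptide/RNA product
(one node); complexes, modified forms and compounds are separate nodes
joined by positive formation edges. Regulation edges carry the mode sign
(`dual` → both signs; `unknown` mode edges are omitted — no information —
whereas a dual edge's ambiguity *is* information). Irreversible reactions
make reactants and enzyme activators of each product, and make the enzyme
and co-reactants inhibitors of each reactant; reversible reactions are
skipped because their net direction is ambiguous. Compounds in more than
`hub_threshold` (default 10) reactions are dropped entirely. Defaults
`depth = 6` and `hub_threshold = 10` are package choices, surfaced as CLI
flags and echoed in output metadata.

Classification iterates to a fixpoint: sign sets are products over simple
paths (length ≤ depth) whose intermediate nodes are determined; entities
collecting both signs are declared unknown and excluded as intermediates;
recomputation repeats until stable. The exclusion set only grows, so at
most |V| rounds occur (2 suffice in practice). After the final round, an
ambiguous entity that still has an admissible path stays unknown; an
entity whose every path was pruned is simply not classified. Simple paths
mean autoregulatory loops cannot feed a node's sign back into itself —
this package's resolution of an otherwise under-determined semantics.
Shortest-path and majority-vote tie-breaking are deliberately *not*
implemented; ambiguity is reported as ambiguity.

One symmetry worth stating precisely: negating the signs of the edges
*into the target* swaps activators and inhibitors exactly (every path
crosses exactly one such edge). Negating *every* edge does not, because
even-length paths keep their product.

## The synthetic generator

The generator emulates the structure of curated bacterial regulatory
databases: geometric operon sizes (mean 2), one promoter per TU with a
uniformly assigned sigma factor, Poisson regulon sizes (mean 6 promoters
per TF), modes drawn as 45% activation / 40% inhibition / 5% dual /
10% unknown, attenuation and translational regulation as small fractions
(5% / 8%) of the expression regulations, a ligand-bound-complex or
modified-form presentation for half the TFs, and a compound/reaction layer
with substrate-level modulation flagged physiologically relevant half the
time. Hub compounds are wired into exactly `hub_degree` (12) reactions to
sit decisively above the default pruning threshold. These defaults are
plausible for a small bacterium and fixed once; they are conditions, not
tuning knobs.

All randomness flows from one master seed through named substreams (one
per entity class), so regenerating with the same parameters is
byte-identical and adding a feature never perturbs earlier draws. During
construction the generator writes a ground-truth ledger (per-class counts,
per-regulator target sets, hub ids) from its own bookkeeping — not by
calling the analysis code — so ledger-versus-analysis comparisons are
genuine cross-checks.

What the generator does **not** emulate: sequence-level realism, genomic
coordinates, scale-free regulon-size distributions, condition-dependent
regulation, or the empirical statistics of any real organism. Tests
passing on generated models therefore validate the algorithms' contracts,
not organism-specific conclusions.

## Problem sizes and verification

The test suite and the acceptance script run entirely on generated or
hand-built inputs: influence is checked on 50 random 20–50-node networks
against a dense eigensolver; parity on 200 random signed graphs (≤ 30
nodes, depth 6) against exhaustive path enumeration; enrichment on all
(N ≤ 20, K, n, k) grid configurations against subset counting; round-trips
and generator fidelity on 20 seeds each; and the end-to-end workflow on a
2000-gene model with 80 TFs. Reproducing the published regulatory content
of any real organism's database is out of scope — those numbers are
functions of licensed database content, and the computations here are
validated by oracle equivalence instead.

## Known limitations

* Qualitative only: no effect strengths, no combinatorial promoter logic.
* The gene network collapses multiple mechanisms between one gene pair
  into a single labeled edge (provenance preserves the underlying
  regulation ids).
* Parity inference treats each regulation independently; a ligand that
  *blocks* a repressor, for example, is representable only through the
  complex/modified-form structure, not as an edge-on-edge effect.
* Enrichment assumes the universe is the right null; users supplying a
  biased universe get the corresponding null.
* Layouts are deterministic coordinate assignments for export, not
  aesthetic optimizations.
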