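# Methods

This note documents the models and procedures implemented in `phylomod`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions.

## Diagonal weights

A *diagonal* is a gap-free alignment of two equal-length segments from two
different sequences. Its score is the sum of integer substitution scores
(BLOSUM62 by default; `X` scores 0 against everything). The statistical
weight is

    w(l, s) = −ln P(l, s),

where `P(l, s)` is the probability that two independent random segments of
length `l`, with residues i.i.d. from the background distribution
(Robinson & Robinson 1991 frequencies by default), reach summed score
≥ `s`. `P` is computed **exactly** by convolving the integer per-column
score distribution `l` times — no Karlin–Altschul asymptotics — so the
weight is meaningful down to `l = 1`.

For enumeration and extension the weight is corrected for the number of
placements: a length-`l` diagonal can sit at
`N = (L_a − l + 1)(L_b − l + 1)` positions in a pair of sequences of
lengths `L_a, L_b`, so the corrected weight is `w − ln N`, bounding the
probability of a chance diagonal *anywhere in the pair comparison*. Without
this correction a threshold of 10 nats admits ~`e⁻¹⁰` *per window*, i.e.
dozens of chance diagonals per pair of 100-residue random sequences, which
is incompatible with treating threshold-passing diagonals as strong
conservation. `ScoringModel.weight`/`diagonal_weight` expose the raw
`−ln P`; `ScoringModel.corrected_weight` applies the length term.

Defaults: maximum diagonal length `M = 20` residues, weight threshold
`t = 10` nats (`e⁻¹⁰ ≈ 4.5 × 10⁻⁵`), minimum module length 5 residues with
the boundary inclusive (a block of exactly 5 columns is a module); all
three are configurable.

## PLMA construction

Candidate diagonals are every window of length 1..`M` over every ordered
sequence pair whose corrected weight reaches `t`. Per diagonal offset the
windows are filtered greedily: strongest first, discarding windows that
overlap an already-kept stronger window, so each conserved stretch
contributes its best-supported window rather than a pyramid of nested
sub-windows.

Retained diagonals are ranked (weight desc, length desc, then coordinates —
determinism is the requirement, the ordering heuristic is ours) and
inserted one at a time into the position-class structure. An insertion
merges, column by column, the classes of the two aligned positions,
transitively with everything already aligned to them. It is accepted
atomically iff afterwards (a) no class contains two positions of one
sequence and (b) the precedence graph between classes — induced by position
order within each sequence — is acyclic. Cycle checking runs on the graph
condensed to merged classes (singleton classes cannot break a cycle's
contraction), with a full uncondensed recheck available for tests.
Rejected insertions restore the previous state exactly.

After an accepted insertion the diagonal is locally extended one column at
a time at both ends, X-drop style: columns are explored while the corrected
weight stays within 8 nats of the running best, and the extension is kept
only up to the weight-maximal endpoint. This bridges isolated mutated
columns inside a conserved stretch but cannot crawl into background, since
background columns only lower the weight. Alternatives considered:
extending only while the weight strictly improves truncates diverged motifs
at their first mismatched column; extending while the weight merely stays
above `t` never stops for strong diagonals. The 8-nat drop-off bridges one
poor column (a worst-case BLOSUM62 column costs ~6–7 nats) but not a run of
noise.

**Blocks** are maximal chains of consecutive columns whose classes hold the
same sequence set at consecutive positions; by construction each segment of
a block is aligned, over its full length, to all and only the other
segments. **Modules** are blocks of length ≥ 5 with ≥ 2 member sequences;
multiple segments of one module in the same sequence collapse to presence
when carriers are derived.

## Representative selection

When a GFF3 annotation is supplied, proteins of one species whose coding
loci overlap by ≥ 1 base on the same contig and strand are grouped as
isoforms of one gene (transitive closure, computed by an interval sweep);
the longest protein represents each gene, ties broken by lexicographically
smallest id. GFF3 coordinates (1-based closed) are converted to 0-based
half-open internally; the overlap test is equivalent to closed-interval
intersection on the original coordinates. Proteins absent from the GFF are
kept as flagged singleton genes rather than dropped.

## Ancestral module composition

Default backend: **Dollo parsimony**. A module arises once — at the last
common ancestor of its carrier leaves — and may be lost any number of
times; the loss-minimising assignment puts the module at exactly the nodes
that descend from that LCA and have ≥ 1 carrier in their clade. On binary
trees this optimum is unique (verified against exhaustive single-gain
enumeration in the tests).

Alternative backend: **LCA mapping** of per-module trees, for module
histories that conflict with the gene tree. Module trees are built by
neighbor joining on p-distances of the gapless segments (modules with < 3
segments fall back to Dollo); each module-tree node maps to the gene-tree
LCA of the gene leaves below it, and presence is closed along the gene-tree
path between the images of module-tree parent and child. Duplication- and
transfer-aware reconciliation is out of scope.

Gains and losses are set differences against the parent node. The root has
no parent: its composition is reported but contributes no gain events, so
family-wide ancestral content never masquerades as a signature.

## Ancestral binary traits

Each trait (a PPI with one partner protein) is a two-state character with
leaf statuses 1 (able to interact), 0 (not able), `?` (missing). The
annotation helper sets focal-species leaves to 1/0 against the partner
universe and everything else to `?`, mirroring the situation where
interaction data exist for one well-studied species.

The model is a two-state continuous-time chain with stationary frequencies
`(π₀, π₁)` and intensity `μ` (an F81-type parameterisation):
`P(i→j|t) = π_j + (δ_ij − π_j) e^(−μt)`. `π₁` and `μ` are estimated per
trait by coordinate-wise bounded likelihood maximisation (4 rounds of
Brent's method on `π₁ ∈ [10⁻⁶, 1−10⁻⁶]` and `ln μ ∈ [ln 10⁻⁴, ln 10³]`),
or can be fixed. Zero or missing branch lengths are replaced by `10⁻⁶`.
Marginal posteriors come from the standard inside/outside pass; pruning is
verified against exhaustive joint summation to `1e-9` in the tests.

States are called per node by MPPA: the subset of states (best state alone,
or both) minimising the Brier distance between the marginal posteriors and
a flat prediction over the subset. For two states this calls the best state
alone iff its posterior exceeds 3/4, preferring the single state on ties;
otherwise the node is ambiguous `{0, 1}`. Ambiguous nodes are **excluded**
from `In`, keeping gain events — which trigger signatures — conservative.
Only the most-likely scenario is reported; posteriors are exported for
inspection. Observed leaves are never overwritten.

## Co-appearance signatures

A signature is a non-root node where both `Mn+` and `In+` are non-empty;
leaves may carry signatures. Nodes with a PPI gain but no module gain are
reported separately. `signature_stats` gives exact counts (events, min/max
modules and PPIs per signature, distinct totals). The packaged ADAMTS-TSL
catalogue of 45 curated events is parsed with exact whitespace tokenisation
and preserves its source identifiers verbatim, including one known
internal inconsistency of that source (node G96's module list reads
"B773 B781" in the table against "(B773, B783)" in the accompanying text;
the catalogue follows the table).

## Synthetic data generator

`simulate_family` emulates the statistical structure the pipeline assumes:

- a species tree (balanced by default, branch lengths U(0.1, 0.5)) and a
  gene tree grown on it by duplication/loss (both rates default 0, giving
  one gene per species — 16 leaves by default);
- modules: each assigned a master motif (length 8–16, residues from the
  background), a gain node (random internal non-root node), and losses on
  branches below the gain (Poisson, rate 0.05 per unit branch length, with
  ≥ 2 surviving carriers enforced); each carrier leaf receives a copy of
  the motif mutated at `divergence/2` per site, so two copies differ at
  ~`divergence` (default 0.10) of their sites;
- sequences: i.i.d. background residues (length 100) with module copies
  inserted in a shared left-to-right order, so planted configurations are
  alignment-consistent; a `shuffled_module_order` mode breaks the order to
  exercise consistency rejection;
- traits: 3 by default, all placed at module gain nodes
  (`coplaced_fraction = 1.0`), leaf statuses 1/0 in focal species and `?`
  elsewhere (default: all species focal, i.e. fully observed leaves).

Everything is deterministic given the seed, and the ground truth (per-node
module and trait sets, gain nodes, planted segments, co-appearance nodes)
is emitted alongside.

What the generator does **not** emulate: indels (within modules or
background), compositional bias and repeats in real protein backgrounds,
correlated module architectures (domains travelling together), trait
losses, and annotation errors in the trait table. Passing recovery tests
therefore demonstrate correctness of the machinery under the model's own
assumptions, not performance on real proteomes, where background homology
and sparse single-species annotation make both module membership and trait
reconstruction harder.

`benchmark_recovery` runs the full pipeline on seeded replicates of this
generator and scores detected co-appearance nodes against the planted ones.
Under the defaults above (20 seeds, 16 leaves, 6 modules, 3 co-placed
traits) it is the basis of the end-to-end acceptance test; the remaining
failure modes are intrinsic: a trait gained at a node covering roughly half
the tree near the root is statistically indistinguishable from root
presence plus one loss (and the root convention suppresses the latter), and
a 2-carrier length-8 module rests on a single diagonal that chance mutation
load can push below threshold.

## Pipeline and outputs

`analyze` is the in-memory pipeline; `run_pipeline` adds file IO and writes
a manifest (package version, seed, parameters, SHA-256 checksums of the
inputs, completed stages). All tables are TSV with fixed column order and
deterministic sorting, so reruns are byte-identical. Each stage is also
exposed as a CLI subcommand (`prep`, `plma`, `modules-anc`, `traits-anc`,
`signatures`, `simulate`, `itol`, `run-all`) operating on the previous
stage's files, which is how partial reruns are done; `run-all` itself
always recomputes, since a full run at package scale takes seconds.

iTOL exports follow the dataset header grammar (`SEPARATOR`,
`DATASET_LABEL`, `COLOR`, `DATA`): `DATASET_BINARY` for per-leaf module
presence, `DATASET_DOMAINS` for module segments drawn along sequences, and
a plain-text per-node gained-module annotation with co-appearance nodes
starred. Module colours and shapes derive from a stable hash of the module
id, so reruns and subsets colour identically.

## Numerical conventions and edge cases

- Sequence coordinates are 0-based half-open everywhere internally.
- Convolution tail probabilities are exact up to float64 rounding; a tail
  of exactly 0 (score unattainable) maps to infinite weight.
- NJ branch-length estimates below 0 are clamped to 0; midpoint rooting is
  used when no outgroup is given; outgroup rooting requires the outgroup to
  be one side of a split of the unrooted tree and reports offenders
  otherwise.
- Ties: equal-length isoforms → smallest id; equal-weight diagonals →
  longer first, then coordinates; MPPA posterior ties at the 3/4 boundary →
  the single state; block and module ids follow first-segment coordinates.
- Traits observed in a single leaf are processed but flagged
  (`single_carrier`), since their gain is necessarily at that leaf; modules
  with a single carrier are retained in compositions but can never
  generalise beyond their leaf.
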