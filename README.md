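# phylomod

Conserved sequence modules by partial local multiple alignment, and
detection of module–interaction co-appearance along a gene tree.

## The problem

Multidomain protein families — the ADAMTS/ADAMTS-like extracellular-matrix
proteases are the motivating example — carry function in conserved sequence
stretches that are often narrower than, or invisible to, curated domain
models. `phylomod` finds **every** gapless stretch conserved in at least two
proteins of a family (a *conserved sequence module*), reconstructs when each
module and each binary trait (here: protein–protein interactions, PPIs) was
gained or lost on the family's gene tree, and reports the nodes where a
module gain and a PPI gain **co-appear**. The gained modules `Mn+` at such a
node form a candidate sequence signature of the gained interactions `In+`.

It is aimed at computational biologists studying gene-family evolution who
have protein sequences, a rooted gene tree, and per-protein trait
annotations (typically from one well-annotated species).

## Method in brief

1. **Diagonals.** All gap-free pairwise alignments ("diagonals") of length
   ≤ *M* (default 20) are scored with BLOSUM62 over Robinson–Robinson
   background frequencies. A diagonal's weight is
   `w = −ln P(length, score)`, with `P` computed by exact convolution of the
   per-column score distribution and corrected for the number of possible
   placements in the two sequences; diagonals with `w ≥ t` (default 10 nats,
   i.e. chance probability below `e⁻¹⁰ ≈ 4.5 × 10⁻⁵`) are kept.
2. **PLMA.** Diagonals are ranked by weight and inserted greedily into a
   *partial local multiple alignment*: a partition of all sequence positions
   into alignment classes, merged transitively, with an insertion accepted
   only if no class ends up holding two positions of one sequence and the
   class precedence order stays acyclic.
3. **Blocks and modules.** Blocks are maximal runs of consecutive columns
   with identical sequence membership; blocks of length ≥ 5 with ≥ 2 member
   sequences are the conserved sequence modules.
4. **Ancestral modules** (`Mn`): Dollo parsimony (one gain at the LCA of the
   carriers, losses free) or LCA mapping of per-module trees.
5. **Ancestral traits** (`In`): two-state F81-type model
   `P(i→j|t) = π_j + (δ_ij − π_j)e^(−μt)` with ML-estimated `π, μ`,
   marginal posteriors by Felsenstein pruning, and Brier-optimal MPPA state
   calls (ambiguous nodes excluded from `In`).
6. **Signatures.** Per node, `Mn+/Mn−` and `In+/In−` are set differences
   against the parent; nodes with both `Mn+` and `In+` non-empty are the
   co-appearance events.

A synthetic-data generator (`phylomod.synthetic`) produces families with
planted modules and traits plus full ground truth, so the entire pipeline is
testable without external data. A packaged catalogue of 45 curated
ADAMTS-TSL co-appearance events ships as a worked-example fixture
(`phylomod.signatures.load_adamts_signatures`).

## Worked example

Simulate a 16-leaf family with 6 planted modules and 3 PPIs co-placed with
module gains, then run the full pipeline:

```bash
phylomod simulate --seed 1 -o sim
phylomod run-all --fasta sim/family.fasta --tree sim/gene_tree.nwk \
                 --traits sim/traits.tsv -o out
```

The run prints the signature summary:

```json
{
  "distinct_modules": 3,
  "distinct_ppis": 3,
  "max_modules": 1,
  "max_ppis": 1,
  "min_modules": 1,
  "min_ppis": 1,
  "n_events": 3,
  "total_module_entries": 3,
  "total_ppi_entries": 3
}
```

Three co-appearance events were detected, each pairing one gained module
with one gained PPI. `out/signatures.tsv` names them:

```
node  paralog_ancestor  descendants  ppis  modules
G12   0                              T2    B5
G3    0                              T3    B1
G5    0                              T1    B2
```

For this seed the generator planted its three trait gains at nodes G12, G3
and G5 (`sim/ground_truth.json`), so detection is exact. The run directory
also contains the module table (`modules.tsv`: one line per gapless segment
with 0-based half-open coordinates), per-node ancestral compositions, trait
posteriors, gain/loss tables, and iTOL annotation files
(`out/itol/`: `DATASET_BINARY` for per-leaf module presence,
`DATASET_DOMAINS` drawing module segments along each sequence, and a
per-node gained-module annotation) ready to drop onto an uploaded tree.

The same analysis is available as a library:

```python
from phylomod import SimConfig, simulate_family
from phylomod.pipeline import analyze

sim = simulate_family(SimConfig(seed=1))
result = analyze(sim.records, sim.gene_tree, sim.trait_table)
for sig in result.signatures:
    print(sig.node, sig.gained_ppis, sig.gained_modules)
```

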