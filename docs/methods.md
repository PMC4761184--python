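# Methods

This note records the model conventions, numerical choices and known
limitations of `unbio`, in the order the pipeline runs.

## Molecular graphs and matching

A molecule is a connected graph of heavy atoms labelled by element, with
integer bond orders 1-3; hydrogens are implicit and fill whatever valence
explicit bonds leave open. The model is strictly 2-D topological:
stereochemistry and isotopes are erased on input and formal charges are
normalized to neutral. Consequences worth knowing: carboxylates read as
the acid; structures that are only valence-legal *as ions* (nitro groups,
quaternary ammonium) are rejected by the neutral valence model (C/Si 4,
N 3, O 2, P ≤ 5, S ≤ 6, halogens 1). This is deliberate — the score is
defined on neutral 2-D structure — but it means charge-separated drawing
conventions must be rewritten before scoring.

Equality is canonical-string equality. Aromatic input is normalized to a
*single* kekulized form by canonicalizing with aromatic perception first
and kekulizing from the canonical atom order, so every spelling of a
molecule produces the same alternating-bond graph. All matching is on
these kekulized graphs.

"Fragment A matches molecule B" means a monomorphic overlay: an injective
atom mapping preserving elements, with every bond of A present in B at
the same order. B may have extra bonds among the matched atoms (a C-C-C
chain matches cyclopropane). Embedding *counts* are per distinct
atom-plus-bond subset, so automorphic re-mappings of a symmetric pattern
onto the same atoms count once; this makes the descriptor an occurrence
count. The maximum common subgraph is required to be connected, maximizes
heavy atoms, and breaks ties by lexicographically smallest canonical
string, making it deterministic and symmetric. MCS candidates range over
connected bond-subsets of induced subgraphs, so ring-versus-chain
overlays are found.

## Chemical-space enumeration

Enumeration grows graphs breadth-first — attach an atom by a legal bond,
or close a ring — deduplicating by canonical string at every step. Any
connected graph is reachable (spanning tree, then closures), so the
enumeration is exhaustive for the rule set, the design contract here.
Oxidation-state policy is applied at emission: phosphorus is kept only
with bond-order sum 4-5 (hydrogen fill then yields P(V)); sulfur with sum
≤ 2 (S(II)) or exactly 6 with at least two double-bonded oxygen
neighbours ("sulfate-like" S(VI)). Ring systems are connected components
of the cycle-edge subgraph (fused rings count once) and at most two are
allowed; `min_ring_size` defaults to 3, i.e. small rings are *not*
excluded from the space even though metabolism avoids them.

The stability ban list is an explicit extension point: the shipped
default (O-O-O, N-N-N, N-O-N chains, embedded O=C=O, S-S) covers
textbook-unstable motifs, but tests pin their own lists and users can
supply pattern files. Banned patterns prune the search (substructure
presence is monotone under growth); state rules do not (a growing sulfur
may still reach sulfate).

Full enumeration is capped at 8 heavy atoms. Within the cap,
`sample_space` draws uniformly from the enumerated space (multi-element
spaces near the cap are expensive to enumerate; `method="grow"` forces
the sampler below). Beyond it, a random-growth sampler applies a random
sequence of legal moves and rejects molecules failing the emission
filters — deterministic under its seed but *not* uniform, which only
matters for spaces too large to enumerate anyway. A size-distribution
control (`exact_size`) is available for null models that must preserve
molecule size.

## Fragment pools and the Ub score

The fragment pool is the fixed point of iterated MCS: molecule pairs,
then fragment-fragment and fragment-molecule pairs, keeping connected
results of 3 to `max_frag_size` (default 14) atoms. Iteration order is
fixed by canonical sort so pools and their serializations are
reproducible; the fixed point itself is order-independent. Every pool
member occurs in at least two source molecules by construction.

Ub_N is computed from *all* connected N-atom node-induced subgraphs of
the metabolites — not from the ≥2-occurrence pool, which is a convenience
restriction for descriptors, not part of the score's definition. A region
of the test molecule is a connected node-induced subgraph; it is
unbiological when no reference N-fragment overlays inside it. Since
regions are induced, a reference embedding lies inside a region exactly
when its atom set does, so scoring reduces to: find the largest connected
atom subset containing no embedding atom set. The solver branches on
deleting one atom of some contained embedding (branch-and-bound with
memoization); the oracle enumerates every connected subset explicitly.
Both run in milliseconds at the molecule sizes used here; the oracle is
capped at 14 atoms.

Conventions, stated because the definition alone does not fix them:

- Regions smaller than N score 0, not N−1. A region with no N-atom
  subgraph satisfies the condition vacuously; admitting those would give
  every molecule a floor of N−1 and metabolites would no longer score 0.
- Metabolites smaller than N contribute no fragments but remain members.
- Disconnected input is an error; salts are scored on the largest organic
  component, matching the toxicity pipeline's salt handling.
- Ub6 ≥ Ub5 whenever Ub5 ≥ 6: every 6-atom reference constraint implies
  5-atom ones, so larger-N constraints are weaker. This is asserted as a
  cross-check in the test suite.

## Coverage

The observed unfound fraction of a fragment set in a collection is direct
matching. The random-collection expectation is mean_f (1−p_f)^M with
per-fragment match probabilities p_f estimated by seeded Monte-Carlo over
the space (binomial standard errors; a batch mode shares one sample
across fragments). The (1−p)^M aggregation treats the M molecule draws as
independent, so null-model comparisons should draw the reference
collection with replacement and pass the draw count as `set_size`. The
reported standard error propagates the p̂ errors by the delta method and
treats fragments as independent — an approximation (fragments share
molecules and the Monte-Carlo sample), so the error bar on the *observed*
side of a null comparison should add the across-fragment sampling term,
as the acceptance suite does.

## Toxicity statistics

Rank correlation is Spearman with average ranks for ties and the
large-sample two-sided t approximation (scipy); Kendall's tau-b is
available behind a flag. Significance tiers are * < 0.05, ** < 0.01 and
*** below the Bonferroni family threshold α/(n_endpoints × n_measures),
all configurable; the family-wise null probability 1−(1−α*)^n and its
reciprocal (expected studies per false threshold hit) are provided as
closed forms. Potency bands are half-open [lo, hi) with open-ended
extremes, so bands partition the records; per-band confidence intervals
are Fisher-z with half-width 1.96/√(n−3), defined only at n ≥ 4. Hit-rate
curves bin log10 concentration into half-open bins of width 0.25 by
default, counting only compounds tested in a bin.

EC50 from a raw inhibition curve is log-linear interpolation at the
*first* upward crossing of 50% (an exact 50% at a tested concentration
returns it); no-crossing curves are undefined rather than extrapolated,
which is what drives the censoring filters. The yeast pipeline applies,
in order: organometallic exclusion (any carbon-metal bond), mixture/salt
exclusion except single-atom halide or alkali-metal counter-ions (allowed
salts are scored on the organic component), the <50%-at-top and
>50%-at-bottom exclusions evaluated on the across-strain mean inhibition
curve (the source rules are per compound; the data is per strain; the
mean curve is this package's concretization), per-strain EC50s, and the
spread exclusion (max−min)/mean > 1. Exclusions are logged outputs, never
errors. Units are carried per endpoint (molar, or mol/kg for mammalian
oral/IP doses) and never mixed within a correlation.

## Synthetic studies

The generator emulates the shape of the real analysis, not any particular
species' data. Metabolome: a seeded sample of `n_metabolites` = 25
molecules from the acyclic CHON space at exactly `metabolite_size` = 4
heavy atoms, excluding the banned motifs. Scaffolds share one size so
that a compound's heavy-atom count tracks its decoration load; the
planted effect acts on Ub *per heavy atom* (to decouple it from size)
while the analysis correlates raw Ub, and heterogeneous scaffold sizes
would inject rank noise unrelated to the mechanism under study.
Compounds: 400 draws, each a scaffold with 0-3 grafted decorations
(halogens, hydrazine, nitrile, dichloromethylene) attached by single
bonds at open valences — undecorated compounds score Ub = 0 against their
metabolome, halogenated ones at least 3. Toxicity: with probability 0.15
a compound is a specific-mechanism toxin at log10 EC50 ~ N(−6, 0.5)
independent of Ub; otherwise N(−2 − 0.8·Ub/size, 0.5). Potent bands are
therefore dominated by the specific population (no Ub relation) and the
millimolar bands carry the Ub signal, which is the qualitative structure
the band analysis must recover.

What passing recovery tests shows — and does not. They show the pipeline
detects a planted monotone effect of this magnitude at n = 400 and
localizes it to the correct potency bands. They say nothing about real
endpoint panels: real compound sets are larger and ring-rich, real
metabolomes are far more diverse than 25 four-atom scaffolds, and real
toxicity mixes many mechanisms, none of which the two-population model
emulates.

## Problem sizes and determinism

Test and acceptance workloads use spaces of ≤ 5 atoms (CHON/CO), growth-
sampled targets of ≤ 12 atoms, 200 oracle triples, 50 five-molecule pool
sets, 2000-draw Monte-Carlo coverage estimates, and 20 replicate seeds of
the 400-compound study — sizes chosen so the whole suite verifies the
contracts in a few minutes while every check still exercises the full
algorithms. All randomness flows from explicit seeds; reruns are
byte-identical, and CSV output is written at six significant figures.

## Known limitations

- Enumeration beyond 8 heavy atoms is sampling-only, and the growth
  sampler is not uniform.
- The neutral-charge valence model rejects zwitterionic/ionic-only
  structures rather than tautomerizing them.
- MCS and Ub solvers are exact but exponential in the worst case; they
  are intended for molecules of tens of atoms, not polymers.
- The Monte-Carlo coverage expectation inherits sampling error and the
  independence approximations noted above.
- The 611-molecule reference metabolome and the deposited compound
  structures of the original study are external downloads; the package
  reads them through its generic SMILES/SDF/CSV readers
  (`scripts/compare_deposit.py` automates the comparison once they are
  downloaded) and ships a synthetic stand-in, and its tests make no
  claim about reproducing that study's printed correlation table.
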