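# unbio

Fragment-based analysis of how far a molecule sits outside the chemical
space of metabolism, and whether that distance predicts non-specific,
low-potency toxicity.

The chemicals of core metabolism occupy a small, structured corner of the
space of valence-legal CHONSP molecules. `unbio` quantifies that
observation and its toxicological consequence with three connected pieces
of machinery:

- **Chemical-space enumeration.** All 2-D structures over a chosen element
  subset of {C, N, O, P, S, Si}, under the valences C/Si: 4, N: 3, O: 2,
  P: 3 or 5, S: 2, 4 or 6 (by default only P(V), S(II) and sulfate-like
  S(VI) are kept), with at most two ring systems and configurable
  banned-substructure stability filters. Enumeration is exhaustive and
  duplicate-free under canonical SMILES.
- **The UnBiological score.** For fragment size *N* and a metabolite
  reference set *M*, **Ub_N(x)** is the size (heavy atoms) of the largest
  connected region of molecule *x* that contains no *N*-atom fragment of
  any molecule in *M*. Regions smaller than *N* score 0, so metabolites
  score 0 against their own reference; a wholly foreign molecule scores
  its full atom count. Ub5 and Ub6 are the sizes used in practice, because
  metabolite coverage of chemical space is most restricted at 5-6 atoms.
  Supporting machinery: subgraph overlay matching, embedding counts,
  maximum-common-subgraph (MCS) fragment pools closed under pairwise MCS.
- **Toxicity statistics.** Spearman rank correlation of Ub with log10
  half-effect concentration (EC50/LD50, molar; mammalian doses as mol/kg),
  significance tiers with the Bonferroni family threshold
  α/(endpoints × measures), potency-band correlations with Fisher-z 95%
  confidence limits, hit-rate curves over log-concentration bins, and an
  EC50 pipeline for raw yeast growth-inhibition matrices (organometallic /
  salt / censoring / strain-spread filters). A negative ρ means larger Ub
  goes with a lower toxic concentration, i.e. a more potent toxin; the
  effect of interest lives in the *low-potency* (millimolar) bands.

A seeded synthetic module generates toy metabolomes, decorated test
compounds spanning a range of Ub, and toxicity data with a planted
low-potency Ub effect, so the full pipeline is testable end to end without
any external data.

## Worked example

Simulate a study (25 four-atom CHON metabolites, 400 decorated compounds,
planted slope −0.8 per normalized Ub unit at baseline log EC50 −2, with a
15% specific-mechanism population at −6), score it, and correlate:

```sh
unbio simulate --seed 3 -o sim/
unbio correlate --toxicity sim/toxicity.csv --ub-table sim/ub.csv --n 3 -o corr.csv
unbio bands --toxicity sim/toxicity.csv --ub-table sim/ub.csv --n 3 --edges="-4,-3" -o bands.csv
```

`corr.csv`:

```
endpoint,ub_n,n,rho,p,tier
synthetic growth inhibition,3,400,-0.199275,5.98646e-05,***
```

Ub3 correlates negatively with log10 EC50 across the 400 compounds
(ρ = −0.20), beyond the *** family threshold 0.05/(35·2) ≈ 0.000714.
`bands.csv` shows where the signal lives:

```
endpoint,lo,hi,n,rho,ci_lo,ci_hi
synthetic growth inhibition,-inf,-4,62,0.0269643,-0.224315,0.274881
synthetic growth inhibition,-4,-3,28,-0.409138,-0.678629,-0.0425565
synthetic growth inhibition,-3,inf,310,-0.178262,-0.284019,-0.0682204
```

Among potent compounds (log EC50 < −4, dominated by the specific-mechanism
population) the correlation is absent (CI spans zero); in the low-potency
bands it is negative with confidence limits below zero — the potency-band
structure the score is designed to expose.

The same operations are available as a library:

```python
from unbio import MoleculeSet, parse_structure, ub_score

mets = MoleculeSet.from_smiles(["CCO", "CC(=O)O", "NCC(=O)O"])
ub_score(parse_structure("CCCCl"), mets, 3).value   # 4: wholly unbiological
ub_score(parse_structure("CCCO"), mets, 3).value    # 3: the C-C-C region
ub_score(parse_structure("CCO"), mets, 3).value     # 0: a metabolite
```

## Layout

- `src/unbio/molgraph.py` — graph model, SMILES/MOL/SDF I/O, canonical
  kekulized forms, overlay matching, embedding counts, MCS
- `src/unbio/combimol.py` — chemical-space enumeration, stability
  filters, seeded sampling
- `src/unbio/fragments.py` — MCS-closure fragment pools, n-atom
  fragments, descriptor vectors
- `src/unbio/unbiological.py` — Ub_N (branch-and-bound solver plus
  exhaustive oracle), batch tables
- `src/unbio/coverage.py` — observed vs expected unfound-fraction
- `src/unbio/toxcorr.py` — correlations, bands, hit rates, yeast EC50
- `src/unbio/synthetic.py` — seeded study generator
- `src/unbio/cli.py` — the `unbio` command

See `docs/methods.md` for the model details, conventions and limitations.
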