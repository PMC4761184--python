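"""Synthetic study data: toy metabolomes, decorated test compounds, and
toxicity endpoints with a planted low-potency Ub effect.

The generator emulates the regime the real analysis operates in, at desk
scale: a small "metabolome" of biological-looking CHON(S,P) molecules, a
compound library built by grafting xenobiotic decorations (halogens,
hydrazine, nitrile...) onto metabolite scaffolds so Ub spans a range, and
log10 EC50 values from a two-population mixture -- a small fraction of
"specific-mechanism" toxins that are potent regardless of Ub, and a
majority whose potency drifts with normalized Ub.  The mixture is the
minimal mechanism that reproduces the empirical phenomenon this package
analyses: rank correlation of Ub with toxicity concentrated in the
low-potency (millimolar) bands, diluted or absent among potent toxins.

Every output is a pure function of the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .combimol import (
    ChemSpaceSpec,
    MoleculeSet,
    default_banned_patterns,
    enumerate_space,
)
from .molgraph import ALLOWED_STATES, MolecularGraph, is_subgraph, parse_structure
from .toxcorr import ToxicityRecord


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study; defaults are the study conditions.

    The toxicity model: with probability ``specific_fraction`` a compound is
    a specific-mechanism toxin, log10 EC50 ~ Normal(``potent_mu``, sigma),
    independent of Ub; otherwise log10 EC50 ~ Normal(``baseline_mu`` +
    ``ub_slope`` * Ub/heavy-atoms, sigma).  Units are log10 molar;
    ``baseline_mu`` = -2 puts the non-specific population at millimolar
    potency and ``potent_mu`` = -6 at micromolar.
    """

    n_metabolites: int = 25
    metabolite_size: int = 4  # exact scaffold heavy-atom count
    n_compounds: int = 400
    decorations: tuple[str, ...] = ("Cl", "F", "Br", "NN", "C#N", "ClCCl")
    max_decorations: int = 3
    baseline_mu: float = -2.0
    potent_mu: float = -6.0
    ub_slope: float = -0.8  # per unit of Ub / heavy-atom count
    noise_sigma: float = 0.5
    specific_fraction: float = 0.15
    endpoint: str = "synthetic growth inhibition"
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if not 0.0 <= self.specific_fraction <= 1.0:
            raise ValueError("specific_fraction must lie in [0, 1]")


#: The metabolome scaffold space: biological-looking CHON molecules,
#: acyclic, single/double bonds, free of the textbook-unstable motifs.
#: Scaffolds share one heavy-atom count so that compound size tracks the
#: decoration load and Ub stays monotone in Ub per atom.
def _scaffold_spec(params: SimulationParams) -> ChemSpaceSpec:
    return ChemSpaceSpec(
        elements=("C", "N", "O"),
        max_size=params.metabolite_size,
        allowed_bond_orders=(1, 2),
        ring_policy="acyclic_only",
        min_size=params.metabolite_size,
    )


def make_toy_metabolome(params: SimulationParams) -> MoleculeSet:
    """A deterministic sample of biological-looking molecules.

    Drawn without replacement from the enumerated CHON space, excluding the
    default banned motifs; every member has >= 3 heavy atoms so it
    contributes reference fragments at the sizes the tests use.
    """
    space = enumerate_space(_scaffold_spec(params))
    banned = default_banned_patterns()
    eligible = [
        m for m in space if not any(is_subgraph(b, m) for b in banned)
    ]
    if params.n_metabolites > len(eligible):
        raise ValueError(
            f"requested {params.n_metabolites} metabolites but the space "
            f"holds only {len(eligible)} eligible molecules"
        )
    rng = random.Random(params.seed)
    chosen = rng.sample(eligible, params.n_metabolites)
    return MoleculeSet(tuple(sorted(chosen)), provenance="synthetic")


def _free_valence(mol: MolecularGraph, i: int) -> int:
    return max(ALLOWED_STATES[mol.atoms[i]]) - mol.bond_order_sum(i)


def _graft(scaffold: MolecularGraph, decoration: MolecularGraph, rng: random.Random) -> Optional[MolecularGraph]:
    """Attach ``decoration`` to ``scaffold`` by one single bond at random
    open-valence atoms; None when no attachment point exists."""
    host_sites = [i for i in range(scaffold.size) if _free_valence(scaffold, i) >= 1]
    dec_sites = [i for i in range(decoration.size) if _free_valence(decoration, i) >= 1]
    if not host_sites or not dec_sites:
        return None
    i = rng.choice(host_sites)
    j = rng.choice(dec_sites)
    atoms = list(scaffold.atoms) + list(decoration.atoms)
    bonds = list(scaffold.bonds) + [
        (a + scaffold.size, b + scaffold.size, o) for a, b, o in decoration.bonds
    ]
    bonds.append((i, scaffold.size + j, 1))
    return MolecularGraph.from_atoms_bonds(atoms, bonds)


def make_test_compounds(
    metabolome: MoleculeSet, params: SimulationParams
) -> list[tuple[str, MolecularGraph]]:
    """Compound library with a declared spread of Ub values.

    Each compound is a metabolome scaffold carrying 0 to
    ``max_decorations`` grafted decoration groups; undecorated compounds
    sit at Ub = 0 against their own metabolome while halogenated ones are
    guaranteed Ub3 >= 3 (no CHON metabolite fragment contains a halogen).
    Ids are ``C0001``...; duplicates across draws are allowed (compounds
    are draws, not a set).
    """
    if len(metabolome) == 0:
        raise ValueError("metabolome is empty")
    rng = random.Random(params.seed + 1)
    decorations = [parse_structure(s) for s in params.decorations]
    scaffolds = list(metabolome)
    out: list[tuple[str, MolecularGraph]] = []
    for k in range(1, params.n_compounds + 1):
        mol = rng.choice(scaffolds)
        for _ in range(rng.randint(0, params.max_decorations)):
            grafted = _graft(mol, rng.choice(decorations), rng)
            if grafted is not None:
                mol = grafted
        out.append((f"C{k:04d}", mol))
    return out


def simulate_toxicity(
    compounds: Sequence[tuple[str, MolecularGraph]],
    ub_values: Sequence[int],
    params: SimulationParams,
) -> list[ToxicityRecord]:
    """Planted log10 EC50 values for the compound library.

    ``ub_values`` must align with ``compounds`` (one score per compound,
    any fragment size); the planted slope acts on Ub normalized by
    heavy-atom count so the effect is decoupled from molecular size.
    """
    if len(ub_values) != len(compounds):
        raise ValueError("ub_values must align with compounds")
    rng = random.Random(params.seed + 2)
    records = []
    for (cid, mol), ub in zip(compounds, ub_values):
        if rng.random() < params.specific_fraction:
            mu = params.potent_mu
        else:
            mu = params.baseline_mu + params.ub_slope * (ub / mol.size)
        records.append(
            ToxicityRecord(
                compound_id=cid,
                smiles=mol.canonical,
                endpoint=params.endpoint,
                log10_value=rng.gauss(mu, params.noise_sigma),
            )
        )
    return records


def simulate_study(params: SimulationParams, ub_n: int = 3):
    """End-to-end synthetic study: metabolome, compounds, Ub table, toxicity.

    Returns ``(metabolome, compounds, ub_table, records)``; the Ub column
    used for the planted effect is ``ub{ub_n}``.
    """
    from .unbiological import ub_table as _ub_table

    metabolome = make_toy_metabolome(params)
    compounds = make_test_compounds(metabolome, params)
    table = _ub_table(compounds, metabolome, ns=(ub_n,))
    ub_values = table[f"ub{ub_n}"].astype(int).tolist()
    records = simulate_toxicity(compounds, ub_values, params)
    return metabolome, compounds, table, records
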