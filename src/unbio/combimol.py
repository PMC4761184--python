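"""Exhaustive enumeration of valence-legal chemical space.

Enumerates *all* 2-D molecular structures over a user-chosen element subset
of {C, N, O, P, S, Si}, up to a maximum heavy-atom count, under the valence
rules 4 bonds for C and Si, 3 for N, 2 for O, 3 or 5 for P and 2, 4 or 6
for S.  By default only the oxidation states relevant to metabolism are
kept: P(V), S(II) and sulfate-like S(VI).

The strategy is breadth-first graph growth with canonical-form
deduplication: starting from single atoms, each step either attaches a new
atom by a bond of an allowed order or closes a ring between two existing
atoms with free valence.  Every connected graph is reachable this way
(spanning tree first, ring closures after), and the canonical-SMILES
dedup makes the enumeration exhaustive and duplicate-free -- the contract
here, in contrast to string-growing generators that under-represent e.g.
quaternary carbon centres.

Stability filters (banned substructures such as the O-O-O chain that makes
COOOC unstable) are applied at the end, never inside the parser.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import networkx as nx

from .molgraph import (
    ALLOWED_STATES,
    Fragment,
    MolecularGraph,
    is_subgraph,
    parse_structure,
)

#: Hard limit on full enumeration; larger sizes must go through
#: :func:`sample_space`, which grows random molecules instead.
ENUMERATION_SIZE_CAP = 8

#: Default banned substructures.  The rule set of the original generator is
#: unpublished beyond the O-O-O example, so this list is an explicit,
#: documented extension point: textbook-unstable motifs only.
DEFAULT_BANNED_SMILES: tuple[str, ...] = (
    "OOO",      # trioxide chain (the COOOC case)
    "NNN",      # triazane chain
    "O=C=O",    # embedded cumulated dioxide
    "NON",      # N-O-N
    "SS",       # disulfide chains excluded from the toy spaces
)


class ChemSpaceError(ValueError):
    """Invalid or unenumerable chemical-space specification."""


@dataclass(frozen=True)
class ChemSpaceSpec:
    """Declarative description of a chemical space to enumerate.

    ``elements`` is a subset of {C, N, O, P, S, Si}; ``max_size`` counts
    heavy atoms; ``ring_policy`` is ``"acyclic_only"`` or ``"rings_allowed"``
    (at most two ring systems, fused rings counting as one system).
    """

    elements: tuple[str, ...] = ("C", "N", "O")
    max_size: int = 5
    allowed_bond_orders: tuple[int, ...] = (1, 2, 3)
    ring_policy: str = "rings_allowed"
    sulfur_states: tuple[str, ...] = ("S(II)", "S(VI)")
    phosphorus_states: tuple[str, ...] = ("P(V)",)
    banned_smiles: tuple[str, ...] = ()
    min_ring_size: int = 3
    min_size: int = 1

    def __post_init__(self):
        if not self.elements:
            raise ChemSpaceError("element set is empty")
        bad = set(self.elements) - {"C", "N", "O", "P", "S", "Si"}
        if bad:
            raise ChemSpaceError(f"unsupported elements: {sorted(bad)}")
        if self.max_size < 1:
            raise ChemSpaceError("max_size must be >= 1")
        if self.ring_policy not in ("acyclic_only", "rings_allowed"):
            raise ChemSpaceError(f"unknown ring_policy {self.ring_policy!r}")
        if not set(self.allowed_bond_orders) <= {1, 2, 3}:
            raise ChemSpaceError("bond orders must be within {1,2,3}")

    @property
    def banned_patterns(self) -> tuple[Fragment, ...]:
        return tuple(parse_structure(s) for s in self.banned_smiles)


@dataclass(frozen=True)
class MoleculeSet:
    """An ordered, duplicate-free collection of canonical molecules."""

    molecules: tuple[MolecularGraph, ...]
    provenance: str = "loaded"  # enumerated | loaded | synthetic

    def __post_init__(self):
        seen = set()
        for m in self.molecules:
            if m.canonical in seen:
                raise ValueError(f"duplicate molecule {m.canonical}")
            seen.add(m.canonical)

    def __iter__(self):
        return iter(self.molecules)

    def __len__(self):
        return len(self.molecules)

    def __contains__(self, mol: MolecularGraph) -> bool:
        return any(m.canonical == mol.canonical for m in self.molecules)

    def canonicals(self) -> list[str]:
        return [m.canonical for m in self.molecules]

    @classmethod
    def from_smiles(cls, smiles: Iterable[str], provenance: str = "loaded") -> "MoleculeSet":
        mols, seen = [], set()
        for s in smiles:
            g = parse_structure(s)
            if g.canonical not in seen:
                seen.add(g.canonical)
                mols.append(g)
        return cls(tuple(mols), provenance)


# ---------------------------------------------------------------------------
# growth moves
# ---------------------------------------------------------------------------


def _max_valence(el: str) -> int:
    return max(ALLOWED_STATES[el])


def _free_valence(atoms: Sequence[str], bond_sum: Sequence[int], i: int) -> int:
    return _max_valence(atoms[i]) - bond_sum[i]


def _grow(state: MolecularGraph, spec: ChemSpaceSpec) -> Iterable[MolecularGraph]:
    atoms = list(state.atoms)
    n = len(atoms)
    bond_sum = [state.bond_order_sum(i) for i in range(n)]
    adjacent = {(i, j) for i, j, _ in state.bonds}
    # attach a new atom
    if n < spec.max_size:
        for el in spec.elements:
            for order in spec.allowed_bond_orders:
                if order > _max_valence(el):
                    continue
                for i in range(n):
                    if _free_valence(atoms, bond_sum, i) >= order:
                        yield MolecularGraph.from_atoms_bonds(
                            atoms + [el], list(state.bonds) + [(i, n, order)]
                        )
    # close a ring
    if spec.ring_policy == "rings_allowed":
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in adjacent:
                    continue
                for order in spec.allowed_bond_orders:
                    if (
                        _free_valence(atoms, bond_sum, i) >= order
                        and _free_valence(atoms, bond_sum, j) >= order
                    ):
                        yield MolecularGraph.from_atoms_bonds(
                            atoms, list(state.bonds) + [(i, j, order)]
                        )


# ---------------------------------------------------------------------------
# emission filters
# ---------------------------------------------------------------------------


def _phosphorus_ok(mol: MolecularGraph, spec: ChemSpaceSpec) -> bool:
    # P(V): hydrogen fill must land on valence 5, i.e. bond-order sum 4 or 5;
    # sums <= 3 would fill to P(III), which metabolism does not use.
    for i, el in enumerate(mol.atoms):
        if el != "P":
            continue
        s = mol.bond_order_sum(i)
        if "P(V)" in spec.phosphorus_states and s in (4, 5):
            continue
        if "P(III)" in spec.phosphorus_states and s <= 3:
            continue
        return False
    return True


def _sulfur_ok(mol: MolecularGraph, spec: ChemSpaceSpec) -> bool:
    for i, el in enumerate(mol.atoms):
        if el != "S":
            continue
        s = mol.bond_order_sum(i)
        if "S(II)" in spec.sulfur_states and s <= 2:
            continue
        if "S(VI)" in spec.sulfur_states and s == 6 and _sulfate_like(mol, i):
            continue
        return False
    return True


def _sulfate_like(mol: MolecularGraph, i: int) -> bool:
    """S(VI) is only admitted in a sulfate/sulfonate O-pattern: at least two
    double-bonded oxygen neighbours."""
    double_o = sum(
        1
        for a, b, o in mol.bonds
        if o == 2 and ((a == i and mol.atoms[b] == "O") or (b == i and mol.atoms[a] == "O"))
    )
    return double_o >= 2


def _ring_stats(mol: MolecularGraph) -> tuple[int, Optional[int]]:
    """(number of ring systems, girth). Ring systems are connected
    components of the subgraph of cycle edges (fused rings = one system)."""
    g = mol.graph
    bridges = set(frozenset(e) for e in nx.bridges(g))
    ring_edges = [e for e in g.edges if frozenset(e) not in bridges]
    if not ring_edges:
        return 0, None
    rg = g.edge_subgraph(ring_edges)
    n_systems = nx.number_connected_components(rg)
    girth = min(len(c) for c in nx.minimum_cycle_basis(g))
    return n_systems, girth


def _passes_filters(mol: MolecularGraph, spec: ChemSpaceSpec) -> bool:
    if mol.size < spec.min_size:
        return False
    if not _phosphorus_ok(mol, spec) or not _sulfur_ok(mol, spec):
        return False
    n_systems, girth = _ring_stats(mol)
    if n_systems > 2:
        return False
    if girth is not None and girth < spec.min_ring_size:
        return False
    for banned in spec.banned_patterns:
        if is_subgraph(banned, mol):
            return False
    return True


# ---------------------------------------------------------------------------
# the public operations
# ---------------------------------------------------------------------------


def estimate_space_size(spec: ChemSpaceSpec) -> int:
    """Crude upper-bound estimate used in size-cap refusals."""
    e, n = len(spec.elements), spec.max_size
    b = len(spec.allowed_bond_orders)
    return e**n * b ** (2 * n)  # labelled-tree bound times bond choices


def enumerate_space(spec: ChemSpaceSpec) -> MoleculeSet:
    """Every valence-legal molecule of the space, canonical and deduplicated.

    Exhaustive for the configured rule set; refuses specs whose ``max_size``
    exceeds the safety cap of 8 heavy atoms.
    """
    if spec.max_size > ENUMERATION_SIZE_CAP:
        raise ChemSpaceError(
            f"max_size {spec.max_size} exceeds the enumeration cap "
            f"{ENUMERATION_SIZE_CAP} (estimated state count "
            f"~{estimate_space_size(spec):.3g}); use sample_space instead"
        )
    return _enumerate_cached(spec)


@lru_cache(maxsize=32)
def _enumerate_cached(spec: ChemSpaceSpec) -> MoleculeSet:
    # banned patterns are monotone under growth, so they prune the search;
    # P/S state rules are not (a growing S may still reach sulfate) and are
    # checked only at emission
    seeds = [MolecularGraph.from_atoms_bonds([el], []) for el in spec.elements]
    frontier = {g.canonical: g for g in seeds}
    visited: dict[str, MolecularGraph] = dict(frontier)
    while frontier:
        nxt: dict[str, MolecularGraph] = {}
        for g in frontier.values():
            for child in _grow(g, spec):
                key = child.canonical
                if key in visited or key in nxt:
                    continue
                if any(is_subgraph(b, child) for b in spec.banned_patterns):
                    continue
                nxt[key] = child
        visited.update(nxt)
        frontier = nxt
    kept = [g for g in visited.values() if _passes_filters(g, spec)]
    kept.sort()
    return MoleculeSet(tuple(kept), provenance="enumerated")


def apply_stability_filters(
    molecules: MoleculeSet, banned: Sequence[Fragment]
) -> MoleculeSet:
    """Drop every molecule containing a banned pattern; order preserved."""
    kept = tuple(
        m for m in molecules if not any(is_subgraph(b, m) for b in banned)
    )
    return MoleculeSet(kept, provenance=molecules.provenance)


def sample_space(
    spec: ChemSpaceSpec,
    n: int,
    seed: int,
    exact_size: Optional[int] = None,
    method: str = "auto",
) -> list[MolecularGraph]:
    """Draw ``n`` molecules with replacement, deterministically under ``seed``.

    For enumerable specs (``max_size`` within the cap) the draw is uniform
    over :func:`enumerate_space`.  Beyond the cap a random-growth sampler is
    used: a random sequence of legal growth moves followed by the emission
    filters (rejection on failure); this covers the space but is *not*
    uniform, which matters only for spaces too large to enumerate.

    ``exact_size`` restricts draws to molecules of exactly that heavy-atom
    count (a size-distribution control for null models).  ``method`` forces
    ``"enumerate"`` or ``"grow"`` sampling; ``"auto"`` enumerates whenever
    the cap allows (enumeration of multi-element spaces near the cap can be
    expensive; pass ``"grow"`` when a non-uniform draw is acceptable).
    """
    if n < 1:
        raise ChemSpaceError("n must be >= 1")
    if method not in ("auto", "enumerate", "grow"):
        raise ChemSpaceError(f"unknown sampling method {method!r}")
    rng = random.Random(seed)
    if method == "enumerate" and spec.max_size > ENUMERATION_SIZE_CAP:
        raise ChemSpaceError("space exceeds the enumeration cap")
    if method != "grow" and spec.max_size <= ENUMERATION_SIZE_CAP:
        pool = list(enumerate_space(spec))
        if exact_size is not None:
            pool = [m for m in pool if m.size == exact_size]
        if not pool:
            raise ChemSpaceError("space is empty under the given constraints")
        return [pool[rng.randrange(len(pool))] for _ in range(n)]
    return [_random_molecule(spec, rng, exact_size) for _ in range(n)]


def _random_molecule(
    spec: ChemSpaceSpec, rng: random.Random, exact_size: Optional[int]
) -> MolecularGraph:
    target = exact_size if exact_size is not None else rng.randint(1, spec.max_size)
    for _ in range(10_000):
        g = MolecularGraph.from_atoms_bonds([rng.choice(spec.elements)], [])
        ok = True
        while g.size < target:
            children = [c for c in _grow(g, replace(spec, max_size=target)) if c.size > g.size]
            if not children:
                ok = False
                break
            g = children[rng.randrange(len(children))]
        if not ok:
            continue
        # optional random ring closures
        if spec.ring_policy == "rings_allowed" and rng.random() < 0.3:
            closures = [c for c in _grow(g, replace(spec, max_size=target)) if c.size == g.size]
            if closures:
                g = closures[rng.randrange(len(closures))]
        if _passes_filters(g, spec):
            return g
    raise ChemSpaceError("random-growth sampler failed to produce a molecule")


def default_banned_patterns() -> list[Fragment]:
    return [parse_structure(s) for s in DEFAULT_BANNED_SMILES]
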