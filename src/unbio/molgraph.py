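"""Molecular graphs and 2-D structure matching.

The unit of every comparison in this package is a heavy-atom labelled graph:
atoms carry an element symbol, bonds carry an integer order (1, 2 or 3), and
hydrogens are implicit (they fill whatever valence the explicit bonds leave
open).  Stereochemistry, isotopes and formal charges are outside the model:
structures are normalized to neutral, 2-D topological form on input.

A :class:`Fragment` is structurally the same object as a molecule -- a
connected labelled graph -- read as a *pattern*: open valences are
unconstrained, and a fragment matches wherever its atoms and bonds can be
overlaid on a target (a monomorphic embedding; the target may have extra
bonds among the matched atoms).

Aromatic input is reduced to a single kekulized canonical form: every input
spelling of a molecule is first canonicalized with aromatic perception and
then kekulized from that canonical atom order, so equal molecules always
yield byte-identical canonical strings and identical kekule bond patterns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx
from networkx.algorithms import isomorphism as nx_iso
from rdkit import Chem, RDLogger
from rdkit.Chem.rdchem import AtomValenceException, KekulizeException

RDLogger.DisableLog("rdApp.*")

# ---------------------------------------------------------------------------
# errors and valence model
# ---------------------------------------------------------------------------


class MoleculeError(ValueError):
    """Base class for structure-handling errors."""


class ParseError(MoleculeError):
    """Input text could not be read as a structure."""

    def __init__(self, message: str, text: str = ""):
        super().__init__(message)
        self.text = text


class ValenceError(MoleculeError):
    """An atom's bond-order sum exceeds its allowed valence."""

    def __init__(self, message: str, atom_index: Optional[int] = None):
        super().__init__(message)
        self.atom_index = atom_index


class DisconnectedError(MoleculeError):
    """A single connected structure was required but the input has several
    components (e.g. a salt)."""


#: Maximum bond-order sum per element.  C/Si: 4, N: 3, O: 2, P: up to 5,
#: S: up to 6; halogens and hydrogen are monovalent.  Elements not listed
#: are accepted without a valence check (needed to *classify* metal salts,
#: which downstream filters then exclude).
MAX_VALENCE: dict[str, int] = {
    "C": 4, "Si": 4, "N": 3, "O": 2, "P": 5, "S": 6,
    "F": 1, "Cl": 1, "Br": 1, "I": 1, "H": 1, "B": 3, "Se": 2,
}

#: Valence states an element may adopt once implicit hydrogens are added.
ALLOWED_STATES: dict[str, tuple[int, ...]] = {
    "C": (4,), "Si": (4,), "N": (3,), "O": (2,), "P": (3, 5), "S": (2, 4, 6),
    "F": (1,), "Cl": (1,), "Br": (1,), "I": (1,), "H": (1,), "B": (3,),
    "Se": (2,),
}

_BOND_TYPE = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}

_NONMETALS = frozenset(
    "H He B C N O F Ne Si P S Cl Ar Ge As Se Br Kr Te I Xe At Rn".split()
)
ALKALI_METALS = frozenset("Li Na K Rb Cs Fr".split())
HALOGENS = frozenset("F Cl Br I At".split())


# ---------------------------------------------------------------------------
# the graph type
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MolecularGraph:
    """A connected heavy-atom graph with integer bond orders.

    Instances are immutable and canonical: ``atoms`` and ``bonds`` are stored
    in RDKit canonical order and ``canonical`` is the kekulized canonical
    SMILES, so two graphs are equal iff their canonical strings are equal.
    Construct via :func:`parse_structure` or :meth:`from_atoms_bonds`.
    """

    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int, int], ...]
    canonical: str

    # -- construction -------------------------------------------------------

    @classmethod
    def from_atoms_bonds(
        cls, atoms: Sequence[str], bonds: Iterable[tuple[int, int, int]]
    ) -> "MolecularGraph":
        """Build (and canonicalize) a graph from explicit atoms and bonds."""
        mol = Chem.RWMol()
        for symbol in atoms:
            mol.AddAtom(Chem.Atom(symbol))
        for i, j, order in bonds:
            if i == j:
                raise MoleculeError(f"self-bond on atom {i}")
            if order not in _BOND_TYPE:
                raise MoleculeError(f"unsupported bond order {order}")
            mol.AddBond(int(i), int(j), _BOND_TYPE[order])
        return cls.from_rdkit(mol.GetMol())

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol) -> "MolecularGraph":
        """Normalize an RDKit molecule into a canonical graph."""
        mol = _neutralize(mol)
        _sanitize(mol)
        mol = Chem.RemoveHs(mol)
        if mol.GetNumAtoms() == 0:
            raise MoleculeError("structure has no heavy atoms")
        frags = Chem.GetMolFrags(mol)
        if len(frags) > 1:
            raise DisconnectedError(
                f"structure has {len(frags)} components; split salts upstream"
            )
        # canonical aromatic SMILES fixes the atom order; re-parsing and
        # kekulizing from it makes the kekule pattern input-independent
        aromatic_smiles = Chem.MolToSmiles(mol)
        canon = Chem.MolFromSmiles(aromatic_smiles)
        if canon is None:  # pragma: no cover - canonical SMILES always parse
            raise ParseError("internal canonicalization failure", aromatic_smiles)
        Chem.Kekulize(canon, clearAromaticFlags=True)
        atoms = tuple(a.GetSymbol() for a in canon.GetAtoms())
        bonds = tuple(
            sorted(
                (
                    min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                    max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                    int(b.GetBondTypeAsDouble()),
                )
                for b in canon.GetBonds()
            )
        )
        canonical = Chem.MolToSmiles(canon, kekuleSmiles=True)
        return cls(atoms=atoms, bonds=bonds, canonical=canonical)

    # -- basic views --------------------------------------------------------

    @property
    def size(self) -> int:
        """Heavy-atom count."""
        return len(self.atoms)

    @cached_property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, el in enumerate(self.atoms):
            g.add_node(i, el=el)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g

    @cached_property
    def element_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for el in self.atoms:
            counts[el] = counts.get(el, 0) + 1
        return counts

    def bond_order_sum(self, index: int) -> int:
        return sum(o for i, j, o in self.bonds if index in (i, j))

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.RWMol()
        for symbol in self.atoms:
            mol.AddAtom(Chem.Atom(symbol))
        for i, j, order in self.bonds:
            mol.AddBond(i, j, _BOND_TYPE[order])
        out = mol.GetMol()
        _sanitize(out)
        return out

    def induced(self, atom_subset: Iterable[int]) -> "MolecularGraph":
        """Node-induced subgraph on ``atom_subset`` (must be connected)."""
        nodes = sorted(set(atom_subset))
        remap = {n: k for k, n in enumerate(nodes)}
        atoms = [self.atoms[n] for n in nodes]
        bonds = [
            (remap[i], remap[j], o)
            for i, j, o in self.bonds
            if i in remap and j in remap
        ]
        return MolecularGraph.from_atoms_bonds(atoms, bonds)

    def __lt__(self, other: "MolecularGraph") -> bool:
        return (self.size, self.canonical) < (other.size, other.canonical)

    def __repr__(self) -> str:
        return f"MolecularGraph({self.canonical!r})"


#: A fragment is the same graph structure read as a pattern with open
#: valences; matching semantics are exact element + bond-order overlay.
Fragment = MolecularGraph


# ---------------------------------------------------------------------------
# RDKit normalization helpers
# ---------------------------------------------------------------------------


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.RWMol(mol)
    Chem.RemoveStereochemistry(mol)
    for atom in mol.GetAtoms():
        if atom.GetFormalCharge() != 0:
            # let RDKit recompute hydrogens for the neutral form
            atom.SetNumExplicitHs(0)
            atom.SetNoImplicit(False)
        atom.SetFormalCharge(0)
        atom.SetIsotope(0)
        atom.SetAtomMapNum(0)
        atom.SetNumRadicalElectrons(0)
    return mol.GetMol()


_VALENCE_RE = re.compile(r"atom # (\d+)")


def _sanitize(mol: Chem.Mol) -> None:
    try:
        Chem.SanitizeMol(mol)
    except AtomValenceException as exc:
        m = _VALENCE_RE.search(str(exc))
        idx = int(m.group(1)) if m else None
        raise ValenceError(str(exc), atom_index=idx) from exc
    except KekulizeException as exc:
        raise ParseError(f"cannot kekulize structure: {exc}") from exc


# ---------------------------------------------------------------------------
# parsing and I/O
# ---------------------------------------------------------------------------


def parse_structure(text: str, fmt: Optional[str] = None) -> MolecularGraph:
    """Parse SMILES line notation or an MDL MOL block into a graph.

    ``fmt`` may be ``"smiles"`` or ``"mol"``; when omitted it is inferred
    (MOL blocks contain an ``M  END`` line).  Raises :class:`ParseError` for
    unreadable input, :class:`ValenceError` when an atom exceeds its allowed
    valence and :class:`DisconnectedError` for multi-component input.
    """
    if fmt is None:
        fmt = "mol" if ("M  END" in text or "V2000" in text or "V3000" in text) else "smiles"
    if fmt == "mol":
        mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=True)
        if mol is None:
            raise ParseError("unreadable MOL block", text)
    elif fmt == "smiles":
        smiles = text.strip().split()[0] if text.strip() else ""
        if not smiles:
            raise ParseError("empty SMILES input", text)
        mol = Chem.MolFromSmiles(smiles, sanitize=False)
        if mol is None:
            raise ParseError(f"unparseable SMILES {smiles!r}", smiles)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return MolecularGraph.from_rdkit(mol)


def parse_components(text: str, fmt: Optional[str] = None) -> list[Chem.Mol]:
    """Split possibly multi-component input into raw RDKit components.

    Unlike :func:`parse_structure` this applies no neutralization or valence
    policy; it exists so that salt/mixture classifiers can inspect every
    component (including metal counter-ions) before deciding what to score.
    """
    if fmt is None:
        fmt = "mol" if ("M  END" in text or "V2000" in text) else "smiles"
    if fmt == "mol":
        mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    else:
        smiles = text.strip().split()[0] if text.strip() else ""
        mol = Chem.MolFromSmiles(smiles, sanitize=False) if smiles else None
    if mol is None:
        raise ParseError("unreadable structure", text)
    return list(Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False))


def largest_organic_component(text: str, fmt: Optional[str] = None) -> MolecularGraph:
    """Parse and return the largest carbon-containing component.

    Used for salts/mixtures where the organic part is the scoring unit.
    """
    comps = parse_components(text, fmt=fmt)
    organic = [c for c in comps if any(a.GetSymbol() == "C" for a in c.GetAtoms())]
    pool = organic or comps
    best = max(pool, key=lambda c: c.GetNumAtoms())
    return MolecularGraph.from_rdkit(best)


def read_smiles_lines(lines: Iterable[str]) -> list[tuple[str, MolecularGraph]]:
    """Read ``smiles[<tab>id]`` lines; returns ``(id, graph)`` pairs.

    Records without an explicit id are numbered from 1.
    """
    out = []
    k = 0
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        k += 1
        parts = line.split("\t") if "\t" in line else line.split()
        smiles = parts[0]
        mol_id = parts[1] if len(parts) > 1 else str(k)
        out.append((mol_id, parse_structure(smiles, fmt="smiles")))
    return out


def read_sdf(text: str) -> list[tuple[str, MolecularGraph]]:
    """Read an SDF string; returns ``(id, graph)`` pairs.

    The id is the record's title line, falling back to its 1-based index.
    A record that fails to parse raises :class:`ParseError` naming the index.
    """
    records: list[list[str]] = []
    current: list[str] = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            records.append(current)
            current = []
        else:
            current.append(line)
    if any(l.strip() for l in current):
        records.append(current)
    out = []
    for idx, rec in enumerate(records, start=1):
        if not any(l.strip() for l in rec):
            continue
        body = "\n".join(rec)
        mol_part = body.split("M  END")[0] + "M  END\n"
        try:
            graph = parse_structure(mol_part, fmt="mol")
        except MoleculeError as exc:
            raise ParseError(f"SDF record {idx}: {exc}", mol_part) from exc
        title = rec[0].strip() if rec else ""
        out.append((title or str(idx), graph))
    return out


def write_smiles_lines(records: Iterable[tuple[str, MolecularGraph]]) -> str:
    return "".join(f"{g.canonical}\t{mol_id}\n" for mol_id, g in records)


# ---------------------------------------------------------------------------
# matching: substructure, embeddings, common subgraphs
# ---------------------------------------------------------------------------

_node_match = nx_iso.categorical_node_match("el", None)
_edge_match = nx_iso.categorical_edge_match("order", None)


def _matcher(target: MolecularGraph, pattern: MolecularGraph) -> nx_iso.GraphMatcher:
    return nx_iso.GraphMatcher(
        target.graph, pattern.graph, node_match=_node_match, edge_match=_edge_match
    )


def _elements_compatible(pattern: MolecularGraph, target: MolecularGraph) -> bool:
    tc = target.element_counts
    return all(tc.get(el, 0) >= n for el, n in pattern.element_counts.items())


def is_subgraph(pattern: Fragment, target: MolecularGraph) -> bool:
    """True iff ``pattern`` can be overlaid on ``target``.

    The overlay is an injective mapping of pattern atoms onto target atoms
    preserving element labels, with every pattern bond present in the target
    at the same order (a monomorphism -- target bonds not in the pattern are
    allowed among matched atoms).
    """
    if pattern.size > target.size or not _elements_compatible(pattern, target):
        return False
    return _matcher(target, pattern).subgraph_is_monomorphic()


def embedding_atom_bond_sets(
    pattern: Fragment, target: MolecularGraph
) -> set[tuple[frozenset[int], frozenset[tuple[int, int]]]]:
    """Distinct (atom set, bond set) pairs at which ``pattern`` embeds."""
    if pattern.size > target.size or not _elements_compatible(pattern, target):
        return set()
    found = set()
    for mapping in _matcher(target, pattern).subgraph_monomorphisms_iter():
        inverse = {p: t for t, p in mapping.items()}
        atoms = frozenset(inverse.values())
        bonds = frozenset(
            (min(inverse[i], inverse[j]), max(inverse[i], inverse[j]))
            for i, j, _ in pattern.bonds
        )
        found.add((atoms, bonds))
    return found


def embedding_atom_sets(pattern: Fragment, target: MolecularGraph) -> set[frozenset[int]]:
    """Distinct target atom sets covered by embeddings of ``pattern``."""
    return {atoms for atoms, _ in embedding_atom_bond_sets(pattern, target)}


def count_embeddings(pattern: Fragment, target: MolecularGraph) -> int:
    """Number of distinct ways ``pattern`` maps onto ``target``.

    Each matched atom-plus-bond subset counts once: automorphic re-mappings
    onto the same atoms and bonds are not multiply counted, so the count is
    the number of *occurrences* of the fragment in the molecule.
    """
    return len(embedding_atom_bond_sets(pattern, target))


# -- connected-subgraph enumeration ----------------------------------------


def connected_atom_subsets(
    g: nx.Graph, min_size: int = 1, max_size: Optional[int] = None
) -> Iterator[frozenset[int]]:
    """Enumerate every connected node subset of ``g`` exactly once.

    Classic rooted enumeration: each subset is generated from its smallest
    node, extending only with larger-indexed neighbours not previously
    offered at the same root.
    """
    if max_size is None:
        max_size = g.number_of_nodes()
    adj = {n: set(g[n]) for n in g.nodes}
    for root in sorted(g.nodes):
        ext0 = sorted(n for n in adj[root] if n > root)
        stack = [(frozenset([root]), ext0, set(ext0))]
        while stack:
            subset, ext, seen = stack.pop()
            if len(subset) >= min_size:
                yield subset
            if len(subset) >= max_size:
                continue
            for idx, u in enumerate(ext):
                new = [n for n in adj[u] if n > root and n not in subset and n not in seen]
                stack.append(
                    (subset | {u}, ext[idx + 1:] + new, seen | set(new))
                )


def connected_k_subsets(g: nx.Graph, k: int) -> Iterator[frozenset[int]]:
    """All connected node subsets of exactly ``k`` nodes."""
    for s in connected_atom_subsets(g, min_size=k, max_size=k):
        yield s


def _spanning_bond_variants(graph: MolecularGraph) -> Iterator[MolecularGraph]:
    """All connected spanning subgraphs of ``graph`` over its bond set.

    For acyclic graphs this is the graph itself; with rings, bond subsets
    that keep the atom set connected are also candidate common subgraphs
    (a chain can be the overlay of a ring on an open-chain molecule).
    """
    n = graph.size
    edges = list(graph.bonds)
    if len(edges) == n - 1:
        yield graph
        return
    from itertools import combinations

    seen: set[str] = set()
    for m in range(len(edges), n - 2, -1):
        for chosen in combinations(edges, m):
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from((i, j) for i, j, _ in chosen)
            if not nx.is_connected(g):
                continue
            cand = MolecularGraph.from_atoms_bonds(graph.atoms, chosen)
            if cand.canonical not in seen:
                seen.add(cand.canonical)
                yield cand


def max_common_subgraph(
    a: MolecularGraph, b: MolecularGraph
) -> Optional[Fragment]:
    """A largest connected common subgraph of ``a`` and ``b``.

    Returns ``None`` when the two structures share no atom type.  Size is
    measured in heavy atoms; among equally large candidates the one with the
    lexicographically smallest canonical string is returned, so the result
    is deterministic and symmetric in its arguments.
    """
    small, large = sorted((a, b))
    if not any(el in large.element_counts for el in small.element_counts):
        return None
    for k in range(small.size, 0, -1):
        hits: list[MolecularGraph] = []
        seen: set[str] = set()
        for subset in connected_k_subsets(small.graph, k):
            sub = small.induced(subset)
            for cand in _spanning_bond_variants(sub):
                if cand.canonical in seen:
                    continue
                seen.add(cand.canonical)
                if is_subgraph(cand, large):
                    hits.append(cand)
        if hits:
            return min(hits, key=lambda f: f.canonical)
    return None
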