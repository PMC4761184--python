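"""The UnBiological score Ub_N.

Ub_N of a test molecule, against a metabolite reference set, is the size of
the largest connected region of the molecule that contains no N-atom
fragment of the reference.  The reference fragments are all connected
N-atom subgraphs of the metabolites; a region "contains" a fragment when
the fragment's atoms and bonds can be overlaid inside it.  Regions smaller
than N are scored 0 by convention: a region with no N-atom subgraph at all
satisfies the condition vacuously, and admitting those would give every
molecule a floor of N-1 -- under the |region| >= N rule a metabolite scores
exactly 0 against its own reference, as intended.  In practice N = 5 and
6 (Ub5, Ub6) are the interesting sizes: metabolite occupancy of chemical
space is most restricted for 5- and 6-atom fragments.

Because regions are node-induced, an embedding of a reference fragment
lies inside a region exactly when its atom set does, so the search reduces
to: find the largest connected atom subset that contains no embedding atom
set ("hit").  ``ub_score`` solves this by branch-and-bound on hit deletion;
``ub_score_oracle`` enumerates every connected subset explicitly and exists
to verify the former.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .combimol import MoleculeSet
from .fragments import n_atom_fragments
from .molgraph import (
    DisconnectedError,
    Fragment,
    MolecularGraph,
    connected_atom_subsets,
    embedding_atom_sets,
)

ORACLE_SIZE_LIMIT = 14


@dataclass(frozen=True)
class UbScore:
    molecule_id: str
    n: int
    value: int

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("Ub is a non-negative integer")


class UbCalculator:
    """Ub_N scorer for a fixed metabolite reference and fragment size.

    Precomputes the reference N-fragment set once and memoizes scores by
    canonical structure, so batch scoring of overlapping compound lists is
    cheap.
    """

    def __init__(self, metabolites: MoleculeSet | Sequence[MolecularGraph], n: int):
        if n < 2:
            raise ValueError("fragment size n must be >= 2")
        mets = list(metabolites)
        if not mets:
            raise ValueError("metabolite reference set is empty")
        self.n = n
        self.reference_fragments: list[Fragment] = sorted(n_atom_fragments(mets, n))
        self._cache: dict[str, int] = {}

    # -- hits ---------------------------------------------------------------

    def _hits(self, molecule: MolecularGraph) -> list[frozenset[int]]:
        """Atom sets of every embedding of every reference fragment."""
        hits: set[frozenset[int]] = set()
        for frag in self.reference_fragments:
            hits.update(embedding_atom_sets(frag, molecule))
        return sorted(hits, key=sorted)

    # -- scoring ------------------------------------------------------------

    def score(self, molecule: MolecularGraph) -> int:
        if not nx.is_connected(molecule.graph):  # pragma: no cover - type invariant
            raise DisconnectedError("Ub is defined on connected structures")
        cached = self._cache.get(molecule.canonical)
        if cached is not None:
            return cached
        value = self._solve(molecule) if molecule.size >= self.n else 0
        self._cache[molecule.canonical] = value
        return value

    def _solve(self, molecule: MolecularGraph) -> int:
        hits = self._hits(molecule)
        g = molecule.graph
        all_atoms = frozenset(g.nodes)
        if not hits:
            return molecule.size
        best = 0
        seen: set[frozenset[int]] = set()

        def component_hits(comp: frozenset[int]) -> list[frozenset[int]]:
            return [h for h in hits if h <= comp]

        def recurse(atoms: frozenset[int]) -> None:
            nonlocal best
            if atoms in seen:
                return
            seen.add(atoms)
            sub = g.subgraph(atoms)
            for comp_nodes in nx.connected_components(sub):
                comp = frozenset(comp_nodes)
                if len(comp) <= best or len(comp) < self.n:
                    continue
                inside = component_hits(comp)
                if not inside:
                    best = len(comp)
                    continue
                # every hit must lose an atom; branch on the first hit
                for atom in sorted(inside[0]):
                    recurse(comp - {atom})

        recurse(all_atoms)
        return best

    def score_oracle(self, molecule: MolecularGraph) -> int:
        """Exhaustive reference implementation: test every connected subset."""
        if molecule.size > ORACLE_SIZE_LIMIT:
            raise ValueError(
                f"oracle is limited to {ORACLE_SIZE_LIMIT} heavy atoms"
            )
        if molecule.size < self.n:
            return 0
        hits = self._hits(molecule)
        best = 0
        for subset in connected_atom_subsets(molecule.graph, min_size=self.n):
            if len(subset) <= best:
                continue
            if not any(h <= subset for h in hits):
                best = len(subset)
        return best


def ub_score(
    molecule: MolecularGraph,
    metabolites: MoleculeSet | Sequence[MolecularGraph],
    n: int,
    molecule_id: str = "",
) -> UbScore:
    """Ub_N of one molecule against a metabolite reference set."""
    calc = UbCalculator(metabolites, n)
    return UbScore(molecule_id or molecule.canonical, n, calc.score(molecule))


def ub_score_oracle(
    molecule: MolecularGraph,
    metabolites: MoleculeSet | Sequence[MolecularGraph],
    n: int,
    molecule_id: str = "",
) -> UbScore:
    """Brute-force Ub_N (for verification; <= 14 heavy atoms)."""
    calc = UbCalculator(metabolites, n)
    return UbScore(molecule_id or molecule.canonical, n, calc.score_oracle(molecule))


def ub_table(
    molecules: Iterable[tuple[str, MolecularGraph]],
    metabolites: MoleculeSet | Sequence[MolecularGraph],
    ns: Sequence[int] = (5, 6),
) -> pd.DataFrame:
    """Batch Ub scores: one row per molecule, one ``ub<n>`` column per size.

    Per-molecule failures (e.g. a disconnected structure that slipped
    through) are recorded in an ``error`` column rather than aborting the
    batch.
    """
    if not ns:
        raise ValueError("at least one fragment size is required")
    calcs = {n: UbCalculator(metabolites, n) for n in ns}
    rows = []
    for mol_id, mol in molecules:
        row: dict = {
            "id": mol_id,
            "smiles": mol.canonical,
            "heavy_atoms": mol.size,
            "error": "",
        }
        for n in ns:
            try:
                row[f"ub{n}"] = calcs[n].score(mol)
            except Exception as exc:  # noqa: BLE001 - reported, not fatal
                row[f"ub{n}"] = pd.NA
                row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
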