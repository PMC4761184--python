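"""Fragment pools by iterated MCS closure, and fragment-count descriptors.

A fragment pool is the fixed point of repeatedly taking maximum common
subgraphs: molecule x molecule, then fragment x fragment and fragment x
molecule, until nothing new appears.  The result is the set of connected
partial structures present in two or more of the source molecules.
Fragments of one or two atoms are ignored, and pools are capped at a
maximum fragment size (14 atoms by default).

Descriptors: a molecule is described by the vector of occurrence counts of
each pool fragment (distinct atom-plus-bond embeddings), with fragments in
canonical order so that descriptor matrices are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .combimol import MoleculeSet
from .molgraph import (
    Fragment,
    MolecularGraph,
    connected_k_subsets,
    count_embeddings,
    is_subgraph,
    max_common_subgraph,
)

DEFAULT_MAX_FRAG_SIZE = 14
MIN_FRAG_SIZE = 3  # 1- and 2-atom fragments carry no shape information


@dataclass(frozen=True)
class FragmentPool:
    """MCS-closure fragments of a molecule set, with occurrence counts.

    ``occurrence[f.canonical]`` is the number of *source molecules* that
    contain fragment ``f``; every pool member occurs in at least two.
    """

    fragments: tuple[Fragment, ...]  # canonical (size, string) order
    occurrence: dict[str, int]
    source: str = ""

    def __iter__(self):
        return iter(self.fragments)

    def __len__(self):
        return len(self.fragments)

    def canonicals(self) -> list[str]:
        return [f.canonical for f in self.fragments]

    def to_tsv(self) -> str:
        lines = ["fragment\tsize\toccurrence"]
        for f in self.fragments:
            lines.append(f"{f.canonical}\t{f.size}\t{self.occurrence[f.canonical]}")
        return "\n".join(lines) + "\n"


def generate_fragment_pool(
    molecules: MoleculeSet | Sequence[MolecularGraph],
    max_frag_size: int = DEFAULT_MAX_FRAG_SIZE,
    source: str = "",
) -> FragmentPool:
    """Close a molecule set under pairwise MCS.

    Rounds alternate: pairwise MCS of the molecules seeds the pool, then MCS
    among fragments and between fragments and molecules is iterated to a
    fixed point.  Candidates below three atoms or above ``max_frag_size``
    are discarded.  Iteration order is fixed (canonical sort), so the pool
    and its serialization are reproducible.

    A single-molecule input yields an empty pool (there is no pair to
    overlap).
    """
    mols = sorted(molecules)
    if len(mols) < 2:
        import warnings

        warnings.warn("fragment pool of a single molecule is empty", stacklevel=2)
        return FragmentPool((), {}, source)

    def admissible(f: Optional[Fragment]) -> bool:
        return f is not None and MIN_FRAG_SIZE <= f.size <= max_frag_size

    pool: dict[str, Fragment] = {}

    def add_all(candidates: Iterable[Optional[Fragment]]) -> bool:
        new = False
        for f in candidates:
            if admissible(f) and f.canonical not in pool:
                pool[f.canonical] = f
                new = True
        return new

    add_all(
        max_common_subgraph(a, b)
        for idx, a in enumerate(mols)
        for b in mols[idx + 1:]
    )
    changed = True
    while changed:
        frags = sorted(pool.values())
        candidates = [
            max_common_subgraph(a, b)
            for idx, a in enumerate(frags)
            for b in frags[idx + 1:]
        ]
        candidates += [max_common_subgraph(f, m) for f in frags for m in mols]
        changed = add_all(candidates)

    occurrence = {
        key: sum(1 for m in mols if is_subgraph(f, m)) for key, f in pool.items()
    }
    ordered = tuple(sorted(pool.values()))
    return FragmentPool(ordered, occurrence, source)


def n_atom_fragments(
    molecules: MoleculeSet | Sequence[MolecularGraph], n: int
) -> set[Fragment]:
    """All distinct connected ``n``-atom subgraphs over the molecule set.

    Subgraphs are node-induced (every bond of the molecule among the chosen
    atoms is kept); molecules smaller than ``n`` contribute nothing.  This
    is a direct enumeration, independent of the >=2-occurrence pool rule,
    because the Ub definition needs *every* reference fragment.
    """
    if n < 1:
        raise ValueError("fragment size must be >= 1")
    out: dict[str, Fragment] = {}
    for mol in molecules:
        if mol.size < n:
            continue
        for subset in connected_k_subsets(mol.graph, n):
            frag = mol.induced(subset)
            out.setdefault(frag.canonical, frag)
    return set(out.values())


def describe_molecule(
    molecule: MolecularGraph, pool: FragmentPool
) -> np.ndarray:
    """Descriptor vector: embedding counts of each pool fragment."""
    if len(pool) == 0:
        raise ValueError("descriptor vector over an empty pool is undefined")
    return np.array(
        [count_embeddings(f, molecule) for f in pool.fragments], dtype=int
    )


def descriptor_table(
    molecules: Sequence[tuple[str, MolecularGraph]], pool: FragmentPool
):
    """Descriptor matrix as a pandas DataFrame (rows: molecules, columns:
    canonical fragment strings)."""
    import pandas as pd

    data = {mol_id: describe_molecule(m, pool) for mol_id, m in molecules}
    return pd.DataFrame.from_dict(
        data, orient="index", columns=pool.canonicals()
    )
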