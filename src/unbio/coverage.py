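"""Observed vs expected occupancy of chemical space.

How much of the fragment vocabulary of a chemical space does a molecule
collection actually use?  ``observed_unfound_fraction`` measures the
fraction of candidate fragments found in *no* molecule of the collection.
The null expectation -- what that fraction would be if the collection of M
molecules were assembled at random from the same space -- is
``mean_f (1 - p_f)^M``, where ``p_f`` is the probability that fragment
``f`` matches one random molecule.  A collection confined to a structured
corner of the space shows observed >> expected; a truly random collection
shows the two agreeing within Monte-Carlo error.

``p_f`` is estimated by seeded Monte-Carlo sampling of the space with a
binomial standard error (the original analytic estimator for the random
match frequency is not published; the Monte-Carlo estimator is this
package's documented replacement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .combimol import ChemSpaceSpec, MoleculeSet, sample_space
from .fragments import n_atom_fragments
from .molgraph import Fragment, MolecularGraph, is_subgraph


@dataclass(frozen=True)
class CoverageEstimate:
    """Coverage of size-``n`` fragments by a set of ``set_size`` molecules."""

    n: int
    observed_unfound: float
    expected_unfound: float
    expected_se: float
    set_size: int
    n_mc_samples: int
    seed: int

    def __post_init__(self):
        for name in ("observed_unfound", "expected_unfound"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def observed_unfound_fraction(
    fragments: Sequence[Fragment] | set[Fragment],
    molecules: MoleculeSet | Sequence[MolecularGraph],
) -> float:
    """Fraction of fragments that are a substructure of no molecule."""
    frags = sorted(fragments)
    if not frags:
        raise ValueError("fragment set is empty")
    mols = list(molecules)
    unfound = sum(
        1 for f in frags if not any(is_subgraph(f, m) for m in mols)
    )
    return unfound / len(frags)


def fragment_match_probability(
    fragment: Fragment,
    spec: ChemSpaceSpec,
    n_samples: int,
    seed: int,
    sample: Optional[Sequence[MolecularGraph]] = None,
) -> tuple[float, float]:
    """(probability, standard error) that a random molecule of the space
    contains ``fragment``.

    Monte-Carlo over ``n_samples`` draws from :func:`sample_space`,
    deterministic under ``seed``; the standard error is binomial.  A
    pre-drawn ``sample`` may be passed to share one draw across fragments.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if sample is None:
        sample = sample_space(spec, n_samples, seed=seed)
    hits = sum(1 for m in sample if is_subgraph(fragment, m))
    p = hits / n_samples
    se = math.sqrt(p * (1.0 - p) / n_samples)
    return p, se


def match_probabilities(
    fragments: Sequence[Fragment],
    spec: ChemSpaceSpec,
    n_samples: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`fragment_match_probability` over one shared sample."""
    sample = sample_space(spec, n_samples, seed=seed)
    out = np.array(
        [
            fragment_match_probability(f, spec, n_samples, seed, sample=sample)
            for f in fragments
        ]
    )
    return out[:, 0], out[:, 1]


def expected_unfound_fraction(
    match_probs: Sequence[float], set_size: int
) -> float:
    """Mean over fragments of (1 - p)^M for a random M-molecule collection.

    Treats the M molecule draws as independent; equals 1 at M = 0 and is
    non-increasing in M.
    """
    probs = np.asarray(match_probs, dtype=float)
    if probs.size == 0:
        raise ValueError("no match probabilities given")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if set_size < 0:
        raise ValueError("set size must be >= 0")
    return float(np.mean((1.0 - probs) ** set_size))


def expected_unfound_se(
    match_probs: Sequence[float],
    match_ses: Sequence[float],
    set_size: int,
) -> float:
    """Delta-method standard error of :func:`expected_unfound_fraction`.

    Propagates the per-fragment binomial error of p through (1-p)^M and
    averages (fragments treated as independent -- an approximation, since
    they share one Monte-Carlo sample).
    """
    p = np.asarray(match_probs, dtype=float)
    se = np.asarray(match_ses, dtype=float)
    grad = set_size * (1.0 - p) ** max(set_size - 1, 0)
    return float(np.sqrt(np.sum((grad * se) ** 2)) / p.size)


def coverage_curve(
    spec: ChemSpaceSpec,
    molecules: MoleculeSet | Sequence[MolecularGraph],
    sizes: Sequence[int] = (3, 4, 5, 6, 7),
    n_mc_samples: int = 2000,
    seed: int = 0,
    set_size: Optional[int] = None,
) -> list[CoverageEstimate]:
    """Observed vs expected unfound fraction per fragment size.

    Candidate fragments of each size are taken from the enumerated space
    itself (all connected n-atom subgraphs over its molecules).  ``set_size``
    defaults to the number of molecules in the collection; pass the number
    of independent draws explicitly when the collection was sampled with
    replacement.
    """
    mols = list(molecules)
    m = set_size if set_size is not None else len(mols)
    space = None
    out = []
    for k, n in enumerate(sizes):
        from .combimol import enumerate_space

        if space is None:
            space = enumerate_space(spec)
        frags = sorted(n_atom_fragments(space, n))
        if not frags:
            continue
        observed = observed_unfound_fraction(frags, mols)
        probs, ses = match_probabilities(frags, spec, n_mc_samples, seed + k)
        expected = expected_unfound_fraction(probs, m)
        se = expected_unfound_se(probs, ses, m)
        out.append(
            CoverageEstimate(
                n=n,
                observed_unfound=observed,
                expected_unfound=expected,
                expected_se=se,
                set_size=m,
                n_mc_samples=n_mc_samples,
                seed=seed + k,
            )
        )
    return out
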