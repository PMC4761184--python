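"""Graph model, parsing, canonicalization and matching primitives."""

import itertools
import random

import pytest

from unbio.molgraph import (
    DisconnectedError,
    MolecularGraph,
    ParseError,
    ValenceError,
    connected_atom_subsets,
    count_embeddings,
    is_subgraph,
    largest_organic_component,
    max_common_subgraph,
    parse_structure,
    read_sdf,
    read_smiles_lines,
)

from conftest import brute_force_mcs_size


class TestParsing:
    def test_ethanol_atoms_and_bonds(self):
        g = parse_structure("CCO")
        assert g.atoms == ("C", "C", "O")
        assert g.bonds == ((0, 1, 1), (1, 2, 1))

    def test_ring_closure(self):
        g = parse_structure("C1CC1")
        assert g.size == 3
        assert all(o == 1 for _, _, o in g.bonds) and len(g.bonds) == 3

    def test_unstable_peroxide_chain_still_parses(self):
        # stability filtering belongs to the space enumerator, not the parser
        assert parse_structure("COOOC").size == 5

    def test_parse_failure_carries_text(self):
        with pytest.raises(ParseError) as err:
            parse_structure("CC(")
        assert "CC(" in str(err.value)

    def test_valence_violation_names_atom(self):
        with pytest.raises(ValenceError) as err:
            parse_structure("C(C)(C)(C)(C)C")
        assert err.value.atom_index == 0

    def test_disconnected_input_rejected(self):
        with pytest.raises(DisconnectedError):
            parse_structure("CC.O")

    def test_salt_scored_on_organic_component(self):
        g = largest_organic_component("[Na+].CC([O-])=O")
        assert g.canonical == parse_structure("CC(=O)O").canonical

    @pytest.mark.parametrize(
        "a,b",
        [
            ("OCC", "CCO"),
            ("Cc1ccccc1", "c1ccc(C)cc1"),
            ("C(=O)(O)CN", "NCC(=O)O"),
        ],
    )
    def test_canonical_form_is_input_order_independent(self, a, b):
        assert parse_structure(a).canonical == parse_structure(b).canonical

    def test_canonicalization_is_a_fixed_point(self, random_molecules):
        for mol in random_molecules[:25]:
            again = parse_structure(mol.canonical)
            assert again.canonical == mol.canonical
            assert again.atoms == mol.atoms and again.bonds == mol.bonds

    def test_charges_normalized_to_neutral(self):
        assert parse_structure("CC(=O)[O-]") == parse_structure("CC(=O)O")


class TestFileIO:
    def test_smiles_lines_roundtrip(self):
        text = "CCO\te1\nCC(=O)O\ta2\n"
        recs = read_smiles_lines(text.splitlines())
        assert [rid for rid, _ in recs] == ["e1", "a2"]
        assert recs[0][1].canonical == "CCO"

    def test_sdf_reading_and_error_reporting(self):
        from rdkit import Chem

        block = Chem.MolToMolBlock(Chem.MolFromSmiles("CCN"))
        sdf = block + "$$$$\n"
        recs = read_sdf(sdf)
        assert len(recs) == 1 and recs[0][1].canonical == "CCN"
        broken = sdf + "garbage\nnot a mol\nM  END\n$$$$\n"
        with pytest.raises(ParseError) as err:
            read_sdf(broken)
        assert "record 2" in str(err.value)


class TestSubstructure:
    @pytest.mark.parametrize(
        "pattern,target,expected",
        [
            ("CCO", "CCCO", True),
            ("CCN", "CCCO", False),
            ("CC=O", "CC(=O)O", True),
            ("CCC", "C1CC1", True),   # overlay needs only the pattern's bonds
            ("C=C", "CC", False),     # bond orders must match exactly
        ],
    )
    def test_overlay_semantics(self, pattern, target, expected):
        assert is_subgraph(parse_structure(pattern), parse_structure(target)) is expected

    @pytest.mark.parametrize(
        "pattern,target,expected",
        [
            ("CCC", "CCCCC", 3),
            ("CCCCC", "CCCCC", 1),
            ("CC=O", "CC(=O)C", 2),
            ("CCC", "C1CC1", 3),  # three bond-pair choices on the triangle
            ("CO", "COC", 2),
        ],
    )
    def test_embedding_counts_per_atom_bond_subset(self, pattern, target, expected):
        assert count_embeddings(parse_structure(pattern), parse_structure(target)) == expected

    def test_count_positive_iff_subgraph(self, random_molecules):
        pats = random_molecules[:10]
        targets = random_molecules[10:25]
        for p in pats:
            for t in targets:
                assert (count_embeddings(p, t) >= 1) == is_subgraph(p, t)


class TestConnectedSubsetEnumeration:
    def test_matches_brute_force(self, random_molecules):
        import networkx as nx

        for mol in random_molecules[:12]:
            g = mol.graph
            expected = {
                frozenset(c)
                for r in range(1, g.number_of_nodes() + 1)
                for c in itertools.combinations(g.nodes, r)
                if nx.is_connected(g.subgraph(c))
            }
            assert set(connected_atom_subsets(g)) == expected


class TestMCS:
    @pytest.mark.parametrize(
        "a,b,expected_smiles,expected_size",
        [
            ("CCCO", "CCCN", "CCC", 3),
            ("C", "O", None, 0),
            ("C1CC1", "CCCC", "CCC", 3),
        ],
    )
    def test_examples(self, a, b, expected_smiles, expected_size):
        res = max_common_subgraph(parse_structure(a), parse_structure(b))
        if expected_smiles is None:
            assert res is None
        else:
            assert res.canonical == expected_smiles and res.size == expected_size

    def test_self_mcs_is_identity(self, random_molecules):
        for mol in random_molecules[:8]:
            assert max_common_subgraph(mol, mol) == mol

    def test_result_is_common_and_symmetric(self, random_molecules):
        rng = random.Random(3)
        pool = random_molecules
        for _ in range(25):
            a, b = rng.choice(pool), rng.choice(pool)
            res = max_common_subgraph(a, b)
            swapped = max_common_subgraph(b, a)
            if res is None:
                assert swapped is None
                continue
            assert is_subgraph(res, a) and is_subgraph(res, b)
            assert swapped == res

    def test_size_matches_exhaustive_search(self, random_molecules):
        rng = random.Random(5)
        pool = [m for m in random_molecules if m.size <= 5]
        for _ in range(15):
            a, b = rng.choice(pool), rng.choice(pool)
            res = max_common_subgraph(a, b)
            size = res.size if res is not None else 0
            assert size == brute_force_mcs_size(a, b)

    def test_size_matches_rdkit_fmcs(self):
        """Independent cross-check against RDKit's FMCS on acyclic pairs."""
        from rdkit import Chem
        from rdkit.Chem import rdFMCS

        pairs = [
            ("CCCO", "CCCN"),
            ("CC(C)CO", "CCCCO"),
            ("NCC(=O)O", "CC(=O)O"),
            ("CC(N)C(=O)O", "NCC(=O)O"),
            ("CCOC", "CCCO"),
        ]
        params = rdFMCS.MCSParameters()
        params.AtomTyper = rdFMCS.AtomCompare.CompareElements
        params.BondTyper = rdFMCS.BondCompare.CompareOrder
        params.MaximizeBonds = False
        for a, b in pairs:
            ours = max_common_subgraph(parse_structure(a), parse_structure(b))
            ref = rdFMCS.FindMCS(
                [Chem.MolFromSmiles(a), Chem.MolFromSmiles(b)], params
            )
            assert ours is not None and ours.size == ref.numAtoms
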