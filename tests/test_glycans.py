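"""Glycan trees: parsing, isomorphism dedup, Y-ion enumeration vs oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycopipe import glycans as G
from glycopipe.masses import MONOSACCHARIDES


def brute_force_y_masses(tree: G.GlycanTree) -> list[float]:
    """Oracle: test every node subset for root-containing connectivity."""
    nodes = list(tree.walk())
    index = {id(n): i for i, n in enumerate(nodes)}
    parents = {}
    for n in nodes:
        for c in n.children:
            parents[index[id(c)]] = index[id(n)]
    masses = [MONOSACCHARIDES[n.symbol] for n in nodes]
    out = [0.0]  # Y0: empty glycan part
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(range(len(nodes)), r):
            sset = set(subset)
            if 0 not in sset:  # must contain the root
                continue
            if all(i == 0 or parents[i] in sset for i in subset):
                out.append(sum(masses[i] for i in subset))
    return sorted(out)


class TestParse:
    def test_single_node(self):
        t = G.parse_glycan("(N)")
        assert t.n_nodes == 1
        assert t.composition.as_tuple() == (0, 1, 0, 0, 0)

    def test_trimannosyl_core(self, trimannosyl_core):
        assert trimannosyl_core.n_nodes == 5
        assert trimannosyl_core.composition.as_tuple() == (3, 2, 0, 0, 0)

    @pytest.mark.parametrize("bad", ["(N(X))", "(N(H)", "N)", "", "(N))(", "(N)x"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(G.GlycanParseError):
            G.parse_glycan(bad)

    def test_composition_mass_is_dot_product(self):
        c = G.GlycanComposition(hex=6, hexnac=5, neuac=1, dhex=1)
        expected = (
            6 * MONOSACCHARIDES["Hex"]
            + 5 * MONOSACCHARIDES["HexNAc"]
            + MONOSACCHARIDES["NeuAc"]
            + MONOSACCHARIDES["dHex"]
        )
        assert c.mass == pytest.approx(expected, abs=1e-9)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            G.GlycanComposition(hex=-1)


class TestDatabase:
    def test_duplicate_lines_deduplicated(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("(N)\n(N)\n")
        assert len(G.load_glycan_db(p)) == 1

    def test_unordered_children_isomorphism(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("(N(H)(F))\n(N(F)(H))\n")
        assert len(G.load_glycan_db(p)) == 1

    def test_empty_file(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("# only a comment\n\n")
        assert G.load_glycan_db(p) == []

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("(N)\n(N(X))\n")
        with pytest.raises(G.GlycanParseError, match="line 2"):
            G.load_glycan_db(p)

    def test_ids_preserved(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("(N(H))\tMYID\n")
        assert G.load_glycan_db(p)[0].id == "MYID"

    def test_round_trip(self, tmp_path, small_db):
        p = tmp_path / "db.txt"
        G.write_glycan_db(small_db, p)
        back = G.load_glycan_db(p)
        assert [t.canonical() for t in back] == [t.canonical() for t in small_db]


# random rooted trees for property tests, encoded directly
@st.composite
def random_tree_encoding(draw, max_nodes=12):
    symbols = "HNAGF"
    n = draw(st.integers(min_value=1, max_value=max_nodes))
    syms = draw(
        st.lists(st.sampled_from(symbols), min_size=n, max_size=n)
    )
    # random parent for each non-root node among earlier nodes
    parents = [draw(st.integers(min_value=0, max_value=i - 1)) for i in range(1, n)]
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, p in enumerate(parents, start=1):
        children[p].append(i)

    def encode(i: int) -> str:
        return f"({syms[i]}" + "".join(encode(c) for c in children[i]) + ")"

    return encode(0)


class TestYIonEnumeration:
    def test_linear_chain(self):
        t = G.parse_glycan("(N(N(H)))")
        got = sorted(G.enumerate_y_ions(t).distinct_masses)
        n, h = MONOSACCHARIDES["HexNAc"], MONOSACCHARIDES["Hex"]
        assert np.allclose(got, [0.0, n, 2 * n, 2 * n + h], atol=1e-6)

    def test_trimannosyl_core_multiplicity(self, trimannosyl_core):
        y = G.enumerate_y_ions(trimannosyl_core)
        assert len(y.entries) == 7  # Y0 + 6 root-containing subtrees
        assert len(y.distinct_masses) == 6  # 2N+2H is doubly realisable
        n, h = MONOSACCHARIDES["HexNAc"], MONOSACCHARIDES["Hex"]
        expected = [0.0, n, 2 * n, 2 * n + h, 2 * n + 2 * h, 2 * n + 3 * h]
        assert np.allclose(sorted(y.distinct_masses), expected, atol=1e-6)

    def test_single_node(self):
        y = G.enumerate_y_ions(G.parse_glycan("(N)"))
        assert np.allclose(
            sorted(y.distinct_masses), [0.0, MONOSACCHARIDES["HexNAc"]], atol=1e-6
        )

    @given(random_tree_encoding())
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_subset_oracle(self, encoding):
        tree = G.parse_glycan(encoding)
        got = sorted(m for m, _ in G.enumerate_y_ions(tree).entries)
        assert np.allclose(got, brute_force_y_masses(tree), atol=1e-9)

    @given(random_tree_encoding())
    @settings(max_examples=40, deadline=None)
    def test_full_tree_entry_equals_composition_mass(self, encoding):
        tree = G.parse_glycan(encoding)
        y = G.enumerate_y_ions(tree)
        assert max(m for m, _ in y.entries) == pytest.approx(
            tree.composition.mass, abs=1e-6
        )

    @given(random_tree_encoding(max_nodes=8))
    @settings(max_examples=40, deadline=None)
    def test_isomorphism_invariant_under_child_permutation(self, encoding):
        tree = G.parse_glycan(encoding)
        for node in tree.walk():
            node.children.reverse()
        assert tree.canonical() == G.parse_glycan(encoding).canonical()


class TestCoreIons:
    def test_exactly_nine_offsets_strictly_increasing(self):
        offsets = sorted(G.CORE_IONS.values())
        assert len(offsets) == 9
        assert all(b > a for a, b in zip(offsets, offsets[1:]))

    def test_backbone_offsets(self):
        masses = G.core_ion_masses(1407.80856)
        assert masses["Y1"] == pytest.approx(1610.88793, abs=1e-4)
        assert masses["0,2X0"] == pytest.approx(1490.84567, abs=1e-4)

    def test_nonpositive_backbone_rejected(self):
        with pytest.raises(ValueError):
            G.core_ion_masses(0.0)

    def test_composition_restriction(self):
        no_fuc = G.core_ion_offsets(G.GlycanComposition(hex=3, hexnac=2))
        assert "Y-01001" not in no_fuc and "Y5" in no_fuc
        small = G.core_ion_offsets(G.GlycanComposition(hex=1, hexnac=2))
        assert "Y4" not in small and "Y3" in small


class TestReversedY:
    def test_single_residue_self_reverse(self):
        y = G.enumerate_y_ions(G.parse_glycan("(N)"))
        rev = G.reversed_y_masses(y)
        assert sorted(rev) == pytest.approx(sorted(m for m, _ in y.entries), abs=1e-9)

    @given(random_tree_encoding())
    @settings(max_examples=40, deadline=None)
    def test_conservation_identity(self, encoding):
        tree = G.parse_glycan(encoding)
        y = G.enumerate_y_ions(tree)
        rev = G.reversed_y_masses(y)
        total = tree.mass
        for (g, _), r in zip(y.entries, rev):
            assert g + r == pytest.approx(total, abs=1e-9)

    def test_symmetric_structure_nearly_self_reverse(self):
        # characterisation of why reversal makes poor decoys: for this
        # (3,4,0,0,0)-composition structure the reversed multiset nearly
        # reproduces the target multiset
        tree = G.parse_glycan("(N(N(H(N)(H(N)))))")
        y = G.enumerate_y_ions(tree)
        fwd = np.sort(y.distinct_masses)
        rev = np.sort(
            G.YIonSet(
                entries=[(m, 0) for m in G.reversed_y_masses(y)],
                total_mass=y.total_mass,
            ).distinct_masses
        )
        overlap = sum(
            1 for m in rev if np.min(np.abs(fwd - m)) < 0.01
        )
        assert overlap >= len(rev) - 2
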