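import pytest

from fragnet.chem_io import parse_structure
from fragnet.fragmentation import (
    FragmentationError,
    build_reduced_graph,
    enumerate_fragments,
    expand_fragment,
    load_unit_smarts,
)
from oracles import connected_subsets_brute_force


class TestBuildReducedGraph:
    def test_nitronaphthalene_three_units(self, nitronaphthalene):
        rg = build_reduced_graph(nitronaphthalene)
        kinds = sorted(u.kind for u in rg.units)
        assert kinds == ["functional_group", "ring", "ring"]
        # path topology: nitro-ring-ring
        assert len(rg.edges) == 2
        nitro = next(u for u in rg.units if u.kind == "functional_group")
        assert nitro.label == "nitro"
        assert len(nitro.atom_ids) == 3

    def test_benzene_single_ring_unit(self, benzene):
        rg = build_reduced_graph(benzene)
        assert len(rg.units) == 1
        assert rg.units[0].kind == "ring"
        assert rg.edges == frozenset()

    def test_butane_four_linkers(self):
        rg = build_reduced_graph(parse_structure("CCCC"))
        assert [u.kind for u in rg.units] == ["linker"] * 4
        assert len(rg.edges) == 3  # a path

    def test_every_atom_covered(self, toy_library):
        for s in toy_library.structures:
            rg = build_reduced_graph(s)
            covered = set()
            for u in rg.units:
                covered |= u.atom_ids
            assert covered == set(s.atom_ids())

    def test_ring_precedence_over_functional_group(self):
        # epoxide oxygen sits in a ring: it must be a ring unit, not hydroxyl/FG
        rg = build_reduced_graph(parse_structure("CC1CO1"))
        ring = [u for u in rg.units if u.kind == "ring"]
        assert len(ring) == 1 and len(ring[0].atom_ids) == 3

    def test_fused_rings_share_atoms_via_edge(self):
        rg = build_reduced_graph(parse_structure("c1ccc2ccccc2c1"))
        assert len(rg.units) == 2
        assert len(rg.edges) == 1

    def test_custom_unit_smarts_file(self, tmp_path, nitronaphthalene):
        p = tmp_path / "units.tsv"
        p.write_text("nitro\t[NX3+](=O)[OX1-]\n")
        rg = build_reduced_graph(nitronaphthalene, load_unit_smarts(p))
        assert sorted(u.kind for u in rg.units) == ["functional_group", "ring", "ring"]


class TestExpandFragment:
    def test_single_nitro_unit(self, nitronaphthalene):
        rg = build_reduced_graph(nitronaphthalene)
        nitro = next(u for u in rg.units if u.label == "nitro")
        frag = expand_fragment(rg, {nitro.unit_id})
        assert len(frag.atom_ids) == 3
        assert "[N" in frag.key and "O" in frag.key

    def test_ring_pair_is_naphthalene(self, nitronaphthalene):
        rg = build_reduced_graph(nitronaphthalene)
        rings = [u.unit_id for u in rg.units if u.kind == "ring"]
        frag = expand_fragment(rg, rings)
        assert frag.key == parse_structure("c1ccc2ccccc2c1").to_smiles()

    def test_all_units_is_whole_structure(self, nitronaphthalene):
        rg = build_reduced_graph(nitronaphthalene)
        frag = expand_fragment(rg, {u.unit_id for u in rg.units})
        assert frag.atom_ids == nitronaphthalene.atom_ids()
        assert frag.bond_ids == nitronaphthalene.bond_ids()

    def test_disconnected_subset_rejected(self, nitronaphthalene):
        rg = build_reduced_graph(nitronaphthalene)
        nitro = next(u.unit_id for u in rg.units if u.kind == "functional_group")
        far_ring = next(
            u.unit_id
            for u in rg.units
            if u.kind == "ring" and frozenset({u.unit_id, nitro}) not in rg.edges
        )
        with pytest.raises(FragmentationError, match="not connected"):
            expand_fragment(rg, {nitro, far_ring})

    def test_bonds_are_exactly_internal(self, toy_library):
        for s in toy_library.structures[:10]:
            rg = build_reduced_graph(s)
            for frag in enumerate_fragments(rg):
                expected = {
                    b.index
                    for b in s.bonds
                    if b.begin in frag.atom_ids and b.end in frag.atom_ids
                }
                assert set(frag.bond_ids) == expected


class TestEnumerateFragments:
    def test_nitronaphthalene_six_fragments(self, nitronaphthalene):
        frags = enumerate_fragments(build_reduced_graph(nitronaphthalene))
        assert len(frags) == 6
        atom_sets = {f.atom_ids for f in frags}
        assert nitronaphthalene.atom_ids() in atom_sets  # the query is included

    def test_benzene_single_fragment(self, benzene):
        frags = enumerate_fragments(build_reduced_graph(benzene))
        assert len(frags) == 1
        assert frags[0].atom_ids == benzene.atom_ids()

    @pytest.mark.parametrize("m", [2, 3, 4, 5, 6])
    def test_path_count_law(self, m):
        """A path of m linker units must yield m(m+1)/2 fragments."""
        s = parse_structure("C" * m)
        rg = build_reduced_graph(s)
        frags = enumerate_fragments(rg)
        assert len(frags) == m * (m + 1) // 2
        oracle = connected_subsets_brute_force(len(rg.units), set(rg.edges))
        assert {f.unit_ids for f in frags} == oracle

    def test_star_count_law(self):
        """A star with m=4 leaves yields 2^m + m connected subsets: any leaf
        subset joined through the hub (2^m, hub-only included) plus the m
        lone leaves.  Verified against the exhaustive oracle below."""
        s = parse_structure("CC(C)(C)C")  # neopentane: central C with 4 leaves
        rg = build_reduced_graph(s)
        frags = enumerate_fragments(rg)
        assert len(frags) == 2**4 + 4
        oracle = connected_subsets_brute_force(len(rg.units), set(rg.edges))
        assert {f.unit_ids for f in frags} == oracle

    def test_matches_brute_force_on_toy_library(self, toy_library):
        for s in toy_library.structures[:15]:
            rg = build_reduced_graph(s)
            frags = enumerate_fragments(rg)
            oracle = connected_subsets_brute_force(len(rg.units), set(rg.edges))
            assert {f.unit_ids for f in frags} == oracle

    def test_max_depth_limits_size_but_keeps_root(self, nitronaphthalene):
        rg = build_reduced_graph(nitronaphthalene)
        frags = enumerate_fragments(rg, max_depth=1)
        sizes = sorted(len(f.unit_ids) for f in frags)
        assert sizes == [1, 1, 1, 3]  # three units plus the full query

    def test_unit_cap(self):
        s = parse_structure("C" * 30)
        rg = build_reduced_graph(s)
        with pytest.raises(FragmentationError, match="cap"):
            enumerate_fragments(rg)
        assert enumerate_fragments(rg, max_depth=2)

    def test_connectivity_invariant(self, toy_library):
        for s in toy_library.structures[:10]:
            for frag in enumerate_fragments(build_reduced_graph(s)):
                adj = {a: set() for a in frag.atom_ids}
                for b in s.bonds:
                    if b.index in frag.bond_ids:
                        adj[b.begin].add(b.end)
                        adj[b.end].add(b.begin)
                seen, stack = set(), [next(iter(frag.atom_ids))]
                while stack:
                    a = stack.pop()
                    if a not in seen:
                        seen.add(a)
                        stack.extend(adj[a] - seen)
                assert seen == set(frag.atom_ids)

    def test_hierarchy_closure(self, toy_library):
        """Every non-root fragment has an enumerated strict superset."""
        for s in toy_library.structures[:10]:
            frags = enumerate_fragments(build_reduced_graph(s))
            atom_sets = [f.atom_ids for f in frags]
            root = max(atom_sets, key=len)
            for a in atom_sets:
                if a != root:
                    assert any(a < b for b in atom_sets)

    def test_no_partial_rings(self, toy_library):
        for s in toy_library.structures[:10]:
            ring_info = s.mol.GetRingInfo()
            for frag in enumerate_fragments(build_reduced_graph(s)):
                for ring_bonds in ring_info.BondRings():
                    if set(ring_bonds) & frag.bond_ids:
                        assert set(ring_bonds) <= frag.bond_ids
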