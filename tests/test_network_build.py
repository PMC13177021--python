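import dataclasses

import numpy as np
import pytest

from scwnet import (Frame, Ion, build_network, candidate_pairs,
                    coulomb_energy, criterion_total, cylinder_blocked,
                    generate_water_frame, inner_cube_ids,
                    lennard_jones_energy, pair_kinetic_energy)
from scwnet.network_build import geometric_pair_table

from conftest import make_molecule
from oracles import all_pairs_within


class TestInnerCube:
    def test_center_molecule_always_retained(self):
        f = Frame(box=[2.0, 2.0, 2.0],
                  molecules=[make_molecule(1, [1.0, 1.0, 1.0])])
        assert inner_cube_ids(f, 0.05) == {1}

    def test_corner_molecule_excluded(self):
        f = Frame(box=[2.0, 2.0, 2.0],
                  molecules=[make_molecule(1, [0.05, 0.05, 0.05])])
        assert inner_cube_ids(f, 0.85) == set()
        assert inner_cube_ids(f, 1.0) == {1}

    def test_unit_fraction_is_identity_filter(self):
        f = generate_water_frame(50, box=2.0, T=600.0, seed=0)
        assert inner_cube_ids(f, 1.0) == {m.id for m in f.molecules}


class TestCylinder:
    def _pair_frame(self, third=None):
        mols = [make_molecule(1, [1.0, 1.0, 1.0]),
                make_molecule(2, [1.6, 1.0, 1.0])]
        if third is not None:
            mols.append(make_molecule(3, third))
        return Frame(box=[3.0, 3.0, 3.0], molecules=mols)

    def test_third_body_at_midpoint_blocks(self):
        f = self._pair_frame(third=[1.3, 1.0, 1.0])
        assert cylinder_blocked(f.molecules[0], f.molecules[1], f, 0.3159)

    def test_third_body_outside_radius_does_not_block(self):
        f = self._pair_frame(third=[1.3, 1.40, 1.0])
        assert not cylinder_blocked(f.molecules[0], f.molecules[1], f, 0.3159)

    def test_cylinder_is_capped_at_the_endpoints(self):
        # on the axis line but beyond molecule 2
        f = self._pair_frame(third=[2.2, 1.0, 1.0])
        assert not cylinder_blocked(f.molecules[0], f.molecules[1], f, 0.3159)

    def test_ion_blocks_when_inside(self):
        f = self._pair_frame()
        f.ions.append(Ion(label="CL", position=[1.3, 1.0, 1.0], charge=-1.0))
        assert cylinder_blocked(f.molecules[0], f.molecules[1], f, 0.3159)
        assert not cylinder_blocked(f.molecules[0], f.molecules[1], f, 0.3159,
                                    include_ions=False)

    def test_coincident_centres_raise(self):
        m1 = make_molecule(1, [1.0, 1.0, 1.0])
        m2 = make_molecule(2, [1.0, 1.0, 1.0])
        f = Frame(box=[3.0, 3.0, 3.0], molecules=[m1, m2])
        with pytest.raises(ValueError):
            cylinder_blocked(m1, m2, f, 0.3159)


class TestCandidatePairs:
    def test_single_close_pair(self):
        f = Frame(box=[2.0, 2.0, 2.0],
                  molecules=[make_molecule(1, [1.0, 1.0, 1.0]),
                             make_molecule(2, [1.3, 1.0, 1.0])])
        assert candidate_pairs(f, {1, 2}, 0.8) == [(1, 2)]

    def test_cutoff_below_all_distances_gives_empty(self):
        f = Frame(box=[2.0, 2.0, 2.0],
                  molecules=[make_molecule(1, [0.5, 0.5, 0.5]),
                             make_molecule(2, [1.5, 1.5, 1.5])])
        assert candidate_pairs(f, {1, 2}, 0.5) == []

    def test_matches_all_pairs_enumeration(self, ff):
        f = generate_water_frame(200, box=2.5, T=650.0, seed=11)
        nodes = {m.id for m in f.molecules}
        got = set(candidate_pairs(f, nodes, 0.6))
        ids = [m.id for m in f.molecules]
        expected = all_pairs_within(ids, f.coms(ff), 0.6)
        assert got == expected


class TestBuildNetwork:
    def test_bound_dimer_yields_one_edge(self, bound_dimer_frame, params673):
        net = build_network(bound_dimer_frame, params673)
        assert net.n_edges == 1
        e = net.edges[0]
        assert {e.i, e.j} == {1, 2}
        assert e.criterion_total < 0

    def test_third_molecule_on_axis_suppresses_the_edge(
            self, bound_dimer_frame, params673):
        blocker = make_molecule(3, [1.64, 1.95, 1.5])  # 0.45 nm off the axis
        blocker_mid = make_molecule(3, [1.64, 1.5, 1.5])
        f = Frame(box=[3.0, 3.0, 3.0],
                  molecules=bound_dimer_frame.molecules[:2] + [blocker_mid])
        assert build_network(f, params673).n_edges == 0
        f2 = Frame(box=[3.0, 3.0, 3.0],
                   molecules=bound_dimer_frame.molecules[:2] + [blocker])
        assert build_network(f2, params673).n_edges == 1

    def test_empty_frame_gives_empty_network(self, params673):
        net = build_network(Frame(box=[2.0, 2.0, 2.0]), params673)
        assert net.nodes == set()
        assert net.n_edges == 0

    def test_raising_pair_cutoff_never_changes_edges(self, params673):
        f = generate_water_frame(150, box=2.2, T=650.0, seed=21, min_sep=0.24)
        base = build_network(f, params673)
        wide = build_network(
            f, dataclasses.replace(params673, pair_cutoff=1.3))
        assert {(e.i, e.j) for e in base.edges} == \
            {(e.i, e.j) for e in wide.edges}

    def test_zero_radius_matches_unfiltered_oracle(self, ff, params673):
        # with r_c = 0 only third bodies exactly on the axis block; random
        # frames have none, so the edge set must equal a no-cylinder oracle
        f = generate_water_frame(120, box=2.2, T=650.0, seed=31, min_sep=0.24)
        p0 = dataclasses.replace(params673, r_c=0.0)
        net = build_network(f, p0)
        nodes = inner_cube_ids(f, p0.cube_fraction, ff)
        by_id = {m.id: m for m in f.molecules}
        expected = set()
        for i, j in candidate_pairs(f, nodes, p0.pair_cutoff, ff):
            mi, mj = by_id[i], by_id[j]
            tot = criterion_total(coulomb_energy(mi, mj, ff),
                                  lennard_jones_energy(mi, mj, ff),
                                  pair_kinetic_energy(mi, mj, ff), p0)
            if tot < 0:
                expected.add((i, j))
        assert {(e.i, e.j) for e in net.edges} == expected

    def test_removing_third_molecules_only_adds_edges(self, params673):
        f = generate_water_frame(150, box=2.0, T=650.0, seed=46, min_sep=0.23)
        net = build_network(f, params673)
        keep = set()
        for e in net.edges:
            keep.update((e.i, e.j))
        assert keep, "fixture must contain edges for the property to bite"
        sub = Frame(box=f.box,
                    molecules=[m for m in f.molecules if m.id in keep])
        net_sub = build_network(sub, params673)
        assert {(e.i, e.j) for e in net.edges} <= \
            {(e.i, e.j) for e in net_sub.edges}

    def test_invariant_under_id_relabelling(self, params673):
        f = generate_water_frame(100, box=2.0, T=650.0, seed=51, min_sep=0.24)
        shift = 1000
        relabelled = Frame(box=f.box, molecules=[
            dataclasses.replace(m, id=m.id + shift) for m in f.molecules])
        a = build_network(f, params673)
        b = build_network(relabelled, params673)
        assert {(i + shift, j + shift) for i, j in
                ((e.i, e.j) for e in a.edges)} == \
            {(e.i, e.j) for e in b.edges}
        assert {n + shift for n in a.nodes} == b.nodes

    def test_interacting_subset_has_degree_at_least_one(
            self, bound_dimer_frame, params673):
        lonely = make_molecule(9, [2.2, 2.2, 2.2])
        f = Frame(box=[3.0, 3.0, 3.0],
                  molecules=bound_dimer_frame.molecules + [lonely])
        net = build_network(f, params673)
        assert net.interacting == {1, 2}
        assert 9 in net.nodes

    def test_pair_table_thresholding_matches_direct_build(self, params673):
        f = generate_water_frame(100, box=2.0, T=650.0, seed=61, min_sep=0.24)
        table = geometric_pair_table(f, params673)
        for lam in (0.0, 0.3, 0.655, 1.0):
            p = params673.with_lambda(lam)
            direct = build_network(f, p)
            cached = table.network_at(p)
            assert {(e.i, e.j) for e in direct.edges} == \
                {(e.i, e.j) for e in cached.edges}
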