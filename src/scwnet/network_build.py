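"""Geometric filters and assembly of the interaction network from a frame.

Construction proceeds cheapest-first: (1) keep molecules whose centre of
mass lies in a concentric cube (boundary treatment replacing minimum-image
distances), (2) enumerate COM pairs within a conservative cutoff, (3) drop
pairs whose COM-COM segment has any third body inside an interference
cylinder of radius r_c, (4) apply the energetic criterion.  The filter
order does not affect the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .energetics import (CriterionParameters, PairEnergies, criterion_total,
                         coulomb_energy, lennard_jones_energy,
                         pair_kinetic_energy)
from .model_io import DEFAULT_FF, ForceFieldParameters, Frame, WaterMolecule


@dataclass
class InteractionNetwork:
    """Molecules-as-nodes graph under the energetic pair criterion.

    Attributes
    ----------
    nodes : set[int]
        Molecule ids surviving the inner-cube filter.
    edges : list[PairEnergies]
        Undirected edges with their energy decomposition (i < j, no
        duplicates, no self-loops).
    """

    nodes: set[int]
    edges: list[PairEnergies] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e.i == e.j:
                raise ValueError("self-loop in interaction network")
            if e.i not in self.nodes or e.j not in self.nodes:
                raise ValueError("edge endpoint outside node set")
            key = (min(e.i, e.j), max(e.i, e.j))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def interacting(self) -> set[int]:
        """Nodes with degree >= 1."""
        out: set[int] = set()
        for e in self.edges:
            out.add(e.i)
            out.add(e.j)
        return out

    def to_networkx(self):
        """Graph view with all nodes and per-edge energy attributes."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.i, e.j, V_coul=e.V_coul, V_LJ=e.V_LJ,
                       E_kin_pair=e.E_kin_pair,
                       criterion_total=e.criterion_total)
        return g


def inner_cube_ids(frame: Frame, cube_fraction: float,
                   ff: ForceFieldParameters = DEFAULT_FF) -> set[int]:
    """Ids of molecules whose COM lies in the concentric shrunken cube.

    The retained region is the axis-aligned box centred in the frame with
    edge ``cube_fraction * L`` per axis.
    """
    if not (0 < cube_fraction <= 1):
        raise ValueError("cube_fraction must be in (0, 1]")
    if not frame.molecules:
        return set()
    coms = frame.coms(ff)
    lo = frame.box * (1.0 - cube_fraction) / 2.0
    hi = frame.box - lo
    inside = np.all((coms >= lo) & (coms <= hi), axis=1)
    return {m.id for m, ok in zip(frame.molecules, inside) if ok}


def _third_body_points(frame: Frame, exclude: tuple[int, int],
                       ff: ForceFieldParameters,
                       include_ions: bool = True) -> np.ndarray:
    pts = [m.com(ff) for m in frame.molecules if m.id not in exclude]
    if include_ions:
        pts.extend(ion.position for ion in frame.ions)
    if not pts:
        return np.zeros((0, 3))
    return np.stack(pts)


def _cylinder_contains(a: np.ndarray, b: np.ndarray, points: np.ndarray,
                       r_c: float) -> bool:
    """Any point inside the finite cylinder of radius r_c on segment a-b?

    A point blocks when its axial projection falls strictly between the
    endpoints and its radial distance from the axis is <= r_c.
    """
    axis = b - a
    length2 = float(axis @ axis)
    if length2 == 0.0:
        raise ValueError("degenerate cylinder axis: coincident centres of mass")
    if points.size == 0:
        return False
    rel = points - a
    t = rel @ axis / length2
    radial2 = np.einsum("ij,ij->i", rel, rel) - t * t * length2
    inside = (t > 0.0) & (t < 1.0) & (radial2 <= r_c * r_c)
    return bool(np.any(inside))


def cylinder_blocked(mol_i: WaterMolecule, mol_j: WaterMolecule, frame: Frame,
                     r_c: float, ff: ForceFieldParameters = DEFAULT_FF,
                     include_ions: bool = True) -> bool:
    """True iff a third body interferes with the pair (i, j).

    The test region is the finite cylinder of radius ``r_c`` whose axis is
    the segment between the two centres of mass; third bodies are the COMs
    of all other molecules in the frame plus (by default) all ions.  A
    blocked pair is disregarded during network assembly so that only
    interference-free pairwise interactions remain.
    """
    a = mol_i.com(ff)
    b = mol_j.com(ff)
    pts = _third_body_points(frame, (mol_i.id, mol_j.id), ff, include_ions)
    return _cylinder_contains(a, b, pts, r_c)


def candidate_pairs(frame: Frame, nodes: set[int], pair_cutoff: float,
                    ff: ForceFieldParameters = DEFAULT_FF) -> list[tuple[int, int]]:
    """All unordered node pairs with COM distance <= pair_cutoff.

    Cell-tree pre-screen; a guaranteed superset of the criterion-passing
    pairs whenever the cutoff exceeds the interaction range.
    """
    if pair_cutoff <= 0:
        raise ValueError("pair_cutoff must be > 0")
    mols = [m for m in frame.molecules if m.id in nodes]
    if len(mols) < 2:
        return []
    coms = np.stack([m.com(ff) for m in mols])
    tree = cKDTree(coms)
    pairs = tree.query_pairs(pair_cutoff, output_type="ndarray")
    ids = np.array([m.id for m in mols])
    out = [(int(min(ids[a], ids[b])), int(max(ids[a], ids[b])))
           for a, b in pairs]
    return sorted(out)


def build_network(frame: Frame, params: CriterionParameters,
                  ff: ForceFieldParameters = DEFAULT_FF,
                  include_ions_as_blockers: bool = True) -> InteractionNetwork:
    """Assemble the interaction network of a frame.

    Nodes are the inner-cube molecules; edges are candidate pairs that are
    free of cylinder interference (third bodies taken from the *full*
    frame) and satisfy the energetic criterion.  Deterministic for a given
    frame and parameters.
    """
    table = geometric_pair_table(frame, params, ff, include_ions_as_blockers)
    nodes = table.nodes
    edges = []
    for (i, j), vc, vlj, ek in zip(table.pairs, table.V_coul, table.V_LJ,
                                   table.E_kin_pair):
        total = criterion_total(vc, vlj, ek, params)
        if total < 0.0:
            edges.append(PairEnergies(i=i, j=j, V_coul=vc, V_LJ=vlj,
                                      E_kin_pair=ek, criterion_total=total))
    return InteractionNetwork(nodes=nodes, edges=edges)


@dataclass
class GeometricPairTable:
    """Energy table of all geometry-surviving pairs, before thresholding.

    Caches the λ-independent work (inner cube, candidate pairs, cylinder
    filter, energy decomposition) so that λ scans re-use it.
    """

    nodes: set[int]
    pairs: list[tuple[int, int]]
    V_coul: np.ndarray
    V_LJ: np.ndarray
    E_kin_pair: np.ndarray

    def network_at(self, params: CriterionParameters) -> InteractionNetwork:
        """Threshold the cached table at the given criterion parameters."""
        edges = []
        for (i, j), vc, vlj, ek in zip(self.pairs, self.V_coul, self.V_LJ,
                                       self.E_kin_pair):
            total = criterion_total(vc, vlj, ek, params)
            if total < 0.0:
                edges.append(PairEnergies(i=i, j=j, V_coul=vc, V_LJ=vlj,
                                          E_kin_pair=ek,
                                          criterion_total=total))
        return InteractionNetwork(nodes=set(self.nodes), edges=edges)


def geometric_pair_table(frame: Frame, params: CriterionParameters,
                         ff: ForceFieldParameters = DEFAULT_FF,
                         include_ions_as_blockers: bool = True) -> GeometricPairTable:
    """Apply the geometric filters and decompose the surviving pair energies."""
    nodes = inner_cube_ids(frame, params.cube_fraction, ff)
    cands = candidate_pairs(frame, nodes, params.pair_cutoff, ff)
    by_id = {m.id: m for m in frame.molecules}
    # pre-stack all third-body test points once (molecule COMs, then ions)
    coms = frame.coms(ff)
    if include_ions_as_blockers and frame.ions:
        all_pts = np.concatenate(
            [coms, np.stack([ion.position for ion in frame.ions])])
    else:
        all_pts = coms
    row_of = {m.id: k for k, m in enumerate(frame.molecules)}
    pairs: list[tuple[int, int]] = []
    vcs: list[float] = []
    vljs: list[float] = []
    eks: list[float] = []
    for i, j in cands:
        mi, mj = by_id[i], by_id[j]
        ri, rj = row_of[i], row_of[j]
        mask = np.ones(len(all_pts), dtype=bool)
        mask[ri] = False
        mask[rj] = False
        if _cylinder_contains(coms[ri], coms[rj], all_pts[mask], params.r_c):
            continue
        pairs.append((i, j))
        vcs.append(coulomb_energy(mi, mj, ff))
        vljs.append(lennard_jones_energy(mi, mj, ff))
        eks.append(pair_kinetic_energy(mi, mj, ff))
    return GeometricPairTable(nodes=nodes, pairs=pairs,
                              V_coul=np.asarray(vcs), V_LJ=np.asarray(vljs),
                              E_kin_pair=np.asarray(eks))


def edge_table_tsv(net: InteractionNetwork) -> str:
    """Render the edge list as a TSV table (6-decimal energies)."""
    lines = ["i\tj\tV_coul\tV_LJ\tE_kin_pair\tcriterion_total"]
    for e in net.edges:
        lines.append(f"{e.i}\t{e.j}\t{e.V_coul:.6f}\t{e.V_LJ:.6f}"
                     f"\t{e.E_kin_pair:.6f}\t{e.criterion_total:.6f}")
    return "\n".join(lines) + "\n"
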