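"""Synthetic configurations with known structure.

Every pipeline stage is testable without running molecular dynamics or
downloading data: this module builds thermally agitated rigid four-site
water frames (Maxwell–Boltzmann centre-of-mass velocities, random rigid
orientations, minimum-separation packing), frames with planted linear
clusters of known sizes (ground truth for network recovery), and synthetic
bond-critical-point tables sampled strictly inside each interaction-class
region.

Velocities are sampled per molecule as rigid-body translations only; no
rotational motion is generated, which is sufficient because only COM
velocities enter the pair kinetic-energy term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .energetics import R_GAS
from .model_io import DEFAULT_FF, ForceFieldParameters, Frame, WaterMolecule
from .qtaim import (BCPRecord, COVALENT, NONCOVALENT, PARTIALLY_COVALENT,
                    make_record)


@dataclass
class ClusterSpec:
    """Planted-cluster layout: how many linear chains of each size.

    ``counts`` maps component size to the number of chains of that size
    (size 1 = monomers); ``spacing`` is the intra-chain O-O distance in nm.
    """

    counts: dict[int, int] = field(default_factory=dict)
    spacing: float = 0.28

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("cluster counts must be >= 0")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    @property
    def n_molecules(self) -> int:
        return sum(s * c for s, c in self.counts.items())


def _site_template(ff: ForceFieldParameters) -> np.ndarray:
    """(4, 3) site offsets from the oxygen: H_a, O, M, H_b.

    H_a lies along +x (the hydrogen-bond donor direction used for chains);
    H_b at the HOH angle from it in the xz-plane; M on the bisector.
    """
    theta = np.deg2rad(ff.theta_HOH)
    ha = ff.r_OH * np.array([1.0, 0.0, 0.0])
    hb = ff.r_OH * np.array([np.cos(theta), 0.0, np.sin(theta)])
    bis = ha / np.linalg.norm(ha) + hb / np.linalg.norm(hb)
    bis /= np.linalg.norm(bis)
    m = ff.d_OM * bis
    return np.stack([ha, np.zeros(3), m, hb])


def _molecule_at(mol_id: int, o_pos: np.ndarray, rot: np.ndarray,
                 vel: np.ndarray, ff: ForceFieldParameters) -> WaterMolecule:
    sites = o_pos + _site_template(ff) @ rot.T
    return WaterMolecule(id=mol_id,
                         pos_Ha=sites[0], pos_O=sites[1], pos_M=sites[2],
                         pos_Hb=sites[3],
                         vel_Ha=vel.copy(), vel_O=vel.copy(),
                         vel_M=vel.copy(), vel_Hb=vel.copy())


def _maxwell_boltzmann_velocities(n: int, T: float, mass: float,
                                  rng: np.random.Generator) -> np.ndarray:
    """(n, 3) COM velocities, nm/ps: each component ~ N(0, R·T/m)."""
    sigma = np.sqrt(R_GAS * T / mass)
    return sigma * rng.standard_normal((n, 3))


def generate_water_frame(n: int, box: float, T: float, seed: int,
                         min_sep: float = 0.25,
                         ff: ForceFieldParameters = DEFAULT_FF,
                         max_attempts_per_molecule: int = 1000) -> Frame:
    """A thermally agitated frame of n randomly placed, oriented molecules.

    Oxygen positions are rejection-sampled with pairwise O-O distance
    >= ``min_sep`` (skip the check with ``min_sep <= 0``); each molecule
    gets an independent uniform random rigid orientation and a
    Maxwell–Boltzmann COM velocity at temperature T.  A small wall padding
    keeps whole molecules inside the box.  Bit-reproducible for a fixed
    seed.

    Raises
    ------
    RuntimeError
        If packing fails (box too dense for min_sep).
    """
    rng = np.random.default_rng(seed)
    box_vec = np.full(3, float(box))
    pad = 0.12  # nm, keeps H/M sites in the box for any orientation
    if box <= 2 * pad:
        raise ValueError("box too small")
    positions = np.empty((n, 3))
    accepted = 0
    attempts = 0
    while accepted < n:
        cand = rng.uniform(pad, box - pad, size=3)
        if min_sep > 0 and accepted:
            d2 = np.sum((positions[:accepted] - cand) ** 2, axis=1)
            if np.min(d2) < min_sep * min_sep:
                attempts += 1
                if attempts > max_attempts_per_molecule * n:
                    raise RuntimeError(
                        f"packing failed: placed {accepted}/{n} molecules "
                        f"at min_sep={min_sep} in box={box}")
                continue
        positions[accepted] = cand
        accepted += 1
    quats = rng.standard_normal((n, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    rots = Rotation.from_quat(quats).as_matrix() if n else np.zeros((0, 3, 3))
    vels = _maxwell_boltzmann_velocities(n, T, ff.molecular_mass, rng)
    molecules = [_molecule_at(k + 1, positions[k], rots[k], vels[k], ff)
                 for k in range(n)]
    return Frame(box=box_vec, molecules=molecules, temperature=T)


def planted_cluster_frame(spec: ClusterSpec, T_cold: float = 10.0,
                          box: float | None = None, seed: int = 0,
                          cube_fraction: float = 0.85,
                          inter_cluster_gap: float = 1.0,
                          ff: ForceFieldParameters = DEFAULT_FF
                          ) -> tuple[Frame, list[set[int]]]:
    """A frame of isolated linear chains plus the true component labels.

    Chains are laid out on a 3D grid: each chain runs along x at the spec's
    O-O spacing, every molecule oriented with its donor hydrogen pointing
    at the next oxygen (a near-linear O-H···O motif).  Grid cells are sized
    so that molecules of different chains stay farther apart than the
    candidate-pair cutoff plus ``inter_cluster_gap``-controlled margin, and
    the whole grid sits inside the concentric ``cube_fraction`` cube so no
    planted molecule is dropped by the boundary filter.  Per-molecule COM
    velocities are Maxwell–Boltzmann at ``T_cold`` (low by default, so
    intra-chain relative kinetic energies are small); the underlying
    normal draws are seed-stable, so raising T_cold only scales them.

    Returns the frame and the list of true component member-id sets.

    Raises
    ------
    ValueError
        If a caller-supplied box cannot hold the grid inside its inner cube.
    """
    rng = np.random.default_rng(seed)
    chains: list[int] = []
    for size in sorted(spec.counts):
        chains.extend([size] * spec.counts[size])
    n_chains = len(chains)
    if n_chains == 0:
        return Frame(box=np.full(3, box or 3.0), molecules=[],
                     temperature=T_cold), []

    max_size = max(chains)
    cell_x = (max_size - 1) * spec.spacing + inter_cluster_gap
    cell_yz = inter_cluster_gap
    n_side = int(np.ceil(n_chains ** (1.0 / 3.0)))
    extent = np.array([n_side * cell_x, n_side * cell_yz, n_side * cell_yz])
    needed = float(np.max(extent))
    if box is None:
        box_edge = (needed + 1.0) / cube_fraction
    else:
        box_edge = float(box)
        if cube_fraction * box_edge < needed:
            raise ValueError(
                f"box {box_edge} nm cannot hold the planted grid "
                f"({needed:.2f} nm) inside its inner cube")
    box_vec = np.full(3, box_edge)
    origin = (box_vec - extent) / 2.0 + np.array([cell_x, cell_yz, cell_yz]) / 2.0

    # seed-stable standard-normal draws; velocity = sqrt(R*T/m) * z
    z = rng.standard_normal((spec.n_molecules, 3))
    sigma = np.sqrt(R_GAS * T_cold / ff.molecular_mass)

    molecules: list[WaterMolecule] = []
    labels: list[set[int]] = []
    # neighbours alternate by a half-turn about the chain axis: the donor
    # O-H stays on the axis (linear O-H···O) while the acceptor side turns
    # its charge distribution into the strongly bound arrangement
    flip = np.diag([1.0, -1.0, -1.0])
    mol_id = 0
    for c, size in enumerate(chains):
        ix, iy, iz = np.unravel_index(c, (n_side, n_side, n_side))
        anchor = origin + np.array([ix * cell_x, iy * cell_yz, iz * cell_yz])
        members: set[int] = set()
        for k in range(size):
            mol_id += 1
            o_pos = anchor + np.array([k * spec.spacing, 0.0, 0.0])
            vel = sigma * z[mol_id - 1]
            rot = np.eye(3) if k % 2 == 0 else flip
            molecules.append(_molecule_at(mol_id, o_pos, rot, vel, ff))
            members.add(mol_id)
        labels.append(members)
    return Frame(box=box_vec, molecules=molecules,
                 temperature=T_cold), labels


_BCP_CLASS_SAMPLERS = {
    # (rho range, laplacian range, G range, -G/V ratio range); each region
    # lies strictly inside one class of the sign/ratio rules
    NONCOVALENT: ((0.002, 0.02), (0.02, 0.15), (0.005, 0.03), (1.1, 2.0)),
    PARTIALLY_COVALENT: ((0.02, 0.06), (0.02, 0.15), (0.02, 0.08), (0.55, 0.95)),
    COVALENT: ((0.2, 0.4), (-0.8, -0.1), (0.05, 0.3), (0.15, 0.45)),
}


def synthetic_bcp_table(n: int, mix: tuple[float, float, float],
                        seed: int = 0) -> tuple[list[BCPRecord], list[str]]:
    """n synthetic BCP records with ground-truth class labels.

    ``mix`` gives the (noncovalent, partially covalent, covalent) fractions
    and must sum to 1.  Records are sampled strictly inside the defining
    region of their class (G >= 0, V < 0, V = −G − K by construction), so a
    correct classifier recovers the truth exactly.

    Returns (records, true_labels).
    """
    if abs(sum(mix) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = [int(round(f * n)) for f in mix]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n:
        counts[int(np.argmax(mix))] += 1
    records: list[BCPRecord] = []
    truth: list[str] = []
    for label, count in zip((NONCOVALENT, PARTIALLY_COVALENT, COVALENT),
                            counts):
        rho_r, lap_r, g_r, ratio_r = _BCP_CLASS_SAMPLERS[label]
        for _ in range(count):
            g = rng.uniform(*g_r)
            ratio = rng.uniform(*ratio_r)
            v = -g / ratio
            records.append(make_record(rho=rng.uniform(*rho_r),
                                       laplacian=rng.uniform(*lap_r),
                                       G=g, V=v))
            truth.append(label)
    return records, truth
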