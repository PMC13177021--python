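"""Pairwise energy decomposition and the energetic interaction criterion.

A pair of water molecules (i, j) is considered energetically connected when

    V_Coulomb(i,j) + V_LJ(i,j) + E_kin(i,j) + λ·4·E_kin_H  <  0

i.e. when the attractive interaction outweighs the kinetic energy of the
pair's relative motion plus a λ-weighted thermal reference for the four
hydrogen atoms involved.  E_kin_H is the kinetic energy of a hydrogen-mass
particle travelling at the Maxwell–Boltzmann most probable speed at the
system temperature (which equals R·T per mole, independent of the mass).

All energies are in kJ/mol; distances in nm; velocities in nm/ps.  With
masses in g/mol these units need no conversion factor:
(g/mol)·(nm/ps)² = kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model_io import DEFAULT_FF, ForceFieldParameters, WaterMolecule

#: Molar gas constant, kJ·mol⁻¹·K⁻¹.
R_GAS = 8.314462618e-3


@dataclass(frozen=True)
class CriterionParameters:
    """Parameters of the pair-interaction criterion and its geometric filters.

    Attributes
    ----------
    lambda_ : float
        Dimensionless weight of the hydrogen thermal-energy term (calibrated
        against a reference cluster-size distribution; 0.655 by default).
    E_kin_H : float
        Hydrogen thermal reference energy, kJ/mol (R·T at the frame
        temperature; see :func:`hydrogen_reference_kinetic_energy`).
    r_c : float
        Interference-cylinder radius, nm (the oxygen diameter by default).
    cube_fraction : float
        Edge fraction of the concentric cube retained by the boundary
        filter.
    pair_cutoff : float
        COM-COM pre-screen distance, nm.  Conservative: beyond ~0.6 nm the
        pair potential cannot reach the thermal penalty, so 0.8 nm leaves a
        safety margin (an invariance test guards this).
    """

    lambda_: float = 0.655
    E_kin_H: float = 5.5955
    r_c: float = 0.3159
    cube_fraction: float = 0.85
    pair_cutoff: float = 0.8

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if not (0 < self.cube_fraction <= 1):
            raise ValueError("cube_fraction must be in (0, 1]")
        if self.r_c < 0:
            raise ValueError("r_c must be >= 0")
        if self.pair_cutoff <= 0:
            raise ValueError("pair_cutoff must be > 0")

    @classmethod
    def at_temperature(cls, T: float, ff: ForceFieldParameters = DEFAULT_FF,
                       **kwargs) -> "CriterionParameters":
        """Build parameters with E_kin_H evaluated at temperature T (K)."""
        return cls(E_kin_H=hydrogen_reference_kinetic_energy(T, ff), **kwargs)

    def with_lambda(self, lambda_: float) -> "CriterionParameters":
        return replace(self, lambda_=lambda_)


@dataclass
class PairEnergies:
    """Energy decomposition of one molecular pair under the criterion.

    ``criterion_total`` is V_coul + V_LJ + E_kin_pair + λ·4·E_kin_H for the
    λ and E_kin_H in force when the pair was evaluated.
    """

    i: int
    j: int
    V_coul: float
    V_LJ: float
    E_kin_pair: float
    criterion_total: float

    @property
    def potential(self) -> float:
        """Pair potential sum V_coul + V_LJ, kJ/mol (kinetic terms excluded)."""
        return self.V_coul + self.V_LJ


def _charged_site_positions(mol: WaterMolecule) -> np.ndarray:
    """(3, 3) positions of the charged sites H_a, H_b, M."""
    return np.stack([mol.pos_Ha, mol.pos_Hb, mol.pos_M])


def coulomb_energy(mol_i: WaterMolecule, mol_j: WaterMolecule,
                   ff: ForceFieldParameters = DEFAULT_FF) -> float:
    """Coulomb energy between the charged sites of two molecules, kJ/mol.

    Sums f·q_a·q_b/r over the 3×3 charged-site pairs (H_a, H_b, M on each
    molecule) using plain Euclidean distances.

    Raises
    ------
    ZeroDivisionError
        If any two charged sites coincide.
    """
    q = np.array([ff.q_H, ff.q_H, ff.q_M])
    ri = _charged_site_positions(mol_i)
    rj = _charged_site_positions(mol_j)
    d = np.linalg.norm(ri[:, None, :] - rj[None, :, :], axis=-1)
    if np.any(d == 0):
        raise ZeroDivisionError("coincident charged sites in Coulomb sum")
    return float(ff.f_coulomb * np.sum(np.outer(q, q) / d))


def lennard_jones_energy(mol_i: WaterMolecule, mol_j: WaterMolecule,
                         ff: ForceFieldParameters = DEFAULT_FF) -> float:
    """Oxygen-oxygen Lennard-Jones energy, kJ/mol.

    Only the O-O interaction carries a Lennard-Jones term in the four-site
    model: 4ε[(σ/r)¹² − (σ/r)⁶].

    Raises
    ------
    ZeroDivisionError
        If the oxygens coincide.
    """
    r = float(np.linalg.norm(mol_i.pos_O - mol_j.pos_O))
    if r == 0:
        raise ZeroDivisionError("coincident oxygen sites in LJ term")
    sr6 = (ff.sigma_OO / r) ** 6
    return float(4.0 * ff.epsilon_OO * (sr6 * sr6 - sr6))


def pair_kinetic_energy(mol_i: WaterMolecule, mol_j: WaterMolecule,
                        ff: ForceFieldParameters = DEFAULT_FF) -> float:
    """Kinetic energy of the pair's relative motion, kJ/mol.

    ½·μ·|Δv_com|² with μ = m_w/2, the reduced mass of two equal water
    molecules (m_w = 2 m_H + m_O).  Zero velocities are allowed.
    """
    mu = ff.molecular_mass / 2.0
    dv = mol_i.com_vel(ff) - mol_j.com_vel(ff)
    return float(0.5 * mu * dv @ dv)


def hydrogen_reference_kinetic_energy(T: float,
                                      ff: ForceFieldParameters = DEFAULT_FF) -> float:
    """Thermal reference energy of a hydrogen atom, kJ/mol.

    Kinetic energy ½·m_H·v_p² of a hydrogen-mass particle at the
    Maxwell–Boltzmann most probable speed v_p = sqrt(2·R·T/m_H).  The mass
    cancels algebraically (the result equals R·T), but the velocity route is
    kept so that the definition mirrors the speed-distribution picture; a
    test asserts the identity.

    Raises
    ------
    ValueError
        If T is not strictly positive.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    v_p = np.sqrt(2.0 * R_GAS * T / ff.m_H)
    return float(0.5 * ff.m_H * v_p ** 2)


def criterion_total(V_coul: float, V_LJ: float, E_kin_pair: float,
                    params: CriterionParameters) -> float:
    """Left-hand side of the interaction criterion, kJ/mol.

    V_coul + V_LJ + E_kin_pair + λ·4·E_kin_H.  The factor 4 is the number
    of hydrogen atoms in a molecular pair and is fixed.
    """
    return V_coul + V_LJ + E_kin_pair + params.lambda_ * 4.0 * params.E_kin_H


def passes_criterion(V_coul: float, V_LJ: float, E_kin_pair: float,
                     params: CriterionParameters) -> bool:
    """True iff the criterion total is strictly negative (ties excluded)."""
    return criterion_total(V_coul, V_LJ, E_kin_pair, params) < 0.0


def pair_energies(mol_i: WaterMolecule, mol_j: WaterMolecule,
                  params: CriterionParameters,
                  ff: ForceFieldParameters = DEFAULT_FF) -> PairEnergies:
    """Full energy decomposition of a molecular pair under the criterion."""
    vc = coulomb_energy(mol_i, mol_j, ff)
    vlj = lennard_jones_energy(mol_i, mol_j, ff)
    ek = pair_kinetic_energy(mol_i, mol_j, ff)
    return PairEnergies(i=mol_i.id, j=mol_j.id, V_coul=vc, V_LJ=vlj,
                        E_kin_pair=ek,
                        criterion_total=criterion_total(vc, vlj, ek, params))
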