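"""Domain types, frame-file I/O and thermodynamic bookkeeping.

The package works on snapshots of rigid four-site water (two hydrogens, an
oxygen carrying the Lennard-Jones centre, and a massless charged M site on
the HOH bisector, i.e. the TIP4P/2005 family).  Frames are exchanged in the
fixed-width GRO dialect (positions in nm, velocities in nm/ps); parsing and
formatting are delegated to MDAnalysis, with molecule assembly layered on
top.

Units are fixed project-wide: nm, nm/ps, kJ/mol, K, bar, e, u (g/mol).
With this choice (g/mol)·(nm/ps)² = kJ/mol, so kinetic energies need no
conversion factor.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Critical temperature of water, K.
T_CRITICAL = 647.096
#: Critical pressure of water, bar.
P_CRITICAL = 220.64

#: Formal charges assigned to monatomic ion records on read, by residue name.
ION_CHARGES = {
    "CL": -1.0,
    "NA": 1.0,
    "K": 1.0,
    "LI": 1.0,
    "F": -1.0,
    "BR": -1.0,
    "I": -1.0,
}


class FrameFormatError(ValueError):
    """Raised when a frame file violates the fixed-width dialect."""


@dataclass(frozen=True)
class ForceFieldParameters:
    """Rigid four-site water parameters.

    Charges sit on the hydrogens and the M site, the Lennard-Jones centre on
    the oxygen, and the M site is massless.  Defaults are the standard
    TIP4P/2005 values.

    Attributes
    ----------
    q_H, q_M : float
        Site charges in e; ``2*q_H + q_M == 0`` (neutral molecule).
    sigma_OO, epsilon_OO : float
        Oxygen-oxygen Lennard-Jones parameters (nm, kJ/mol).
    m_H, m_O : float
        Site masses in u (g/mol); M carries no mass.
    r_OH : float
        O-H bond length, nm.
    theta_HOH : float
        H-O-H angle, degrees.
    d_OM : float
        O-M distance along the HOH bisector, nm.
    f_coulomb : float
        Coulomb prefactor, kJ·mol⁻¹·nm·e⁻².
    """

    q_H: float = 0.5564
    q_M: float = -1.1128
    sigma_OO: float = 0.3159
    epsilon_OO: float = 0.7749
    m_H: float = 1.00794
    m_O: float = 15.9994
    r_OH: float = 0.09572
    theta_HOH: float = 104.52
    d_OM: float = 0.01546
    f_coulomb: float = 138.935458

    def __post_init__(self) -> None:
        if abs(2.0 * self.q_H + self.q_M) > 1e-9:
            raise ValueError("molecule is not neutral: 2*q_H + q_M != 0")
        for name in ("sigma_OO", "epsilon_OO", "m_H", "m_O", "r_OH", "d_OM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def molecular_mass(self) -> float:
        """Mass of one water molecule, u (the M site is massless)."""
        return 2.0 * self.m_H + self.m_O


DEFAULT_FF = ForceFieldParameters()

_SITE_NAMES = ("Ha", "O", "M", "Hb")


@dataclass
class WaterMolecule:
    """One rigid four-site water molecule: per-site positions and velocities.

    Sites are ordered H_a, O, M, H_b.  Centre-of-mass quantities are
    mass-weighted over the massive sites (H_a, O, H_b); the M site carries
    charge but no mass.
    """

    id: int
    pos_Ha: np.ndarray
    pos_O: np.ndarray
    pos_M: np.ndarray
    pos_Hb: np.ndarray
    vel_Ha: np.ndarray = field(default_factory=lambda: np.zeros(3))
    vel_O: np.ndarray = field(default_factory=lambda: np.zeros(3))
    vel_M: np.ndarray = field(default_factory=lambda: np.zeros(3))
    vel_Hb: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("pos_Ha", "pos_O", "pos_M", "pos_Hb",
                     "vel_Ha", "vel_O", "vel_M", "vel_Hb"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def positions(self) -> np.ndarray:
        """(4, 3) array of site positions in H_a, O, M, H_b order."""
        return np.stack([self.pos_Ha, self.pos_O, self.pos_M, self.pos_Hb])

    def velocities(self) -> np.ndarray:
        """(4, 3) array of site velocities in H_a, O, M, H_b order."""
        return np.stack([self.vel_Ha, self.vel_O, self.vel_M, self.vel_Hb])

    def com(self, ff: ForceFieldParameters = DEFAULT_FF) -> np.ndarray:
        """Mass-weighted centre of mass over H_a, O, H_b, nm."""
        m = np.array([ff.m_H, ff.m_O, ff.m_H])
        r = np.stack([self.pos_Ha, self.pos_O, self.pos_Hb])
        return m @ r / m.sum()

    def com_vel(self, ff: ForceFieldParameters = DEFAULT_FF) -> np.ndarray:
        """Mass-weighted centre-of-mass velocity over H_a, O, H_b, nm/ps."""
        m = np.array([ff.m_H, ff.m_O, ff.m_H])
        v = np.stack([self.vel_Ha, self.vel_O, self.vel_Hb])
        return m @ v / m.sum()


@dataclass
class Ion:
    """A monatomic ion record: label, position (nm), velocity (nm/ps), charge (e)."""

    label: str
    position: np.ndarray
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    charge: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)


@dataclass
class Frame:
    """A snapshot: orthorhombic box, water molecules and optional ions.

    Attributes
    ----------
    box : np.ndarray
        Edge lengths (Lx, Ly, Lz) in nm.
    molecules : list[WaterMolecule]
    ions : list[Ion]
    temperature : float | None
        K, when known (used to evaluate the thermal reference energy).
    pressure : float | None
        bar, when known.
    """

    box: np.ndarray
    molecules: list[WaterMolecule] = field(default_factory=list)
    ions: list[Ion] = field(default_factory=list)
    temperature: float | None = None
    pressure: float | None = None

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        ids = [m.id for m in self.molecules]
        if len(ids) != len(set(ids)):
            raise ValueError("molecule ids must be unique")

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def coms(self, ff: ForceFieldParameters = DEFAULT_FF) -> np.ndarray:
        """(N, 3) array of molecular centres of mass, in molecule list order."""
        if not self.molecules:
            return np.zeros((0, 3))
        return np.stack([m.com(ff) for m in self.molecules])

    def molecule_by_id(self, mol_id: int) -> WaterMolecule:
        for m in self.molecules:
            if m.id == mol_id:
                return m
        raise KeyError(f"no molecule with id {mol_id}")


@dataclass(frozen=True)
class ThermodynamicState:
    """A simulated state point with its reduced coordinates and density error.

    Tr = T / 647.096 K and Pr = P / 220.64 bar are the reduced temperature
    and pressure; ``error_pct`` is the percent deviation of the simulated
    density from the experimental one.
    """

    T: float
    P: float
    Tr: float
    Pr: float
    density_sim: float | None = None
    density_exp: float | None = None
    error_pct: float | None = None

    @classmethod
    def from_conditions(cls, T: float, P: float,
                        density_sim: float | None = None,
                        density_exp: float | None = None) -> "ThermodynamicState":
        Tr, Pr = reduced_state(T, P)
        err = None
        if density_sim is not None and density_exp is not None:
            err = density_percent_error(density_sim, density_exp)
        return cls(T=T, P=P, Tr=Tr, Pr=Pr, density_sim=density_sim,
                   density_exp=density_exp, error_pct=err)


#: Validation grid of supercritical state points: average temperature and
#: pressure of each production run, simulated density, and the experimental
#: (NIST) density at the same conditions.  Used to screen conditions by
#: percent density error.
SIMULATION_CONDITIONS = pd.DataFrame(
    [
        (1, 679.451, 551.780, 584.852, 581.043),
        (2, 679.441, 606.894, 601.227, 599.995),
        (3, 679.448, 662.010, 615.569, 616.043),
        (4, 679.454, 717.096, 628.451, 630.040),
        (5, 679.449, 772.485, 640.036, 642.582),
        (6, 711.805, 551.690, 505.245, 485.125),
        (7, 711.814, 606.844, 529.353, 516.209),
        (8, 711.815, 661.918, 549.482, 540.903),
        (9, 711.809, 716.868, 566.706, 561.344),
        (10, 711.809, 772.345, 581.943, 578.963),
        (11, 744.167, 551.574, 419.497, 377.487),
        (12, 744.171, 606.735, 450.922, 421.276),
        (13, 744.159, 661.966, 478.421, 456.273),
        (14, 744.162, 717.228, 501.073, 484.784),
        (15, 744.152, 772.460, 520.543, 508.587),
    ],
    columns=["condition", "temperature_K", "pressure_bar",
             "density_sim_kg_m3", "density_exp_kg_m3"],
)


def reduced_state(T: float, P: float) -> tuple[float, float]:
    """Map (T in K, P in bar) to reduced coordinates (Tr, Pr).

    Tr = T / 647.096, Pr = P / 220.64, returned at full precision; callers
    round for display.

    Raises
    ------
    ValueError
        If T or P is not strictly positive.
    """
    if T <= 0 or P <= 0:
        raise ValueError("temperature and pressure must be positive")
    return T / T_CRITICAL, P / P_CRITICAL


def density_percent_error(density_sim: float, density_exp: float) -> float:
    """Percent deviation 100·|ρ_sim − ρ_exp| / ρ_exp.

    Raises
    ------
    ValueError
        If the experimental density is not strictly positive.
    """
    if density_exp <= 0:
        raise ValueError("experimental density must be positive")
    return 100.0 * abs(density_sim - density_exp) / density_exp


# ---------------------------------------------------------------------------
# Frame file I/O (fixed-width GRO dialect, via MDAnalysis)
# ---------------------------------------------------------------------------

def _classify_sites(names: list[str]) -> list[str] | None:
    """Map the four atom names of a water residue to site roles.

    Returns a list drawn from {"Ha", "O", "M", "Hb"} in file order, or None
    if the names are not informative enough (caller falls back to positional
    order).
    """
    roles: list[str | None] = [None] * 4
    n_h = 0
    for k, raw in enumerate(names):
        u = raw.strip().upper()
        if u.startswith("O"):
            roles[k] = "O"
        elif u.startswith("M"):
            roles[k] = "M"
        elif u.startswith("H"):
            roles[k] = "Ha" if n_h == 0 else "Hb"
            n_h += 1
    if sorted(r for r in roles if r is not None) != ["Ha", "Hb", "M", "O"]:
        return None
    return roles  # type: ignore[return-value]


def read_frame(path, site_order: tuple[str, str, str, str] | None = None,
               ion_charges: dict[str, float] | None = None) -> Frame:
    """Read a fixed-width frame file into a :class:`Frame`.

    Four-atom residues become water molecules, single-atom residues become
    ions.  The site order within a water residue is auto-detected from atom
    names (O*/H*/M* prefixes); pass ``site_order`` (e.g. ``("O", "Ha", "Hb",
    "M")``) to override.  Positions are wrapped to [0, L) per axis.  Missing
    velocities are set to zero with a logged warning.

    Raises
    ------
    FrameFormatError
        On atom-count mismatch or residues with a site count not in {1, 4}.
    """
    import MDAnalysis as mda

    if ion_charges is None:
        ion_charges = ION_CHARGES

    with open(path) as fh:
        header_lines = [fh.readline(), fh.readline()]
        try:
            declared = int(header_lines[1].strip())
        except ValueError as exc:
            raise FrameFormatError("second line must be the atom count") from exc
        if declared == 0:
            box_fields = fh.readline().split()
            box = np.array([float(x) for x in box_fields[:3]])
            return Frame(box=box, molecules=[], ions=[])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format="GRO")
    except (ValueError, EOFError, IndexError, OSError) as exc:
        raise FrameFormatError(f"cannot parse frame file: {exc}") from exc
    if len(u.atoms) != declared:
        raise FrameFormatError(
            f"atom count mismatch: header says {declared}, found {len(u.atoms)}")

    dims = u.dimensions
    if dims is None or not np.allclose(dims[3:], 90.0):
        raise FrameFormatError("only orthorhombic boxes are supported")
    box = np.asarray(dims[:3], dtype=float) / 10.0  # Å -> nm

    positions = np.asarray(u.atoms.positions, dtype=float) / 10.0
    if u.trajectory.ts.has_velocities:
        velocities = np.asarray(u.atoms.velocities, dtype=float) / 10.0
    else:
        logger.warning("frame file has no velocities; using zero vectors")
        velocities = np.zeros_like(positions)

    # wrap to [0, L) per axis (orthorhombic)
    positions = np.mod(positions, box)

    molecules: list[WaterMolecule] = []
    ions: list[Ion] = []
    for res in u.residues:
        idx = res.atoms.ix
        n = len(idx)
        if n == 4:
            names = list(res.atoms.names)
            if site_order is not None:
                roles = list(site_order)
            else:
                roles = _classify_sites(names) or list(_SITE_NAMES)
            by_role = {role: k for k, role in enumerate(roles)}
            pos = {r: positions[idx[by_role[r]]] for r in _SITE_NAMES}
            vel = {r: velocities[idx[by_role[r]]] for r in _SITE_NAMES}
            molecules.append(WaterMolecule(
                id=int(res.resid),
                pos_Ha=pos["Ha"], pos_O=pos["O"], pos_M=pos["M"], pos_Hb=pos["Hb"],
                vel_Ha=vel["Ha"], vel_O=vel["O"], vel_M=vel["M"], vel_Hb=vel["Hb"],
            ))
        elif n == 1:
            label = str(res.resname).strip()
            charge = ion_charges.get(label.upper(), 0.0)
            if label.upper() not in ion_charges:
                logger.warning("unknown ion %r; assigning charge 0", label)
            ions.append(Ion(label=label, position=positions[idx[0]],
                            velocity=velocities[idx[0]], charge=charge))
        else:
            raise FrameFormatError(
                f"residue {res.resid} has {n} atoms; expected 1 (ion) or 4 (water)")
    return Frame(box=box, molecules=molecules, ions=ions)


def write_frame(frame: Frame, path, title: str = "four-site water frame") -> None:
    """Write a :class:`Frame` in the fixed-width dialect ``read_frame`` consumes.

    Water sites are emitted in H_a, O, M, H_b order with names HW1/OW/MW/HW2;
    positions are formatted at %8.3f nm and velocities at %8.4f nm/ps.

    Raises
    ------
    FrameFormatError
        If the frame's box is not a 3-vector of edge lengths.
    """
    import MDAnalysis as mda

    if np.shape(frame.box) != (3,):
        raise FrameFormatError("only orthorhombic boxes (3 edge lengths) supported")

    if not frame.molecules and not frame.ions:
        box_line = "".join(f"{edge:10.5f}" for edge in frame.box)
        with open(path, "w") as fh:
            fh.write(f"{title}\n    0\n{box_line}\n")
        return

    n_mol = len(frame.molecules)
    n_ion = len(frame.ions)
    n_atoms = 4 * n_mol + n_ion
    n_res = n_mol + n_ion

    resindex = np.repeat(np.arange(n_mol), 4)
    resindex = np.concatenate([resindex, np.arange(n_mol, n_res)]).astype(int)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=n_atoms, n_residues=max(n_res, 1), n_segments=1,
            atom_resindex=resindex if n_atoms else None,
            trajectory=True, velocities=True,
        )
        names = []
        resnames = []
        resids = []
        pos = np.zeros((n_atoms, 3))
        vel = np.zeros((n_atoms, 3))
        for k, m in enumerate(frame.molecules):
            names.extend(["HW1", "OW", "MW", "HW2"])
            resnames.append("SOL")
            resids.append(m.id)
            pos[4 * k:4 * k + 4] = m.positions()
            vel[4 * k:4 * k + 4] = m.velocities()
        for k, ion in enumerate(frame.ions):
            names.append(ion.label)
            resnames.append(ion.label)
            resids.append(n_mol + k + 1 if not frame.molecules
                          else max(mm.id for mm in frame.molecules) + k + 1)
            pos[4 * n_mol + k] = ion.position
            vel[4 * n_mol + k] = ion.velocity
        if n_atoms:
            u.add_TopologyAttr("names", names)
            u.add_TopologyAttr("resnames", resnames)
            u.add_TopologyAttr("resids", resids)
            u.atoms.positions = pos * 10.0  # nm -> Å
            u.atoms.velocities = vel * 10.0
        u.dimensions = [frame.box[0] * 10, frame.box[1] * 10, frame.box[2] * 10,
                        90.0, 90.0, 90.0]
        with mda.coordinates.GRO.GROWriter(str(path), n_atoms=n_atoms) as w:
            u.trajectory.ts.data["time"] = 0.0
            w.write(u.atoms)

    # MDAnalysis writes its own title; normalise the header line for stable
    # round-trips while keeping every coordinate byte untouched.
    with open(path) as fh:
        lines = fh.readlines()
    lines[0] = title.rstrip("\n") + "\n"
    with open(path, "w") as fh:
        fh.writelines(lines)


def frame_to_text(frame: Frame, title: str = "four-site water frame") -> str:
    """Render a frame to the fixed-width dialect as a string."""
    import tempfile
    import os

    fd, tmp = tempfile.mkstemp(suffix=".gro")
    os.close(fd)
    try:
        write_frame(frame, tmp, title=title)
        with open(tmp) as fh:
            return fh.read()
    finally:
        os.unlink(tmp)


def frame_from_text(text: str, **kwargs) -> Frame:
    """Parse a frame from a string in the fixed-width dialect."""
    import tempfile
    import os

    fd, tmp = tempfile.mkstemp(suffix=".gro")
    os.close(fd)
    try:
        with open(tmp, "w") as fh:
            fh.write(text)
        return read_frame(tmp, **kwargs)
    finally:
        os.unlink(tmp)
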