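import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from scwnet import (CriterionParameters, DEFAULT_FF, Frame, WaterMolecule)

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ff():
    return DEFAULT_FF


@pytest.fixture(scope="session")
def params673():
    """Criterion parameters with the thermal reference evaluated at 673 K."""
    return CriterionParameters.at_temperature(673.0)


def make_molecule(mol_id, o_pos, flip=False, velocity=(0.0, 0.0, 0.0),
                  ff=DEFAULT_FF):
    """A water molecule with its donor O-H along +x.

    The geometry is derived from the rigid-model parameters: H_a on the
    +x axis, H_b at the HOH angle in the xz-plane, M on the bisector.
    ``flip`` applies a half-turn about x (the bound-dimer acceptor
    orientation).
    """
    theta = np.deg2rad(ff.theta_HOH)
    ha = ff.r_OH * np.array([1.0, 0.0, 0.0])
    hb = ff.r_OH * np.array([np.cos(theta), 0.0, np.sin(theta)])
    bis = ha / np.linalg.norm(ha) + hb / np.linalg.norm(hb)
    m = ff.d_OM * bis / np.linalg.norm(bis)
    sign = -1.0 if flip else 1.0
    s = np.diag([1.0, sign, sign])
    o = np.asarray(o_pos, dtype=float)
    v = np.asarray(velocity, dtype=float)
    return WaterMolecule(id=mol_id, pos_Ha=o + s @ ha, pos_O=o.copy(),
                         pos_M=o + s @ m, pos_Hb=o + s @ hb,
                         vel_Ha=v, vel_O=v.copy(), vel_M=v.copy(),
                         vel_Hb=v.copy())


@pytest.fixture
def bound_dimer_frame():
    """A strongly bound dimer: O-O = 0.28 nm, linear O-H···O, equal
    velocities, centred in a 3 nm box."""
    c = np.array([1.5, 1.5, 1.5])
    m1 = make_molecule(1, c)
    m2 = make_molecule(2, c + [0.28, 0.0, 0.0], flip=True)
    return Frame(box=[3.0, 3.0, 3.0], molecules=[m1, m2], temperature=673.0)


def random_dimer(rng, spread=0.5):
    """Two molecules with random (unphysical) site positions and velocities;
    sites are guaranteed distinct."""
    def mol(k):
        base = rng.uniform(0, spread, 3) + (0.0 if k == 1 else 1.0)
        sites = base + 0.1 * rng.standard_normal((4, 3))
        vels = 0.5 * rng.standard_normal((4, 3))
        return WaterMolecule(id=k, pos_Ha=sites[0], pos_O=sites[1],
                             pos_M=sites[2], pos_Hb=sites[3],
                             vel_Ha=vels[0], vel_O=vels[1], vel_M=vels[2],
                             vel_Hb=vels[3])
    return mol(1), mol(2)
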