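"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from hampkin.bundle_synth import BundleParams, build_dimer_model


@pytest.fixture(scope="session")
def default_params() -> BundleParams:
    return BundleParams()


@pytest.fixture(scope="session")
def dimer_model(default_params):
    """The default CpxA-like synthetic dimer (built once per session)."""
    return build_dimer_model(default_params)


def nerf_place(a, b, c, bond, angle_deg, dihedral_deg):
    """Independent internal-coordinate atom placement (test oracle)."""
    angle = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(angle),
                   bond * np.sin(angle) * np.cos(dih),
                   bond * np.sin(angle) * np.sin(dih)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_chain_from_dihedrals(n_res: int, phi: float, psi: float,
                               chain: str = "A", start_resid: int = 1):
    """Backbone chain with prescribed phi/psi (independent of the package
    helix builder; used as the oracle for secondary-structure assignment)."""
    from hampkin.structure_io import Structure

    bNCA, bCAC, bCN = 1.458, 1.525, 1.329
    aNCAC, aCACN, aCNCA = 111.2, 116.2, 121.7
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([bNCA, 0.0, 0.0])]
    ang = np.radians(aNCAC)
    C = [CA[0] + bCAC * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_res):
        N.append(nerf_place(N[i - 1], CA[i - 1], C[i - 1], bCN, aCACN, psi))
        CA.append(nerf_place(CA[i - 1], C[i - 1], N[i], bNCA, aCNCA, 180.0))
        C.append(nerf_place(C[i - 1], N[i], CA[i], bCAC, aNCAC, phi))
    chains, resids, names, coords = [], [], [], []
    for i in range(n_res):
        for name, pos in (("N", N[i]), ("CA", CA[i]), ("C", C[i])):
            chains.append(chain)
            resids.append(start_resid + i)
            names.append(name)
            coords.append(pos)
    n = len(chains)
    return Structure(
        chain=np.array(chains), resid=np.array(resids),
        resname=np.full(n, "ALA"), atom_name=np.array(names),
        element=np.array([s[0] for s in names]), coord=np.array(coords),
    )


def kabsch_oracle(mobile: np.ndarray, reference: np.ndarray):
    """Brute-force least-squares rigid fit (independent of the package)."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = rc - rot @ mc
    return rot, t
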