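"""Synthetic CpxA-like dimer models and trajectories with known motions.

Builds a two-chain scaffold in 4BIV residue numbering — four HAMP helices in
a parallel square bundle (N/C antiparallel within a chain), four DHp
helices, and two CA pseudo-domains (rigid ~30-point clouds with a real
gripper helix and marker Calpha for H248 partners, N360, D386, R363) — and
emits trajectories in which piston, axial rotation, chain-B scissor tilt
and CA-domain swings are injected with machine-readable ground truth.

Design notes that matter for exactness of the ground truth:

* Helices are placed parametrically, so the Calpha set is an exact helix of
  the stated radius/rise/twist; backbone N, C, O ride on companion helices
  with cylindrical offsets derived once from ideal alpha internal
  coordinates (phi=-57, psi=-47), keeping dihedrals inside the alpha window.
* Piston translates a helix along its *measured* (head-tail) axis, and
  axial rotation turns the helix together with its anchor Calpha set about
  the measured axis through the measured center: both are therefore
  recovered exactly by the descriptor formulas.
* The chain-B scissor tilt rotates the chain-B HAMP unit about the line
  joining the measured N2/C2 helix centers, which is made perpendicular to
  the measured chain axis during construction; the tilt angle is then
  recovered exactly and commutes with pistons and axial rotations.
* Frames are emitted in the reference lab frame (no global drift), and
  Gaussian positional noise is added after the motions, i.i.d. per
  coordinate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from . import presets
from .hamp_descriptors import HelixSpec, default_helix_specs, helix_geometry
from .structure_io import Structure, Trajectory, write_pdb, write_trajectory

__all__ = [
    "BundleParams",
    "Motion",
    "MotionSchedule",
    "SyntheticTrajectory",
    "ideal_helix",
    "build_dimer_model",
    "apply_motion",
    "generate_trajectory",
    "random_schedule",
    "DEFAULT_RESIDUE_MAP",
]

# Cylindrical offsets of backbone atoms relative to the same-residue Calpha
# on an ideal alpha helix (radius A, phase deg, axial offset A); derived from
# internal coordinates phi=-57, psi=-47, omega=180 with standard bond geometry.
_BACKBONE_OFFSETS = {
    "N": (1.5514, -26.771, -0.9187),
    "C": (1.6661, +26.743, +1.0689),
    "O": (1.9208, +20.338, +2.2566),
}

_HELIX_ROLES = ("hamp_n", "hamp_c", "dhp1", "dhp2")
_TOP_ROLES = _HELIX_ROLES + ("ca",)

DEFAULT_RESIDUE_MAP: dict[str, tuple[str, int, int]] = {}
for _chain in ("A", "B"):
    DEFAULT_RESIDUE_MAP.update(
        {
            f"hamp_n_{_chain}": (_chain, 188, 204),
            # one residue before 217 so that residue 217 has a phi dihedral
            f"hamp_c_{_chain}": (_chain, 216, 234),
            f"dhp1_{_chain}": (_chain, 235, 268),
            f"dhp2_{_chain}": (_chain, 271, 299),
            f"ca_{_chain}": (_chain, 306, 452),
            f"gripper_{_chain}": (_chain, 420, 430),
        }
    )

_MARKER_RESNAMES = {248: "HIS", 360: "ASN", 386: "ASP", 363: "ARG"}


@dataclass
class BundleParams:
    """Geometry, noise and numbering parameters of the synthetic dimer."""

    helix_rise: float = 1.5          # A per residue
    helix_twist: float = 100.0       # deg per residue
    helix_radius: float = 2.3        # A, Calpha radius
    bundle_spacing: float = 8.5      # A, HAMP inter-monomer center distance
    residue_map: dict[str, tuple[str, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_MAP))
    noise_sigma: float = 0.3         # A, positional jitter (sd per coordinate)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.helix_rise <= 0:
            raise ValueError("helix_rise must be > 0")
        if self.helix_radius <= 0:
            raise ValueError("helix_radius must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for chain in ("A", "B"):
            spans = []
            for role in _TOP_ROLES:
                key = f"{role}_{chain}"
                if key not in self.residue_map:
                    raise ValueError(f"residue_map is missing role {key!r}")
                c, lo, hi = self.residue_map[key]
                if lo > hi:
                    raise ValueError(f"role {key!r}: empty range {lo}-{hi}")
                spans.append((lo, hi, key))
            spans.sort()
            for (l0, h0, k0), (l1, h1, k1) in zip(spans, spans[1:]):
                if l1 <= h0:
                    raise ValueError(
                        f"overlapping residue ranges in chain {chain}: {k0} and {k1}")

    def role(self, name: str, chain: str) -> tuple[str, int, int]:
        return self.residue_map[f"{name}_{chain}"]


# ---------------------------------------------------------------------------
# primitive builders
# ---------------------------------------------------------------------------

def _frame_for_axis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(a)
    if norm < 1e-8:
        raise ValueError("degenerate helix axis (norm < 1e-8)")
    a = a / norm
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, a)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - np.dot(seed, a) * a
    u /= np.linalg.norm(u)
    w = np.cross(a, u)
    return a, u, w


def ideal_helix(n_res: int, params: BundleParams, origin, axis,
                start_resid: int, chain: str,
                phase_deg: float = 0.0, resname: str = "ALA") -> Structure:
    """Parametric alpha helix (N, CA, C, O per residue).

    Calpha atoms lie exactly on a helix of the stated radius/rise/twist
    about ``axis`` (right-handed, residues advancing along the axis);
    backbone atoms ride companion helices so that phi/psi fall in the
    alpha-helical window.
    """
    if n_res < 5:
        raise ValueError("ideal_helix needs n_res >= 5")
    a, u, w = _frame_for_axis(axis)
    origin = np.asarray(origin, dtype=float)
    tw = np.radians(params.helix_twist)
    chains, resids, resnames, names, elements, coords = [], [], [], [], [], []
    for i in range(n_res):
        theta0 = np.radians(phase_deg) + i * tw
        z0 = i * params.helix_rise
        for name in ("N", "CA", "C", "O"):
            if name == "CA":
                r, dph, dz = params.helix_radius, 0.0, 0.0
            else:
                r, dph, dz = _BACKBONE_OFFSETS[name]
            th = theta0 + np.radians(dph)
            pos = origin + a * (z0 + dz) + r * (np.cos(th) * u + np.sin(th) * w)
            chains.append(chain)
            resids.append(start_resid + i)
            resnames.append(resname)
            names.append(name)
            elements.append(name[0])
            coords.append(pos)
    return Structure(
        chain=np.array(chains), resid=np.array(resids),
        resname=np.array(resnames), atom_name=np.array(names),
        element=np.array(elements), coord=np.array(coords),
    )


def _concat(parts: list[Structure]) -> Structure:
    return Structure(
        chain=np.concatenate([p.chain for p in parts]),
        resid=np.concatenate([p.resid for p in parts]),
        resname=np.concatenate([p.resname for p in parts]),
        atom_name=np.concatenate([p.atom_name for p in parts]),
        element=np.concatenate([p.element for p in parts]),
        coord=np.concatenate([p.coord for p in parts]),
    )


def _point_cloud(resids: list[int], center: np.ndarray, radius: float,
                 chain: str) -> Structure:
    """Deterministic Fibonacci-sphere Calpha cloud (rigid pseudo-domain)."""
    n = len(resids)
    k = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    zs = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(1.0 - zs * zs)
    th = golden * k
    pts = center + radius * np.c_[rho * np.cos(th), rho * np.sin(th), zs]
    return Structure(
        chain=np.full(n, chain), resid=np.array(resids),
        resname=np.full(n, "ALA"), atom_name=np.full(n, "CA"),
        element=np.full(n, "C"), coord=pts,
    )


def _ca_cloud_resids(params: BundleParams, chain: str) -> list[int]:
    _, lo, hi = params.role("ca", chain)
    _, glo, ghi = params.role("gripper", chain)
    base = set(range(lo, hi + 1, 5))
    base -= set(range(glo, ghi + 1))
    base -= {presets.MARKER_ASN, presets.MARKER_ASP, presets.MARKER_ARG}
    base |= set(presets.ROTATION_ANCHORS_C)
    return sorted(base)


# ---------------------------------------------------------------------------
# dimer assembly
# ---------------------------------------------------------------------------

def _domain_center(structure: Structure, chain: str,
                   ranges: tuple[tuple[int, int], ...]) -> np.ndarray:
    mask = (structure.chain == chain) & (structure.atom_name == "CA")
    rmask = np.zeros(structure.n_atoms, dtype=bool)
    for lo, hi in ranges:
        rmask |= (structure.resid >= lo) & (structure.resid <= hi)
    idx = np.flatnonzero(mask & rmask)
    return structure.coord[idx].mean(axis=0)


def build_dimer_model(params: BundleParams | None = None,
                      inter_monomer_distance: float | None = None,
                      theta_had: float = presets.THETA_HAD_4BIV,
                      theta_hastar: float = presets.THETA_HASTARD_4BIV,
                      gripper_angle: float = 40.0) -> Structure:
    """Assemble the CpxA-like dimer scaffold.

    ``inter_monomer_distance`` (default: ``params.bundle_spacing``) is hit
    exactly by construction; ``theta_had`` / ``theta_hastar`` place the two
    CA pseudo-domain centers so the HAMP-CA-DHp vertex angles equal the
    requested values exactly (defaults: the crystallographic CpxA
    architecture). ``gripper_angle`` orients each gripper helix relative to
    its companion DHp helix (approximate, within ~2 deg).
    """
    if params is None:
        params = BundleParams()
    d = params.bundle_spacing if inter_monomer_distance is None else float(inter_monomer_distance)

    z_top = 52.0  # z of the first HAMP N-helix Calpha
    parts: list[Structure] = []

    # --- HAMP helices: chain A at x=0, chain B a translated copy at x=d ----
    for chain, x0 in (("A", 0.0), ("B", d)):
        _, nlo, nhi = params.role("hamp_n", chain)
        n_n = nhi - nlo + 1
        helix_n = ideal_helix(n_n, params, origin=(x0, 0.0, z_top),
                              axis=(0, 0, -1.0), start_resid=nlo, chain=chain)
        _, clo, chi_ = params.role("hamp_c", chain)
        n_c = chi_ - clo + 1
        z0_c = z_top - (n_n - 1) * params.helix_rise  # roughly level with N tail
        helix_c = ideal_helix(n_c, params, origin=(x0, d, z0_c),
                              axis=(0, 0, 1.0), start_resid=clo, chain=chain)
        # align the measured helix centers perpendicular to the measured
        # chain axis: shift the C helix so (C_c - N_c) . a_chain == 0
        tmp = _concat([helix_n, helix_c])
        spec_n = HelixSpec(f"N{'1' if chain == 'A' else '2'}", chain,
                           presets.HAMP_DESCRIPTOR_RANGES[0], presets.ROTATION_ANCHORS_N)
        spec_c = HelixSpec(f"C{'1' if chain == 'A' else '2'}", chain,
                           presets.HAMP_DESCRIPTOR_RANGES[1], presets.ROTATION_ANCHORS_C)
        g_n = _helix_points(tmp, spec_n)
        g_c = _helix_points(tmp, spec_c)
        a_chain = _avg_axis(g_n, g_c)
        mis = float(np.dot(g_c["r_c"] - g_n["r_c"], a_chain))
        dz = -mis / float(np.dot(np.array([0.0, 0.0, 1.0]), a_chain))
        helix_c = helix_c.with_coord(helix_c.coord + np.array([0.0, 0.0, dz]))
        parts.extend([helix_n, helix_c])

    # --- DHp helices: inner square below HAMP -----------------------------
    cx = cy = d / 2.0
    for chain, xo in (("A", -4.0), ("B", +4.0)):
        _, lo1, hi1 = params.role("dhp1", chain)
        n1 = hi1 - lo1 + 1
        parts.append(ideal_helix(n1, params, origin=(cx + xo, cy - 4.0, 26.0),
                                 axis=(0, 0, -1.0), start_resid=lo1, chain=chain))
        _, lo2, hi2 = params.role("dhp2", chain)
        n2 = hi2 - lo2 + 1
        parts.append(ideal_helix(n2, params, origin=(cx + xo, cy + 4.0, -23.0),
                                 axis=(0, 0, 1.0), start_resid=lo2, chain=chain))

    scaffold = _concat(parts)

    # --- CA pseudo-domains -------------------------------------------------
    h_center = _domain_center(scaffold, "A", presets.HAMP_DISTANCE_RANGES)
    h_center = 0.5 * (h_center + _domain_center(scaffold, "B", presets.HAMP_DISTANCE_RANGES))
    d_center = 0.5 * (_domain_center(scaffold, "A", presets.DHP_ARCHITECTURE_RANGES)
                      + _domain_center(scaffold, "B", presets.DHP_ARCHITECTURE_RANGES))
    hd = h_center - d_center
    length = np.linalg.norm(hd)
    e = hd / length
    lateral = np.array([1.0, 0.0, 0.0])
    lateral -= np.dot(lateral, e) * e
    lateral /= np.linalg.norm(lateral)
    mid = 0.5 * (h_center + d_center)

    for chain, theta, side in (("A", theta_had, -1.0), ("B", theta_hastar, +1.0)):
        half = np.radians(theta) / 2.0
        w = (length / 2.0) / np.tan(half)
        center = mid + side * w * lateral
        ca_parts: list[Structure] = []
        cloud = _point_cloud(_ca_cloud_resids(params, chain), np.zeros(3), 7.0, chain)
        ca_parts.append(cloud)
        # gripper helix at `gripper_angle` to its companion DHp helix axis
        _, glo, ghi = params.role("gripper", chain)
        gdir = -np.array([np.sin(np.radians(gripper_angle)), 0.0,
                          np.cos(np.radians(gripper_angle))])
        ca_parts.append(ideal_helix(ghi - glo + 1, params, origin=(0.0, 4.0, 8.0),
                                    axis=gdir, start_resid=glo, chain=chain))
        movable = _concat(ca_parts)

        # markers at fixed absolute positions
        other = "B" if chain == "A" else "A"
        h248_other = scaffold.atom_coord(other, presets.MARKER_HIS, "CA")
        target = 25.0 if chain == "A" else 13.0  # CA(-) vs CA(*) side
        u_toward = center - h248_other
        u_toward /= np.linalg.norm(u_toward)
        n360 = h248_other + target * u_toward
        d386 = center + np.array([-2.0, 3.0, -4.0])
        r363 = center + np.array([1.5, -2.5, -3.5])
        markers = Structure(
            chain=np.full(3, chain),
            resid=np.array([presets.MARKER_ASN, presets.MARKER_ARG, presets.MARKER_ASP]),
            resname=np.array(["ASN", "ARG", "ASP"]),
            atom_name=np.full(3, "CA"),
            element=np.full(3, "C"),
            coord=np.array([n360, r363, d386]),
        )
        # translate the movable part so the Calpha centroid of the whole CA
        # span (cloud + gripper + markers) sits exactly at `center`
        span_lo, span_hi = presets.CA_ARCHITECTURE_RANGE
        mov_ca = (movable.atom_name == "CA") & (movable.resid >= span_lo) & (movable.resid <= span_hi)
        n_mov = int(mov_ca.sum())
        n_tot = n_mov + 3
        t = (center * n_tot - markers.coord.sum(axis=0)
             - movable.coord[mov_ca].sum(axis=0)) / n_mov
        movable = movable.with_coord(movable.coord + t)
        parts.extend([movable, markers])

    model = _concat(parts)
    # rename marker residues for readability
    for resid, resname in _MARKER_RESNAMES.items():
        model.resname[model.resid == resid] = resname
    # stable order: chain, resid, then backbone atom order
    atom_rank = {"N": 0, "CA": 1, "C": 2, "O": 3}
    order = np.lexsort((
        np.array([atom_rank.get(a, 4) for a in model.atom_name]),
        model.resid,
        model.chain,
    ))
    return model.subset(order)


def _helix_points(structure: Structure, spec: HelixSpec) -> dict:
    """Head/tail/axis/center of a helix without requiring anchor residues."""
    lo, hi = spec.resid_range
    mask = (structure.chain == spec.chain) & (structure.atom_name == "CA")
    resid_to_coord = {int(structure.resid[i]): structure.coord[i]
                      for i in np.flatnonzero(mask)}
    ca = np.array([resid_to_coord[r] for r in range(lo, hi + 1)])
    r_h = ca[:4].mean(axis=0)
    r_t = ca[-4:].mean(axis=0)
    return {"r_h": r_h, "r_t": r_t, "r": r_h - r_t, "r_c": 0.5 * (r_h + r_t)}


def _avg_axis(g_n: dict, g_c: dict) -> np.ndarray:
    axis_c = g_c["r"] if np.dot(g_c["r"], g_n["r"]) > 0 else -g_c["r"]
    a = g_n["r"] + axis_c
    return a / np.linalg.norm(a)


# ---------------------------------------------------------------------------
# motions
# ---------------------------------------------------------------------------

HELIX_LABELS = ("N1", "C1", "N2", "C2")


@dataclass
class Motion:
    """Ground-truth motion of one frame.

    ``rotation`` follows the sign convention of the rotation descriptor
    (the value the descriptor reads back); ``tilt`` opens the chain-B
    scissor by the given angle; ``swing`` rotates a CA pseudo-domain about
    the HAMP center toward the HAMP-DHp axis.
    """

    piston: dict[str, float] = field(default_factory=dict)    # A per helix
    rotation: dict[str, float] = field(default_factory=dict)  # deg per helix
    tilt: float = 0.0                                          # deg, chain B
    swing: dict[str, float] = field(default_factory=dict)      # deg per chain

    def is_identity(self) -> bool:
        return (
            all(abs(v) < 1e-15 for v in self.piston.values())
            and all(abs(v) < 1e-15 for v in self.rotation.values())
            and abs(self.tilt) < 1e-15
            and all(abs(v) < 1e-15 for v in self.swing.values())
        )


@dataclass
class MotionSchedule:
    """Per-frame ground-truth motion parameters; frame 0 is the identity."""

    piston: np.ndarray    # (n_frames, 4) A, order N1, C1, N2, C2
    rotation: np.ndarray  # (n_frames, 4) deg
    tilt: np.ndarray      # (n_frames,) deg
    swing: np.ndarray     # (n_frames, 2) deg, chains A, B

    def __post_init__(self) -> None:
        n = len(self.tilt)
        self.piston = np.asarray(self.piston, dtype=float).reshape(n, 4)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(n, 4)
        self.tilt = np.asarray(self.tilt, dtype=float)
        self.swing = np.asarray(self.swing, dtype=float).reshape(n, 2)
        if not self.entry(0).is_identity():
            raise ValueError("frame 0 of a MotionSchedule must be the identity")

    @property
    def n_frames(self) -> int:
        return len(self.tilt)

    @classmethod
    def zeros(cls, n_frames: int) -> "MotionSchedule":
        return cls(np.zeros((n_frames, 4)), np.zeros((n_frames, 4)),
                   np.zeros(n_frames), np.zeros((n_frames, 2)))

    def entry(self, i: int) -> Motion:
        return Motion(
            piston={lbl: float(self.piston[i, k]) for k, lbl in enumerate(HELIX_LABELS)},
            rotation={lbl: float(self.rotation[i, k]) for k, lbl in enumerate(HELIX_LABELS)},
            tilt=float(self.tilt[i]),
            swing={"A": float(self.swing[i, 0]), "B": float(self.swing[i, 1])},
        )

    def to_dict(self) -> dict:
        return {
            "piston": {lbl: self.piston[:, k].tolist() for k, lbl in enumerate(HELIX_LABELS)},
            "rotation": {lbl: self.rotation[:, k].tolist() for k, lbl in enumerate(HELIX_LABELS)},
            "tilt": self.tilt.tolist(),
            "swing": {"A": self.swing[:, 0].tolist(), "B": self.swing[:, 1].tolist()},
        }


def random_schedule(n_frames: int, seed: int = 0,
                    piston_amp: float = 1.8, rotation_amp: float = 35.0,
                    tilt_max: float = 15.0, swing_amp: float = 0.0) -> MotionSchedule:
    """Smooth sinusoidal schedule inside the observed motion envelopes.

    Default amplitudes stay within the ranges seen for CpxA-like HAMP
    bundles: pistons within +-2 A, rotations within +-40 deg, tilt within
    0-35 deg. Every channel starts at the identity at frame 0.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / max(n_frames - 1, 1)

    def channel(amp):
        f = rng.integers(1, 4)
        sign = rng.choice([-1.0, 1.0])
        scale = rng.uniform(0.5, 1.0)
        return amp * scale * sign * np.sin(2 * np.pi * f * t)

    piston = np.column_stack([channel(piston_amp) for _ in range(4)])
    rot = np.column_stack([channel(rotation_amp) for _ in range(4)])
    tilt = tilt_max * rng.uniform(0.3, 1.0) * 0.5 * (1 - np.cos(2 * np.pi * rng.integers(1, 3) * t))
    swing = np.column_stack([channel(swing_amp) for _ in range(2)])
    return MotionSchedule(piston, rot, tilt, swing)


def _rotate_about(coords: np.ndarray, point: np.ndarray, axis: np.ndarray,
                  angle_deg: float) -> np.ndarray:
    a = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(a)
    if norm < 1e-8:
        raise ValueError("degenerate rotation axis")
    rot = Rotation.from_rotvec(np.radians(angle_deg) * a / norm)
    return (coords - point) @ rot.as_matrix().T + point


def _helix_spec_for(label: str) -> HelixSpec:
    specs = {s.label: s for s in default_helix_specs("descriptor")}
    return specs[label]


def _built_range_mask(structure: Structure, params: BundleParams,
                      label: str) -> np.ndarray:
    role = "hamp_n" if label.startswith("N") else "hamp_c"
    chain = "A" if label.endswith("1") else "B"
    c, lo, hi = params.role(role, chain)
    return (structure.chain == c) & (structure.resid >= lo) & (structure.resid <= hi)


def _anchor_mask(structure: Structure, spec: HelixSpec) -> np.ndarray:
    m = (structure.chain == spec.anchor_chain) & (structure.atom_name == "CA")
    rm = np.isin(structure.resid, list(spec.ref_resids))
    return m & rm


def apply_motion(structure: Structure, motion: Motion,
                 params: BundleParams | None = None) -> Structure:
    """Apply one frame's rigid motions to a dimer model.

    Order: chain-B scissor tilt, then per-helix piston and axial rotation
    along/about the current measured axes (rotation carries the helix's
    anchor Calpha set, i.e. it is a helix-versus-anchor azimuthal motion,
    which is the quantity the rotation descriptor measures), then CA swings.
    The identity motion returns a bitwise-identical coordinate set.
    """
    if params is None:
        params = BundleParams()
    out = structure.copy()

    # --- chain-B scissor tilt ---------------------------------------------
    if motion.tilt != 0.0:
        spec_n2 = _helix_spec_for("N2")
        spec_c2 = _helix_spec_for("C2")
        g_n = helix_geometry(out, spec_n2)
        g_c = helix_geometry(out, spec_c2)
        axis = g_c.r_c - g_n.r_c
        mask = _built_range_mask(out, params, "N2") | _built_range_mask(out, params, "C2")
        out.coord[mask] = _rotate_about(out.coord[mask], g_n.r_c, axis, motion.tilt)

    # --- per-helix piston and axial rotation ------------------------------
    for label in HELIX_LABELS:
        p = motion.piston.get(label, 0.0)
        rdeg = motion.rotation.get(label, 0.0)
        if p == 0.0 and rdeg == 0.0:
            continue
        spec = _helix_spec_for(label)
        hmask = _built_range_mask(out, params, label)
        if p != 0.0:
            g = helix_geometry(out, spec)
            out.coord[hmask] = out.coord[hmask] + p * g.axis_unit
        if rdeg != 0.0:
            g = helix_geometry(out, spec)
            unit = hmask | _anchor_mask(out, spec)
            # descriptor sign convention: schedule +phi == right-handed -phi
            out.coord[unit] = _rotate_about(out.coord[unit], g.r_c, g.axis_unit, -rdeg)

    # --- CA-domain swings ---------------------------------------------------
    for chain in ("A", "B"):
        s = motion.swing.get(chain, 0.0)
        if s == 0.0:
            continue
        h_center = 0.5 * (_domain_center(out, "A", presets.HAMP_DISTANCE_RANGES)
                          + _domain_center(out, "B", presets.HAMP_DISTANCE_RANGES))
        d_center = 0.5 * (_domain_center(out, "A", presets.DHP_ARCHITECTURE_RANGES)
                          + _domain_center(out, "B", presets.DHP_ARCHITECTURE_RANGES))
        span_lo, span_hi = presets.CA_ARCHITECTURE_RANGE
        mask = (out.chain == chain) & (out.resid >= span_lo) & (out.resid <= span_hi)
        ca_center = out.coord[mask & (out.atom_name == "CA")].mean(axis=0)
        axis = np.cross(ca_center - h_center, d_center - h_center)
        out.coord[mask] = _rotate_about(out.coord[mask], h_center, axis, s)

    return out


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTrajectory:
    """A generated trajectory with its noiseless reference and ground truth."""

    trajectory: Trajectory
    reference: Structure
    schedule: MotionSchedule
    params: BundleParams

    def ground_truth(self) -> dict:
        gt = self.schedule.to_dict()
        gt["noise_sigma"] = self.params.noise_sigma
        gt["seed"] = self.params.seed
        return gt


def generate_trajectory(params: BundleParams | None = None,
                        schedule: MotionSchedule | None = None,
                        out_dir: str | Path | None = None,
                        frame_spacing_ps: float = 10.0,
                        **model_kwargs) -> SyntheticTrajectory:
    """Emit a trajectory with the scheduled motions plus Gaussian noise.

    Noise (sd ``params.noise_sigma`` per coordinate) is added after the
    motions, independently per atom coordinate and frame. With ``out_dir``
    set, writes ``reference.pdb``, ``trajectory.pdb`` (one MODEL per frame)
    and ``ground_truth.json``; a fixed seed reproduces identical bytes.
    """
    if params is None:
        params = BundleParams()
    if schedule is None:
        schedule = MotionSchedule.zeros(1)
    if schedule.n_frames < 1:
        raise ValueError("schedule must contain at least one frame")
    reference = build_dimer_model(params, **model_kwargs)
    rng = np.random.default_rng(params.seed)
    coords = np.empty((schedule.n_frames, reference.n_atoms, 3))
    for i in range(schedule.n_frames):
        moved = apply_motion(reference, schedule.entry(i), params)
        coords[i] = moved.coord
    if params.noise_sigma > 0:
        coords += rng.normal(0.0, params.noise_sigma, size=coords.shape)
    traj = Trajectory(topology=reference, coords=coords,
                      times_ps=np.arange(schedule.n_frames) * frame_spacing_ps)
    result = SyntheticTrajectory(traj, reference, schedule, params)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pdb(reference, out / "reference.pdb")
        write_trajectory(traj, out / "trajectory.pdb")
        (out / "ground_truth.json").write_text(
            json.dumps(result.ground_truth(), indent=1))
    return result


def trajectory_checksum(path: str | Path) -> str:
    """SHA-256 of a trajectory file (byte-identity check for fixed seeds)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
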