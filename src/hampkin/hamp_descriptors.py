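"""HAMP alpha-helix kinematics: piston, rotation, tilt, and bundle health.

The HAMP four-helix bundle (helices N1, C1 in chain A and N2, C2 in chain B)
is reduced per helix to five geometric quantities: the head point R_h (mean
of the four N-terminal Calpha), the tail point R_t (mean of the four
C-terminal Calpha), the axis R = R_h - R_t, the center R_c = (R_h + R_t)/2,
and a reference point R_r (Calpha centroid of anchor residues on DHp or CA).

From these and their reference-frame counterparts (superscript 0):

* piston   = (R_c - R_c0) . R/|R|                        [A]
* rotation = sign(R_rc . (R_0c x R)) *
             arccos( (R_rc x R).(R_0c x R) / |R_rc x R||R_0c x R| )  [deg]
  with R_rc = R_r - R_c and R_0c = R_r0 - R_c0 (both reference-frame
  quantities, so every descriptor vanishes when frame == reference)
* tilt     = angle between the per-chain averaged head-tail axes  [deg]

Frames are normally superposed onto the reference over all four helix
Calpha ranges before measuring, so that the descriptors are invariant under
whole-frame rigid motion. Synthetic trajectories from
:mod:`hampkin.bundle_synth` are emitted in the reference lab frame, where
the superposition is the identity and may be skipped for exact
ground-truth recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import presets
from .series import DescriptorSeries
from .structure_io import Selection, Structure, Trajectory, geometric_center, superpose

__all__ = [
    "HelixSpec",
    "HelixGeometry",
    "default_helix_specs",
    "helix_geometry",
    "superpose_hamp",
    "piston",
    "rotation",
    "average_tilt",
    "inter_monomer_distance",
    "helix_content",
    "compute_descriptors",
]

_DEG = 180.0 / np.pi


@dataclass(frozen=True)
class HelixSpec:
    """Residue-range definition of one HAMP helix plus its rotation anchors."""

    label: str                      # N1 | C1 | N2 | C2
    chain: str
    resid_range: tuple[int, int]    # inclusive
    ref_resids: tuple[int, ...]     # anchor Calpha residues for R_r
    ref_chain: str | None = None    # defaults to `chain`

    def __post_init__(self) -> None:
        lo, hi = self.resid_range
        if hi - lo + 1 < 8:
            raise ValueError(
                f"helix {self.label}: range {self.resid_range} shorter than 8 "
                "residues (head and tail need 4 Calpha each)"
            )

    @property
    def anchor_chain(self) -> str:
        return self.ref_chain if self.ref_chain is not None else self.chain


@dataclass
class HelixGeometry:
    """Derived helix points/vectors (all in A, lab frame)."""

    r_h: np.ndarray   # head point
    r_t: np.ndarray   # tail point
    r: np.ndarray     # axis, head - tail
    r_c: np.ndarray   # center
    r_r: np.ndarray   # anchor reference point

    @property
    def axis_unit(self) -> np.ndarray:
        return self.r / np.linalg.norm(self.r)


def default_helix_specs(preset: str = "descriptor") -> tuple[HelixSpec, ...]:
    """The four HAMP helices with chain-matched anchor sets.

    ``preset`` selects the residue window: ``descriptor`` (189-204/217-232,
    used for piston/rotation/tilt), ``cv`` (188-201/219-234) or
    ``distance`` (189-203/217-231).
    """
    ranges = {
        "descriptor": presets.HAMP_DESCRIPTOR_RANGES,
        "cv": presets.HAMP_CV_RANGES,
        "distance": presets.HAMP_DISTANCE_RANGES,
    }[preset]
    n_range, c_range = ranges
    return (
        HelixSpec("N1", "A", n_range, presets.ROTATION_ANCHORS_N),
        HelixSpec("C1", "A", c_range, presets.ROTATION_ANCHORS_C),
        HelixSpec("N2", "B", n_range, presets.ROTATION_ANCHORS_N),
        HelixSpec("C2", "B", c_range, presets.ROTATION_ANCHORS_C),
    )


def _ca_coords(structure: Structure, chain: str,
               resids: list[int], what: str) -> np.ndarray:
    table = {}
    mask = (structure.chain == chain) & (structure.atom_name == "CA")
    for i in np.flatnonzero(mask):
        table[int(structure.resid[i])] = structure.coord[i]
    missing = [r for r in resids if r not in table]
    if missing:
        raise ValueError(f"{what}: missing Calpha for chain {chain} residues {missing}")
    return np.array([table[r] for r in resids])


def helix_geometry(structure: Structure, spec: HelixSpec) -> HelixGeometry:
    """Head/tail/axis/center/reference points of one helix."""
    lo, hi = spec.resid_range
    resids = list(range(lo, hi + 1))
    ca = _ca_coords(structure, spec.chain, resids, f"helix {spec.label}")
    r_h = ca[:4].mean(axis=0)
    r_t = ca[-4:].mean(axis=0)
    r = r_h - r_t
    if np.linalg.norm(r) < 1.0:
        raise ValueError(f"helix {spec.label}: degenerate axis |R| < 1 A")
    r_c = 0.5 * (r_h + r_t)
    anchors = _ca_coords(structure, spec.anchor_chain, list(spec.ref_resids),
                         f"helix {spec.label} anchors")
    r_r = anchors.mean(axis=0)
    return HelixGeometry(r_h=r_h, r_t=r_t, r=r, r_c=r_c, r_r=r_r)


def superpose_hamp(frame: Structure, reference: Structure,
                   specs: tuple[HelixSpec, ...] | None = None) -> Structure:
    """Calpha fit of the frame onto the reference over all four helix ranges."""
    if specs is None:
        specs = default_helix_specs()
    sel = Selection(atom_names=("CA",),
                    resid_ranges=tuple(s.resid_range for s in specs))
    _, _, fitted = superpose(frame, reference, sel)
    return fitted


def piston(frame_geom: HelixGeometry, ref_geom: HelixGeometry) -> float:
    """Signed axial displacement of the helix center (A)."""
    u = frame_geom.axis_unit
    return float(np.dot(frame_geom.r_c - ref_geom.r_c, u))


def rotation(frame_geom: HelixGeometry, ref_geom: HelixGeometry) -> float:
    """Signed azimuthal angle (deg) of the anchor direction about the axis.

    Implements the cross-product construction: both the current anchor
    vector R_rc and its reference counterpart R_0c are implicitly projected
    off the current axis R by the cross products; the sign term orients the
    angle about R. Range (-180, 180].
    """
    r = frame_geom.r
    r_rc = frame_geom.r_r - frame_geom.r_c
    r_0c = ref_geom.r_r - ref_geom.r_c
    c_cur = np.cross(r_rc, r)
    c_ref = np.cross(r_0c, r)
    n_cur = np.linalg.norm(c_cur)
    n_ref = np.linalg.norm(c_ref)
    sin_floor = 1e-6
    if n_cur < sin_floor * np.linalg.norm(r_rc) * np.linalg.norm(r) or \
       n_ref < sin_floor * np.linalg.norm(r_0c) * np.linalg.norm(r):
        raise ValueError("rotation ill-conditioned: reference vector parallel to axis")
    # same angle as the arccos of the normalized dot product, but conditioned
    # well near 0 and 180 degrees
    ang = np.degrees(np.arctan2(np.linalg.norm(np.cross(c_cur, c_ref)),
                                np.dot(c_cur, c_ref)))
    sign = np.dot(r_rc, c_ref)
    if sign < 0:
        ang = -ang
    return float(ang)


def _chain_axis(structure: Structure, chain_specs: list[HelixSpec]) -> np.ndarray:
    """Averaged head-tail vector of one chain's helices.

    The C helix runs antiparallel to the N helix; its head/tail are swapped
    when its axis opposes the N-helix axis, so that averaging does not
    cancel to a degenerate vector.
    """
    geoms = [helix_geometry(structure, s) for s in chain_specs]
    ref_axis = geoms[0].r
    heads, tails = [], []
    for g in geoms:
        if np.dot(g.r, ref_axis) < 0:
            heads.append(g.r_t)
            tails.append(g.r_h)
        else:
            heads.append(g.r_h)
            tails.append(g.r_t)
    axis = np.mean(heads, axis=0) - np.mean(tails, axis=0)
    if np.linalg.norm(axis) < 1.0:
        raise ValueError("degenerate averaged chain axis |R| < 1 A")
    return axis


def average_tilt(structure: Structure,
                 specs: tuple[HelixSpec, ...] | None = None) -> float:
    """Scissor (tilt) angle between the chain-A and chain-B average axes (deg).

    Computed from the average positions of helix heads and tails in each
    chain; reported in [0, 180].
    """
    if specs is None:
        specs = default_helix_specs()
    by_chain: dict[str, list[HelixSpec]] = {}
    for s in specs:
        by_chain.setdefault(s.chain, []).append(s)
    if len(by_chain) != 2:
        raise ValueError("tilt needs helices in exactly two chains")
    (ca_specs, cb_specs) = by_chain.values()
    a = _chain_axis(structure, ca_specs)
    b = _chain_axis(structure, cb_specs)
    cosang = np.clip(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)),
                     -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def inter_monomer_distance(structure: Structure,
                           ranges: tuple[tuple[int, int], ...] | None = None,
                           chains: tuple[str, str] = ("A", "B")) -> float:
    """Distance between the per-chain HAMP Calpha geometric centers (A)."""
    if ranges is None:
        ranges = presets.HAMP_DISTANCE_RANGES
    centers = []
    for chain in chains:
        sel = Selection.ca(chains=(chain,), resid_ranges=ranges)
        idx = sel.resolve(structure)
        lo_hi = [r for rng in ranges for r in rng]
        if len(idx) == 0:
            raise ValueError(
                f"no Calpha in chain {chain} residues {lo_hi} for inter-monomer distance"
            )
        want = sum(hi - lo + 1 for lo, hi in ranges)
        if len(idx) != want:
            present = set(int(r) for r in structure.resid[idx])
            missing = [r for lo, hi in ranges for r in range(lo, hi + 1)
                       if r not in present]
            raise ValueError(f"chain {chain}: missing residues {missing}")
        centers.append(geometric_center(structure, idx))
    return float(np.linalg.norm(centers[0] - centers[1]))


# ---------------------------------------------------------------------------
# alpha-helix content from backbone dihedrals
# ---------------------------------------------------------------------------

#: dihedral windows for the alpha assignment (deg)
PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-80.0, -5.0)
MIN_HELIX_RUN = 3


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral (deg), IUPAC convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _helical_flags(structure: Structure, chain: str,
                   resids: list[int]) -> np.ndarray:
    """Alpha-helical assignment for each residue in ``resids``.

    A residue is helical if both phi and psi exist and fall inside the
    alpha windows; runs shorter than MIN_HELIX_RUN are then demoted.
    Terminal residues lacking a dihedral are non-helical.
    """
    mask = (structure.chain == chain)
    table: dict[tuple[int, str], np.ndarray] = {}
    for i in np.flatnonzero(mask):
        table[(int(structure.resid[i]), str(structure.atom_name[i]))] = structure.coord[i]

    def get(resid: int, name: str):
        return table.get((resid, name))

    flags = np.zeros(len(resids), dtype=bool)
    for k, r in enumerate(resids):
        c_prev = get(r - 1, "C")
        n = get(r, "N")
        ca = get(r, "CA")
        c = get(r, "C")
        n_next = get(r + 1, "N")
        if n is None or ca is None or c is None:
            raise ValueError(f"chain {chain} residue {r}: missing backbone atoms")
        if c_prev is None or n_next is None:
            continue
        phi = _dihedral(c_prev, n, ca, c)
        psi = _dihedral(n, ca, c, n_next)
        if PHI_WINDOW[0] <= phi <= PHI_WINDOW[1] and PSI_WINDOW[0] <= psi <= PSI_WINDOW[1]:
            flags[k] = True
    # demote runs shorter than the minimum
    out = flags.copy()
    k = 0
    while k < len(flags):
        if flags[k]:
            j = k
            while j < len(flags) and flags[j]:
                j += 1
            if j - k < MIN_HELIX_RUN:
                out[k:j] = False
            k = j
        else:
            k += 1
    return out


def helix_content(traj: Trajectory | Structure,
                  ranges: tuple[tuple[int, int], ...] | None = None,
                  chains: tuple[str, ...] = ("A", "B")) -> dict[str, float]:
    """Percentage of alpha-helical residues, per chain and overall.

    Averaged over frames; a residue counts as helical when its phi/psi fall
    in the alpha windows and it belongs to a run of at least 3 residues.
    """
    if ranges is None:
        ranges = presets.HAMP_DISTANCE_RANGES
    if isinstance(traj, Structure):
        frames: list[Structure] = [traj]
    else:
        frames = list(traj)
    resids = [r for lo, hi in ranges for r in range(lo, hi + 1)]
    per_chain = {c: [] for c in chains}
    for frame in frames:
        for c in chains:
            flags = _helical_flags(frame, c, resids)
            per_chain[c].append(flags.mean())
    result = {c: 100.0 * float(np.mean(v)) for c, v in per_chain.items()}
    result["overall"] = float(np.mean(list(result.values())))
    return result


# ---------------------------------------------------------------------------
# trajectory pipeline
# ---------------------------------------------------------------------------

def compute_descriptors(traj: Trajectory, reference: Structure,
                        specs: tuple[HelixSpec, ...] | None = None,
                        fit: bool = True) -> pd.DataFrame:
    """Per-frame piston/rotation (per helix), tilt and inter-monomer distance.

    With ``fit=True`` every frame is first superposed onto the reference over
    the four helix Calpha ranges (rigid-motion invariant). Synthetic
    lab-frame trajectories may use ``fit=False`` for exact ground-truth
    recovery.
    """
    if specs is None:
        specs = default_helix_specs()
    ref_geoms = {s.label: helix_geometry(reference, s) for s in specs}
    rows = []
    for frame in traj:
        if fit:
            frame = superpose_hamp(frame, reference, specs)
        row: dict[str, float] = {}
        for s in specs:
            g = helix_geometry(frame, s)
            row[f"piston_{s.label}"] = piston(g, ref_geoms[s.label])
            row[f"rotation_{s.label}"] = rotation(g, ref_geoms[s.label])
        row["tilt"] = average_tilt(frame, specs)
        row["inter_monomer_distance"] = inter_monomer_distance(frame)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.insert(0, "time_ps", traj.times_ps)
    return df


def descriptor_series(df: pd.DataFrame, name: str) -> DescriptorSeries:
    """Extract one column of :func:`compute_descriptors` output as a series."""
    units = "deg" if name.startswith(("rotation", "tilt")) else "Angstrom"
    return DescriptorSeries(name=name, units=units,
                            values=df[name].to_numpy(),
                            times_ps=df["time_ps"].to_numpy())
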