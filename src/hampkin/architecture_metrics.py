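"""Whole-protein architecture and enzymatic-state metrics.

Covers the segmental-motion and enzymatic-state readouts of a CpxA-like
histidine-kinase dimer:

* the HAMP-CA-DHp vertex angles theta_HAD (CA-, chain A) and theta_HA*D
  (CA*, chain B) and their asymmetry ratio;
* gripper-helix vs companion-DHp-helix crossing angles;
* marker Calpha-Calpha distances (N360/H248 across chains);
* contact distance series with the 3 A dissociation-interval rule;
* flat-bottom harmonic distance restraints (single or r^-6 ambiguous) with
  strict and widened-interval violation percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import presets
from .series import DescriptorSeries
from .structure_io import Selection, Structure, Trajectory, geometric_center

__all__ = [
    "DomainSpec",
    "RestraintSpec",
    "default_domain_specs",
    "domain_angles",
    "gripper_dhp_angle",
    "marker_distance",
    "contact_series",
    "dissociation_intervals",
    "effective_distance",
    "restraint_energy",
    "restraint_gradient",
    "violation_stats",
    "restraint_presets",
    "read_restraints_tsv",
    "write_restraints_tsv",
]

_DEG = 180.0 / np.pi


@dataclass(frozen=True)
class DomainSpec:
    """Residue ranges whose Calpha geometric center represents a domain."""

    name: str                              # HAMP | DHp | CA_A | CA_B
    chains: tuple[str, ...]
    ranges: tuple[tuple[int, int], ...]

    def center(self, structure: Structure) -> np.ndarray:
        sel = Selection.ca(chains=self.chains, resid_ranges=self.ranges)
        idx = sel.resolve(structure)
        if len(idx) == 0:
            raise ValueError(
                f"domain {self.name}: no Calpha in chains {self.chains} "
                f"ranges {self.ranges}")
        return geometric_center(structure, idx)


def default_domain_specs(preset: str = "s2") -> dict[str, DomainSpec]:
    """Domain centers; ``s2`` is the architecture set, ``methods`` the CV set."""
    if preset == "s2":
        hamp, dhp, ca = (presets.HAMP_DISTANCE_RANGES,
                         presets.DHP_ARCHITECTURE_RANGES,
                         (presets.CA_ARCHITECTURE_RANGE,))
    elif preset == "methods":
        hamp, dhp, ca = (presets.HAMP_CV_RANGES, presets.DHP_CV_RANGES,
                         (presets.CA_CV_RANGE,))
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return {
        "HAMP": DomainSpec("HAMP", ("A", "B"), hamp),
        "DHp": DomainSpec("DHp", ("A", "B"), dhp),
        "CA_A": DomainSpec("CA_A", ("A",), ca),
        "CA_B": DomainSpec("CA_B", ("B",), ca),
    }


def _vertex_angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    va = a - vertex
    vb = b - vertex
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na < 1e-9 or nb < 1e-9:
        raise ValueError("coincident domain centers: vertex angle undefined")
    cosang = np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def domain_angles(structure: Structure,
                  specs: dict[str, DomainSpec] | None = None
                  ) -> tuple[float, float, float]:
    """(theta_HAD, theta_HA*D, ratio) from the domain geometric centers.

    Each angle sits at the CA-domain vertex between the directions to the
    HAMP and DHp centers; theta_HAD uses the chain-A (CA-) domain and
    theta_HA*D the chain-B (CA*) domain. Values near ratio = 1 indicate a
    symmetric HAMP/DHp arrangement; larger ratios the asymmetric
    (segmental-motion) arrangement.
    """
    if specs is None:
        specs = default_domain_specs()
    h = specs["HAMP"].center(structure)
    d = specs["DHp"].center(structure)
    theta_had = _vertex_angle(h, specs["CA_A"].center(structure), d)
    theta_hastar = _vertex_angle(h, specs["CA_B"].center(structure), d)
    return theta_had, theta_hastar, theta_had / theta_hastar


def _axis_from_range(structure: Structure, chain: str,
                     resid_range: tuple[int, int], what: str) -> np.ndarray:
    lo, hi = resid_range
    mask = (structure.chain == chain) & (structure.atom_name == "CA")
    table = {int(structure.resid[i]): structure.coord[i]
             for i in np.flatnonzero(mask)}
    missing = [r for r in range(lo, hi + 1) if r not in table]
    if missing:
        raise ValueError(f"{what}: missing Calpha for chain {chain} residues {missing}")
    ca = np.array([table[r] for r in range(lo, hi + 1)])
    axis = ca[:4].mean(axis=0) - ca[-4:].mean(axis=0)
    if np.linalg.norm(axis) < 1.0:
        raise ValueError(f"{what}: degenerate axis")
    return axis


def gripper_dhp_angle(structure: Structure,
                      gripper_range: tuple[int, int] | None = None,
                      companion_range: tuple[int, int] | None = None
                      ) -> dict[str, float]:
    """Gripper-helix vs companion-DHp-helix angles (deg, [0, 180]).

    Pairing follows the enzymatic-state convention: the CA* gripper (chain
    B) pairs with DHp helix 1A and the CA- gripper (chain A) with helix 1B.
    Axes are head-tail vectors (4-Calpha means at each end).
    """
    if gripper_range is None:
        gripper_range = presets.GRIPPER_RANGE
    if companion_range is None:
        companion_range = presets.DHP_COMPANION_RANGE
    out = {}
    for key, gripper_chain, dhp_chain in (("CA-", "A", "B"), ("CA*", "B", "A")):
        g = _axis_from_range(structure, gripper_chain, gripper_range,
                             f"gripper {gripper_chain}")
        h = _axis_from_range(structure, dhp_chain, companion_range,
                             f"DHp helix 1{dhp_chain}")
        cosang = np.clip(np.dot(g, h) / (np.linalg.norm(g) * np.linalg.norm(h)),
                         -1.0, 1.0)
        out[key] = float(np.degrees(np.arccos(cosang)))
    return out


def marker_distance(structure: Structure,
                    a: tuple[str, int, str] | tuple[str, int],
                    b: tuple[str, int, str] | tuple[str, int]) -> float:
    """Euclidean distance (A) between two named atoms (default Calpha)."""
    pa = structure.atom_coord(*a)
    pb = structure.atom_coord(*b)
    return float(np.linalg.norm(pa - pb))


def n360_h248_distances(structure: Structure) -> dict[str, float]:
    """The two cross-chain N360-H248 Calpha distances (CA- and CA* sides)."""
    return {
        "CA-": marker_distance(structure, ("A", presets.MARKER_ASN),
                               ("B", presets.MARKER_HIS)),
        "CA*": marker_distance(structure, ("B", presets.MARKER_ASN),
                               ("A", presets.MARKER_HIS)),
    }


# ---------------------------------------------------------------------------
# contacts and dissociation
# ---------------------------------------------------------------------------

def contact_series(traj: Trajectory, group_a, group_b,
                   mode: str = "mean", name: str = "contact") -> DescriptorSeries:
    """Per-frame mean (or min) over all cross-pair distances of two groups."""
    if mode not in ("mean", "min"):
        raise ValueError("mode must be 'mean' or 'min'")
    ia = group_a.resolve(traj.topology) if isinstance(group_a, Selection) else np.asarray(group_a)
    ib = group_b.resolve(traj.topology) if isinstance(group_b, Selection) else np.asarray(group_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("contact groups must be non-empty")
    diff = traj.coords[:, ia, None, :] - traj.coords[:, None, ib, :]
    dist = np.sqrt((diff * diff).sum(axis=-1)).reshape(traj.n_frames, -1)
    values = dist.mean(axis=1) if mode == "mean" else dist.min(axis=1)
    return DescriptorSeries(name=name, units="Angstrom", values=values,
                            times_ps=traj.times_ps.copy(),
                            provenance={"mode": mode})


@dataclass
class DissociationReport:
    intervals: list[tuple[float, float]]   # (start time, end time), ps
    final_value: float                     # A, last frame
    isolated_events: bool                  # above threshold only briefly


def dissociation_intervals(series: DescriptorSeries, threshold: float = 3.0,
                           min_duration: int = 1) -> DissociationReport:
    """Maximal runs above the dissociation threshold.

    Runs shorter than ``min_duration`` frames are dropped; when the total
    above-threshold fraction is below 5% and no run survives, the contact
    is flagged as showing only a few isolated dissociation events.
    """
    v = series.values
    if len(v) == 0:
        raise ValueError("empty series")
    above = v > threshold
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(v):
        if above[i]:
            j = i
            while j < len(v) and above[j]:
                j += 1
            runs.append((i, j - 1))
            i = j
        else:
            i += 1
    kept = [(a, b) for a, b in runs if b - a + 1 >= min_duration]
    isolated = (not kept) and 0 < above.mean() < 0.05
    times = series.times_ps
    return DissociationReport(
        intervals=[(float(times[a]), float(times[b])) for a, b in kept],
        final_value=float(v[-1]),
        isolated_events=bool(isolated),
    )


# ---------------------------------------------------------------------------
# flat-bottom distance restraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RestraintSpec:
    """Flat-bottom harmonic distance restraint on Calpha pairs.

    An ambiguous restraint combines its pair distances into one effective
    distance d_eff = (sum d_k^-6)^(-1/6) (optionally the minimum distance);
    the energy is zero inside [lower, upper] and half k (d - bound)^2
    outside the nearest bound. The force constant is in kcal/(mol A^2).
    """

    pairs: tuple[tuple[tuple[str, int], tuple[str, int]], ...]
    ambiguous: bool = False
    force_constant: float = 1.0
    lower: float = 0.0
    upper: float = np.inf
    combine: str = "r-6"   # or "min"

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("restraint needs at least one atom pair")
        if not self.lower < self.upper:
            raise ValueError("restraint requires lower < upper")


def _pair_distances(structure: Structure, spec: RestraintSpec) -> np.ndarray:
    return np.array([
        np.linalg.norm(structure.atom_coord(ca, ra) - structure.atom_coord(cb, rb))
        for (ca, ra), (cb, rb) in spec.pairs
    ])


def effective_distance(structure: Structure, spec: RestraintSpec) -> float:
    """Single-pair distance, or the ambiguous r^-6 combination (A).

    The r^-6 effective distance is always <= the minimum pair distance and
    approaches it as the other pairs recede.
    """
    d = _pair_distances(structure, spec)
    if len(d) == 1 or not spec.ambiguous:
        if len(d) > 1 and not spec.ambiguous:
            raise ValueError("multiple pairs require ambiguous=True")
        return float(d[0])
    if spec.combine == "min":
        return float(d.min())
    return float((d ** -6.0).sum() ** (-1.0 / 6.0))


def restraint_energy(structure: Structure, spec: RestraintSpec) -> float:
    """Flat-bottom harmonic energy (kcal/mol); zero inside the bounds."""
    d = effective_distance(structure, spec)
    if d < spec.lower:
        return 0.5 * spec.force_constant * (d - spec.lower) ** 2
    if d > spec.upper:
        return 0.5 * spec.force_constant * (d - spec.upper) ** 2
    return 0.0


def restraint_gradient(coords: np.ndarray, index_pairs: np.ndarray,
                       spec: RestraintSpec) -> np.ndarray:
    """Analytic gradient of the restraint energy wrt flat coordinates.

    ``index_pairs`` gives, per restraint pair, the two atom indices into
    ``coords`` (shape (n_atoms, 3)). Used by harmonic-network surrogates.
    """
    d = np.array([np.linalg.norm(coords[i] - coords[j]) for i, j in index_pairs])
    grad = np.zeros_like(coords)
    if spec.ambiguous and len(d) > 1 and spec.combine != "min":
        deff = (d ** -6.0).sum() ** (-1.0 / 6.0)
    else:
        deff = d.min() if (spec.ambiguous and len(d) > 1) else d[0]
    if spec.lower <= deff <= spec.upper:
        return grad
    bound = spec.lower if deff < spec.lower else spec.upper
    dE_ddeff = spec.force_constant * (deff - bound)
    if spec.ambiguous and len(d) > 1 and spec.combine != "min":
        # deff = s^(-1/6) with s = sum d_k^-6, so d(deff)/d(d_k) = s^(-7/6) d_k^-7
        s = (d ** -6.0).sum()
        weights = (s ** (-7.0 / 6.0)) * (d ** -7.0)
    elif spec.ambiguous and len(d) > 1:
        weights = (d == d.min()).astype(float)
    else:
        weights = np.ones(1)
    for (k, (i, j)) in enumerate(index_pairs):
        if weights[k] == 0:
            continue
        u = (coords[i] - coords[j]) / d[k]
        g = dE_ddeff * weights[k] * u
        grad[i] += g
        grad[j] -= g
    return grad


def _widened_bounds(spec: RestraintSpec, mode: str) -> tuple[float, float]:
    if mode == "width":
        w = 0.1 * (spec.upper - spec.lower)
        return spec.lower - w, spec.upper + w
    if mode == "relative":
        return 0.9 * spec.lower, 1.1 * spec.upper
    raise ValueError(f"unknown widening mode {mode!r}")


def violation_stats(traj: Trajectory, spec: RestraintSpec,
                    widen_mode: str = "width") -> tuple[float, float]:
    """(strict %, widened-10% %) of frames violating the restraint.

    Strict counts frames whose effective distance is outside
    [lower, upper]; widened counts frames outside the interval enlarged by
    10% of its width on each side (``widen_mode='relative'`` instead scales
    each bound by 10%). An ambiguous group counts once per frame.
    """
    lo_w, hi_w = _widened_bounds(spec, widen_mode)
    strict = widened = 0
    for frame in traj:
        d = effective_distance(frame, spec)
        if not (spec.lower <= d <= spec.upper):
            strict += 1
        if not (lo_w <= d <= hi_w):
            widened += 1
    n = traj.n_frames
    return 100.0 * strict / n, 100.0 * widened / n


def restraint_presets(name: str) -> list[RestraintSpec]:
    """The dbl / mid / tet HAMP inter-monomer restraint sets."""
    raw = presets.RESTRAINT_SETS[name]
    out = []
    for pairs, ambiguous, k, lower, upper in raw:
        out.append(RestraintSpec(pairs=tuple(pairs), ambiguous=ambiguous,
                                 force_constant=k, lower=lower, upper=upper))
    return out


# ---------------------------------------------------------------------------
# restraint table I/O (TSV mirroring the published table columns)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["resid1", "resid2", "force_constant", "lower_bound", "upper_bound"]


def write_restraints_tsv(specs: list[RestraintSpec], path: str | Path) -> None:
    rows = []
    for spec in specs:
        for i, ((ca, ra), (cb, rb)) in enumerate(spec.pairs):
            if i == 0:
                rows.append([f"{ca}-{ra}", f"{cb}-{rb}", spec.force_constant,
                             spec.lower, spec.upper])
            else:  # continuation row of an ambiguous group
                rows.append([f"{ca}-{ra}", f"{cb}-{rb}", "", "", ""])
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_restraints_tsv(path: str | Path) -> list[RestraintSpec]:
    """Read a restraint table; rows with blank constants continue an
    ambiguous group started by the previous full row."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    specs: list[RestraintSpec] = []
    current: dict | None = None

    def parse_atom(token: str) -> tuple[str, int]:
        chain, resid = token.replace(" ", "-").split("-", 1)
        return chain, int(resid)

    for _, row in df.iterrows():
        pair = (parse_atom(row["resid1"]), parse_atom(row["resid2"]))
        if row["force_constant"] != "":
            if current is not None:
                specs.append(RestraintSpec(**current))
            current = {
                "pairs": (pair,),
                "ambiguous": False,
                "force_constant": float(row["force_constant"]),
                "lower": float(row["lower_bound"]),
                "upper": float(row["upper_bound"]),
            }
        else:
            if current is None:
                raise ValueError("continuation row before any full restraint row")
            current["pairs"] = current["pairs"] + (pair,)
            current["ambiguous"] = True
    if current is not None:
        specs.append(RestraintSpec(**current))
    return specs
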