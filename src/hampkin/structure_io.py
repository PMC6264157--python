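"""Structures, trajectories, selections, superposition, RMSD and RMSF.

This module is the shared substrate of the package: a thin, ordered
atom-record container (chain id, residue number/name, atom name, element,
coordinates in Angstrom) with deterministic selections, least-squares rigid
superposition (Kabsch, proper rotations only), and the per-frame deviation /
fluctuation measures used by every descriptor module.

PDB reading and writing are delegated to biotite; residue numbering is kept
1-based exactly as in the file, insertion codes are rejected, and alternate
locations are resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

from .series import DescriptorSeries

__all__ = [
    "Structure",
    "Trajectory",
    "Selection",
    "PDBFormatError",
    "read_pdb",
    "read_trajectory",
    "write_pdb",
    "write_trajectory",
    "geometric_center",
    "superpose",
    "rmsd",
    "rmsd_series",
    "rmsf",
    "BACKBONE_ATOMS",
    "DEFAULT_FRAME_SPACING_PS",
]

#: heavy atoms of the protein backbone (standard reading)
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: frame spacing assumed when a trajectory container stores no times (ps)
DEFAULT_FRAME_SPACING_PS = 10.0


class PDBFormatError(ValueError):
    """Raised for malformed or unsupported PDB content."""


@dataclass
class Structure:
    """One frame: ordered labeled atoms with coordinates in Angstrom.

    Invariant: (chain, residue number, atom name) is unique and all
    coordinates are finite.
    """

    chain: np.ndarray          # (n,) str
    resid: np.ndarray          # (n,) int
    resname: np.ndarray        # (n,) str
    atom_name: np.ndarray      # (n,) str
    element: np.ndarray        # (n,) str
    coord: np.ndarray          # (n, 3) float64
    time_ps: float | None = None

    def __post_init__(self) -> None:
        n = len(self.chain)
        self.chain = np.asarray(self.chain, dtype="U4")
        self.resid = np.asarray(self.resid, dtype=np.int64)
        self.resname = np.asarray(self.resname, dtype="U5")
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.element = np.asarray(self.element, dtype="U2")
        self.coord = np.ascontiguousarray(self.coord, dtype=np.float64)
        if self.coord.shape != (n, 3):
            raise ValueError(f"coord shape {self.coord.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.chain)

    def copy(self) -> "Structure":
        return Structure(
            self.chain.copy(), self.resid.copy(), self.resname.copy(),
            self.atom_name.copy(), self.element.copy(), self.coord.copy(),
            self.time_ps,
        )

    def with_coord(self, coord: np.ndarray) -> "Structure":
        return replace(self, coord=np.asarray(coord, dtype=np.float64))

    def subset(self, indices: np.ndarray) -> "Structure":
        idx = np.asarray(indices)
        return Structure(
            self.chain[idx], self.resid[idx], self.resname[idx],
            self.atom_name[idx], self.element[idx], self.coord[idx],
            self.time_ps,
        )

    def atom_index(self, chain: str, resid: int, atom_name: str = "CA") -> int:
        """Index of a single atom; raises KeyError if absent."""
        mask = (
            (self.chain == chain)
            & (self.resid == int(resid))
            & (self.atom_name == atom_name)
        )
        hits = np.flatnonzero(mask)
        if len(hits) == 0:
            raise KeyError(f"atom {chain}-{resid}-{atom_name} not found")
        return int(hits[0])

    def atom_coord(self, chain: str, resid: int, atom_name: str = "CA") -> np.ndarray:
        return self.coord[self.atom_index(chain, resid, atom_name)]

    def key_table(self) -> dict[tuple[str, int, str], int]:
        return {
            (c, int(r), a): i
            for i, (c, r, a) in enumerate(zip(self.chain, self.resid, self.atom_name))
        }


@dataclass
class Selection:
    """Predicate over chains, residue-number ranges and atom names.

    Resolves to a deterministic ordered index list against a topology
    (file/atom order is preserved).
    """

    chains: tuple[str, ...] | None = None
    resid_ranges: tuple[tuple[int, int], ...] | None = None  # inclusive
    atom_names: tuple[str, ...] | None = None

    def resolve(self, structure: Structure) -> np.ndarray:
        mask = np.ones(structure.n_atoms, dtype=bool)
        if self.chains is not None:
            mask &= np.isin(structure.chain, list(self.chains))
        if self.resid_ranges is not None:
            rmask = np.zeros(structure.n_atoms, dtype=bool)
            for lo, hi in self.resid_ranges:
                rmask |= (structure.resid >= lo) & (structure.resid <= hi)
            mask &= rmask
        if self.atom_names is not None:
            mask &= np.isin(structure.atom_name, list(self.atom_names))
        return np.flatnonzero(mask)

    @staticmethod
    def ca(chains: Iterable[str] | None = None,
           resid_ranges: Iterable[tuple[int, int]] | None = None) -> "Selection":
        return Selection(
            chains=tuple(chains) if chains is not None else None,
            resid_ranges=tuple(tuple(r) for r in resid_ranges) if resid_ranges is not None else None,
            atom_names=("CA",),
        )

    @staticmethod
    def backbone(chains: Iterable[str] | None = None,
                 resid_ranges: Iterable[tuple[int, int]] | None = None) -> "Selection":
        return Selection(
            chains=tuple(chains) if chains is not None else None,
            resid_ranges=tuple(tuple(r) for r in resid_ranges) if resid_ranges is not None else None,
            atom_names=BACKBONE_ATOMS,
        )


@dataclass
class Trajectory:
    """Frames sharing one topology, with frame times in ps."""

    topology: Structure
    coords: np.ndarray               # (n_frames, n_atoms, 3)
    times_ps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} incompatible with topology "
                f"({self.topology.n_atoms} atoms)"
            )
        if self.times_ps is None:
            self.times_ps = np.arange(len(self.coords)) * DEFAULT_FRAME_SPACING_PS
        self.times_ps = np.asarray(self.times_ps, dtype=np.float64)
        if len(self.times_ps) != len(self.coords):
            raise ValueError("times length != number of frames")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    def frame(self, i: int) -> Structure:
        s = self.topology.with_coord(self.coords[i])
        s.time_ps = float(self.times_ps[i])
        return s

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _atom_array_to_structure(arr: bts.AtomArray) -> Structure:
    ins = arr.ins_code
    bad = np.flatnonzero(np.asarray(ins) != "")
    if len(bad):
        i = bad[0]
        raise PDBFormatError(
            f"insertion code {ins[i]!r} on residue {arr.chain_id[i]}-{arr.res_id[i]} "
            "is not supported"
        )
    return Structure(
        chain=arr.chain_id.astype("U4"),
        resid=arr.res_id.astype(np.int64),
        resname=arr.res_name.astype("U5"),
        atom_name=arr.atom_name.astype("U6"),
        element=arr.element.astype("U2"),
        coord=arr.coord.astype(np.float64),
    )


def _structure_to_atom_array(structure: Structure) -> bts.AtomArray:
    n = structure.n_atoms
    arr = bts.AtomArray(n)
    arr.chain_id = structure.chain.astype("U4")
    arr.res_id = structure.resid.astype(int)
    arr.res_name = structure.resname.astype("U5")
    arr.atom_name = structure.atom_name.astype("U6")
    arr.element = structure.element.astype("U2")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.coord = structure.coord.astype(np.float32)
    return arr


def _read_pdb_file(path: str | Path) -> PDBFile:
    try:
        return PDBFile.read(str(path))
    except Exception as exc:  # pragma: no cover - biotite message passthrough
        raise PDBFormatError(f"cannot parse PDB file {path}: {exc}") from exc


def read_pdb(path: str | Path, model: int = 1) -> Structure:
    """Read one model of a PDB file (highest-occupancy altloc, tie -> 'A')."""
    pdb = _read_pdb_file(path)
    try:
        arr = pdb.get_structure(model=model, altloc="occupancy",
                                extra_fields=[])
    except Exception as exc:
        raise PDBFormatError(f"cannot interpret PDB file {path}: {exc}") from exc
    return _atom_array_to_structure(arr)


def read_trajectory(path: str | Path,
                    topology: Structure | None = None,
                    frame_spacing_ps: float = DEFAULT_FRAME_SPACING_PS) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    All models must be congruent; if ``topology`` is given, every frame must
    carry exactly its atoms (checked by (chain, resid, atom name) keys).
    """
    pdb = _read_pdb_file(path)
    try:
        stack = pdb.get_structure(altloc="occupancy")
    except Exception as exc:
        raise PDBFormatError(f"cannot interpret PDB file {path}: {exc}") from exc
    if isinstance(stack, bts.AtomArray):  # single model
        stack = bts.stack([stack])
    first = _atom_array_to_structure(stack[0])
    if topology is not None:
        want = topology.key_table()
        have = first.key_table()
        missing = [k for k in want if k not in have]
        if missing:
            raise PDBFormatError(
                f"frame is missing {len(missing)} topology atoms, "
                f"first: {missing[0]}"
            )
        order = np.array([have[k] for k in want], dtype=int)
        coords = stack.coord[:, order, :].astype(np.float64)
        top = topology
    else:
        coords = stack.coord.astype(np.float64)
        top = first
    times = np.arange(len(coords)) * frame_spacing_ps
    return Trajectory(topology=top, coords=coords, times_ps=times)


def write_pdb(structure: Structure, path: str | Path) -> None:
    pdb = PDBFile()
    pdb.set_structure(_structure_to_atom_array(structure))
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    arrays = []
    for i in range(traj.n_frames):
        arr = _structure_to_atom_array(traj.topology)
        arr.coord = traj.coords[i].astype(np.float32)
        arrays.append(arr)
    pdb = PDBFile()
    pdb.set_structure(bts.stack(arrays))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def geometric_center(structure: Structure,
                     selection: Selection | np.ndarray | None = None) -> np.ndarray:
    """Unweighted mean of the selected coordinates.

    The gradient of the center with respect to each selected atom is 1/N times
    the identity (and zero elsewhere), which is what makes geometric centers
    convenient collective variables.
    """
    if selection is None:
        idx = np.arange(structure.n_atoms)
    elif isinstance(selection, Selection):
        idx = selection.resolve(structure)
    else:
        idx = np.asarray(selection)
    if len(idx) == 0:
        raise ValueError("empty selection has no geometric center")
    return structure.coord[idx].mean(axis=0)


def _match_selections(mobile: Structure, reference: Structure,
                      fit_selection: Selection) -> tuple[np.ndarray, np.ndarray]:
    """1:1 atom correspondence by (chain, resid, atom name) over a selection."""
    mob_idx = fit_selection.resolve(mobile)
    ref_idx = fit_selection.resolve(reference)
    ref_keys = {}
    for i in ref_idx:
        ref_keys[(reference.chain[i], int(reference.resid[i]),
                  reference.atom_name[i])] = i
    pairs_m, pairs_r = [], []
    missing = []
    for i in mob_idx:
        key = (mobile.chain[i], int(mobile.resid[i]), mobile.atom_name[i])
        j = ref_keys.pop(key, None)
        if j is None:
            missing.append(key)
        else:
            pairs_m.append(i)
            pairs_r.append(j)
    if missing or ref_keys:
        extra = sorted(ref_keys)
        raise ValueError(
            "fit selections do not map 1:1; "
            f"unmatched mobile atoms: {missing[:5]}; "
            f"unmatched reference atoms: {extra[:5]}"
        )
    return np.array(pairs_m, dtype=int), np.array(pairs_r, dtype=int)


def superpose(mobile: Structure, reference: Structure,
              fit_selection: Selection | None = None
              ) -> tuple[np.ndarray, np.ndarray, Structure]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, fitted)`` with ``fitted.coord =
    mobile.coord @ rotation.T + translation``. Rotations are proper
    (determinant +1); reflections are never returned.
    """
    if fit_selection is None:
        fit_selection = Selection()
    mi, ri = _match_selections(mobile, reference, fit_selection)
    if len(mi) < 3:
        raise ValueError(f"need >= 3 atoms to superpose, got {len(mi)}")
    x = mobile.coord[mi]
    y = reference.coord[ri]
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    rot, _ = Rotation.align_vectors(y - yc, x - xc)
    rmat = rot.as_matrix()
    t = yc - xc @ rmat.T
    fitted = mobile.with_coord(mobile.coord @ rmat.T + t)
    fitted.time_ps = mobile.time_ps
    return rmat, t, fitted


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain root-mean-square deviation of two matched coordinate sets."""
    d = np.asarray(a) - np.asarray(b)
    return float(np.sqrt((d * d).sum(axis=-1).mean()))


def rmsd_series(traj: Trajectory, reference: Structure,
                fit_selection: Selection | None = None,
                measure_selection: Selection | None = None,
                name: str = "rmsd") -> DescriptorSeries:
    """Per-frame fit onto the reference, then RMSD over the measured atoms.

    The default measured set is the fit set (Table-style domain RMSD:
    superimpose the analyzed region, measure it).
    """
    if fit_selection is None:
        fit_selection = Selection(atom_names=BACKBONE_ATOMS)
    if measure_selection is None:
        measure_selection = fit_selection
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj):
        _, _, fitted = superpose(frame, reference, fit_selection)
        mi, ri = _match_selections(fitted, reference, measure_selection)
        values[i] = rmsd(fitted.coord[mi], reference.coord[ri])
    return DescriptorSeries(name=name, units="Angstrom", values=values,
                            times_ps=traj.times_ps.copy())


def rmsf(traj: Trajectory, reference: Structure,
         fit_selection: Selection | None = None,
         measure_selection: Selection | None = None,
         group_by_residue: bool = False):
    """Root-mean-square fluctuation about the trajectory-mean position.

    Every frame is first superposed onto the reference over
    ``fit_selection``; fluctuations are then the RMS deviation of each
    measured atom from its mean fitted position. With ``group_by_residue``
    the per-atom values are averaged within each residue and returned as
    ``(labels, values)`` where labels are (chain, resid).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if fit_selection is None:
        fit_selection = Selection(atom_names=BACKBONE_ATOMS)
    if measure_selection is None:
        measure_selection = fit_selection
    midx = measure_selection.resolve(traj.topology)
    fitted_coords = np.empty((traj.n_frames, len(midx), 3))
    for i, frame in enumerate(traj):
        _, _, fitted = superpose(frame, reference, fit_selection)
        fitted_coords[i] = fitted.coord[midx]
    mean = fitted_coords.mean(axis=0)
    dev = fitted_coords - mean
    per_atom = np.sqrt((dev * dev).sum(axis=-1).mean(axis=0))
    if not group_by_residue:
        return midx, per_atom
    labels: list[tuple[str, int]] = []
    values: list[float] = []
    top = traj.topology
    seen: dict[tuple[str, int], list[float]] = {}
    order: list[tuple[str, int]] = []
    for k, ai in enumerate(midx):
        key = (str(top.chain[ai]), int(top.resid[ai]))
        if key not in seen:
            seen[key] = []
            order.append(key)
        seen[key].append(per_atom[k])
    for key in order:
        labels.append(key)
        values.append(float(np.mean(seen[key])))
    return labels, np.array(values)
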