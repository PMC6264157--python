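"""Temperature-accelerated dynamics on pluggable systems.

The physical coordinates x follow Langevin dynamics at thermal energy
beta^-1 under the extended potential

    U_kappa(x, z) = V(x) + 1/2 kappa ||theta(x) - z||^2,

while the collective-variable targets z follow overdamped dynamics at the
artificial thermal energy betabar^-1 with large friction gammabar:

    gammabar dz/dt = kappa (theta(x) - z) + sqrt(2 gammabar betabar^-1) eta(t).

With kappa stiff and gammabar large, z(t) samples the free-energy surface
F(z) of the physical system at the artificial temperature, which is what
accelerates barrier crossing. Units are kcal/mol, A and ps throughout, with
thermal energies given directly in kcal/mol.

The x-equation is integrated with the BAOAB Langevin splitting, the
z-equation with Euler-Maruyama (it has no inertial term). Systems are
pluggable: analytic toy potentials (harmonic well, double well) and a
coarse harmonic-network surrogate of the synthetic dimer with
geometric-center collective variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import presets
from .structure_io import Selection, Structure

__all__ = [
    "SystemModel",
    "TAMDParams",
    "TAMDState",
    "TAMDRecord",
    "harmonic_system",
    "double_well_system",
    "harmonic_network_system",
    "hdc_cv_groups",
    "extended_potential",
    "step",
    "run_tamd",
    "transition_count",
    "calibrate_gamma_bar",
    "free_energy_estimate",
]


@dataclass
class SystemModel:
    """Potential, gradient, collective-variable map and masses."""

    dim: int
    potential: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    cv: Callable[[np.ndarray], np.ndarray] | None = None       # default: identity
    cv_jacobian: Callable[[np.ndarray], np.ndarray] | None = None
    masses: np.ndarray | None = None
    n_cv: int | None = None
    # optional scalar variants (float -> float) enabling the fast 1-D loop
    potential_scalar: Callable[[float], float] | None = None
    gradient_scalar: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.masses is None:
            self.masses = np.ones(self.dim)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.cv is None:
            self.n_cv = self.dim
        elif self.n_cv is None:
            self.n_cv = len(np.atleast_1d(self.cv(np.zeros(self.dim))))

    def theta(self, x: np.ndarray) -> np.ndarray:
        return x if self.cv is None else np.atleast_1d(self.cv(x))

    def jacobian(self, x: np.ndarray) -> np.ndarray | None:
        """CV Jacobian (n_cv, dim); None means identity."""
        if self.cv is None:
            return None
        if self.cv_jacobian is None:
            raise ValueError("system defines cv but no cv_jacobian")
        return self.cv_jacobian(x)

    def check_gradient(self, x: np.ndarray, h: float = 1e-5,
                       rtol: float = 1e-4) -> bool:
        """Central finite-difference consistency of gradient with potential."""
        x = np.asarray(x, dtype=float)
        g = self.gradient(x)
        num = np.empty_like(g)
        for i in range(self.dim):
            e = np.zeros(self.dim)
            e[i] = h
            num[i] = (self.potential(x + e) - self.potential(x - e)) / (2 * h)
        scale = max(np.abs(num).max(), 1e-8)
        return bool(np.abs(g - num).max() <= rtol * scale + 1e-8)


@dataclass
class TAMDParams:
    """Thermostat, spring and integration constants."""

    kappa: float = presets.KAPPA          # kcal/(mol unit^2), CV spring
    gamma: float = presets.GAMMA          # ps^-1, physical friction
    beta_inv: float = presets.BETA_INV    # kcal/mol, physical thermal energy
    gamma_bar: float = 50.0               # energy.time/unit^2, CV friction
    beta_bar_inv: float = 15.0            # kcal/mol, artificial thermal energy
    dt: float = 0.002                     # ps
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "beta_inv", "gamma_bar",
                     "beta_bar_inv", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TAMDState:
    x: np.ndarray
    v: np.ndarray
    z: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        self.z = np.atleast_1d(np.asarray(self.z, dtype=float))


def extended_potential(x: np.ndarray, z: np.ndarray,
                       system: SystemModel, params: TAMDParams) -> float:
    """U = V(x) + 1/2 kappa ||theta(x) - z||^2 (kcal/mol)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if len(x) != system.dim or len(z) != system.n_cv:
        raise ValueError(
            f"shape mismatch: x has {len(x)} (dim {system.dim}), "
            f"z has {len(z)} (n_cv {system.n_cv})")
    diff = system.theta(x) - z
    return float(system.potential(x) + 0.5 * params.kappa * np.dot(diff, diff))


def _force(x: np.ndarray, z: np.ndarray, system: SystemModel,
           params: TAMDParams) -> np.ndarray:
    f = -system.gradient(x)
    diff = system.theta(x) - z
    jac = system.jacobian(x)
    if jac is None:
        f = f - params.kappa * diff
    else:
        f = f - params.kappa * (diff @ jac)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite forces during integration")
    return f


def step(state: TAMDState, system: SystemModel, params: TAMDParams,
         rng: np.random.Generator | None = None,
         noise_x: np.ndarray | None = None,
         noise_z: np.ndarray | None = None,
         evolve_z: bool = True) -> TAMDState:
    """One BAOAB step of x/v and one Euler-Maruyama step of z.

    Noise draws may be passed explicitly (standard normals); with a
    generator they are drawn in the order (x-noise, z-noise). Setting both
    noises to zero gives the deterministic drift (in particular z is
    unchanged whenever theta(x) == z).
    """
    if rng is None and (noise_x is None or (noise_z is None and evolve_z)):
        rng = np.random.default_rng(params.seed)
    m = system.masses
    dt = params.dt
    c1 = np.exp(-params.gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * params.beta_inv / m)
    if noise_x is None:
        noise_x = rng.standard_normal(system.dim)
    x = state.x.copy()
    v = state.v.copy()
    z = state.z.copy()

    f = _force(x, z, system, params)
    v += 0.5 * dt * f / m
    x += 0.5 * dt * v
    v = c1 * v + c2 * noise_x
    x += 0.5 * dt * v
    f = _force(x, z, system, params)
    v += 0.5 * dt * f / m

    if evolve_z:
        if noise_z is None:
            noise_z = rng.standard_normal(system.n_cv)
        diff = system.theta(x) - z
        z += (dt / params.gamma_bar) * params.kappa * diff
        z += np.sqrt(2.0 * dt * params.beta_bar_inv / params.gamma_bar) * noise_z
    return TAMDState(x=x, v=v, z=z, t=state.t + dt)


@dataclass
class TAMDRecord:
    """Strided record of a run: times, CV values, targets and energies."""

    times: np.ndarray        # ps
    theta: np.ndarray        # (n_records, n_cv)
    z: np.ndarray            # (n_records, n_cv)
    u: np.ndarray            # kcal/mol, extended potential
    x: np.ndarray | None = None   # (n_records, dim), small systems only
    v2_mean: float = np.nan  # time-averaged v.v/dim (equipartition check)


def run_tamd(system: SystemModel, params: TAMDParams, n_steps: int,
             record_every: int = 10, x0: np.ndarray | None = None,
             z0: np.ndarray | None = None, evolve_z: bool = True,
             store_x: bool | None = None) -> TAMDRecord:
    """Integrate the extended dynamics and record at the given stride.

    Fully reproducible under ``params.seed``; velocities start from the
    physical Maxwell distribution and z from theta(x0) unless given.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(params.seed)
    m = system.masses
    dt = params.dt
    x = np.zeros(system.dim) if x0 is None else np.atleast_1d(np.asarray(x0, float)).copy()
    v = rng.standard_normal(system.dim) * np.sqrt(params.beta_inv / m)
    z = system.theta(x).astype(float).copy() if z0 is None else np.atleast_1d(np.asarray(z0, float)).copy()
    if store_x is None:
        store_x = system.dim <= 8

    if (system.dim == 1 and system.cv is None
            and system.gradient_scalar is not None
            and system.potential_scalar is not None):
        return _run_tamd_1d(system, params, n_steps, record_every, rng,
                            float(x[0]), float(v[0]), float(z[0]),
                            evolve_z, store_x)

    c1 = np.exp(-params.gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * params.beta_inv / m)
    z_noise_amp = np.sqrt(2.0 * dt * params.beta_bar_inv / params.gamma_bar)
    kdg = dt * params.kappa / params.gamma_bar

    n_rec = n_steps // record_every
    times = np.empty(n_rec)
    theta_rec = np.empty((n_rec, system.n_cv))
    z_rec = np.empty((n_rec, system.n_cv))
    u_rec = np.empty(n_rec)
    x_rec = np.empty((n_rec, system.dim)) if store_x else None

    grad = system.gradient
    pot = system.potential
    identity_cv = system.cv is None
    kappa = params.kappa
    v2_sum = 0.0

    chunk = 8192
    k_rec = 0
    i = 0
    while i < n_steps:
        nblock = min(chunk, n_steps - i)
        nx = rng.standard_normal((nblock, system.dim))
        nz = rng.standard_normal((nblock, system.n_cv)) if evolve_z else None
        for b in range(nblock):
            if identity_cv:
                diff = x - z
                f = -grad(x) - kappa * diff
            else:
                diff = system.theta(x) - z
                f = -grad(x) - kappa * (diff @ system.jacobian(x))
            v += 0.5 * dt * f / m
            x += 0.5 * dt * v
            v = c1 * v + c2 * nx[b]
            x += 0.5 * dt * v
            if identity_cv:
                diff = x - z
                f = -grad(x) - kappa * diff
            else:
                diff = system.theta(x) - z
                f = -grad(x) - kappa * (diff @ system.jacobian(x))
            v += 0.5 * dt * f / m
            if evolve_z:
                z = z + kdg * diff + z_noise_amp * nz[b]
            v2_sum += float(v @ v)
            i += 1
            if i % record_every == 0 and k_rec < n_rec:
                times[k_rec] = i * dt
                th = x if identity_cv else system.theta(x)
                theta_rec[k_rec] = th
                z_rec[k_rec] = z
                u_rec[k_rec] = pot(x) + 0.5 * kappa * float((th - z) @ (th - z))
                if store_x:
                    x_rec[k_rec] = x
                k_rec += 1
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite coordinates at step {i}")
    return TAMDRecord(times=times, theta=theta_rec, z=z_rec, u=u_rec,
                      x=x_rec, v2_mean=v2_sum / (n_steps * system.dim))


def _run_tamd_1d(system: SystemModel, params: TAMDParams, n_steps: int,
                 record_every: int, rng: np.random.Generator,
                 x: float, v: float, z: float,
                 evolve_z: bool, store_x: bool) -> TAMDRecord:
    """Scalar-arithmetic loop for 1-D identity-CV systems (same scheme)."""
    import math

    dt = params.dt
    m = float(system.masses[0])
    c1 = math.exp(-params.gamma * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * params.beta_inv / m)
    z_amp = math.sqrt(2.0 * dt * params.beta_bar_inv / params.gamma_bar)
    kdg = dt * params.kappa / params.gamma_bar
    kappa = params.kappa
    grad = system.gradient_scalar
    pot = system.potential_scalar
    half = 0.5 * dt

    n_rec = n_steps // record_every
    times = np.empty(n_rec)
    theta_rec = np.empty((n_rec, 1))
    z_rec = np.empty((n_rec, 1))
    u_rec = np.empty(n_rec)
    x_rec = np.empty((n_rec, 1)) if store_x else None

    v2_sum = 0.0
    k_rec = 0
    i = 0
    chunk = 65536
    while i < n_steps:
        nblock = min(chunk, n_steps - i)
        nx = rng.standard_normal(nblock)
        nz = rng.standard_normal(nblock) if evolve_z else None
        for b in range(nblock):
            f = -grad(x) - kappa * (x - z)
            v += half * f / m
            x += half * v
            v = c1 * v + c2 * nx[b]
            x += half * v
            f = -grad(x) - kappa * (x - z)
            v += half * f / m
            if evolve_z:
                z += kdg * (x - z) + z_amp * nz[b]
            v2_sum += v * v
            i += 1
            if i % record_every == 0 and k_rec < n_rec:
                times[k_rec] = i * dt
                theta_rec[k_rec, 0] = x
                z_rec[k_rec, 0] = z
                d = x - z
                u_rec[k_rec] = pot(x) + 0.5 * kappa * d * d
                if store_x:
                    x_rec[k_rec, 0] = x
                k_rec += 1
        if not math.isfinite(x):
            raise FloatingPointError(f"non-finite coordinates at step {i}")
    return TAMDRecord(times=times, theta=theta_rec, z=z_rec, u=u_rec,
                      x=x_rec, v2_mean=v2_sum / n_steps)


def transition_count(z_series: np.ndarray, center: float = 0.0) -> int:
    """Number of sign changes of (z - center) along a 1-D record."""
    s = np.sign(np.asarray(z_series).ravel() - center)
    s = s[s != 0]
    return int(np.sum(s[1:] != s[:-1]))


@dataclass
class GammaBarCalibration:
    """Running averages G_j(N) of the restraining force, per CV component."""

    times: np.ndarray     # ps
    g: np.ndarray         # (n_records, n_cv), kcal/(mol unit)
    last_quarter_sd: np.ndarray  # convergence diagnostic per CV

    @property
    def limits(self) -> np.ndarray:
        return self.g[-1]


def calibrate_gamma_bar(system: SystemModel, params: TAMDParams,
                        z_fixed: np.ndarray, duration_ps: float,
                        record_every: int = 1,
                        x0: np.ndarray | None = None) -> GammaBarCalibration:
    """Restrained-force running average used to choose the CV friction.

    The collective variables are held at ``z_fixed`` while the physical
    system evolves; G_j(N) = (kappa/N) sum_i [theta_j(x(t_i)) - z_j] is
    returned per component together with the standard deviation of its last
    quarter as a convergence diagnostic. For a harmonic system of stiffness
    k_w displaced by delta, G converges to -k_w kappa delta / (k_w + kappa).
    """
    if duration_ps < 10.0:
        raise ValueError("calibration needs at least 10 ps")
    n_steps = int(round(duration_ps / params.dt))
    z_fixed = np.atleast_1d(np.asarray(z_fixed, dtype=float))
    rec = run_tamd(system, params, n_steps, record_every=record_every,
                   x0=x0, z0=z_fixed, evolve_z=False, store_x=False)
    force = params.kappa * (rec.theta - z_fixed)
    g = np.cumsum(force, axis=0) / np.arange(1, len(force) + 1)[:, None]
    q = len(g) // 4
    sd = g[-q:].std(axis=0) if q >= 2 else np.full(g.shape[1], np.nan)
    return GammaBarCalibration(times=rec.times, g=g, last_quarter_sd=sd)


def free_energy_estimate(z_record: np.ndarray, bins: int,
                         beta_bar_inv: float) -> tuple[np.ndarray, np.ndarray]:
    """F(z) = -betabar^-1 ln p(z) + const from a 1-D target record.

    The minimum is shifted to zero; empty bins interior to the sampled
    range are masked (NaN) with a warning.
    """
    z = np.asarray(z_record).ravel()
    if len(z) < 10_000:
        raise ValueError("free-energy estimate needs >= 1e4 samples")
    hist, edges = np.histogram(z, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    f = np.full(len(hist), np.nan)
    nonzero = hist > 0
    f[nonzero] = -beta_bar_inv * np.log(hist[nonzero])
    interior_empty = np.flatnonzero(~nonzero)
    interior_empty = interior_empty[
        (interior_empty > np.flatnonzero(nonzero)[0])
        & (interior_empty < np.flatnonzero(nonzero)[-1])]
    if len(interior_empty):
        warnings.warn(f"{len(interior_empty)} empty bins interior to the "
                      "sampled range were masked")
    f -= np.nanmin(f)
    return centers, f


# ---------------------------------------------------------------------------
# systems
# ---------------------------------------------------------------------------

def harmonic_system(k_w: float, x0: float = 0.0, dim: int = 1) -> SystemModel:
    """V = 1/2 k_w ||x - x0||^2 with identity CV."""
    x0v = np.full(dim, float(x0))

    def pot(x):
        d = x - x0v
        return 0.5 * k_w * float(d @ d)

    kwargs = {}
    if dim == 1:
        kwargs = {
            "potential_scalar": lambda x: 0.5 * k_w * (x - x0) ** 2,
            "gradient_scalar": lambda x: k_w * (x - x0),
        }
    return SystemModel(dim=dim, potential=pot,
                       gradient=lambda x: k_w * (x - x0v), **kwargs)


def double_well_system(h: float = 6.0) -> SystemModel:
    """1-D double well V = h (x^2 - 1)^2 with minima at +-1 and barrier h."""

    def pot(x):
        q = x[0] * x[0] - 1.0
        return h * q * q

    def grad(x):
        return np.array([4.0 * h * x[0] * (x[0] * x[0] - 1.0)])

    return SystemModel(
        dim=1, potential=pot, gradient=grad,
        potential_scalar=lambda x: h * (x * x - 1.0) ** 2,
        gradient_scalar=lambda x: 4.0 * h * x * (x * x - 1.0),
    )


def hdc_cv_groups(structure: Structure) -> tuple[list[np.ndarray], list[str]]:
    """Atom-index groups of the H/D/C geometric-center collective variables.

    H: the four HAMP helices (CV residue set) per chain; D: the four DHp
    helices; C: the two CA domains. Returns (index groups, labels).
    """
    groups, labels = [], []
    for chain in ("A", "B"):
        for label, rng in zip(("HAMP1", "HAMP2"), presets.HAMP_CV_RANGES):
            groups.append(Selection.ca((chain,), (rng,)).resolve(structure))
            labels.append(f"{label}{chain}")
        for label, rng in zip(("DHp1", "DHp2"), presets.DHP_CV_RANGES):
            groups.append(Selection.ca((chain,), (rng,)).resolve(structure))
            labels.append(f"{label}{chain}")
    for chain in ("A", "B"):
        groups.append(Selection.ca((chain,), (presets.CA_CV_RANGE,)).resolve(structure))
        labels.append(f"CA{chain}")
    for g, lbl in zip(groups, labels):
        if len(g) == 0:
            raise ValueError(f"CV group {lbl} resolves to no atoms")
    return groups, labels


def harmonic_network_system(structure: Structure,
                            cutoff: float = 10.0,
                            k_spring: float = 1.0,
                            cv_groups: Sequence[np.ndarray] | None = None,
                            restraints=None) -> SystemModel:
    """Coarse elastic-network surrogate with geometric-center CVs.

    Calpha atoms interact through harmonic springs (stiffness ``k_spring``
    kcal/(mol A^2)) between all pairs closer than ``cutoff`` in the input
    conformation; optional flat-bottom restraints from
    :mod:`hampkin.architecture_metrics` are added. Collective variables are
    the geometric centers of ``cv_groups`` (default: the H/D/C set), three
    components each.
    """
    from .architecture_metrics import RestraintSpec, restraint_gradient  # local import

    ca_idx = Selection(atom_names=("CA",)).resolve(structure)
    ref = structure.coord[ca_idx].copy()
    n = len(ca_idx)
    dim = 3 * n
    # neighbor list from the reference conformation
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
    ii, jj = np.where((d2 < cutoff ** 2) & (np.arange(n)[:, None] < np.arange(n)[None, :]))
    d0 = np.sqrt(d2[ii, jj])

    # map original atom indices -> position within the Calpha subset
    pos_of = {int(a): k for k, a in enumerate(ca_idx)}
    if cv_groups is None:
        groups, _ = hdc_cv_groups(structure)
    else:
        groups = list(cv_groups)
    groups_ca = [np.array([pos_of[int(a)] for a in g]) for g in groups]
    n_cv = 3 * len(groups_ca)

    restraint_pairs = []
    if restraints:
        sub = structure.subset(ca_idx)
        for spec in restraints:
            idx_pairs = np.array([
                [sub.atom_index(ca, ra), sub.atom_index(cb, rb)]
                for (ca, ra), (cb, rb) in spec.pairs])
            restraint_pairs.append((spec, idx_pairs))

    def pot(xflat: np.ndarray) -> float:
        c = xflat.reshape(n, 3)
        d = np.linalg.norm(c[ii] - c[jj], axis=1)
        e = 0.5 * k_spring * float(((d - d0) ** 2).sum())
        for spec, idx_pairs in restraint_pairs:
            dd = np.linalg.norm(c[idx_pairs[:, 0]] - c[idx_pairs[:, 1]], axis=1)
            if spec.ambiguous and len(dd) > 1 and spec.combine != "min":
                deff = float((dd ** -6.0).sum() ** (-1.0 / 6.0))
            elif spec.ambiguous and len(dd) > 1:
                deff = float(dd.min())
            else:
                deff = float(dd[0])
            if deff < spec.lower:
                e += 0.5 * spec.force_constant * (deff - spec.lower) ** 2
            elif deff > spec.upper:
                e += 0.5 * spec.force_constant * (deff - spec.upper) ** 2
        return e

    def grad(xflat: np.ndarray) -> np.ndarray:
        c = xflat.reshape(n, 3)
        delta = c[ii] - c[jj]
        d = np.linalg.norm(delta, axis=1)
        gpair = (k_spring * (d - d0) / d)[:, None] * delta
        g = np.zeros((n, 3))
        np.add.at(g, ii, gpair)
        np.add.at(g, jj, -gpair)
        for spec, idx_pairs in restraint_pairs:
            g += restraint_gradient(c, idx_pairs, spec)
        return g.ravel()

    def cv(xflat: np.ndarray) -> np.ndarray:
        c = xflat.reshape(n, 3)
        return np.concatenate([c[g].mean(axis=0) for g in groups_ca])

    jac = np.zeros((n_cv, dim))
    for gi, g in enumerate(groups_ca):
        for a in g:
            for k in range(3):
                jac[3 * gi + k, 3 * a + k] = 1.0 / len(g)

    system = SystemModel(dim=dim, potential=pot, gradient=grad,
                         cv=cv, cv_jacobian=lambda x: jac, n_cv=n_cv)
    system.x_ref = ref.ravel()  # convenient starting point for run_tamd
    return system
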