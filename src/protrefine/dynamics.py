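"""Gradient-based minimization and short Langevin relaxation.

A 4 fs timestep is made stable by hydrogen-mass repartitioning (hydrogen
mass raised to 3 amu, borrowed from the bonded heavy atom) combined with
iterative projection (SHAKE/RATTLE-style) constraints on X-H bond lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .energy import EnergyParams, SystemTopology
from .pdb_model import StructureModel

__all__ = ["MDSettings", "minimize", "md_relax", "MDDivergenceError"]

KB = 0.0019872041        # kcal/mol/K
ACC = 4.184e-4           # (kcal/mol/A)/amu -> A/fs^2
H_REPARTITION_MASS = 3.0  # amu


class MDDivergenceError(RuntimeError):
    pass


@dataclass
class MDSettings:
    timestep_fs: float = 4.0
    duration_ps: float = 0.6
    temperature: float = 300.0
    friction_per_ps: float = 5.0
    seed: int = 0
    constraints: str = "h-bonds"   # "h-bonds" | "none"

    def __post_init__(self):
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.duration_ps < 0:
            raise ValueError("duration must be non-negative")

    @property
    def n_steps(self) -> int:
        return int(round(1000.0 * self.duration_ps / self.timestep_fs))


def _repartitioned_masses(topo: SystemTopology, scheme: str) -> np.ndarray:
    masses = topo.masses.copy()
    if scheme != "h-bonds":
        return masses
    for (a, b), _b0 in zip(topo.bond_idx, topo.bond_b0):
        ea, eb = topo.elements[a], topo.elements[b]
        if ea == "H" and eb != "H":
            delta = H_REPARTITION_MASS - masses[a]
            masses[a] += delta
            masses[b] -= delta
        elif eb == "H" and ea != "H":
            delta = H_REPARTITION_MASS - masses[b]
            masses[b] += delta
            masses[a] -= delta
    return masses


def _h_constraints(topo: SystemTopology):
    idx, d0 = [], []
    for (a, b), b0 in zip(topo.bond_idx, topo.bond_b0):
        if (topo.elements[a] == "H") != (topo.elements[b] == "H"):
            idx.append((a, b))
            d0.append(b0)
    return np.array(idx, int).reshape(-1, 2), np.array(d0)


def _shake(xyz, cons_idx, cons_d0, inv_mass, tol=1e-8, max_iter=200):
    """Iterative projection of bond-length constraints onto positions."""
    for _ in range(max_iter):
        worst = 0.0
        for (a, b), d0 in zip(cons_idx, cons_d0):
            d = xyz[a] - xyz[b]
            r2 = float(d @ d)
            diff = r2 - d0 * d0
            worst = max(worst, abs(diff))
            if abs(diff) < tol:
                continue
            g = diff / (2.0 * r2 * (inv_mass[a] + inv_mass[b]))
            xyz[a] -= g * inv_mass[a] * d
            xyz[b] += g * inv_mass[b] * d
        if worst < tol:
            break
    return xyz


def _rattle_velocities(vel, xyz, cons_idx, inv_mass):
    for _ in range(50):
        worst = 0.0
        for (a, b) in cons_idx:
            d = xyz[a] - xyz[b]
            r2 = float(d @ d)
            rv = float(d @ (vel[a] - vel[b]))
            worst = max(worst, abs(rv))
            g = rv / (r2 * (inv_mass[a] + inv_mass[b]))
            vel[a] -= g * inv_mass[a] * d
            vel[b] += g * inv_mass[b] * d
        if worst < 1e-10:
            break
    return vel


def minimize(model: StructureModel, reference: StructureModel,
             params: EnergyParams | None = None, regime: str = "mild",
             max_steps: int = 200):
    """L-BFGS minimization of the composite energy.

    Returns (minimized model, final EnergyBreakdown).  The energy along
    accepted iterates is non-increasing; iteration stops at `max_steps`
    or when the gradient infinity-norm falls below 1e-3 kcal/mol/A.
    """
    params = params or EnergyParams()
    topo = SystemTopology(model, params)
    ref_xyz = reference.coords()
    w_rst = params.w_rst(regime)
    x0 = model.coords()

    bd0, _ = topo.evaluate(x0, ref_xyz=ref_xyz, w_rst=w_rst,
                           compute_grad=False)
    if not np.isfinite(bd0.total):
        raise ValueError("non-finite energy at minimization input")
    if max_steps <= 0:
        return model.copy(), bd0

    shape = x0.shape

    def fun(flat):
        bd, grad = topo.evaluate(flat.reshape(shape), ref_xyz=ref_xyz,
                                 w_rst=w_rst)
        return bd.total, grad.ravel()

    res = _scipy_minimize(fun, x0.ravel(), jac=True, method="L-BFGS-B",
                          options={"maxiter": max_steps, "gtol": 1e-3,
                                   "ftol": 1e-16})
    out = model.copy()
    out.set_coords(res.x.reshape(shape))
    bd, _ = topo.evaluate(res.x.reshape(shape), ref_xyz=ref_xyz,
                          w_rst=w_rst, compute_grad=False)
    if bd.total > bd0.total + 1e-9:
        # line search failed to improve; keep the input
        return model.copy(), bd0
    return out, bd


def md_relax(model: StructureModel, reference: StructureModel,
             params: EnergyParams | None = None, regime: str = "mild",
             settings: MDSettings | None = None) -> StructureModel:
    """Short Langevin dynamics on the composite energy (BAOAB splitting).

    Bit-reproducible for a fixed seed; raises MDDivergenceError if the
    energy magnitude exceeds 1e9 kcal/mol.
    """
    params = params or EnergyParams()
    settings = settings or MDSettings()
    n_steps = settings.n_steps
    out = model.copy()
    if n_steps == 0:
        return out
    topo = SystemTopology(model, params)
    ref_xyz = reference.coords()
    w_rst = params.w_rst(regime)
    masses = _repartitioned_masses(topo, settings.constraints)
    inv_mass = 1.0 / masses
    cons_idx, cons_d0 = _h_constraints(topo)
    use_cons = settings.constraints == "h-bonds" and len(cons_idx) > 0

    dt = settings.timestep_fs
    kt = KB * settings.temperature
    gamma = settings.friction_per_ps / 1000.0  # 1/fs
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    rng = np.random.default_rng(settings.seed)

    xyz = out.coords()
    vel = rng.normal(size=xyz.shape) * np.sqrt(kt * inv_mass * ACC)[:, None]
    bd, grad = topo.evaluate(xyz, ref_xyz=ref_xyz, w_rst=w_rst)
    force = -grad

    for _ in range(n_steps):
        vel += 0.5 * dt * force * (inv_mass * ACC)[:, None]
        xyz += 0.5 * dt * vel
        if use_cons:
            xyz = _shake(xyz, cons_idx, cons_d0, inv_mass)
        if gamma > 0:
            noise = rng.normal(size=vel.shape)
            vel = c1 * vel + c2 * np.sqrt(kt * inv_mass * ACC)[:, None] \
                * noise
        xyz += 0.5 * dt * vel
        if use_cons:
            xyz = _shake(xyz, cons_idx, cons_d0, inv_mass)
        bd, grad = topo.evaluate(xyz, ref_xyz=ref_xyz, w_rst=w_rst)
        force = -grad
        vel += 0.5 * dt * force * (inv_mass * ACC)[:, None]
        if use_cons:
            vel = _rattle_velocities(vel, xyz, cons_idx, inv_mass)
        if not np.all(np.isfinite(xyz)) or abs(bd.total) > 1e9:
            raise MDDivergenceError(
                f"energy diverged during MD (total={bd.total:.3g})")
    out.set_coords(xyz)
    return out


def kinetic_energy(vel: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy in kcal/mol for velocities in A/fs."""
    return float(0.5 * np.sum(masses[:, None] * vel * vel) / ACC)
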