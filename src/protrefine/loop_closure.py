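"""Analytic triaxial loop closure.

Given a chain segment with fixed end stems and three pivot residues, solve
for the pivot (phi, psi) torsions that reconnect the segment to the C-side
stem exactly, while all other torsions (including every omega) keep their
current values.

Geometry: with non-pivot torsions frozen, the three pivot CA atoms form a
triangle with fixed side lengths whose two outer vertices are anchored in
space, so the middle CA moves on a circle (one parameter, sigma).  For
each sigma the carbonyl carbon of pivot 1 and the amide nitrogen of pivot
3 each lie on a cone/sphere intersection with at most two solutions, and
one scalar condition remains: the N-CA-C bond angle at pivot 2.  Scanning
sigma over the circle for each of the four branch combinations and
root-polishing yields all closure solutions (at most 16).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .geometry import angle as bond_angle
from .geometry import dihedral, kabsch, rotation_about_axis, wrap_angle
from .pdb_model import StructureModel, set_torsion

__all__ = ["ClosureProblem", "ClosureSolution", "triaxial_close",
           "apply_closure_solution", "perturb_and_close",
           "CLOSURE_TOLERANCE"]

CLOSURE_TOLERANCE = 1e-6  # A, max stem-atom deviation
_N_SCAN = 256


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class ClosureSolution:
    """Pivot torsions that close the segment."""

    pivot_torsions: list        # [(phi, psi)] for the three pivots, degrees
    residual: float             # A, max deviation of the C-side stem
    torsion_distance: float     # degrees, L2 distance from the input state


@dataclass
class ClosureProblem:
    """A chain segment, three pivots, and the target C-side stem.

    `model` carries the current (possibly perturbed) conformation whose
    internal geometry is held rigid except at the pivots.  `target_stem`
    holds the N/CA/C coordinates of the residue after the segment that the
    solved chain must reproduce.
    """

    model: StructureModel
    segment: tuple              # (first, last) residue indices, inclusive
    pivots: tuple               # three residue indices inside the segment
    target_stem: np.ndarray = field(default=None)  # (3,3): N, CA, C of e+1

    def __post_init__(self):
        s, e = self.segment
        p1, p2, p3 = self.pivots
        if not (0 < s <= e < len(self.model.residues) - 1):
            raise ValueError("segment must leave one stem residue on "
                             "each side")
        if not (s <= p1 < p2 < p3 <= e):
            raise ValueError("pivots must be strictly increasing and "
                             "inside the segment")
        for p in self.pivots:
            if self.model.residues[p].resname == "PRO":
                raise ValueError("proline cannot serve as a closure pivot")
        if self.target_stem is None:
            res = self.model.residues[e + 1]
            self.target_stem = np.array([res.coord("N"), res.coord("CA"),
                                         res.coord("C")])
        self.target_stem = np.asarray(self.target_stem, float)
        for tri in (self._stem_coords(s - 1), self.target_stem):
            d = np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
            if d < 1e-6:
                raise DegenerateGeometryError("collinear stem geometry")

    def _stem_coords(self, i):
        res = self.model.residues[i]
        return np.array([res.coord("N"), res.coord("CA"), res.coord("C")])


# ---------------------------------------------------------------------------
# Fast backbone-only kinematics for residual evaluation and polishing
# ---------------------------------------------------------------------------

class _BackboneSegment:
    """N/CA/C coordinates of residues s-1 .. e+1 with pivot torsions as
    the only degrees of freedom."""

    def __init__(self, problem: ClosureProblem):
        s, e = problem.segment
        self.s = s
        self.offset = s - 1
        self.coords0 = np.array([
            [problem.model.residues[i].coord(nm) for nm in ("N", "CA", "C")]
            for i in range(s - 1, e + 2)])
        self.pivots = [p - self.offset for p in problem.pivots]
        self.n_res = self.coords0.shape[0]
        self.target = problem.target_stem

    def current_torsions(self, coords):
        out = []
        for ip in self.pivots:
            phi = dihedral(coords[ip - 1, 2], coords[ip, 0],
                           coords[ip, 1], coords[ip, 2])
            psi = dihedral(coords[ip, 0], coords[ip, 1],
                           coords[ip, 2], coords[ip + 1, 0])
            out.extend([phi, psi])
        return np.array(out)

    def apply(self, tors6):
        """Return backbone coordinates with the six pivot torsions set."""
        c = self.coords0.copy()
        k = 0
        for ip in self.pivots:
            for kind in ("phi", "psi"):
                target = tors6[k]
                k += 1
                if kind == "phi":
                    a = c[ip - 1, 2]
                    b, piv = c[ip, 0], c[ip, 1]
                    current = dihedral(a, b, piv, c[ip, 2])
                    moving = [(ip, 2)] + [(j, t) for j in
                                          range(ip + 1, self.n_res)
                                          for t in range(3)]
                else:
                    a, b, piv = c[ip, 0], c[ip, 1], c[ip, 2]
                    current = dihedral(a, b, piv, c[ip + 1, 0])
                    moving = [(j, t) for j in range(ip + 1, self.n_res)
                              for t in range(3)]
                delta = np.radians(wrap_angle(target - current))
                if abs(delta) < 1e-15:
                    continue
                rot = rotation_about_axis(piv - b, float(delta))
                for (j, t) in moving:
                    c[j, t] = (rot @ (c[j, t] - piv)) + piv
        return c

    def residual(self, tors6) -> float:
        c = self.apply(tors6)
        return float(np.abs(c[-1] - self.target).max())

    def stem_vector(self, tors6) -> np.ndarray:
        return self.apply(tors6)[-1].ravel()

    def polish(self, tors6, max_iter=12):
        """Gauss-Newton refinement of the six torsions on the stem match."""
        t = np.asarray(tors6, float).copy()
        target = self.target.ravel()
        for _ in range(max_iter):
            r = self.stem_vector(t) - target
            if np.abs(r).max() < 1e-10:
                break
            J = np.zeros((9, 6))
            h = 1e-4
            for k in range(6):
                tp = t.copy()
                tp[k] += h
                J[:, k] = (self.stem_vector(tp) - r - target) / h
            try:
                step, *_ = np.linalg.lstsq(J, -r, rcond=None)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)):
                break
            t = t + step
            if np.abs(step).max() < 1e-12:
                break
        return t


# ---------------------------------------------------------------------------
# Analytic reduction
# ---------------------------------------------------------------------------

def _cone_sphere(apex, axis_u, half_angle_rad, radius, center, r_sphere):
    """Intersect the circle {apex + radius*(cos(th)u + sin(th)(cos t v +
    sin t w))} with a sphere; returns 0-2 points (vectorized over centers).

    Returns array (n_centers, 2, 3) with NaN rows where infeasible.
    """
    u = axis_u / np.linalg.norm(axis_u)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    q = center - apex                      # (n, 3)
    b = radius
    st, ct = np.sin(half_angle_rad), np.cos(half_angle_rad)
    A = q @ v
    B = q @ w
    C = ((b * b + np.sum(q * q, axis=1) - r_sphere * r_sphere)
         / (2.0 * b * st)) - ct * (q @ u) / st
    R = np.hypot(A, B)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(R > 0, C / np.where(R > 0, R, 1.0), np.inf)
        base = np.arctan2(B, A)
        dt = np.arccos(np.clip(ratio, -1.0, 1.0))
        feasible = np.abs(ratio) <= 1.0
    out = np.full((len(center), 2, 3), np.nan)
    for sgn, col in ((+1.0, 0), (-1.0, 1)):
        t = base + sgn * dt
        pts = apex + b * (ct * u[None, :]
                          + st * (np.cos(t)[:, None] * v[None, :]
                                  + np.sin(t)[:, None] * w[None, :]))
        pts[~feasible] = np.nan
        out[:, col, :] = pts
    return out


def _frame_from(p0, p1, p2):
    """Orthonormal frame anchored at three points (origin p0)."""
    ex = p1 - p0
    nex = np.linalg.norm(ex)
    ex = ex / nex
    ey = (p2 - p0) - np.dot(p2 - p0, ex) * ex
    ney = np.linalg.norm(ey)
    if ney < 1e-9:
        raise DegenerateGeometryError("collinear anchor points")
    ey = ey / ney
    ez = np.cross(ex, ey)
    return np.column_stack([ex, ey, ez])


def _local(frame, origin, point):
    return frame.T @ (point - origin)


def _world(frame, origin, local):
    return frame @ local + origin


def triaxial_close(problem: ClosureProblem) -> list:
    """All closure solutions of a triaxial problem, sorted by torsional
    distance from the input conformation.

    Unreachable anchors yield an empty list; degenerate stem geometry
    raises an error (checked at problem construction).
    """
    model = problem.model
    s, e = problem.segment
    p1, p2, p3 = problem.pivots
    res = model.residues

    N1, CA1, C1 = (res[p1].coord(n) for n in ("N", "CA", "C"))
    N2, CA2, C2 = (res[p2].coord(n) for n in ("N", "CA", "C"))
    N3, CA3, C3 = (res[p3].coord(n) for n in ("N", "CA", "C"))

    # map the C-side rigid body onto the target stem
    cur_stem = problem._stem_coords(e + 1)
    R_d, t_d, fit = kabsch(cur_stem, problem.target_stem)
    if fit > 1e-6:
        # the stems are rigid triples; a perfect fit must exist
        raise DegenerateGeometryError("inconsistent C-side stem geometry")
    CA3_t = R_d @ CA3 + t_d
    C3_t = R_d @ C3 + t_d

    d12 = float(np.linalg.norm(CA2 - CA1))
    d23 = float(np.linalg.norm(CA3 - CA2))
    d13 = float(np.linalg.norm(CA3_t - CA1))
    if d13 > d12 + d23 - 1e-12 or d13 < abs(d12 - d23) + 1e-12:
        return []

    # circle of CA2 positions about the CA1 - CA3_t axis
    axis = (CA3_t - CA1) / d13
    cos_a = (d12 * d12 + d13 * d13 - d23 * d23) / (2.0 * d12 * d13)
    cos_a = float(np.clip(cos_a, -1.0, 1.0))
    center = CA1 + d12 * cos_a * axis
    rho = d12 * float(np.sqrt(max(0.0, 1.0 - cos_a * cos_a)))
    if rho < 1e-9:
        return []
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    def ca2_of(sigma):
        sigma = np.atleast_1d(sigma)
        return (center[None, :]
                + rho * (np.cos(sigma)[:, None] * e1[None, :]
                         + np.sin(sigma)[:, None] * e2[None, :]))

    # joint-1 constants
    theta1 = np.radians(bond_angle(N1, CA1, C1))
    b1 = float(np.linalg.norm(C1 - CA1))
    r1 = float(np.linalg.norm(C1 - CA2))
    u1 = (N1 - CA1) / np.linalg.norm(N1 - CA1)
    # joint-3 constants
    theta3 = np.radians(bond_angle(N3, CA3, C3))
    b3 = float(np.linalg.norm(N3 - CA3))
    r3 = float(np.linalg.norm(N3 - CA2))
    u3 = (C3_t - CA3_t) / np.linalg.norm(C3_t - CA3_t)
    theta2 = bond_angle(N2, CA2, C2)

    # local coordinates of the inter-pivot rigid bodies
    f12 = _frame_from(CA1, C1, CA2)
    n2_loc = _local(f12, CA1, N2)
    f23 = _frame_from(CA3, N3, CA2)
    c2_loc = _local(f23, CA3, C2)

    seg = _BackboneSegment(problem)
    tors_in = seg.current_torsions(seg.coords0)

    def branch_g(sigma_arr, k1, k3):
        ca2 = ca2_of(sigma_arr)
        c1p = _cone_sphere(CA1, u1, theta1, b1, ca2, r1)[:, k1, :]
        n3p = _cone_sphere(CA3_t, u3, theta3, b3, ca2, r3)[:, k3, :]
        g = np.full(len(ca2), np.nan)
        for m in range(len(ca2)):
            if np.any(np.isnan(c1p[m])) or np.any(np.isnan(n3p[m])):
                continue
            try:
                fr12 = _frame_from(CA1, c1p[m], ca2[m])
                fr23 = _frame_from(CA3_t, n3p[m], ca2[m])
            except DegenerateGeometryError:
                continue
            n2w = _world(fr12, CA1, n2_loc)
            c2w = _world(fr23, CA3_t, c2_loc)
            g[m] = bond_angle(n2w, ca2[m], c2w) - theta2
        return g, c1p, n3p, ca2

    sigmas = np.linspace(0.0, 2.0 * np.pi, _N_SCAN, endpoint=False)
    solutions = []
    for k1 in (0, 1):
        for k3 in (0, 1):
            g, _, _, _ = branch_g(sigmas, k1, k3)

            def scalar_g(sig, k1=k1, k3=k3):
                val = branch_g(np.array([sig]), k1, k3)[0][0]
                return val if np.isfinite(val) else np.nan

            for m in range(_N_SCAN):
                m2 = (m + 1) % _N_SCAN
                ga, gb = g[m], g[m2]
                if not (np.isfinite(ga) and np.isfinite(gb)):
                    continue
                if ga == 0.0:
                    root = sigmas[m]
                elif ga * gb < 0.0:
                    lo = sigmas[m]
                    hi = sigmas[m2] if m2 != 0 else 2.0 * np.pi
                    try:
                        root = brentq(scalar_g, lo, hi, xtol=1e-12)
                    except ValueError:
                        continue
                else:
                    continue
                sol = _extract_solution(root, k1, k3, ca2_of, branch_g,
                                        model, problem, f12, f23,
                                        CA1, CA3_t, C3_t, R_d, t_d, seg,
                                        tors_in)
                if sol is not None:
                    solutions.append(sol)

    # deduplicate (same torsion set found on several branches)
    unique = []
    for sol in solutions:
        flat = np.array([v for pair in sol.pivot_torsions for v in pair])
        dup = False
        for other in unique:
            oflat = np.array([v for pair in other.pivot_torsions
                              for v in pair])
            if np.abs(wrap_angle(flat - oflat)).max() < 0.01:
                dup = True
                break
        if not dup:
            unique.append(sol)
    unique.sort(key=lambda sol: sol.torsion_distance)
    return unique[:16]


def _extract_solution(sigma, k1, k3, ca2_of, branch_g, model, problem,
                      f12_cur, f23_cur, CA1, CA3_t, C3_t, R_d, t_d, seg,
                      tors_in):
    s, e = problem.segment
    p1, p2, p3 = problem.pivots
    res = model.residues
    g, c1p, n3p, ca2 = branch_g(np.array([sigma]), k1, k3)
    if not np.isfinite(g[0]):
        return None
    c1w, n3w, ca2w = c1p[0], n3p[0], ca2[0]
    try:
        fr12 = _frame_from(CA1, c1w, ca2w)
        fr23 = _frame_from(CA3_t, n3w, ca2w)
    except DegenerateGeometryError:
        return None

    # body-frame local coordinates of the atoms needed for torsions
    def loc12(point):
        return _local(f12_cur, CA1, point)

    def loc23(point):
        return _local(f23_cur, res[p3].coord("CA"), point)

    N1 = res[p1].coord("N")
    prev_c = res[p1 - 1].coord("C")
    n_after_p1 = _world(fr12, CA1, loc12(res[p1 + 1].coord("N")))
    c_before_p2 = _world(fr12, CA1, loc12(res[p2 - 1].coord("C")))
    n2w = _world(fr12, CA1, loc12(res[p2].coord("N")))
    c2w = _world(fr23, CA3_t, loc23(res[p2].coord("C")))
    n_after_p2 = _world(fr23, CA3_t, loc23(res[p2 + 1].coord("N")))
    c_before_p3 = _world(fr23, CA3_t, loc23(res[p3 - 1].coord("C")))
    n3_final = n3w
    n_after_p3 = problem.target_stem[0]

    phi1 = dihedral(prev_c, N1, CA1, c1w)
    psi1 = dihedral(N1, CA1, c1w, n_after_p1)
    phi2 = dihedral(c_before_p2, n2w, ca2w, c2w)
    psi2 = dihedral(n2w, ca2w, c2w, n_after_p2)
    phi3 = dihedral(c_before_p3, n3_final, CA3_t, C3_t)
    psi3 = dihedral(n3_final, CA3_t, C3_t, n_after_p3)
    tors = np.array([phi1, psi1, phi2, psi2, phi3, psi3])

    tors = seg.polish(tors)
    residual = seg.residual(tors)
    if residual > CLOSURE_TOLERANCE:
        return None
    dist = float(np.sqrt(np.sum(wrap_angle(tors - tors_in) ** 2)))
    return ClosureSolution(
        pivot_torsions=[(float(tors[0]), float(tors[1])),
                        (float(tors[2]), float(tors[3])),
                        (float(tors[4]), float(tors[5]))],
        residual=residual,
        torsion_distance=dist,
    )


def apply_closure_solution(model: StructureModel, pivots,
                           solution: ClosureSolution) -> StructureModel:
    """Apply solved pivot torsions to a model (full-atom)."""
    out = model
    for p, (phi, psi) in zip(pivots, solution.pivot_torsions):
        out = set_torsion(out, p, "phi", phi)
        out = set_torsion(out, p, "psi", psi)
    return out


def perturb_and_close(model: StructureModel, segment, pivots,
                      noise_deg: float, rng):
    """Gaussian-perturb non-pivot backbone torsions in a segment, then
    restore connectivity by triaxial closure at the pivots.

    Returns (model, rejected): on closure failure the input model is
    returned unchanged with rejected=True.  Residues outside the segment
    are never moved.
    """
    s, e = segment
    pivot_set = set(pivots)
    work = model.copy()
    original_stem = np.array([
        model.residues[e + 1].coord(n) for n in ("N", "CA", "C")])
    if noise_deg > 0:
        for i in range(s, e + 1):
            if i in pivot_set:
                continue
            for kind in ("phi", "psi"):
                if kind == "phi" and work.residues[i].resname == "PRO":
                    continue
                try:
                    cur = (work.phi(i) if kind == "phi" else work.psi(i))
                except Exception:
                    continue
                work = set_torsion(work, i, kind,
                                   cur + float(rng.normal(0.0, noise_deg)))
    problem = ClosureProblem(work, segment, tuple(pivots),
                             target_stem=original_stem)
    solutions = triaxial_close(problem)
    if not solutions:
        return model.copy(), True
    closed = apply_closure_solution(work, pivots, solutions[0])
    # re-anchor everything after the segment to its original position
    for i in range(e + 1, len(model.residues)):
        for atom, orig in zip(closed.residues[i].atoms,
                              model.residues[i].atoms):
            atom.coord = orig.coord.copy()
    return closed, False
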