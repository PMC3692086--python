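"""Composite refinement energy with analytic gradients.

Physics terms (harmonic bonded terms, Lennard-Jones, distance-dependent-
dielectric Coulomb, Gaussian-exclusion implicit solvation, smooth
surface-area proxy) plus database-derived terms (backbone/side-chain
torsion propensities, residue-pair distance potential, backbone hydrogen
bonds) plus a harmonic restraint to the starting model:

    E = E_phys + w_db * E_db + w_rst * E_rst

with w_rst five times larger in the mild regime than in the aggressive
regime.  Every term is smooth in the coordinates and ships an analytic
gradient, validated against central differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from . import chemdata
from .pdb_model import StructureModel, bond_graph

__all__ = [
    "EnergyParams", "EnergyBreakdown", "SystemTopology",
    "physics_energy", "database_energy", "restraint_energy", "total_energy",
    "total_energy_and_gradient", "lj_pair", "coulomb_pair",
    "RESTRAINT_WEIGHT_RATIO",
]

COULOMB_K = 332.0637  # kcal/mol * A * e^-2
RESTRAINT_WEIGHT_RATIO = 5.0  # mild w_rst / aggressive w_rst


def _default_pair_table():
    """Smooth residue-pair distance potential sampled on 0.5 A bins.

    Shallow attractive well near typical CB-CB contact distance with a
    soft repulsive shoulder below it; scaled by the product of residue
    hydrophobicities at evaluation time.
    """
    r = np.arange(0.25, 15.0, 0.5)
    g = (-np.exp(-((r - 5.5) / 1.8) ** 2)
         + 0.8 * np.exp(-((r - 3.0) / 0.7) ** 2))
    return r, g


@dataclass
class EnergyParams:
    """Tunable constants of the composite energy."""

    w_db: float = 1.0
    w_rst_mild: float = 1.0
    w_rst_aggressive: float = 0.2
    k_restraint: float = 0.5       # kcal/mol/A^2, heavy atoms
    cutoff: float = 12.0           # A, nonbonded
    switch_start: float = 10.0     # A
    k_bond: float = 300.0          # kcal/mol/A^2
    k_bond_h: float = 340.0
    k_angle: float = 50.0          # kcal/mol/rad^2
    k_angle_h: float = 35.0
    k_omega: float = 10.0          # kcal/mol, 2-fold peptide torsion
    hbond_e0: float = 2.0          # kcal/mol well depth
    hbond_r0: float = 2.0          # A, H...O optimum
    hbond_cut: float = 5.0         # A
    w_bb_torsion: float = 0.5
    w_chi_torsion: float = 0.3
    chi_width: float = 30.0        # degrees
    k_pair: float = 0.3
    sasa_alpha: float = 0.4
    pair_table: tuple = field(default_factory=_default_pair_table)

    def w_rst(self, regime: str) -> float:
        if regime == "mild":
            return self.w_rst_mild
        if regime == "aggressive":
            return self.w_rst_aggressive
        raise ValueError(f"unknown regime {regime!r}")


@dataclass
class EnergyBreakdown:
    bonded: float = 0.0
    lj: float = 0.0
    coulomb: float = 0.0
    solvation: float = 0.0
    sasa: float = 0.0
    hbond: float = 0.0
    torsion_stat: float = 0.0
    pair_stat: float = 0.0
    restraint: float = 0.0
    w_db: float = 1.0
    w_rst: float = 0.0

    @property
    def total(self) -> float:
        return (self.bonded + self.lj + self.coulomb + self.solvation
                + self.sasa
                + self.w_db * (self.hbond + self.torsion_stat
                               + self.pair_stat)
                + self.w_rst * self.restraint)


def lj_pair(r: float, elem_a: str, elem_b: str) -> float:
    """Lennard-Jones energy of one atom pair (no switching)."""
    ra, ea = chemdata.LJ_PARAMS[elem_a]
    rb, eb = chemdata.LJ_PARAMS[elem_b]
    rmin = ra + rb
    eps = math.sqrt(ea * eb)
    q = (rmin / r) ** 6
    return eps * (q * q - 2.0 * q)


def coulomb_pair(r: float, q1: float, q2: float) -> float:
    """Coulomb energy with the distance-dependent dielectric eps(r) = 4r."""
    return COULOMB_K * q1 * q2 / (4.0 * r * r)


# ---------------------------------------------------------------------------
# Backbone / chi torsion propensities (smooth periodic mixtures)
# ---------------------------------------------------------------------------

# (phi center, psi center, amplitude, width in degrees)
_BB_BASINS = [
    (-63.0, -43.0, 1.0, 25.0),    # alpha
    (-120.0, 130.0, 0.8, 30.0),   # beta
    (-75.0, 145.0, 0.6, 25.0),    # PPII
    (57.0, 40.0, 0.2, 20.0),      # left-handed alpha
]
_BB_FLOOR = 1e-3


def _bb_propensity(phi_deg, psi_deg):
    """P(phi, psi) and its partial derivatives (per degree)."""
    p = _BB_FLOOR
    dphi_sum = dpsi_sum = 0.0
    for c_phi, c_psi, amp, width in _BB_BASINS:
        dphi = (phi_deg - c_phi + 180.0) % 360.0 - 180.0
        dpsi = (psi_deg - c_psi + 180.0) % 360.0 - 180.0
        g = amp * math.exp(-(dphi * dphi + dpsi * dpsi)
                           / (2.0 * width * width))
        p += g
        dphi_sum += g * (-dphi / (width * width))
        dpsi_sum += g * (-dpsi / (width * width))
    return p, dphi_sum, dpsi_sum


def export_bb_grid(step: float = 10.0) -> str:
    """The backbone propensity table on a regular grid, as TSV text."""
    lines = ["# phi\tpsi\tpropensity"]
    grid = np.arange(-180.0, 180.0, step)
    for phi in grid:
        for psi in grid:
            p, _, _ = _bb_propensity(phi, psi)
            lines.append(f"{phi:.0f}\t{psi:.0f}\t{p:.6f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# System topology: static per-model arrays for fast evaluation
# ---------------------------------------------------------------------------

def _switch(r, r_on, r_off):
    """CHARMM-style C1 switching function and its derivative."""
    r = np.asarray(r, float)
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    mid = (r > r_on) & (r < r_off)
    t = (r_off ** 2 - r[mid] ** 2)
    denom = (r_off ** 2 - r_on ** 2) ** 3
    s[mid] = t * t * (r_off ** 2 + 2.0 * r[mid] ** 2 - 3.0 * r_on ** 2) \
        / denom
    ds[mid] = (t * (-4.0 * r[mid]) * (r_off ** 2 + 2.0 * r[mid] ** 2
                                      - 3.0 * r_on ** 2)
               + t * t * 4.0 * r[mid]) / denom
    s[r >= r_off] = 0.0
    return s, ds


@dataclass
class _IdealGeom:
    bonds: dict
    angles: dict


_IDEAL_CACHE: dict = {}


def _ideal_geometry(resname: str) -> _IdealGeom:
    """Equilibrium bond lengths/angles of a residue measured on an
    ideally built G-X-G tripeptide (hydrogens included)."""
    if resname in _IDEAL_CACHE:
        return _IDEAL_CACHE[resname]
    from .fixtures import FixtureSpec, build_peptide
    from .pdb_model import add_hydrogens
    from .geometry import angle as angle_of

    letter = chemdata.AA3_TO_1[resname]
    model = add_hydrogens(build_peptide(
        FixtureSpec("G" + letter + "G", conformation="strand")))
    adj = bond_graph(model)

    def label(key):
        ri, name = key
        if ri == 1:
            return name
        if ri == 0 and name == "C":
            return "-C"
        if ri == 2 and name == "N":
            return "+N"
        return None

    def coord(key):
        return model.residues[key[0]].coord(key[1])

    bonds, angles = {}, {}
    keys = [k for k in model.atom_keys() if label(k) is not None]
    for k in keys:
        for nb in adj[k]:
            if label(nb) is None:
                continue
            pair = tuple(sorted((label(k), label(nb))))
            bonds[pair] = float(np.linalg.norm(coord(k) - coord(nb)))
    for center in keys:
        nbs = [nb for nb in sorted(adj[center]) if label(nb) is not None]
        for x in range(len(nbs)):
            for y in range(x + 1, len(nbs)):
                a, c = nbs[x], nbs[y]
                names = (label(a), label(center), label(c))
                key = (min(names[0], names[2]), names[1],
                       max(names[0], names[2]))
                angles[key] = angle_of(coord(a), coord(center), coord(c))
    geom = _IdealGeom(bonds, angles)
    _IDEAL_CACHE[resname] = geom
    return geom


class SystemTopology:
    """Static description of one model's atoms and interactions."""

    def __init__(self, model: StructureModel, params: EnergyParams):
        self.params = params
        self.keys = model.atom_keys()
        self.index = {k: n for n, k in enumerate(self.keys)}
        n = len(self.keys)
        self.n_atoms = n
        res = model.residues
        self.elements = np.array([a.element for _, a in model.iter_atoms()])
        self.heavy_mask = self.elements != "H"
        self.charges = np.array([
            chemdata.partial_charge(res[i].resname, a.name)
            for i, a in model.iter_atoms()])
        lj = np.array([chemdata.LJ_PARAMS[e] for e in self.elements])
        self.lj_rmin_half = lj[:, 0]
        self.lj_eps = lj[:, 1]
        solv = np.array([chemdata.SOLVATION_PARAMS.get(e, (0, 0, 0, 3.5))
                         for e in self.elements])
        self.solv_dgref = solv[:, 0] * self.heavy_mask
        self.solv_alpha = (2.0 * solv[:, 1]
                           / (4.0 * math.pi * math.sqrt(math.pi) * solv[:, 3])
                           ) * self.heavy_mask
        self.solv_vol = solv[:, 2] * self.heavy_mask
        self.solv_lambda = solv[:, 3]
        self.solv_rad = np.array([chemdata.VDW_RADIUS[e]
                                  for e in self.elements])
        self.sasa_gamma = np.array([chemdata.SASA_GAMMA[e]
                                    for e in self.elements])
        self.sasa_amax = np.array([chemdata.SASA_MAX_AREA[e]
                                   for e in self.elements])
        self.masses = np.array([chemdata.ELEMENT_MASS[e]
                                for e in self.elements])

        adj = bond_graph(model)
        # --- bonded lists with equilibrium values from ideal templates
        bond_idx, bond_b0, bond_k = [], [], []
        seen = set()
        for k in self.keys:
            for nb in adj[k]:
                pair = tuple(sorted((self.index[k], self.index[nb])))
                if pair in seen:
                    continue
                seen.add(pair)
                b0 = self._bond_b0(res, k, nb)
                kk = (params.k_bond_h
                      if "H" in (chemdata.element_of(k[1]),
                                 chemdata.element_of(nb[1]))
                      else params.k_bond)
                bond_idx.append(pair)
                bond_b0.append(b0)
                bond_k.append(kk)
        self.bond_idx = np.array(bond_idx, int)
        self.bond_b0 = np.array(bond_b0)
        self.bond_k = np.array(bond_k)

        ang_idx, ang_t0, ang_k = [], [], []
        for center in self.keys:
            nbs = sorted(adj[center])
            for x in range(len(nbs)):
                for y in range(x + 1, len(nbs)):
                    a, c = nbs[x], nbs[y]
                    t0 = self._angle_t0(res, a, center, c)
                    if t0 is None:
                        continue
                    kk = (params.k_angle_h
                          if "H" in (chemdata.element_of(a[1]),
                                     chemdata.element_of(c[1]))
                          else params.k_angle)
                    ang_idx.append((self.index[a], self.index[center],
                                    self.index[c]))
                    ang_t0.append(math.radians(t0))
                    ang_k.append(kk)
        self.ang_idx = np.array(ang_idx, int)
        self.ang_t0 = np.array(ang_t0)
        self.ang_k = np.array(ang_k)

        omg = []
        for i in range(len(res) - 1):
            quad = [(i, "CA"), (i, "C"), (i + 1, "N"), (i + 1, "CA")]
            if all(k in self.index for k in quad):
                omg.append([self.index[k] for k in quad])
        self.omega_idx = np.array(omg, int) if omg else np.zeros((0, 4), int)

        # --- backbone torsion-statistics quads (non-terminal residues)
        bb = []
        for i in range(1, len(res) - 1):
            phi = [(i - 1, "C"), (i, "N"), (i, "CA"), (i, "C")]
            psi = [(i, "N"), (i, "CA"), (i, "C"), (i + 1, "N")]
            if all(k in self.index for k in phi + psi):
                bb.append([self.index[k] for k in phi]
                          + [self.index[k] for k in psi])
        self.bb_idx = np.array(bb, int) if bb else np.zeros((0, 8), int)

        # --- chi quads with per-residue rotamer data
        from .rotamer_repack import default_rotamer_library
        lib = default_rotamer_library()
        self.chi_groups = []  # (quad indices (nchi,4), rot array, probs)
        for i, r in enumerate(res):
            quads = chemdata.CHI_ATOMS[r.resname]
            if not quads or r.resname not in lib.rotamers:
                continue
            if not all(r.has_atom(nm) for q in quads for nm in q):
                continue
            qidx = np.array([[self.index[(i, nm)] for nm in q]
                             for q in quads], int)
            rots = np.array([rot for rot, _ in lib.rotamers[r.resname]])
            probs = np.array([p for _, p in lib.rotamers[r.resname]])
            self.chi_groups.append((qidx, rots, probs / probs.sum()))

        # --- residue-pair potential over CB atoms
        cb_idx, cb_h = [], []
        for i, r in enumerate(res):
            if r.has_atom("CB"):
                cb_idx.append(self.index[(i, "CB")])
                cb_h.append(chemdata.HYDROPHOBICITY[r.resname])
        self.cb_idx = np.array(cb_idx, int)
        self.cb_h = np.array(cb_h)
        self.cb_res = np.array([i for i, r in enumerate(res)
                                if r.has_atom("CB")], int)
        r_grid, g_vals = params.pair_table
        self.pair_spline = CubicSpline(r_grid, g_vals, bc_type="natural")
        self.pair_rmax = float(r_grid[-1])

        # --- backbone hydrogen-bond donors/acceptors
        donors, acceptors = [], []
        for i, r in enumerate(res):
            if r.has_atom("N") and r.has_atom("H"):
                donors.append((i, self.index[(i, "N")],
                               self.index[(i, "H")]))
            if r.has_atom("C") and r.has_atom("O"):
                acceptors.append((i, self.index[(i, "C")],
                                  self.index[(i, "O")]))
        self.hb_donors = donors
        self.hb_acceptors = acceptors

        # --- nonbonded exclusions (<= 3 bonds apart)
        from .rotamer_repack import _excluded_pairs
        excl = _excluded_pairs(model)
        self.excl_codes = np.array(sorted(a * n + b for a, b in excl),
                                   dtype=np.int64)

    # -- equilibrium lookups ------------------------------------------
    @staticmethod
    def _bond_b0(res, k, nb):
        (ri, na), (rj, nb_name) = k, nb
        if ri == rj:
            geom = _ideal_geometry(res[ri].resname)
            pair = tuple(sorted((na, nb_name)))
            if pair in geom.bonds:
                return geom.bonds[pair]
        # peptide bond
        return chemdata.BOND_C_N

    @staticmethod
    def _angle_t0(res, a, center, c):
        ra, rc_, rcen = a[0], c[0], center[0]
        if ra == rcen == rc_:
            geom = _ideal_geometry(res[rcen].resname)
            names = tuple(sorted((a[1], c[1])))
            key = (names[0], center[1], names[1])
            return geom.angles.get(key)
        # inter-residue angles at the peptide junction

        def lab(k):
            if k[0] == rcen:
                return k[1]
            if k[0] == rcen - 1 and k[1] == "C":
                return "-C"
            if k[0] == rcen + 1 and k[1] == "N":
                return "+N"
            return None
        la, lc = lab(a), lab(c)
        if la is None or lc is None:
            return None
        geom = _ideal_geometry(res[rcen].resname)
        key = (min(la, lc), center[1], max(la, lc))
        return geom.angles.get(key)

    # -- evaluation ----------------------------------------------------
    def nonbonded_pairs(self, xyz):
        tree = cKDTree(xyz)
        pairs = tree.query_pairs(r=self.params.cutoff,
                                 output_type="ndarray")
        if len(pairs) == 0:
            return pairs
        codes = pairs[:, 0] * self.n_atoms + pairs[:, 1]
        keep = ~np.isin(codes, self.excl_codes, assume_unique=False)
        return pairs[keep]

    def evaluate(self, xyz, ref_xyz=None, w_rst=0.0, compute_grad=True):
        """Energy breakdown (and gradient) at coordinates `xyz`."""
        p = self.params
        grad = np.zeros_like(xyz) if compute_grad else None
        bd = EnergyBreakdown(w_db=p.w_db, w_rst=w_rst)

        # bonds
        if len(self.bond_idx):
            d = xyz[self.bond_idx[:, 0]] - xyz[self.bond_idx[:, 1]]
            r = np.linalg.norm(d, axis=1)
            dev = r - self.bond_b0
            bd.bonded += float(np.sum(self.bond_k * dev * dev))
            if compute_grad:
                f = (2.0 * self.bond_k * dev / r)[:, None] * d
                np.add.at(grad, self.bond_idx[:, 0], f)
                np.add.at(grad, self.bond_idx[:, 1], -f)

        # angles
        if len(self.ang_idx):
            ai, bi, ci = (self.ang_idx[:, 0], self.ang_idx[:, 1],
                          self.ang_idx[:, 2])
            u = xyz[ai] - xyz[bi]
            v = xyz[ci] - xyz[bi]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cth = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
            th = np.arccos(cth)
            dev = th - self.ang_t0
            bd.bonded += float(np.sum(self.ang_k * dev * dev))
            if compute_grad:
                sth = np.sqrt(np.clip(1.0 - cth * cth, 1e-12, None))
                uh = u / nu[:, None]
                vh = v / nv[:, None]
                dth_da = (cth[:, None] * uh - vh) / (nu * sth)[:, None]
                dth_dc = (cth[:, None] * vh - uh) / (nv * sth)[:, None]
                coef = (2.0 * self.ang_k * dev)[:, None]
                np.add.at(grad, ai, coef * dth_da)
                np.add.at(grad, ci, coef * dth_dc)
                np.add.at(grad, bi, -coef * (dth_da + dth_dc))

        # omega 2-fold torsion
        if len(self.omega_idx):
            e, dphi = self._torsion_terms(
                xyz, self.omega_idx,
                lambda w: (p.k_omega * (1.0 - np.cos(2.0 * w)),
                           2.0 * p.k_omega * np.sin(2.0 * w)))
            bd.bonded += e
            if compute_grad:
                self._add_torsion_grad(grad, xyz, self.omega_idx, dphi)

        # nonbonded pairs
        pairs = self.nonbonded_pairs(xyz)
        if len(pairs):
            a, b = pairs[:, 0], pairs[:, 1]
            d = xyz[a] - xyz[b]
            r = np.linalg.norm(d, axis=1)
            s, ds = _switch(r, p.switch_start, p.cutoff)

            rmin = self.lj_rmin_half[a] + self.lj_rmin_half[b]
            eps = np.sqrt(self.lj_eps[a] * self.lj_eps[b])
            q6 = (rmin / r) ** 6
            elj = eps * (q6 * q6 - 2.0 * q6)
            delj = eps * (-12.0 * q6 * q6 + 12.0 * q6) / r
            bd.lj = float(np.sum(elj * s))

            qq = COULOMB_K * self.charges[a] * self.charges[b] / 4.0
            ec = qq / (r * r)
            dec = -2.0 * qq / (r ** 3)
            bd.coulomb = float(np.sum(ec * s))

            # Gaussian-exclusion solvation (heavy pairs only)
            hh = self.heavy_mask[a] & self.heavy_mask[b]
            ah, bh, rh = a[hh], b[hh], r[hh]
            xa = (rh - self.solv_rad[ah]) / self.solv_lambda[ah]
            xb = (rh - self.solv_rad[bh]) / self.solv_lambda[bh]
            fa = self.solv_alpha[ah] / (rh * rh) * np.exp(-xa * xa)
            fb = self.solv_alpha[bh] / (rh * rh) * np.exp(-xb * xb)
            esolv_pair = -(fa * self.solv_vol[bh] + fb * self.solv_vol[ah])
            bd.solvation = float(np.sum(self.solv_dgref)
                                 + np.sum(esolv_pair))
            if compute_grad:
                dfa = fa * (-2.0 / rh - 2.0 * xa / self.solv_lambda[ah])
                dfb = fb * (-2.0 / rh - 2.0 * xb / self.solv_lambda[bh])
                dsolv = -(dfa * self.solv_vol[bh] + dfb * self.solv_vol[ah])
                dtot = (delj + dec) * s + (elj + ec) * ds
                dvec = (dtot / r)[:, None] * d
                np.add.at(grad, a, dvec)
                np.add.at(grad, b, -dvec)
                dvec_s = (dsolv / rh)[:, None] * d[hh]
                np.add.at(grad, ah, dvec_s)
                np.add.at(grad, bh, -dvec_s)

            # smooth surface-area proxy from heavy-atom occlusion
            occ = np.zeros(self.n_atoms)
            sw, dsw = _sasa_switch(rh)
            np.add.at(occ, ah, sw)
            np.add.at(occ, bh, sw)
            area = self.sasa_amax * np.exp(-p.sasa_alpha * occ) \
                * self.heavy_mask
            bd.sasa = float(np.sum(self.sasa_gamma * area))
            if compute_grad:
                gfac = self.sasa_gamma * area * (-p.sasa_alpha)
                coeff = (gfac[ah] + gfac[bh]) * dsw
                dvec = (coeff / rh)[:, None] * d[hh]
                np.add.at(grad, ah, dvec)
                np.add.at(grad, bh, -dvec)
        else:
            bd.solvation = float(np.sum(self.solv_dgref))
            bd.sasa = float(np.sum(
                self.sasa_gamma * self.sasa_amax * self.heavy_mask))

        # database terms
        bd.hbond = self._hbond(xyz, grad, p.w_db)
        bd.torsion_stat = self._torsion_stat(xyz, grad, p.w_db)
        bd.pair_stat = self._pair_stat(xyz, grad, p.w_db)

        # restraints
        if ref_xyz is not None and w_rst > 0.0:
            disp = (xyz - ref_xyz) * self.heavy_mask[:, None]
            bd.restraint = float(p.k_restraint * np.sum(disp * disp))
            if compute_grad:
                grad += w_rst * 2.0 * p.k_restraint * disp
        return bd, grad

    # -- torsion helpers ----------------------------------------------
    @staticmethod
    def _dihedrals(xyz, quads):
        b1 = xyz[quads[:, 1]] - xyz[quads[:, 0]]
        b2 = xyz[quads[:, 2]] - xyz[quads[:, 1]]
        b3 = xyz[quads[:, 3]] - xyz[quads[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        m1 = np.cross(n1, b2 / nb2[:, None])
        x = np.sum(n1 * n2, axis=1)
        y = np.sum(m1 * n2, axis=1)
        return -np.arctan2(y, x)

    def _torsion_terms(self, xyz, quads, fn):
        w = self._dihedrals(xyz, quads)
        e, de = fn(w)
        return float(np.sum(e)), de

    @staticmethod
    def _torsion_grad_vectors(xyz, quads):
        """d(dihedral)/d(coordinates) for each quad (radians/A)."""
        b1 = xyz[quads[:, 1]] - xyz[quads[:, 0]]
        b2 = xyz[quads[:, 2]] - xyz[quads[:, 1]]
        b3 = xyz[quads[:, 3]] - xyz[quads[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        n1sq = np.sum(n1 * n1, axis=1)
        n2sq = np.sum(n2 * n2, axis=1)
        # Blondel & Karplus exact dihedral derivatives
        da = (-nb2 / n1sq)[:, None] * n1
        dd = (nb2 / n2sq)[:, None] * n2
        g1 = (np.sum(b1 * b2, axis=1) / nb2 ** 2)
        g2 = (np.sum(b3 * b2, axis=1) / nb2 ** 2)
        db = (-g1 - 1.0)[:, None] * da + g2[:, None] * dd
        dc = g1[:, None] * da - (g2 + 1.0)[:, None] * dd
        return da, db, dc, dd

    def _add_torsion_grad(self, grad, xyz, quads, de_dphi):
        da, db, dc, dd = self._torsion_grad_vectors(xyz, quads)
        c = de_dphi[:, None]
        np.add.at(grad, quads[:, 0], c * da)
        np.add.at(grad, quads[:, 1], c * db)
        np.add.at(grad, quads[:, 2], c * dc)
        np.add.at(grad, quads[:, 3], c * dd)

    # -- database terms -----------------------------------------------
    def _hbond(self, xyz, grad, w_db):
        p = self.params
        total = 0.0
        for (di, ni, hi) in self.hb_donors:
            for (aj, cj, oj) in self.hb_acceptors:
                if abs(di - aj) < 2:
                    continue
                w = xyz[oj] - xyz[hi]          # H -> O
                r = float(np.linalg.norm(w))
                if r > p.hbond_cut or r < 0.5:
                    continue
                u = p.hbond_r0 / r
                rad = p.hbond_e0 * (5.0 * u ** 12 - 6.0 * u ** 10)
                drad = p.hbond_e0 * (-60.0 * u ** 12 + 60.0 * u ** 10) / r
                vhn = xyz[ni] - xyz[hi]        # H -> N
                nh = float(np.linalg.norm(vhn))
                w_hat = w / r
                un = vhn / nh
                cosang = float(np.dot(un, w_hat))
                a = max(0.0, cosang)
                total += rad * a * a
                if grad is not None:
                    # radial part: dr/do = w_hat, dr/dh = -w_hat
                    gv = w_db * drad * a * a * w_hat
                    grad[oj] += gv
                    grad[hi] -= gv
                    if a > 0.0:
                        dcos_dn = (w_hat - cosang * un) / nh
                        dcos_do = (un - cosang * w_hat) / r
                        dcos_dh = -dcos_dn - dcos_do
                        cc = w_db * rad * 2.0 * a
                        grad[ni] += cc * dcos_dn
                        grad[oj] += cc * dcos_do
                        grad[hi] += cc * dcos_dh
        return total

    def _torsion_stat(self, xyz, grad, w_db):
        p = self.params
        total = 0.0
        # backbone
        if len(self.bb_idx):
            phi_q = self.bb_idx[:, :4]
            psi_q = self.bb_idx[:, 4:]
            phi = np.degrees(self._dihedrals(xyz, phi_q))
            psi = np.degrees(self._dihedrals(xyz, psi_q))
            de_phi = np.zeros(len(phi))
            de_psi = np.zeros(len(psi))
            for m in range(len(phi)):
                prob, dp_phi, dp_psi = _bb_propensity(phi[m], psi[m])
                total += -p.w_bb_torsion * math.log(prob)
                de_phi[m] = -p.w_bb_torsion * dp_phi / prob
                de_psi[m] = -p.w_bb_torsion * dp_psi / prob
            if grad is not None:
                conv = 180.0 / math.pi
                self._add_torsion_grad(grad, xyz, phi_q,
                                       w_db * de_phi * conv)
                self._add_torsion_grad(grad, xyz, psi_q,
                                       w_db * de_psi * conv)
        # side-chain chi mixture over rotamers
        for qidx, rots, probs in self.chi_groups:
            chi = np.degrees(self._dihedrals(xyz, qidx))
            dchi = (chi[None, :] - rots + 180.0) % 360.0 - 180.0
            logg = -np.sum(dchi * dchi, axis=1) / (2.0 * p.chi_width ** 2)
            g = probs * np.exp(logg)
            z = float(np.sum(g)) + 1e-6
            total += -p.w_chi_torsion * math.log(z)
            if grad is not None:
                # dE/dchi_k = w * sum_r g_r * dchi_rk / width^2 / z
                de = (p.w_chi_torsion / z) * np.sum(
                    g[:, None] * dchi, axis=0) / (p.chi_width ** 2)
                conv = 180.0 / math.pi
                self._add_torsion_grad(grad, xyz, qidx, w_db * de * conv)
        return total

    def _pair_stat(self, xyz, grad, w_db):
        if len(self.cb_idx) < 2:
            return 0.0
        p = self.params
        pos = xyz[self.cb_idx]
        tree = cKDTree(pos)
        pairs = tree.query_pairs(r=self.pair_rmax, output_type="ndarray")
        if len(pairs) == 0:
            return 0.0
        keep = np.abs(self.cb_res[pairs[:, 0]]
                      - self.cb_res[pairs[:, 1]]) >= 2
        pairs = pairs[keep]
        if len(pairs) == 0:
            return 0.0
        a, b = pairs[:, 0], pairs[:, 1]
        d = pos[a] - pos[b]
        r = np.linalg.norm(d, axis=1)
        h = p.k_pair * self.cb_h[a] * self.cb_h[b]
        total = float(np.sum(h * self.pair_spline(r)))
        if grad is not None:
            dg = h * self.pair_spline(r, 1)
            dvec = (w_db * dg / r)[:, None] * d
            np.add.at(grad, self.cb_idx[a], dvec)
            np.add.at(grad, self.cb_idx[b], -dvec)
        return total


def _sasa_switch(r, r_on: float = 3.5, r_off: float = 7.0):
    """Smooth occlusion weight: 1 below r_on, 0 above r_off (C1)."""
    r = np.asarray(r, float)
    t = np.clip((r - r_on) / (r_off - r_on), 0.0, 1.0)
    s = 1.0 - t * t * (3.0 - 2.0 * t)
    ds = np.where((r > r_on) & (r < r_off),
                  -6.0 * t * (1.0 - t) / (r_off - r_on), 0.0)
    return s, ds


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _check_same_atoms(model: StructureModel, reference: StructureModel):
    if model.atom_keys() != reference.atom_keys():
        raise ValueError("model and reference atom sets differ")


def physics_energy(model: StructureModel,
                   params: EnergyParams | None = None) -> EnergyBreakdown:
    """Physics-based terms only (bonded, lj, coulomb, solvation, sasa)."""
    params = params or EnergyParams()
    topo = SystemTopology(model, params)
    bd, _ = topo.evaluate(model.coords(), compute_grad=False)
    return EnergyBreakdown(bonded=bd.bonded, lj=bd.lj, coulomb=bd.coulomb,
                           solvation=bd.solvation, sasa=bd.sasa,
                           w_db=0.0, w_rst=0.0)


def database_energy(model: StructureModel,
                    params: EnergyParams | None = None) -> EnergyBreakdown:
    """Database-derived terms only (hbond, torsion_stat, pair_stat)."""
    params = params or EnergyParams()
    topo = SystemTopology(model, params)
    bd, _ = topo.evaluate(model.coords(), compute_grad=False)
    return EnergyBreakdown(hbond=bd.hbond, torsion_stat=bd.torsion_stat,
                           pair_stat=bd.pair_stat, w_db=params.w_db,
                           w_rst=0.0)


def restraint_energy(model: StructureModel, reference: StructureModel,
                     k: float = 0.5) -> float:
    """Harmonic tether of heavy atoms to the reference (no superposition)."""
    _check_same_atoms(model, reference)
    heavy = np.array([a.element != "H" for _, a in model.iter_atoms()])
    disp = (model.coords() - reference.coords()) * heavy[:, None]
    return float(k * np.sum(disp * disp))


def total_energy(model: StructureModel, reference: StructureModel,
                 params: EnergyParams | None = None,
                 regime: str = "mild") -> EnergyBreakdown:
    """Full weighted energy of a model restrained to `reference`."""
    params = params or EnergyParams()
    _check_same_atoms(model, reference)
    topo = SystemTopology(model, params)
    bd, _ = topo.evaluate(model.coords(), ref_xyz=reference.coords(),
                          w_rst=params.w_rst(regime), compute_grad=False)
    return bd


def total_energy_and_gradient(model: StructureModel,
                              reference: StructureModel,
                              params: EnergyParams | None = None,
                              regime: str = "mild"):
    """As total_energy, returning also dE/dx (kcal/mol/A, atoms x 3)."""
    params = params or EnergyParams()
    _check_same_atoms(model, reference)
    topo = SystemTopology(model, params)
    bd, grad = topo.evaluate(model.coords(), ref_xyz=reference.coords(),
                             w_rst=params.w_rst(regime), compute_grad=True)
    return bd, grad
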