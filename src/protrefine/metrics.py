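"""Model-quality assessment.

Superposition-based accuracy scores (CA RMSD, GDT-HA over CA atoms, GDC
over side-chain characteristic atoms) and physical-correctness scores
(clashscore, rotamer outliers, Ramachandran-favored percentage and the
MolProbity-style combination).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from . import chemdata
from .geometry import kabsch, wrap_angle
from .pdb_model import StructureModel, add_hydrogens
from .rotamer_repack import (RotamerLibrary, default_rotamer_library,
                             detect_clashes)

__all__ = [
    "QualityReport", "superpose", "rmsd_ca", "gdt_ha", "gdc_sc",
    "clashscore", "rotamer_outliers", "rama_favored", "molprobity_score",
    "quality_report", "GDT_THRESHOLDS",
]

GDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
GDC_THRESHOLDS = tuple(0.5 * k for k in range(1, 11))  # 0.5 ... 5.0 A
ROTAMER_OUTLIER_CUTOFF = 40.0  # degrees, per chi angle


@dataclass
class QualityReport:
    model: str
    rmsd: float
    gdt_ha: float
    gdc_sc: float
    clashscore: float
    rotamer_outliers_pct: float
    rama_favored_pct: float
    molprobity: float

    COLUMNS = ("model", "rmsd", "gdt_ha", "gdc_sc", "clashscore",
               "rotamer_outliers_pct", "rama_favored_pct", "molprobity")

    def to_tsv_row(self) -> str:
        vals = asdict(self)
        out = [str(vals["model"])]
        out += [f"{vals[c]:.3f}" for c in self.COLUMNS[1:]]
        return "\t".join(out)

    @staticmethod
    def tsv_header() -> str:
        return "\t".join(QualityReport.COLUMNS)


# ---------------------------------------------------------------------------
# Superposition and distance metrics
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition (proper rotation).

    Returns ((R, t), rmsd); `R @ x + t` maps mobile onto reference.
    """
    R, t, rmsd = kabsch(mobile, reference)
    return (R, t), rmsd


def _paired_ca(model: StructureModel, reference: StructureModel):
    ref_by_seq = {r.resseq: r for r in reference.residues}
    mob, ref = [], []
    for r in model.residues:
        other = ref_by_seq.get(r.resseq)
        if other is not None and r.has_atom("CA") and other.has_atom("CA"):
            mob.append(r.coord("CA"))
            ref.append(other.coord("CA"))
    if not mob:
        raise ValueError("no common residues between model and reference")
    return np.array(mob), np.array(ref)


def rmsd_ca(model: StructureModel, reference: StructureModel) -> float:
    """CA RMSD after optimal superposition."""
    mob, ref = _paired_ca(model, reference)
    _, rmsd = superpose(mob, ref)
    return rmsd


def _coverage_fractions(mob, ref, thresholds, seeds):
    """Best fraction of atoms within each threshold over iterative
    superpositions started from each seed subset."""
    n = len(mob)
    best = {t: 0.0 for t in thresholds}
    for seed in seeds:
        idx = np.asarray(seed)
        if len(idx) < 3:
            continue
        for t in thresholds:
            sel = idx
            for _ in range(20):
                try:
                    (R, tr), _ = superpose(mob[sel], ref[sel])
                except ValueError:
                    break
                d = np.linalg.norm(mob @ R.T + tr - ref, axis=1)
                inliers = np.nonzero(d <= t)[0]
                if len(inliers) < 3:
                    break
                if len(inliers) == len(sel) and np.array_equal(inliers, sel):
                    break
                sel = inliers
            else:
                pass
            try:
                (R, tr), _ = superpose(mob[sel], ref[sel])
                d = np.linalg.norm(mob @ R.T + tr - ref, axis=1)
                frac = float(np.mean(d <= t))
                best[t] = max(best[t], frac)
            except ValueError:
                continue
    return [best[t] for t in thresholds]


def _gdt_seeds(n: int, window: int = 5):
    seeds = [list(range(n))]
    for start in range(0, max(1, n - window + 1)):
        seeds.append(list(range(start, min(n, start + window))))
    return seeds


def gdt_ha(model: StructureModel, reference: StructureModel) -> float:
    """High-accuracy global distance test over CA atoms (percent).

    Mean over the 0.5/1/2/4 A thresholds of the maximal fraction of CA
    atoms superposable within the threshold, estimated by multi-seed
    iterative superposition (all contiguous 5-residue windows plus the
    global alignment as seeds).
    """
    mob, ref = _paired_ca(model, reference)
    fracs = _coverage_fractions(mob, ref, GDT_THRESHOLDS,
                                _gdt_seeds(len(mob)))
    return 100.0 * float(np.mean(fracs))


def gdc_sc(model: StructureModel, reference: StructureModel) -> float:
    """Side-chain global distance calculation (percent).

    One characteristic atom per residue type (GLY excluded), scored over
    thresholds 0.5..5.0 A with linearly decreasing weights 10..1, under
    CA-based superpositions as in gdt_ha.
    """
    ref_by_seq = {r.resseq: r for r in reference.residues}
    mob_ca, ref_ca, mob_sc, ref_sc = [], [], [], []
    for r in model.residues:
        other = ref_by_seq.get(r.resseq)
        if other is None:
            continue
        if r.has_atom("CA") and other.has_atom("CA"):
            mob_ca.append(r.coord("CA"))
            ref_ca.append(other.coord("CA"))
        name = chemdata.GDC_SC_ATOM.get(r.resname)
        if name and r.has_atom(name) and other.has_atom(name):
            mob_sc.append(r.coord(name))
            ref_sc.append(other.coord(name))
    if not mob_ca:
        raise ValueError("no common residues between model and reference")
    if not mob_sc:
        return 0.0
    mob_ca, ref_ca = np.array(mob_ca), np.array(ref_ca)
    mob_sc, ref_sc = np.array(mob_sc), np.array(ref_sc)
    weights = np.arange(10, 0, -1, dtype=float)
    best = np.zeros(len(GDC_THRESHOLDS))
    for seed in _gdt_seeds(len(mob_ca)):
        idx = np.asarray(seed)
        if len(idx) < 3:
            continue
        (R, t), _ = superpose(mob_ca[idx], ref_ca[idx])
        d = np.linalg.norm(mob_sc @ R.T + t - ref_sc, axis=1)
        fracs = np.array([np.mean(d <= thr) for thr in GDC_THRESHOLDS])
        best = np.maximum(best, fracs)
    return float(100.0 * np.sum(weights * best) / weights.sum())


# ---------------------------------------------------------------------------
# Physical-correctness metrics
# ---------------------------------------------------------------------------

def clashscore(model: StructureModel, add_missing_hydrogens: bool = True
               ) -> float:
    """Steric clashes (>=0.4 A vdW overlap) per 1000 atoms."""
    work = add_hydrogens(model) if add_missing_hydrogens else model
    n_atoms = sum(1 for _ in work.iter_atoms())
    if n_atoms == 0:
        return 0.0
    clashes = detect_clashes(work)
    return 1000.0 * len(clashes) / n_atoms


def rotamer_outliers(model: StructureModel,
                     library: RotamerLibrary | None = None) -> float:
    """Percent of chi-bearing residues whose chi vector is farther than
    40 degrees (per angle, circular) from every library rotamer."""
    library = library or default_rotamer_library()
    total = outliers = 0
    for i, res in enumerate(model.residues):
        if res.n_chi == 0:
            continue
        entries = library.rotamers.get(res.resname)
        if not entries:
            continue
        chis = np.array(model.chi(i))
        total += 1
        ok = False
        for rot, _p in entries:
            dev = np.abs(wrap_angle(chis - np.array(rot)))
            if np.all(dev <= ROTAMER_OUTLIER_CUTOFF):
                ok = True
                break
        if not ok:
            outliers += 1
    return 100.0 * outliers / total if total else 0.0


# Coarse favored-region rectangles (phi_lo, phi_hi, psi_lo, psi_hi) per
# class; approximations to the kernel-density contours used by full
# MolProbity.  psi intervals may wrap through 180.
_GENERAL_FAVORED = [
    (-160.0, -20.0, -80.0, 0.0),     # alpha
    (-180.0, -40.0, 90.0, 180.0),    # beta / PPII
    (-180.0, -40.0, -180.0, -150.0),  # beta, wrapped psi
    (40.0, 90.0, 0.0, 80.0),         # left-handed alpha
]
_GLY_FAVORED = _GENERAL_FAVORED + [
    (20.0, 180.0, -60.0, 60.0),
    (40.0, 180.0, 90.0, 180.0),
    (40.0, 180.0, -180.0, -150.0),
]
_PRO_FAVORED = [
    (-100.0, -40.0, -60.0, 10.0),
    (-100.0, -40.0, 110.0, 180.0),
]


def _in_favored(phi: float, psi: float, resname: str) -> bool:
    boxes = (_GLY_FAVORED if resname == "GLY"
             else _PRO_FAVORED if resname == "PRO" else _GENERAL_FAVORED)
    phi = float(wrap_angle(phi))
    psi = float(wrap_angle(psi))
    return any(plo <= phi <= phi_hi and pslo <= psi <= pshi
               for plo, phi_hi, pslo, pshi in boxes)


def rama_favored(model: StructureModel) -> float:
    """Percent of non-terminal residues in the favored backbone regions."""
    if len(model.residues) < 3:
        raise ValueError("need at least 3 residues for backbone torsions")
    total = favored = 0
    for i in range(1, len(model.residues) - 1):
        res = model.residues[i]
        total += 1
        if _in_favored(model.phi(i), model.psi(i), res.resname):
            favored += 1
    return 100.0 * favored / total if total else 0.0


def molprobity_score(clash: float, rot_out: float, rama_fav: float) -> float:
    """MolProbity-style composite physical-correctness score (lower is
    better; experimental structures typically score 1-2)."""
    return (0.42574 * math.log(1.0 + clash)
            + 0.32996 * math.log(1.0 + max(0.0, rot_out - 1.0))
            + 0.24979 * math.log(1.0 + max(0.0, (100.0 - rama_fav) - 2.0))
            + 0.5)


def quality_report(model: StructureModel, reference: StructureModel,
                   label: str = "model") -> QualityReport:
    """Full quality report of `model` against the reference structure."""
    clash = clashscore(model)
    rot = rotamer_outliers(model)
    rama = rama_favored(model)
    return QualityReport(
        model=label,
        rmsd=rmsd_ca(model, reference),
        gdt_ha=gdt_ha(model, reference),
        gdc_sc=gdc_sc(model, reference),
        clashscore=clash,
        rotamer_outliers_pct=rot,
        rama_favored_pct=rama,
        molprobity=molprobity_score(clash, rot, rama),
    )
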