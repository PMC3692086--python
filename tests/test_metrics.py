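"""Quality metrics: identities, invariances, oracle agreement."""

import math

import numpy as np
import pytest

from protrefine import chemdata, metrics
from protrefine.fixtures import FixtureSpec, build_peptide
from protrefine.geometry import rotation_about_axis


# ------------------------------------------------------------ superpose
def test_superpose_identity(strand_model):
    ca = strand_model.ca_coords()
    (rot, trans), rmsd = metrics.superpose(ca, ca)
    assert rmsd < 1e-9
    assert np.abs(rot - np.eye(3)).max() < 1e-9
    assert np.abs(trans).max() < 1e-9


def test_superpose_recovers_rigid_motion(strand_model):
    ca = strand_model.ca_coords()
    rot = rotation_about_axis([2.0, -1.0, 0.5], 0.9)
    moved = ca @ rot.T + np.array([1.0, 2.0, 3.0])
    _, rmsd = metrics.superpose(moved, ca)
    assert rmsd < 1e-9


def test_superpose_proper_rotation_only(strand_model):
    ca = strand_model.ca_coords()
    mirrored = ca * np.array([-1.0, 1.0, 1.0])
    (rot, _), _ = metrics.superpose(mirrored, ca)
    assert np.linalg.det(rot) > 0.99


def test_superpose_matches_scipy_oracle(rng):
    """Independent oracle: scipy's align_vectors on a 10-point toy with
    one point displaced."""
    from scipy.spatial.transform import Rotation
    pts = rng.normal(size=(10, 3)) * 4.0
    target = pts.copy()
    target[3] += np.array([1.0, -0.5, 0.7])
    (rot, trans), rmsd = metrics.superpose(pts, target)
    r_or, rssd = Rotation.align_vectors(target - target.mean(axis=0),
                                        pts - pts.mean(axis=0))
    oracle_rmsd = rssd / math.sqrt(len(pts))
    assert abs(rmsd - oracle_rmsd) < 1e-6


def test_superpose_rejects_degenerate():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError):
        metrics.superpose(line, line)
    with pytest.raises(ValueError):
        metrics.superpose(line[:2], line[:2])


# --------------------------------------------------------------- GDT-HA
def test_gdt_ha_self_is_100(strand_model):
    assert metrics.gdt_ha(strand_model, strand_model) == 100.0


def test_gdt_ha_rigid_motion_invariant(strand_model):
    moved = strand_model.copy()
    rot = rotation_about_axis([1.0, 2.0, 3.0], 0.7)
    moved.set_coords(strand_model.coords() @ rot.T + 5.0)
    assert abs(metrics.gdt_ha(moved, strand_model) - 100.0) < 1e-6


def _exhaustive_gdt_oracle(mob, ref, thresholds):
    """Iterative superposition from every contiguous window of every
    length >= 3, plus the global alignment."""
    n = len(mob)
    seeds = [list(range(n))]
    for length in range(3, n + 1):
        for start in range(0, n - length + 1):
            seeds.append(list(range(start, start + length)))
    return metrics._coverage_fractions(mob, ref, thresholds, seeds)


def test_gdt_ha_matches_exhaustive_seed_oracle():
    """Half of a 20-residue coil displaced far beyond every threshold:
    the multi-seed search must agree with the exhaustive contiguous-seed
    oracle, and the score is exactly 50."""
    model = build_peptide(FixtureSpec("AVKLDSETAGKLMNQRSTVA",
                                      conformation="coil", seed=1))
    moved = model.copy()
    for i in range(10):
        for atom in moved.residues[i].atoms:
            atom.coord = atom.coord + np.array([0.0, 0.0, 20.0])
    got = metrics.gdt_ha(moved, model)
    mob = moved.ca_coords()
    ref = model.ca_coords()
    oracle = 100.0 * np.mean(_exhaustive_gdt_oracle(
        mob, ref, metrics.GDT_THRESHOLDS))
    assert abs(got - oracle) < 1e-9
    assert got == 50.0  # half the CAs displaced far beyond 4 A


def test_gdt_ha_at_least_global_superposition_coverage(coil_model):
    moved = coil_model.copy()
    rng = np.random.default_rng(3)
    moved.set_coords(coil_model.coords()
                     + rng.normal(0, 1.0, coil_model.coords().shape))
    mob, ref = moved.ca_coords(), coil_model.ca_coords()
    (rot, tr), _ = metrics.superpose(mob, ref)
    d = np.linalg.norm(mob @ rot.T + tr - ref, axis=1)
    global_cov = 100.0 * np.mean([
        np.mean(d <= t) for t in metrics.GDT_THRESHOLDS])
    assert metrics.gdt_ha(moved, coil_model) >= global_cov - 1e-9


# --------------------------------------------------------------- GDC-SC
def test_gdc_sc_self_is_100(strand_model):
    assert metrics.gdc_sc(strand_model, strand_model) == 100.0


def test_gdc_sc_zero_beyond_all_thresholds(strand_model):
    moved = strand_model.copy()
    for res in moved.residues:
        name = chemdata.GDC_SC_ATOM.get(res.resname)
        if name and res.has_atom(name):
            res.atom(name).coord = res.atom(name).coord + 40.0
    assert metrics.gdc_sc(moved, strand_model) == 0.0


def test_gdc_sc_single_displacement_closed_form(strand_model):
    """One characteristic atom displaced 0.7 A with an exact backbone:
    hand-evaluated linear weighting 10..1 over thresholds 0.5..5.0."""
    moved = strand_model.copy()
    res = moved.residues[3]  # LEU, characteristic atom CD1
    res.atom("CD1").coord = res.atom("CD1").coord + \
        np.array([0.0, 0.0, 0.7])
    n_sc = sum(1 for r in strand_model.residues
               if r.resname in chemdata.GDC_SC_ATOM)
    weights = np.arange(10, 0, -1, dtype=float)
    fracs = np.array([(n_sc - 1 + (0.7 <= t)) / n_sc
                      for t in metrics.GDC_THRESHOLDS])
    expected = 100.0 * np.sum(weights * fracs) / weights.sum()
    assert abs(metrics.gdc_sc(moved, strand_model) - expected) < 1e-6


# ----------------------------------------------------------- clashscore
def test_clashscore_zero_on_clean_fixture(strand_model):
    assert metrics.clashscore(strand_model) == 0.0


def test_clashscore_formula_single_pair():
    """Clashscore is 1000 x clashes / atoms by definition."""
    model = build_peptide(FixtureSpec(
        "AGAGAGAGAGAGAGAG", conformation="strand",
        defects=[("clash_pair",
                  {"residue_a": 2, "residue_b": 8, "distance": 2.7})]))
    from protrefine.pdb_model import add_hydrogens
    from protrefine.rotamer_repack import detect_clashes
    withh = add_hydrogens(model)
    n_atoms = sum(1 for _ in withh.iter_atoms())
    n_clash = len(detect_clashes(withh))
    assert n_clash >= 1
    expected = 1000.0 * n_clash / n_atoms
    assert abs(metrics.clashscore(model) - expected) < 1e-9


def test_clashscore_intensive_under_duplication():
    base = build_peptide(FixtureSpec(
        "AGAGAGAG", conformation="strand",
        defects=[("clash_pair",
                  {"residue_a": 2, "residue_b": 6, "distance": 2.7})]))
    score = metrics.clashscore(base)
    assert score > 0.0
    # a far-away clash-free copy doubles atoms; clashes stay constant,
    # so the per-1000-atom score halves (intensive in the atom count)
    import copy
    doubled = base.copy()
    extra = build_peptide(FixtureSpec("AGAGAGAG", conformation="strand"))
    for k, res in enumerate(extra.residues):
        shifted = copy.deepcopy(res)
        shifted.resseq = len(base.residues) + k + 1
        for atom in shifted.atoms:
            atom.coord = atom.coord + np.array([500.0, 0.0, 0.0])
        doubled.residues.append(shifted)
    assert abs(metrics.clashscore(doubled) - score / 2.0) < 0.3


# ------------------------------------------------------ rotamer outliers
def test_rotamer_outliers_zero_at_library(strand_model):
    assert metrics.rotamer_outliers(strand_model) == 0.0


def test_rotamer_outliers_counts_forced_outlier():
    model = build_peptide(FixtureSpec(
        "AVKLDEFSTA", conformation="strand",
        defects=[("scramble_chi",
                  {"residue": 3, "chi": [100.0, -100.0]})]))
    n_chi = sum(1 for r in model.residues if r.n_chi > 0)
    expected = 100.0 / n_chi
    assert abs(metrics.rotamer_outliers(model) - expected) < 1e-9


def test_rotamer_outliers_gly_ala_denominator():
    model = build_peptide(FixtureSpec("AGAGA", conformation="strand"))
    assert metrics.rotamer_outliers(model) == 0.0


# ---------------------------------------------------------- Ramachandran
def test_rama_helix_favored(helix_model):
    assert metrics.rama_favored(helix_model) == 100.0


def test_rama_disallowed_region_scores_zero():
    model = build_peptide(FixtureSpec(
        "AVKLDSET", conformation="custom",
        phi_psi=[(170.0, 170.0)] * 8))
    assert metrics.rama_favored(model) == 0.0


def test_rama_excludes_termini():
    model = build_peptide(FixtureSpec("AAAA", conformation="helix"))
    # only residues 1..n-2 enter; 2 interior residues here
    assert metrics.rama_favored(model) in (0.0, 50.0, 100.0)


# ------------------------------------------------------------ MolProbity
def test_molprobity_floor():
    assert metrics.molprobity_score(0.0, 0.0, 100.0) == 0.5


def test_molprobity_frozen_example():
    expected = (0.42574 * math.log(11.0) + 0.32996 * math.log(5.0)
                + 0.24979 * math.log(9.0) + 0.5)
    assert abs(expected - 2.6007748) < 1e-6  # frozen closed-form value
    assert abs(metrics.molprobity_score(10.0, 5.0, 90.0)
               - expected) < 1e-12


def test_molprobity_monotonicity():
    base = metrics.molprobity_score(0.0, 5.0, 90.0)
    assert metrics.molprobity_score(10.0, 5.0, 90.0) > base
    assert metrics.molprobity_score(0.0, 8.0, 90.0) > base
    assert metrics.molprobity_score(0.0, 5.0, 80.0) > base


# -------------------------------------------------------- quality report
def test_report_self_comparison(helix_model):
    rep = metrics.quality_report(helix_model, helix_model, "m")
    assert rep.rmsd < 1e-9
    assert rep.gdt_ha == 100.0
    assert rep.gdc_sc == 100.0


def test_report_fields_match_individual_calls(strand_model, coil_model):
    # compare same-length models residue-by-residue
    rep = metrics.quality_report(strand_model, strand_model, "m")
    assert rep.clashscore == metrics.clashscore(strand_model)
    assert rep.rotamer_outliers_pct == \
        metrics.rotamer_outliers(strand_model)
    assert rep.rama_favored_pct == metrics.rama_favored(strand_model)
    assert rep.molprobity == metrics.molprobity_score(
        rep.clashscore, rep.rotamer_outliers_pct, rep.rama_favored_pct)


def test_report_tsv_roundtrip(helix_model):
    rep = metrics.quality_report(helix_model, helix_model, "model_1")
    header = metrics.QualityReport.tsv_header().split("\t")
    row = rep.to_tsv_row().split("\t")
    assert len(header) == len(row) == 8
    assert row[0] == "model_1"
    assert float(row[2]) == 100.0
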