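"""Triaxial loop closure: exactness, solution sets, locality."""

import numpy as np
import pytest

from protrefine.geometry import wrap_angle
from protrefine.loop_closure import (ClosureProblem, CLOSURE_TOLERANCE,
                                     apply_closure_solution,
                                     perturb_and_close, triaxial_close)
from protrefine.pdb_model import set_torsion

SEGMENT = (4, 11)
PIVOTS = (4, 8, 11)


def _stem_deviation(model, reference, e):
    worst = 0.0
    for i in range(e + 1, len(reference.residues)):
        for name in ("N", "CA", "C"):
            d = np.abs(model.residues[i].coord(name)
                       - reference.residues[i].coord(name)).max()
            worst = max(worst, float(d))
    return worst


def test_identity_problem_recovers_original_torsions(coil_model):
    problem = ClosureProblem(coil_model.copy(), SEGMENT, PIVOTS)
    solutions = triaxial_close(problem)
    assert solutions
    original = []
    for p in PIVOTS:
        original.extend([coil_model.phi(p), coil_model.psi(p)])
    deviations = [
        np.abs(wrap_angle(np.array(
            [v for pair in sol.pivot_torsions for v in pair])
            - np.array(original))).max()
        for sol in solutions]
    assert min(deviations) < 1e-4


def test_solutions_close_exactly_forward_kinematics(coil_model):
    """Residuals re-verified by applying torsions through set_torsion,
    independently of the solver's internal kinematics."""
    problem = ClosureProblem(coil_model.copy(), SEGMENT, PIVOTS)
    for sol in triaxial_close(problem):
        applied = apply_closure_solution(coil_model.copy(), PIVOTS, sol)
        dev = _stem_deviation(applied, coil_model, SEGMENT[1])
        assert dev < CLOSURE_TOLERANCE


def test_solution_count_capped(coil_model, rng):
    for _ in range(5):
        perturbed = coil_model
        for i in (5, 6, 9):
            perturbed = set_torsion(perturbed, i, "psi",
                                    perturbed.psi(i)
                                    + float(rng.normal(0, 12)))
        problem = ClosureProblem(
            perturbed, SEGMENT, PIVOTS,
            target_stem=np.array([coil_model.residues[12].coord(n)
                                  for n in ("N", "CA", "C")]))
        assert len(triaxial_close(problem)) <= 16


def test_reapplying_a_solution_is_a_fixed_point(coil_model):
    problem = ClosureProblem(coil_model.copy(), SEGMENT, PIVOTS)
    sol = triaxial_close(problem)[0]
    applied = apply_closure_solution(coil_model.copy(), PIVOTS, sol)
    again = triaxial_close(ClosureProblem(
        applied.copy(), SEGMENT, PIVOTS,
        target_stem=problem.target_stem))
    flat = np.array([v for pair in sol.pivot_torsions for v in pair])
    best = min(np.abs(wrap_angle(np.array(
        [v for pair in s.pivot_torsions for v in pair]) - flat)).max()
        for s in again)
    assert best < 1e-6


def test_unreachable_anchor_returns_empty(coil_model):
    target = np.array([coil_model.residues[12].coord(n)
                       for n in ("N", "CA", "C")]) + 60.0
    problem = ClosureProblem(coil_model.copy(), SEGMENT, PIVOTS,
                             target_stem=target)
    assert triaxial_close(problem) == []


def test_pivot_validation():
    import protrefine.fixtures as fx
    model = fx.build_peptide(fx.FixtureSpec("AVSLDSETAGSL",
                                            conformation="coil", seed=2))
    with pytest.raises(ValueError):
        ClosureProblem(model, (2, 9), (5, 4, 8))  # not increasing
    with pytest.raises(ValueError):
        ClosureProblem(model, (2, 9), (1, 4, 8))  # outside segment


def test_proline_pivot_rejected():
    import protrefine.fixtures as fx
    model = fx.build_peptide(fx.FixtureSpec("AVSLPSETAGSL",
                                            conformation="coil", seed=2))
    with pytest.raises(ValueError):
        ClosureProblem(model, (2, 9), (3, 4, 8))


def test_perturb_and_close_zero_noise_identity(coil_model, rng):
    out, rejected = perturb_and_close(coil_model, SEGMENT, PIVOTS,
                                      0.0, rng)
    assert not rejected
    assert np.abs(out.coords() - coil_model.coords()).max() < 1e-6


def test_perturb_and_close_locality(coil_model, rng):
    out, rejected = perturb_and_close(coil_model, SEGMENT, PIVOTS,
                                      8.0, rng)
    assert not rejected
    s, e = SEGMENT
    for i in list(range(0, s)) + list(range(e + 1,
                                            len(coil_model.residues))):
        for a, b in zip(out.residues[i].atoms,
                        coil_model.residues[i].atoms):
            assert np.array_equal(a.coord, b.coord)


def test_perturb_and_close_preserves_peptide_bonds(coil_model, rng):
    out, rejected = perturb_and_close(coil_model, SEGMENT, PIVOTS,
                                      8.0, rng)
    assert not rejected
    for i in range(len(out.residues) - 1):
        d_new = np.linalg.norm(out.residues[i].coord("C")
                               - out.residues[i + 1].coord("N"))
        d_old = np.linalg.norm(coil_model.residues[i].coord("C")
                               - coil_model.residues[i + 1].coord("N"))
        assert abs(d_new - d_old) < 1e-6


def test_random_solvable_problems_meet_residual_contract(coil_model):
    """Batch of random perturb-then-close problems, all residuals under
    the closure tolerance (larger batch in the acceptance suite)."""
    rng = np.random.default_rng(5)
    solved = 0
    for _ in range(30):
        out, rejected = perturb_and_close(coil_model, SEGMENT, PIVOTS,
                                          float(rng.uniform(2, 12)), rng)
        if rejected:
            continue
        solved += 1
        assert _stem_deviation(out, coil_model, SEGMENT[1]) < 1e-6
    assert solved >= 15
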