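"""Protocol orchestration: counts, selection, clustering, determinism."""

import numpy as np
import pytest

from protrefine.energy import total_energy
from protrefine.fixtures import FixtureSpec, build_peptide, make_decoy_pool
from protrefine.pdb_model import add_hydrogens
from protrefine.protocol import (RefinementConfig, generate_pool, refine,
                                 run_trajectory, secondary_structure,
                                 select_cluster_representatives,
                                 select_model1)
from protrefine.rotamer_repack import rebuild_side_chains


@pytest.fixture(scope="module")
def prepared():
    model = build_peptide(FixtureSpec("AVSLDSETAGSLKNQA",
                                      conformation="coil", seed=2))
    return add_hydrogens(rebuild_side_chains(model))


def test_default_config_matches_protocol_constants():
    cfg = RefinementConfig()
    assert cfg.pool_size == 32
    assert cfg.mild_cycles == 22
    assert cfg.aggressive_cycles == 17
    assert cfg.timestep_fs == 4.0
    assert cfg.mild_md_ps == 0.6
    assert cfg.aggressive_md_ps == 0.8
    assert cfg.n_representatives == 4
    assert cfg.energy.w_rst_mild / cfg.energy.w_rst_aggressive == 5.0


def test_config_validation():
    with pytest.raises(ValueError):
        RefinementConfig(pool_size=0)
    with pytest.raises(ValueError):
        RefinementConfig(pool_size=2, n_representatives=4)


def test_config_yaml_roundtrip():
    cfg = RefinementConfig.desk(master_seed=9)
    again = RefinementConfig.from_yaml(cfg.to_yaml())
    assert again.to_dict() == cfg.to_dict()


def test_secondary_structure_classes():
    helix = build_peptide(FixtureSpec("ADKLSEIAQKMEETFKAA", "helix"))
    assert set(secondary_structure(helix)) <= {"H", "C"}
    assert secondary_structure(helix).count("H") >= 10
    strand = build_peptide(FixtureSpec("AVKVTVSV", "strand"))
    assert secondary_structure(strand).count("E") >= 4


def test_trajectory_executes_exact_cycle_count(prepared):
    cfg = RefinementConfig.desk(mild_cycles=3, aggressive_cycles=2,
                                mild_md_ps=0.008, aggressive_md_ps=0.008,
                                minimize_steps=3)
    _, log = run_trajectory(prepared, "mild", cfg, seed=1)
    assert len(log) == 3
    _, log = run_trajectory(prepared, "aggressive", cfg, seed=1)
    assert len(log) == 2
    assert all(row["regime"] == "aggressive" for row in log)


def test_null_protocol_is_near_identity(prepared):
    cfg = RefinementConfig.desk(
        mild_cycles=1, mild_md_ps=0.0, minimize_steps=0,
        sidechain_cluster_radius=-1.0)  # radius < 0: no residue selected
    out, _ = run_trajectory(prepared, "mild", cfg, seed=1)
    assert np.abs(out.coords() - prepared.coords()).max() < 1e-3


def test_mild_perturbation_leaves_backbone(prepared):
    """With minimization and MD disabled, the mild regime's side-chain
    perturbations leave every backbone atom untouched."""
    cfg = RefinementConfig.desk(mild_cycles=2, mild_md_ps=0.0,
                                minimize_steps=0)
    out, _ = run_trajectory(prepared, "mild", cfg, seed=5)
    assert np.abs(out.backbone_coords()
                  - prepared.backbone_coords()).max() == 0.0


def test_pool_counts_and_seed_derivation(prepared):
    cfg = RefinementConfig.desk(pool_size=3, mild_cycles=1,
                                mild_md_ps=0.008, minimize_steps=2,
                                n_representatives=2, master_seed=11)
    pool, _ = generate_pool(prepared, "mild", cfg)
    assert len(pool) == 3
    # trajectory i equals a lone run with seed master+i
    lone, _ = run_trajectory(prepared, "mild", cfg, seed=12)
    assert np.array_equal(pool[1].coords(), lone.coords())


def test_pool_bitwise_reproducible(prepared):
    cfg = RefinementConfig.desk(pool_size=2, mild_cycles=1,
                                mild_md_ps=0.008, minimize_steps=2,
                                n_representatives=2, master_seed=4)
    a, _ = generate_pool(prepared, "mild", cfg)
    b, _ = generate_pool(prepared, "mild", cfg)
    for x, y in zip(a, b):
        assert np.array_equal(x.coords(), y.coords())


def test_select_model1_argmin_and_ties(prepared):
    pool = [prepared.copy() for _ in range(3)]
    assert select_model1(pool, [3.0, -1.0, 2.0]) is pool[1]
    assert select_model1(pool, [2.0, 2.0, 2.0]) is pool[0]
    with pytest.raises(ValueError):
        select_model1([], [])


def test_select_model1_permutation_invariant(prepared, rng):
    pool = [prepared.copy() for _ in range(5)]
    energies = [4.0, 1.0, 3.0, 0.5, 2.0]
    best = select_model1(pool, energies)
    order = rng.permutation(5)
    best2 = select_model1([pool[i] for i in order],
                          [energies[i] for i in order])
    assert best is best2


def test_cluster_representatives_recover_planted_modes():
    pool, labels = make_decoy_pool(
        FixtureSpec("AVSLDSETAGSLKNQA", conformation="coil", seed=2),
        8, 4, 0.15, seed=9)
    reps = select_cluster_representatives(pool, 4)
    rep_modes = sorted(labels[pool.index(r)] for r in reps)
    assert rep_modes == [0, 1, 2, 3]


def test_cluster_singletons_return_pool_in_order():
    pool, _ = make_decoy_pool(
        FixtureSpec("AVSLDSETAGSLKNQA", conformation="coil", seed=2),
        4, 4, 0.0, seed=9)
    reps = select_cluster_representatives(pool, 4, cutoff=0.01)
    assert [pool.index(r) for r in reps] == [0, 1, 2, 3]


def test_cluster_padding_with_low_energy_members():
    pool, _ = make_decoy_pool(
        FixtureSpec("AVSLDSETAGSLKNQA", conformation="coil", seed=2),
        6, 1, 0.001, seed=9)
    energies = [5.0, 4.0, 3.0, 2.0, 1.0, 0.0]
    reps = select_cluster_representatives(pool, 3, energies,
                                          cutoff=5.0)
    # one real cluster; two pads from the lowest-energy unpicked members
    assert len(reps) == 3


def test_refine_end_to_end_desk_scale():
    model = build_peptide(FixtureSpec(
        "AVKLDSETAYHQ", conformation="strand",
        defects=[("scramble_chi", {"residue": 3})], seed=4))
    cfg = RefinementConfig.desk(master_seed=3, pool_size=2,
                                mild_cycles=1, aggressive_cycles=1,
                                mild_md_ps=0.02, aggressive_md_ps=0.02,
                                n_representatives=2, minimize_steps=5)
    result = refine(model, cfg)
    assert len(result.models) == 3  # model 1 + 2 representatives
    assert len(result.reports) == 3
    # model 1 energy is minimal over its pool by construction
    prepared = add_hydrogens(rebuild_side_chains(model))
    pool, _ = generate_pool(prepared, "mild", cfg)
    energies = [total_energy(m, prepared, cfg.energy, "mild").total
                for m in pool]
    assert abs(total_energy(result.models[0], prepared, cfg.energy,
                            "mild").total - min(energies)) < 1e-9


def test_refine_rejects_invalid_input():
    broken = build_peptide(FixtureSpec(
        "AVKLDSETAG", conformation="helix",
        defects=[("delete_residue", {"residue": 4})]))
    with pytest.raises(ValueError):
        refine(broken, RefinementConfig.desk())


def test_refine_outputs_reparse(tmp_path):
    from protrefine.pdb_model import read_pdb
    model = build_peptide(FixtureSpec("AVSLDSET", conformation="strand"))
    cfg = RefinementConfig.desk(pool_size=2, mild_cycles=1,
                                aggressive_cycles=1, mild_md_ps=0.008,
                                aggressive_md_ps=0.008,
                                n_representatives=2, minimize_steps=3)
    result = refine(model, cfg, output_dir=str(tmp_path))
    assert (tmp_path / "report.tsv").exists()
    assert (tmp_path / "run_log.tsv").exists()
    assert (tmp_path / "config.yaml").exists()
    for k in range(1, len(result.models) + 1):
        text = (tmp_path / f"model_{k}.pdb").read_text()
        parsed = read_pdb(text)
        assert len(parsed.residues) == len(model.residues)
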