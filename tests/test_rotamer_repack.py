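"""Side-chain repacking: neighbor counts, clash detection, rebuild rules."""

import numpy as np
import pytest

from protrefine import chemdata
from protrefine.fixtures import FixtureSpec, build_peptide
from protrefine.pdb_model import bond_graph, virtual_cbeta
from protrefine.rotamer_repack import (
    BurialProfile, CBETA_CUTOFF, OVERLAP_THRESHOLD, RotamerLibrary,
    cbeta_neighbor_count, contact_radii, default_burial_profile,
    default_rotamer_library, detect_clashes, exposure_class,
    perturb_side_chain_cluster, rebuild_side_chains,
    side_chain_neighbor_count)


# ---------------------------------------------------------------- library
def test_default_library_invariants():
    lib = default_rotamer_library()
    for resname, entries in lib.rotamers.items():
        probs = [p for _, p in entries]
        assert probs == sorted(probs, reverse=True)
        assert all(0.0 < p <= 1.0 for p in probs)
        for chis, _ in entries:
            assert len(chis) == chemdata.CHI_COUNT[resname]
    # every chi-bearing type is covered
    for resname, n in chemdata.CHI_COUNT.items():
        if n > 0:
            assert resname in lib.rotamers


def test_library_rejects_unsorted():
    with pytest.raises(ValueError):
        RotamerLibrary({"SER": [((-60.0,), 0.2), ((60.0,), 0.5)]})


def test_burial_profile_intervals_valid():
    prof = default_burial_profile()
    for (resname, klass), (lo, hi) in prof.intervals.items():
        assert resname in chemdata.AA3
        assert klass in ("buried", "intermediate", "exposed")
        assert 0 <= lo <= hi


# ------------------------------------------------------- neighbor counts
def test_single_residue_has_no_neighbors():
    model = build_peptide(FixtureSpec("V"))
    assert cbeta_neighbor_count(model, 0) == 0


def test_neighbor_count_matches_brute_force(strand_model):
    cb = [virtual_cbeta(r) for r in strand_model.residues]
    for i in range(len(cb)):
        brute = sum(1 for j in range(len(cb)) if j != i
                    and np.linalg.norm(cb[i] - cb[j]) <= CBETA_CUTOFF)
        assert cbeta_neighbor_count(strand_model, i) == brute


def test_neighbor_count_symmetry(coil_model):
    cb = [virtual_cbeta(r) for r in coil_model.residues]
    for i in range(len(cb)):
        for j in range(len(cb)):
            if i == j:
                continue
            near_ij = np.linalg.norm(cb[i] - cb[j]) <= CBETA_CUTOFF
            near_ji = np.linalg.norm(cb[j] - cb[i]) <= CBETA_CUTOFF
            assert near_ij == near_ji


def test_exposure_classes_partition():
    assert exposure_class(0) == "exposed"
    assert exposure_class(7) == "intermediate"
    assert exposure_class(15) == "buried"


# -------------------------------------------------------- clash detection
def test_clash_free_fixture_empty(helix_model):
    assert detect_clashes(helix_model) == []


def test_forced_cb_overlap_reported():
    model = build_peptide(FixtureSpec(
        "AVKLDSETAG", conformation="helix",
        defects=[("clash_pair",
                  {"residue_a": 2, "residue_b": 7, "distance": 1.0})]))
    clashes = detect_clashes(model)
    cb_pairs = [(a, b) for a, b, _ in clashes
                if a[1] == "CB" and b[1] == "CB"]
    assert ((2, "CB"), (7, "CB")) in cb_pairs or \
        ((7, "CB"), (2, "CB")) in cb_pairs


def test_clash_detector_matches_brute_force():
    import networkx as nx
    model = build_peptide(FixtureSpec(
        "AVKLDEFSTAYHQNMRWICGAVKLDEFSTAYHQNMRWICGAVKLDSETAG",
        conformation="coil", seed=8))
    # independent bond-path oracle via networkx shortest paths
    adj = bond_graph(model)
    g = nx.Graph()
    for k, nbs in adj.items():
        for nb in nbs:
            g.add_edge(k, nb)
    keys = model.atom_keys()
    coords = model.coords()
    radii = contact_radii(model)
    paths = dict(nx.all_pairs_shortest_path_length(g, cutoff=3))
    expected = set()
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if paths.get(keys[i], {}).get(keys[j], 99) <= 3:
                continue
            d = np.linalg.norm(coords[i] - coords[j])
            if radii[i] + radii[j] - d > OVERLAP_THRESHOLD:
                expected.add((keys[i], keys[j]))
    got = {(a, b) for a, b, _ in detect_clashes(model)}
    assert got == expected


# --------------------------------------------------------------- rebuild
def test_rebuild_no_chi_is_identity():
    model = build_peptide(FixtureSpec("AGAGAG", conformation="strand"))
    out = rebuild_side_chains(model)
    assert np.array_equal(out.coords(), model.coords())


def test_rebuild_reduces_clashes_of_scrambled_leu():
    model = build_peptide(FixtureSpec(
        "AVKLDEFSTAYHQNMRWICG", conformation="strand",
        defects=[("scramble_chi",
                  {"residue": 3, "chi": [60.0, -60.0]})]))
    before = len(detect_clashes(model))
    assert before > 0
    out = rebuild_side_chains(model)
    assert len(detect_clashes(out)) < before


def test_rebuild_never_moves_backbone(strand_model):
    out = rebuild_side_chains(strand_model)
    assert np.abs(out.backbone_coords()
                  - strand_model.backbone_coords()).max() == 0.0


def test_rebuild_idempotent_on_library_conformation(strand_model):
    once = rebuild_side_chains(strand_model)
    twice = rebuild_side_chains(once)
    assert np.abs(twice.coords() - once.coords()).max() < 1e-9


def test_rebuild_errors_on_missing_type(strand_model):
    lib = default_rotamer_library()
    partial = RotamerLibrary({k: v for k, v in lib.rotamers.items()
                              if k != "LEU"})
    with pytest.raises(KeyError):
        rebuild_side_chains(strand_model, library=partial)


def test_burial_filter_restores_input_conformation(strand_model):
    """A narrow burial interval that the rebuilt rotamer violates must
    revert that residue to its input chi angles."""
    i = 6  # PHE in the strand fixture
    scrambled = build_peptide(FixtureSpec(
        "AVKLDEFSTAYHQNMRWICG", conformation="strand",
        defects=[("scramble_chi",
                  {"residue": i, "chi": [-177.0, 55.0]})]))
    input_chi = scrambled.chi(i)
    count = cbeta_neighbor_count(scrambled, i)
    klass = exposure_class(count)
    sc = side_chain_neighbor_count
    # interval that the top-rotamer rebuild violates but the input obeys
    rebuilt_plain = rebuild_side_chains(scrambled)
    rebuilt_count = sc(rebuilt_plain, i)
    tight = BurialProfile({("PHE", klass): (rebuilt_count + 1,
                                            rebuilt_count + 5)})
    out = rebuild_side_chains(scrambled, burial=tight)
    assert np.allclose(out.chi(i), input_chi, atol=1e-6)


# ---------------------------------------------------------- perturbation
def test_perturb_radius_zero_only_seed(coil_model, rng):
    out = perturb_side_chain_cluster(coil_model, 5, 0.0, rng)
    moved = {k[0] for k, (a, b) in zip(
        coil_model.atom_keys(),
        zip(out.coords(), coil_model.coords()))
        if np.abs(a - b).max() > 1e-12}
    assert moved <= {5}


def test_perturb_backbone_invariant(coil_model, rng):
    out = perturb_side_chain_cluster(coil_model, 5, 8.0, rng)
    assert np.abs(out.backbone_coords()
                  - coil_model.backbone_coords()).max() == 0.0


def test_perturb_bit_reproducible(coil_model):
    a = perturb_side_chain_cluster(coil_model, 4, 6.0,
                                   np.random.default_rng(77))
    b = perturb_side_chain_cluster(coil_model, 4, 6.0,
                                   np.random.default_rng(77))
    assert np.array_equal(a.coords(), b.coords())


def test_layer_order_is_neighbor_sorted(coil_model):
    counts = [cbeta_neighbor_count(coil_model, i)
              for i in range(len(coil_model.residues))]
    order = sorted(range(len(counts)), key=lambda i: (-counts[i], i))
    assert counts == sorted(counts, reverse=True) or \
        all(counts[order[k]] >= counts[order[k + 1]]
            for k in range(len(order) - 1))
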