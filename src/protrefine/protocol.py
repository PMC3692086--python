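"""Refinement protocol: two relaxation regimes and model selection.

The mild regime perturbs clusters of side chains only and relaxes under
strong restraints; the aggressive regime perturbs secondary-structure
elements and loops (reconnected by triaxial loop closure) under restraints
five times weaker.  The lowest-energy member of the mild pool becomes
model 1; representatives of the largest clusters of the aggressive pool
become models 2-5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform

from .dynamics import MDSettings, md_relax, minimize
from .energy import EnergyParams, total_energy
from .loop_closure import perturb_and_close
from .metrics import QualityReport, quality_report, superpose
from .pdb_model import (StructureModel, add_hydrogens, validate_model,
                        write_pdb)
from .rotamer_repack import perturb_side_chain_cluster, rebuild_side_chains

__all__ = [
    "RefinementConfig", "RefinementResult", "secondary_structure",
    "run_trajectory", "generate_pool", "select_model1",
    "select_cluster_representatives", "refine",
]


@dataclass
class RefinementConfig:
    """All protocol constants, defaulting to the full protocol scale."""

    pool_size: int = 32
    mild_cycles: int = 22
    aggressive_cycles: int = 17
    timestep_fs: float = 4.0
    mild_md_ps: float = 0.6
    aggressive_md_ps: float = 0.8
    temperature: float = 300.0
    friction_per_ps: float = 5.0
    sidechain_cluster_radius: float = 6.0   # A
    segment_noise_deg: float = 10.0
    element_shift_max: float = 0.5          # A
    element_rot_max_deg: float = 5.0
    n_representatives: int = 4
    cluster_cutoff: float = 2.0             # A CA-RMSD
    minimize_steps: int = 50
    master_seed: int = 0
    energy: EnergyParams = field(default_factory=EnergyParams)

    def __post_init__(self):
        if self.pool_size < 1:
            raise ValueError("pool size must be >= 1")
        if self.mild_cycles < 1 or self.aggressive_cycles < 1:
            raise ValueError("cycle counts must be >= 1")
        if self.n_representatives > self.pool_size:
            raise ValueError("representatives cannot exceed pool size")

    def cycles(self, regime: str) -> int:
        return (self.mild_cycles if regime == "mild"
                else self.aggressive_cycles)

    def md_settings(self, regime: str, seed: int) -> MDSettings:
        duration = (self.mild_md_ps if regime == "mild"
                    else self.aggressive_md_ps)
        return MDSettings(timestep_fs=self.timestep_fs,
                          duration_ps=duration,
                          temperature=self.temperature,
                          friction_per_ps=self.friction_per_ps,
                          seed=seed)

    @classmethod
    def desk(cls, **overrides) -> "RefinementConfig":
        """Reduced desk-scale preset for fast end-to-end runs."""
        kw = dict(pool_size=4, mild_cycles=2, aggressive_cycles=2,
                  mild_md_ps=0.04, aggressive_md_ps=0.04,
                  minimize_steps=15)
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        energy = d.pop("energy")
        energy.pop("pair_table", None)
        d["energy"] = energy
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RefinementConfig":
        data = dict(data)
        energy = data.pop("energy", {})
        if isinstance(energy, dict):
            energy.pop("pair_table", None)
            energy = EnergyParams(**energy)
        return cls(energy=energy, **data)

    @classmethod
    def from_yaml(cls, text: str) -> "RefinementConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


@dataclass
class RefinementResult:
    models: list                 # model 1 + cluster representatives
    breakdowns: list             # EnergyBreakdown per output model
    reports: list                # QualityReport per output model vs input
    run_log: list                # per-cycle dicts

    def write(self, output_dir) -> None:
        import os
        os.makedirs(output_dir, exist_ok=True)
        for k, model in enumerate(self.models, start=1):
            with open(os.path.join(output_dir, f"model_{k}.pdb"), "w") as fh:
                fh.write(write_pdb(model))
        with open(os.path.join(output_dir, "report.tsv"), "w") as fh:
            fh.write(QualityReport.tsv_header() + "\n")
            for rep in self.reports:
                fh.write(rep.to_tsv_row() + "\n")
        with open(os.path.join(output_dir, "run_log.tsv"), "w") as fh:
            fh.write("trajectory\tregime\tcycle\tmove\trejected\ttotal\n")
            for row in self.run_log:
                fh.write("{trajectory}\t{regime}\t{cycle}\t{move}\t"
                         "{rejected}\t{total:.4f}\n".format(**row))


# ---------------------------------------------------------------------------
# Secondary structure and aggressive moves
# ---------------------------------------------------------------------------

def secondary_structure(model: StructureModel) -> str:
    """Per-residue H/E/C assignment from backbone torsions; helix runs
    are corroborated by an i -> i+4 backbone hydrogen-bond pattern."""
    n = len(model.residues)
    ss = ["C"] * n
    for i in range(1, n - 1):
        phi, psi = model.phi(i), model.psi(i)
        if -100.0 < phi < -30.0 and -80.0 < psi < -5.0:
            ss[i] = "H"
        elif -180.0 <= phi < -45.0 and (psi > 90.0 or psi < -150.0):
            ss[i] = "E"
    # demote short runs; helix runs need at least one i->i+4 H bond
    out = ss[:]
    i = 0
    while i < n:
        j = i
        while j < n and ss[j] == ss[i]:
            j += 1
        run, kind = j - i, ss[i]
        if kind == "H":
            if run < 4:
                out[i:j] = ["C"] * run
            else:
                ok = False
                for k in range(i, j - 4):
                    o = model.residues[k].coord("O")
                    nn = model.residues[k + 4].coord("N")
                    if np.linalg.norm(o - nn) < 3.5:
                        ok = True
                        break
                if not ok:
                    out[i:j] = ["C"] * run
        elif kind == "E" and run < 3:
            out[i:j] = ["C"] * run
        i = j
    return "".join(out)


def _runs(ss: str, kind_set) -> list:
    runs, i = [], 0
    while i < len(ss):
        j = i
        while j < len(ss) and ss[j] == ss[i]:
            j += 1
        if ss[i] in kind_set:
            runs.append((i, j - 1))
        i = j
    return runs


def _closable(segment, model) -> tuple | None:
    """Clip a segment to valid closure bounds and choose non-PRO pivots."""
    s, e = segment
    s = max(s, 1)
    e = min(e, len(model.residues) - 2)
    if e - s < 2:
        return None
    candidates = [i for i in range(s, e + 1)
                  if model.residues[i].resname != "PRO"]
    if len(candidates) < 3:
        return None
    p1, p3 = candidates[0], candidates[-1]
    inner = [i for i in candidates if p1 < i < p3]
    if not inner:
        return None
    p2 = inner[len(inner) // 2]
    return (s, e), (p1, p2, p3)


def _loop_move(model, segment, config, rng):
    clip = _closable(segment, model)
    if clip is None:
        return model.copy(), True
    seg, pivots = clip
    return perturb_and_close(model, seg, pivots,
                             config.segment_noise_deg, rng)


def _element_move(model, element, config, rng):
    """Rigid shift/rotation of a secondary-structure element with
    triaxial closure of the flanking loops."""
    s, e = element
    n = len(model.residues)
    ss = secondary_structure(model)
    # flanking coil stretches
    left = right = None
    if s > 0:
        i = s - 1
        while i >= 0 and ss[i] == "C":
            i -= 1
        left = (i + 1, s - 1)
    if e < n - 1:
        j = e + 1
        while j < n and ss[j] == "C":
            j += 1
        right = (e + 1, j - 1)
    need_left = s > 0
    need_right = e < n - 1
    left_clip = _closable(left, model) if need_left and left else None
    right_clip = _closable(right, model) if need_right and right else None
    if (need_left and left_clip is None) or \
            (need_right and right_clip is None):
        return model.copy(), True

    work = model.copy()
    atoms = [a for i in range(s, e + 1) for a in work.residues[i].atoms]
    centroid = np.mean([a.coord for a in atoms], axis=0)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-config.element_rot_max_deg,
                                   config.element_rot_max_deg))
    shift = rng.normal(size=3)
    shift = shift / np.linalg.norm(shift) \
        * rng.uniform(0.0, config.element_shift_max)
    from .geometry import rotation_about_axis
    rot = rotation_about_axis(axis, float(angle))
    for a in atoms:
        a.coord = rot @ (a.coord - centroid) + centroid + shift

    if need_left:
        seg, pivots = left_clip
        # close the left loop onto the moved element start
        target = np.array([work.residues[seg[1] + 1].coord(nm)
                           for nm in ("N", "CA", "C")])
        from .loop_closure import (ClosureProblem, apply_closure_solution,
                                   triaxial_close)
        try:
            prob = ClosureProblem(work, seg, pivots, target_stem=target)
            sols = triaxial_close(prob)
        except ValueError:
            return model.copy(), True
        if not sols:
            return model.copy(), True
        work = apply_closure_solution(work, pivots, sols[0])
    if need_right:
        seg, pivots = right_clip
        target = np.array([model.residues[seg[1] + 1].coord(nm)
                           for nm in ("N", "CA", "C")])
        from .loop_closure import (ClosureProblem, apply_closure_solution,
                                   triaxial_close)
        try:
            prob = ClosureProblem(work, seg, pivots, target_stem=target)
            sols = triaxial_close(prob)
        except ValueError:
            return model.copy(), True
        if not sols:
            return model.copy(), True
        work = apply_closure_solution(work, pivots, sols[0])
        # snap everything after the right loop back to the input
        for i in range(seg[1] + 1, n):
            for atom, orig in zip(work.residues[i].atoms,
                                  model.residues[i].atoms):
                atom.coord = orig.coord.copy()
    return work, False


def _aggressive_perturbation(model, config, rng):
    ss = secondary_structure(model)
    loops = [r for r in _runs(ss, {"C"}) if r[1] - r[0] + 1 >= 3]
    elements = _runs(ss, {"H", "E"})
    targets = [("loop", r) for r in loops] + \
              [("element", r) for r in elements]
    if not targets:
        # no classified target: fall back to a window in the chain middle
        n = len(model.residues)
        seg = (max(1, n // 3), min(n - 2, 2 * n // 3 + 2))
        targets = [("loop", seg)]
    kind, seg = targets[int(rng.integers(len(targets)))]
    if kind == "loop":
        return _loop_move(model, seg, config, rng), kind
    return _element_move(model, seg, config, rng), kind


# ---------------------------------------------------------------------------
# Trajectories and pools
# ---------------------------------------------------------------------------

def run_trajectory(initial: StructureModel, regime: str,
                   config: RefinementConfig, seed: int):
    """One trajectory: `cycles` iterations of perturb -> minimize -> MD.

    Returns (final model, per-cycle log).  The restraint reference is the
    starting model.
    """
    rng = np.random.default_rng(seed)
    reference = initial
    model = initial.copy()
    log = []
    for cycle in range(config.cycles(regime)):
        rejected = False
        if regime == "mild":
            seed_res = int(rng.integers(len(model.residues)))
            model = perturb_side_chain_cluster(
                model, seed_res, config.sidechain_cluster_radius, rng)
            move = f"sidechain@{seed_res}"
        else:
            (model, rejected), kind = _aggressive_perturbation(
                model, config, rng)
            move = kind
        model, _ = minimize(model, reference, config.energy, regime,
                            max_steps=config.minimize_steps)
        md_seed = int(rng.integers(2 ** 31))
        settings = config.md_settings(regime, md_seed)
        model = md_relax(model, reference, config.energy, regime, settings)
        bd = total_energy(model, reference, config.energy, regime)
        log.append({"regime": regime, "cycle": cycle, "move": move,
                    "rejected": rejected, "total": bd.total})
    return model, log


def generate_pool(initial: StructureModel, regime: str,
                  config: RefinementConfig):
    """Independent trajectories with seeds master_seed + i.

    Returns (models, logs)."""
    models, logs = [], []
    for i in range(config.pool_size):
        model, log = run_trajectory(initial, regime, config,
                                    config.master_seed + i)
        for row in log:
            row["trajectory"] = i
        models.append(model)
        logs.extend(log)
    return models, logs


def select_model1(pool: list, energies: list) -> StructureModel:
    """Pool member with the minimum total energy (ties: lowest index)."""
    if not pool:
        raise ValueError("empty pool")
    if len(pool) != len(energies):
        raise ValueError("energies not aligned with pool")
    best = int(np.argmin(np.asarray(energies, float)))
    return pool[best]


def _ca_rmsd_matrix(pool: list) -> np.ndarray:
    n = len(pool)
    coords = [m.ca_coords() for m in pool]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, r = superpose(coords[i], coords[j])
            mat[i, j] = mat[j, i] = r
    return mat


def select_cluster_representatives(pool: list, n: int,
                                   energies: list | None = None,
                                   cutoff: float = 2.0) -> list:
    """Representatives of the `n` largest CA-RMSD clusters.

    Average-linkage hierarchical clustering cut at `cutoff` A; each
    cluster is represented by the member with the lowest mean RMSD to its
    cluster (ties: lowest index).  If fewer than `n` clusters exist, the
    selection is padded with the lowest-energy unpicked members (by pool
    order when no energies are given)."""
    if n < 1:
        raise ValueError("need n >= 1 representatives")
    if len(pool) < n:
        raise ValueError("pool smaller than requested representatives")
    mat = _ca_rmsd_matrix(pool)
    if len(pool) == 1:
        return [pool[0]]
    z = linkage(squareform(mat, checks=False), method="average")
    labels = fcluster(z, t=cutoff, criterion="distance")
    clusters: dict = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(idx)
    ordered = sorted(clusters.values(), key=lambda c: (-len(c), min(c)))
    picked = []
    for members in ordered[:n]:
        sub = mat[np.ix_(members, members)]
        mean_r = sub.mean(axis=1)
        rep = members[int(np.argmin(mean_r))]
        picked.append(rep)
    if len(picked) < n:
        remaining = [i for i in range(len(pool)) if i not in picked]
        if energies is not None:
            remaining.sort(key=lambda i: (energies[i], i))
        picked.extend(remaining[: n - len(picked)])
    return [pool[i] for i in picked]


def refine(model: StructureModel, config: RefinementConfig | None = None,
           output_dir=None) -> RefinementResult:
    """Full refinement: side-chain rebuild, mild pool -> model 1,
    aggressive pool -> cluster-representative models 2..(1+n)."""
    config = config or RefinementConfig()
    check = validate_model(model)
    if not check.ok:
        raise ValueError("input failed validation: "
                         + "; ".join(check.findings))
    prepared = add_hydrogens(rebuild_side_chains(model))

    mild_pool, mild_log = generate_pool(prepared, "mild", config)
    mild_energies = [total_energy(m, prepared, config.energy, "mild").total
                     for m in mild_pool]
    model1 = select_model1(mild_pool, mild_energies)

    aggr_pool, aggr_log = generate_pool(prepared, "aggressive", config)
    aggr_energies = [
        total_energy(m, prepared, config.energy, "aggressive").total
        for m in aggr_pool]
    reps = select_cluster_representatives(
        aggr_pool, config.n_representatives, aggr_energies,
        cutoff=config.cluster_cutoff)

    models = [model1] + reps
    breakdowns = []
    reports = []
    for k, out in enumerate(models, start=1):
        regime = "mild" if k == 1 else "aggressive"
        breakdowns.append(total_energy(out, prepared, config.energy, regime))
        reports.append(quality_report(out, model, label=f"model_{k}"))
    result = RefinementResult(models=models, breakdowns=breakdowns,
                              reports=reports,
                              run_log=mild_log + aggr_log)
    if output_dir is not None:
        result.write(output_dir)
        import os
        with open(os.path.join(output_dir, "config.yaml"), "w") as fh:
            fh.write(config.to_yaml())
    return result
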