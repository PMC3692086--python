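"""Deterministic synthetic-structure generator.

Builds ideal-geometry polypeptides (helix/strand/coil/custom backbone
torsions, side chains at top-probability rotamers) and decoy pools with
planted conformational modes, so that every stage of the refinement
pipeline is testable without any external structure files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import chemdata
from .geometry import place_atom
from .pdb_model import Atom, Residue, StructureModel, set_torsion, write_pdb

__all__ = ["FixtureSpec", "build_peptide", "fixture_pdb_text",
           "make_decoy_pool", "HELIX_PHI_PSI", "STRAND_PHI_PSI"]

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 130.0)
_COIL_CHOICES = [(-57.0, -47.0), (-120.0, 130.0), (-75.0, 145.0),
                 (-90.0, 0.0), (-140.0, 160.0)]


@dataclass
class FixtureSpec:
    sequence: str
    conformation: str = "helix"  # helix | strand | coil | custom
    phi_psi: list = field(default_factory=list)  # used when custom
    defects: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        bad = [c for c in self.sequence if c not in chemdata.AA1_TO_3]
        if bad:
            raise ValueError(f"invalid sequence letter(s): {bad}")
        if self.conformation not in ("helix", "strand", "coil", "custom"):
            raise ValueError(f"unknown conformation {self.conformation!r}")
        if self.conformation == "custom" and \
                len(self.phi_psi) != len(self.sequence):
            raise ValueError("custom conformation needs one (phi,psi) "
                             "pair per residue")

    @classmethod
    def from_yaml(cls, text: str) -> "FixtureSpec":
        data = yaml.safe_load(text)
        return cls(**data)


def _backbone_torsions(spec: FixtureSpec) -> list:
    n = len(spec.sequence)
    if spec.conformation == "helix":
        return [HELIX_PHI_PSI] * n
    if spec.conformation == "strand":
        return [STRAND_PHI_PSI] * n
    if spec.conformation == "custom":
        return [tuple(map(float, pp)) for pp in spec.phi_psi]
    rng = np.random.default_rng(spec.seed)
    idx = rng.integers(0, len(_COIL_CHOICES), size=n)
    return [_COIL_CHOICES[k] for k in idx]


def _resolve_torsion(tors, chi: list) -> float:
    if isinstance(tors, (int, float)):
        return float(tors)
    expr = tors[3:]  # strip "chi"
    for sep in ("+", "-"):
        if sep in expr:
            k, off = expr.split(sep)
            base = chi[int(k) - 1]
            return base + float(off) if sep == "+" else base - float(off)
    return chi[int(expr) - 1]


def _build_side_chain(res: Residue, chi: list) -> None:
    for entry in chemdata.SIDECHAIN_TEMPLATES[res.resname]:
        name, a, b, c, bond, ang, tors = entry
        coord = place_atom(res.coord(a), res.coord(b), res.coord(c),
                           bond, ang, _resolve_torsion(tors, chi))
        res.atoms.append(Atom(name, chemdata.element_of(name), coord))


def top_rotamer(resname: str) -> list:
    """Highest-probability rotamer chi set for a residue type."""
    from .rotamer_repack import default_rotamer_library
    lib = default_rotamer_library()
    if chemdata.CHI_COUNT[resname] == 0:
        return []
    return list(lib.rotamers[resname][0][0])


def build_peptide(spec: FixtureSpec) -> StructureModel:
    """Build an ideal-geometry peptide from a fixture spec.

    Deterministic for a fixed spec: ideal bond lengths/angles, requested
    backbone torsions, side chains at the top library rotamer.
    """
    torsions = _backbone_torsions(spec)
    cd = chemdata
    residues = []
    prev = None
    for i, letter in enumerate(spec.sequence):
        resname = cd.AA1_TO_3[letter]
        res = Residue(resname, i + 1)
        phi_i = torsions[i][0]
        if prev is None:
            n = np.zeros(3)
            ca = np.array([cd.BOND_N_CA, 0.0, 0.0])
            th = np.radians(180.0 - cd.ANGLE_N_CA_C)
            c = ca + cd.BOND_CA_C * np.array([np.cos(th), np.sin(th), 0.0])
        else:
            psi_prev = torsions[i - 1][1]
            n = place_atom(prev.coord("N"), prev.coord("CA"), prev.coord("C"),
                           cd.BOND_C_N, cd.ANGLE_CA_C_N, psi_prev)
            ca = place_atom(prev.coord("CA"), prev.coord("C"), n,
                            cd.BOND_N_CA, cd.ANGLE_C_N_CA, cd.OMEGA_TRANS)
            c = place_atom(prev.coord("C"), n, ca,
                           cd.BOND_CA_C, cd.ANGLE_N_CA_C, phi_i)
        res.atoms.append(Atom("N", "N", n))
        res.atoms.append(Atom("CA", "C", ca))
        res.atoms.append(Atom("C", "C", c))
        if prev is not None:
            # carbonyl O of the previous residue, anti to this N
            o = place_atom(n, prev.coord("CA"), prev.coord("C"),
                           cd.BOND_C_O, cd.ANGLE_CA_C_O, 180.0)
            prev.atoms.insert(3, Atom("O", "O", o))
        residues.append(res)
        prev = res
    # C-terminal carbonyl O from psi of the last residue
    last = residues[-1]
    psi_last = torsions[-1][1]
    o = place_atom(last.coord("N"), last.coord("CA"), last.coord("C"),
                   cd.BOND_C_O, cd.ANGLE_CA_C_O, psi_last + 180.0)
    last.atoms.insert(3, Atom("O", "O", o))
    for res in residues:
        if res.resname == "GLY":
            continue
        cb_angle = cd.ANGLE_N_CA_CB_BY_RES.get(res.resname, cd.ANGLE_N_CA_CB)
        cb = place_atom(res.coord("C"), res.coord("N"), res.coord("CA"),
                        cd.BOND_CA_CB, cb_angle, cd.CB_IMPROPER)
        res.atoms.append(Atom("CB", "C", cb))
        _build_side_chain(res, top_rotamer(res.resname))
    model = StructureModel(residues, "A", provenance="fixture")
    return _apply_defects(model, spec)


def _apply_defects(model: StructureModel, spec: FixtureSpec):
    rng = np.random.default_rng(spec.seed)
    for defect in spec.defects:
        kind, params = defect[0], dict(defect[1]) if len(defect) > 1 else {}
        if kind == "scramble_chi":
            i = params["residue"]
            res = model.residues[i]
            values = params.get("chi")
            for k in range(res.n_chi):
                val = (values[k] if values is not None
                       else float(rng.uniform(-180.0, 180.0)))
                model = set_torsion(model, i, f"chi{k + 1}", val)
        elif kind == "displace_residue":
            i = params["residue"]
            offset = np.asarray(params.get("offset", [10.0, 0.0, 0.0]), float)
            for atom in model.residues[i].atoms:
                atom.coord = atom.coord + offset
        elif kind == "delete_residue":
            i = params["residue"]
            model = StructureModel(
                [r for j, r in enumerate(model.residues) if j != i],
                model.chain_id, model.provenance)
        elif kind == "clash_pair":
            # slide residue_b's side chain until its CB sits `distance`
            # from residue_a's CB; the backbone stays intact
            ia, ib = params["residue_a"], params["residue_b"]
            sep = float(params.get("distance", 1.0))
            ra, rb = model.residues[ia], model.residues[ib]
            direction = rb.coord("CB") - ra.coord("CB")
            direction /= np.linalg.norm(direction)
            target = ra.coord("CB") + sep * direction
            shift = target - rb.coord("CB")
            for atom in rb.atoms:
                if atom.name not in ("N", "CA", "C", "O"):
                    atom.coord = atom.coord + shift
        elif kind == "split_chain":
            pass  # applied at text level by fixture_pdb_text
        else:
            raise ValueError(f"unknown defect type {kind!r}")
    return model


def fixture_pdb_text(spec: FixtureSpec) -> str:
    """PDB text for a fixture; split_chain defects take effect here."""
    model = build_peptide(spec)
    split_at = None
    for defect in spec.defects:
        if defect[0] == "split_chain":
            split_at = defect[1]["residue"] if len(defect) > 1 else \
                len(model.residues) // 2
    text = write_pdb(model)
    if split_at is None:
        return text
    out = []
    for line in text.splitlines():
        if line.startswith(("ATOM", "TER")):
            resseq = int(line[22:26])
            if resseq > split_at:
                line = line[:21] + "B" + line[22:]
        out.append(line)
    return "\n".join(out) + "\n"


def make_decoy_pool(base_spec: FixtureSpec, n: int, k: int,
                    sigma: float, seed: int):
    """Decoy pool with `k` planted conformational modes.

    Modes differ by a large psi change at the central residue; each decoy
    is its mode conformation plus isotropic Gaussian coordinate noise of
    width `sigma` (A).  Returns (models, mode_labels).
    """
    if not (n >= k >= 1):
        raise ValueError("need n >= k >= 1")
    base = build_peptide(base_spec)
    center = len(base.residues) // 2
    psi0 = base.psi(center)
    offsets = [0.0] + [s * 60.0 * ((j // 2) + 1)
                       for j, s in enumerate([1, -1] * k)][: k - 1]
    modes = [set_torsion(base, center, "psi", psi0 + off) for off in offsets]
    rng = np.random.default_rng(seed)
    pool, labels = [], []
    for i in range(n):
        m = i % k
        decoy = modes[m].copy()
        if sigma > 0:
            xyz = decoy.coords()
            xyz = xyz + rng.normal(0.0, sigma, size=xyz.shape)
            decoy.set_coords(xyz)
        decoy.provenance = f"decoy mode={m}"
        pool.append(decoy)
        labels.append(m)
    return pool, labels
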