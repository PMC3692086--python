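"""Single-chain protein structure model: I/O, validation, torsions.

The model is deliberately minimal: one chain of standard amino acids with
Cartesian coordinates, plus conversion between Cartesian and internal
(torsion) coordinates.  Reading goes through Bio.PDB; writing emits
fixed-column ATOM records directly.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import chemdata
from .geometry import dihedral, rotate_points, wrap_angle

__all__ = [
    "Atom", "Residue", "StructureModel", "ValidationResult",
    "read_pdb", "write_pdb", "validate_model", "set_torsion", "get_torsion",
    "add_hydrogens", "virtual_cbeta",
    "PDBError", "EmptyInputError", "MultiChainError",
    "UnsupportedResidueError", "UndefinedTorsionError",
]

# Peptide C-N distance above which consecutive residues count as a chain
# break (covalent length ~1.33 A; generous slack for distorted models).
GAP_CN_THRESHOLD = 2.5


class PDBError(ValueError):
    """Base class for structure-input errors."""


class EmptyInputError(PDBError):
    pass


class MultiChainError(PDBError):
    pass


class UnsupportedResidueError(PDBError):
    pass


class UndefinedTorsionError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name}")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coord.copy(),
                    self.occupancy, self.bfactor)


@dataclass
class Residue:
    resname: str
    resseq: int
    atoms: list = field(default_factory=list)

    def __post_init__(self):
        if self.resname not in chemdata.AA3:
            raise UnsupportedResidueError(
                f"unsupported residue name {self.resname!r}")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.resname}{self.resseq} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coord(self, name: str) -> np.ndarray:
        return self.atom(name).coord

    @property
    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if a.element != "H"]

    @property
    def n_chi(self) -> int:
        return chemdata.CHI_COUNT[self.resname]

    def copy(self) -> "Residue":
        return Residue(self.resname, self.resseq,
                       [a.copy() for a in self.atoms])


class StructureModel:
    """Ordered single-chain list of residues with torsion access."""

    def __init__(self, residues, chain_id: str = "A", provenance: str = ""):
        self.residues = list(residues)
        self.chain_id = chain_id
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.residues)

    def copy(self) -> "StructureModel":
        return StructureModel([r.copy() for r in self.residues],
                              self.chain_id, self.provenance)

    # ---- flat coordinate access -------------------------------------
    def iter_atoms(self):
        for i, res in enumerate(self.residues):
            for atom in res.atoms:
                yield i, atom

    def atom_keys(self) -> list:
        return [(i, a.name) for i, a in self.iter_atoms()]

    def coords(self) -> np.ndarray:
        return np.array([a.coord for _, a in self.iter_atoms()], float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, float)
        k = 0
        for _, atom in self.iter_atoms():
            atom.coord = xyz[k].copy()
            k += 1
        if k != len(xyz):
            raise ValueError("coordinate array length mismatch")

    def ca_coords(self) -> np.ndarray:
        return np.array([r.coord("CA") for r in self.residues])

    def backbone_coords(self) -> np.ndarray:
        out = []
        for r in self.residues:
            for name in ("N", "CA", "C", "O"):
                if r.has_atom(name):
                    out.append(r.coord(name))
        return np.array(out)

    @property
    def sequence(self) -> str:
        return "".join(chemdata.AA3_TO_1[r.resname] for r in self.residues)

    # ---- torsions ----------------------------------------------------
    def phi(self, i: int) -> float:
        return get_torsion(self, i, "phi")

    def psi(self, i: int) -> float:
        return get_torsion(self, i, "psi")

    def omega(self, i: int) -> float:
        return get_torsion(self, i, "omega")

    def chi(self, i: int) -> list:
        res = self.residues[i]
        out = []
        for quad in chemdata.CHI_ATOMS[res.resname]:
            out.append(dihedral(*(res.coord(n) for n in quad)))
        return out


@dataclass
class ValidationResult:
    ok: bool
    findings: list


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def read_pdb(text: str) -> StructureModel:
    """Parse PDB-format text into a StructureModel.

    HETATM records, waters and alternate locations other than 'A'/' ' are
    dropped; hydrogens are kept.  A single chain is required.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("input", io.StringIO(text))
    models = list(structure)
    if not models:
        raise EmptyInputError("no ATOM records found")
    chains = []
    for chain in models[0]:
        if any(res.id[0] == " " for res in chain):
            chains.append(chain)
    if not chains:
        raise EmptyInputError("no ATOM records for standard residues")
    if len(chains) > 1:
        ids = ",".join(c.id for c in chains)
        raise MultiChainError(
            f"input must contain a single chain, found chains {ids}")
    chain = chains[0]
    residues = []
    for res in chain:
        if res.id[0] != " ":
            continue
        resname = res.get_resname().strip()
        if resname not in chemdata.AA3:
            raise UnsupportedResidueError(
                f"unsupported residue {resname} {res.id[1]}")
        canonical = set(chemdata.heavy_atom_names(resname))
        atoms = []
        for atom in res.get_unpacked_list():
            if atom.get_altloc() not in (" ", "A"):
                continue
            name = atom.get_name().strip()
            element = (atom.element or chemdata.element_of(name)).strip()
            if element != "H" and name not in canonical:
                continue  # OXT and other non-template heavy atoms dropped
            atoms.append(Atom(name, element, np.array(atom.get_coord(), float),
                              float(atom.get_occupancy() or 1.0),
                              float(atom.get_bfactor() or 0.0)))
        if atoms:
            residues.append(Residue(resname, int(res.id[1]), atoms))
    if not residues:
        raise EmptyInputError("no ATOM records for standard residues")
    return StructureModel(residues, chain.id if chain.id.strip() else "A",
                          provenance="read_pdb")


def write_pdb(model: StructureModel) -> str:
    """Serialize a model to fixed-column PDB ATOM records."""
    if len(model.residues) == 0:
        raise EmptyInputError("cannot write an empty model")
    lines = []
    serial = 1
    chain = (model.chain_id or "A")[0]
    for res in model.residues:
        for atom in res.atoms:
            name = atom.name
            if len(name) < 4:
                name = f" {name:<3s}"
            lines.append(
                "ATOM  {serial:5d} {name:4s} {res:3s} {chain}{seq:4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                "{elem:>2s}".format(
                    serial=serial, name=name, res=res.resname, chain=chain,
                    seq=res.resseq, x=atom.coord[0], y=atom.coord[1],
                    z=atom.coord[2], occ=atom.occupancy, b=atom.bfactor,
                    elem=atom.element))
            serial += 1
    last = model.residues[-1]
    lines.append(f"TER   {serial:5d}      {last.resname:3s} "
                 f"{chain}{last.resseq:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def validate_model(model: StructureModel) -> ValidationResult:
    """Check backbone completeness and the internal-gap rule."""
    findings = []
    for res in model.residues:
        missing = [n for n in ("N", "CA", "C", "O") if not res.has_atom(n)]
        if missing:
            findings.append(
                f"residue {res.resname}{res.resseq} missing backbone "
                f"atom(s) {','.join(missing)}")
    for prev, cur in zip(model.residues, model.residues[1:]):
        if cur.resseq <= prev.resseq:
            findings.append(
                f"residue numbering not increasing {prev.resseq}->{cur.resseq}")
        elif cur.resseq != prev.resseq + 1:
            findings.append(
                f"numbering gap {prev.resseq}→{cur.resseq}")
        if prev.has_atom("C") and cur.has_atom("N"):
            d = float(np.linalg.norm(prev.coord("C") - cur.coord("N")))
            if d > GAP_CN_THRESHOLD:
                findings.append(
                    f"chain break: C({prev.resseq})-N({cur.resseq}) "
                    f"distance {d:.2f} A exceeds {GAP_CN_THRESHOLD} A")
    return ValidationResult(ok=not findings, findings=findings)


# ---------------------------------------------------------------------------
# Bond graph
# ---------------------------------------------------------------------------

def bond_graph(model: StructureModel) -> dict:
    """Adjacency over (residue index, atom name) keys, peptide bonds included.

    Hydrogens with unrecognized names are attached to the nearest heavy atom.
    """
    adj: dict = {key: set() for key in model.atom_keys()}

    def link(a, b):
        if a in adj and b in adj:
            adj[a].add(b)
            adj[b].add(a)

    for i, res in enumerate(model.residues):
        for a, b in chemdata.residue_bonds(res.resname):
            link((i, a), (i, b))
        hmap = {}
        for heavy in chemdata.heavy_atom_names(res.resname):
            for hname in chemdata.hydrogen_names(res.resname, heavy):
                hmap[hname] = heavy
        for atom in res.atoms:
            if atom.element != "H":
                continue
            parent = hmap.get(atom.name)
            if parent is None or not res.has_atom(parent):
                heavies = res.heavy_atoms
                dists = [np.linalg.norm(atom.coord - h.coord)
                         for h in heavies]
                parent = heavies[int(np.argmin(dists))].name
            link((i, atom.name), (i, parent))
    for i in range(len(model.residues) - 1):
        link((i, "C"), (i + 1, "N"))
    return adj


def _downstream(adj, axis_b, axis_c):
    """Atoms reachable from axis_c without crossing back through axis_b."""
    seen = {axis_b, axis_c}
    stack = [axis_c]
    out = []
    while stack:
        node = stack.pop()
        for nxt in adj[node]:
            if nxt not in seen:
                seen.add(nxt)
                out.append(nxt)
                stack.append(nxt)
    return out


# ---------------------------------------------------------------------------
# Torsions
# ---------------------------------------------------------------------------

def _torsion_quad(model: StructureModel, i: int, name: str):
    n = len(model.residues)
    res = model.residues[i]
    if name == "phi":
        if i == 0:
            raise UndefinedTorsionError("phi undefined at the N-terminus")
        return ((i - 1, "C"), (i, "N"), (i, "CA"), (i, "C"))
    if name == "psi":
        if i == n - 1:
            raise UndefinedTorsionError("psi undefined at the C-terminus")
        return ((i, "N"), (i, "CA"), (i, "C"), (i + 1, "N"))
    if name == "omega":
        if i == n - 1:
            raise UndefinedTorsionError("omega undefined at the C-terminus")
        return ((i, "CA"), (i, "C"), (i + 1, "N"), (i + 1, "CA"))
    if name.startswith("chi"):
        k = int(name[3:])
        quads = chemdata.CHI_ATOMS[res.resname]
        if k < 1 or k > len(quads):
            raise UndefinedTorsionError(
                f"{name} undefined for {res.resname}")
        a, b, c, d = quads[k - 1]
        return ((i, a), (i, b), (i, c), (i, d))
    raise UndefinedTorsionError(f"unknown torsion name {name!r}")


def get_torsion(model: StructureModel, i: int, name: str) -> float:
    quad = _torsion_quad(model, i, name)
    pts = [model.residues[ri].coord(an) for ri, an in quad]
    return dihedral(*pts)


def set_torsion(model: StructureModel, i: int, name: str,
                value: float) -> StructureModel:
    """Return a copy of the model with one torsion rotated to `value`.

    Bond lengths and angles are untouched: all atoms distal of the rotation
    axis turn rigidly.  Rotating any torsion of a proline ring (phi or chi)
    is refused because the ring makes the rotation ill defined.
    """
    res = model.residues[i]
    if res.resname == "PRO" and (name == "phi" or name.startswith("chi")):
        raise UndefinedTorsionError(
            f"{name} of PRO is part of the pyrrolidine ring")
    quad = _torsion_quad(model, i, name)
    out = model.copy()
    adj = bond_graph(out)
    pts = [out.residues[ri].coord(an) for ri, an in quad]
    current = dihedral(*pts)
    delta = np.radians(wrap_angle(value - current))
    if abs(delta) < 1e-15:
        return out
    b, c = quad[1], quad[2]
    origin = out.residues[c[0]].coord(c[1])
    axis = origin - out.residues[b[0]].coord(b[1])
    moving = _downstream(adj, b, c)
    coords = np.array([out.residues[ri].coord(an) for ri, an in moving])
    # right-handed rotation about b->c by +delta increases the dihedral
    rotated = rotate_points(coords, origin, axis, float(delta))
    for (ri, an), xyz in zip(moving, rotated):
        out.residues[ri].atom(an).coord = xyz
    return out


# ---------------------------------------------------------------------------
# Hydrogens / virtual atoms
# ---------------------------------------------------------------------------

def virtual_cbeta(res: Residue) -> np.ndarray:
    """CB coordinate; for GLY an ideal-geometry virtual CB."""
    if res.has_atom("CB"):
        return res.coord("CB")
    from .geometry import place_atom
    return place_atom(res.coord("C"), res.coord("N"), res.coord("CA"),
                      chemdata.BOND_CA_CB, chemdata.ANGLE_N_CA_CB,
                      chemdata.CB_IMPROPER)


def _h_positions(res, heavy_name, neighbor_coords, graph_nb, model, i, adj):
    """Ideal positions for the hydrogens of one heavy atom."""
    from .geometry import place_atom

    x = res.coord(heavy_name)
    elem = chemdata.element_of(heavy_name)
    L = chemdata.H_BOND_LENGTH[elem]
    n_h = chemdata.H_COUNT.get(res.resname, {}).get(heavy_name, 0)
    nbs = neighbor_coords
    units = [(p - x) / np.linalg.norm(p - x) for p in nbs]

    def parent_frame():
        # heavy's first heavy neighbor and a grandparent for the dihedral
        p_key = graph_nb[0]
        p = model.residues[p_key[0]].coord(p_key[1])
        gp_candidates = [k for k in sorted(adj[p_key])
                         if chemdata.element_of(k[1]) != "H"
                         and k != (i, heavy_name)]
        gp = model.residues[gp_candidates[0][0]].coord(gp_candidates[0][1])
        return gp, p

    if n_h == 1 and len(units) >= 2:
        d = -np.sum(units, axis=0)
        d /= np.linalg.norm(d)
        return [x + L * d]
    if n_h == 2 and len(units) == 2:
        d1 = -np.sum(units, axis=0)
        d1 /= np.linalg.norm(d1)
        d2 = np.cross(units[0], units[1])
        d2 /= np.linalg.norm(d2)
        half = np.radians(54.75)
        return [x + L * (d1 * np.cos(half) + s * d2 * np.sin(half))
                for s in (+1.0, -1.0)]
    if n_h == 1 and len(units) == 1:
        gp, p = parent_frame()
        ang = 109.5 if elem != "S" else 96.0
        return [place_atom(gp, p, x, L, ang, 180.0)]
    if n_h == 2 and len(units) == 1:
        gp, p = parent_frame()
        return [place_atom(gp, p, x, L, 120.0, t) for t in (0.0, 180.0)]
    if n_h == 3 and len(units) == 1:
        gp, p = parent_frame()
        return [place_atom(gp, p, x, L, 109.47, t)
                for t in (180.0, 60.0, -60.0)]
    raise ValueError(
        f"no hydrogen rule for {res.resname} {heavy_name} "
        f"({n_h} H, {len(units)} heavy neighbors)")


def add_hydrogens(model: StructureModel) -> StructureModel:
    """Return a copy with missing hydrogens placed at ideal geometry.

    Existing hydrogens are kept.  The N-terminal nitrogen receives a single
    amide-style hydrogen (no protonated NH3+ cap is modeled).
    """
    out = model.copy()
    adj = bond_graph(out)
    for i, res in enumerate(out.residues):
        new_atoms = []
        for atom in list(res.atoms):
            new_atoms.append(atom)
            if atom.element == "H":
                continue
            names = chemdata.hydrogen_names(res.resname, atom.name)
            if not names or all(res.has_atom(h) for h in names):
                continue
            graph_nb = [k for k in sorted(adj[(i, atom.name)])
                        if chemdata.element_of(k[1]) != "H"]
            nb_coords = [out.residues[ri].coord(an) for ri, an in graph_nb]
            try:
                positions = _h_positions(res, atom.name, nb_coords,
                                         graph_nb, out, i, adj)
            except (ValueError, IndexError):
                continue  # e.g. N-terminal N with no preceding C
            for hname, pos in zip(names, positions):
                if not res.has_atom(hname):
                    new_atoms.append(Atom(hname, "H", pos))
        res.atoms = new_atoms
    out.provenance = (model.provenance + "+H").strip("+")
    return out
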