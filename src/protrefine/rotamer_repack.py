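"""Side-chain rebuilding by ranked rotamer placement.

Residues are repacked from the protein core outward (descending
C-beta-neighbor count, in quintile layers): each residue receives its
highest-probability rotamer that introduces no new steric clash against the
backbone and already-placed side chains; if every rotamer clashes, the
least-clashing one is kept.  A final burial filter restores the input
conformation of any residue whose rebuilt side chain is packed unlike the
canonical expectation for its amino-acid type at the same exposure.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from . import chemdata
from .pdb_model import StructureModel, bond_graph, virtual_cbeta

__all__ = [
    "RotamerLibrary", "BurialProfile", "default_rotamer_library",
    "default_burial_profile", "cbeta_neighbor_count", "detect_clashes",
    "rebuild_side_chains", "perturb_side_chain_cluster",
    "CBETA_CUTOFF", "OVERLAP_THRESHOLD", "exposure_class",
]

CBETA_CUTOFF = 8.0        # A, C-beta contact convention
OVERLAP_THRESHOLD = 0.4   # A, vdW overlap counted as a clash
EXPOSED_MAX = 4           # neighbor-count bounds for exposure classes
BURIED_MIN = 10


@dataclass
class RotamerLibrary:
    """Per-residue-type ranked side-chain rotamers.

    rotamers: resname -> list of (chi tuple in degrees, probability),
    sorted by descending probability.
    """

    rotamers: dict

    def __post_init__(self):
        for resname, entries in self.rotamers.items():
            nchi = chemdata.CHI_COUNT[resname]
            probs = [p for _, p in entries]
            if any(not (0.0 < p <= 1.0) for p in probs):
                raise ValueError(f"{resname}: probabilities must be in (0,1]")
            if probs != sorted(probs, reverse=True):
                raise ValueError(f"{resname}: rotamers must be sorted by "
                                 "descending probability")
            for chi, _ in entries:
                if len(chi) != nchi:
                    raise ValueError(f"{resname}: chi tuple length mismatch")

    @classmethod
    def from_tsv(cls, text: str) -> "RotamerLibrary":
        rotamers: dict = {}
        for line in text.splitlines():
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            resname = fields[0].strip()
            chis = tuple(float(f) for f in fields[1:5] if f.strip())
            prob = float(fields[5])
            rotamers.setdefault(resname, []).append((chis, prob))
        for entries in rotamers.values():
            entries.sort(key=lambda e: -e[1])
        return cls(rotamers)


@dataclass
class BurialProfile:
    """Expected side-chain neighbor-count interval per (type, exposure)."""

    intervals: dict  # (resname, exposure_class) -> (lo, hi)

    def __post_init__(self):
        for (resname, klass), (lo, hi) in self.intervals.items():
            if lo > hi or lo < 0:
                raise ValueError(
                    f"bad interval for {resname}/{klass}: [{lo},{hi}]")

    @classmethod
    def from_tsv(cls, text: str) -> "BurialProfile":
        intervals = {}
        for line in text.splitlines():
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            resname, klass, lo, hi = line.split("\t")
            intervals[(resname.strip(), klass.strip())] = (int(lo), int(hi))
        return cls(intervals)


@functools.lru_cache(maxsize=1)
def default_rotamer_library() -> RotamerLibrary:
    text = resources.files("protrefine.data").joinpath(
        "rotamer_library.tsv").read_text()
    return RotamerLibrary.from_tsv(text)


@functools.lru_cache(maxsize=1)
def default_burial_profile() -> BurialProfile:
    text = resources.files("protrefine.data").joinpath(
        "burial_profile.tsv").read_text()
    return BurialProfile.from_tsv(text)


# ---------------------------------------------------------------------------
# Burial / clash primitives
# ---------------------------------------------------------------------------

def _cbeta_array(model: StructureModel) -> np.ndarray:
    return np.array([virtual_cbeta(r) for r in model.residues])


def cbeta_neighbor_count(model: StructureModel, i: int,
                         cutoff: float = CBETA_CUTOFF) -> int:
    """Number of other residues whose C-beta lies within `cutoff` of i's."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cb = _cbeta_array(model)
    d = np.linalg.norm(cb - cb[i], axis=1)
    return int(np.sum(d <= cutoff) - 1)


def exposure_class(count: int) -> str:
    if count <= EXPOSED_MAX:
        return "exposed"
    if count >= BURIED_MIN:
        return "buried"
    return "intermediate"


def side_chain_neighbor_count(model: StructureModel, i: int,
                              cutoff: float = CBETA_CUTOFF) -> int:
    """C-beta neighbors counted around the side-chain centroid of residue i."""
    res = model.residues[i]
    side = [a.coord for a in res.heavy_atoms
            if a.name not in ("N", "CA", "C", "O")]
    center = np.mean(side, axis=0) if side else virtual_cbeta(res)
    cb = _cbeta_array(model)
    d = np.linalg.norm(cb - center, axis=1)
    d[i] = np.inf
    return int(np.sum(d <= cutoff))


def contact_radii(model: StructureModel) -> np.ndarray:
    """Per-atom vdW contact radii; polar hydrogens (on N/O/S) are smaller."""
    adj = bond_graph(model)
    radii = []
    for key in model.atom_keys():
        i, name = key
        elem = model.residues[i].atom(name).element
        r = chemdata.VDW_RADIUS[elem]
        if elem == "H":
            parents = [k for k in adj[key]
                       if chemdata.element_of(k[1]) != "H"]
            if parents and chemdata.element_of(parents[0][1]) in "NOS":
                r = chemdata.VDW_RADIUS_H_POLAR
        radii.append(r)
    return np.array(radii)


def _excluded_pairs(model: StructureModel) -> set:
    """Atom index pairs within 3 bonds of each other (1-2, 1-3, 1-4)."""
    adj = bond_graph(model)
    keys = model.atom_keys()
    index = {k: n for n, k in enumerate(keys)}
    excluded = set()
    for k in keys:
        frontier = {k}
        seen = {k}
        for _ in range(3):
            frontier = {n for f in frontier for n in adj[f]} - seen
            seen |= frontier
        a = index[k]
        for other in seen:
            b = index[other]
            if a < b:
                excluded.add((a, b))
    return excluded


def detect_clashes(model: StructureModel, scope=None,
                   threshold: float = OVERLAP_THRESHOLD) -> list:
    """Non-bonded atom pairs overlapping by more than `threshold` (A).

    A pair clashes when its distance is below r_vdw(a)+r_vdw(b)-threshold
    and the atoms are more than 3 bonds apart.  `scope`, if given, is a set
    of (residue index, atom name) keys restricting the report to pairs with
    both atoms inside the scope.  Returns [((i, name_a), (j, name_b),
    overlap), ...] sorted by decreasing overlap.
    """
    keys = model.atom_keys()
    coords = model.coords()
    radii = contact_radii(model)
    excluded = _excluded_pairs(model)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=float(2 * radii.max() - threshold),
                             output_type="ndarray")
    out = []
    for a, b in pairs:
        a, b = int(min(a, b)), int(max(a, b))
        if (a, b) in excluded:
            continue
        if scope is not None and (keys[a] not in scope or
                                  keys[b] not in scope):
            continue
        d = float(np.linalg.norm(coords[a] - coords[b]))
        overlap = radii[a] + radii[b] - d
        if overlap > threshold:
            out.append((keys[a], keys[b], overlap))
    out.sort(key=lambda t: -t[2])
    return out


# ---------------------------------------------------------------------------
# In-place chi rotation within one residue
# ---------------------------------------------------------------------------

def _residue_adjacency(res) -> dict:
    adj: dict = {a.name: set() for a in res.atoms}

    def link(a, b):
        if a in adj and b in adj:
            adj[a].add(b)
            adj[b].add(a)

    for a, b in chemdata.residue_bonds(res.resname):
        link(a, b)
    hmap = {}
    for heavy in chemdata.heavy_atom_names(res.resname):
        for hname in chemdata.hydrogen_names(res.resname, heavy):
            hmap[hname] = heavy
    for atom in res.atoms:
        if atom.element == "H" and atom.name in hmap:
            link(atom.name, hmap[atom.name])
    return adj


def set_chi(res, k: int, value: float) -> None:
    """Rotate chi_k of a residue in place (side-chain atoms only)."""
    from .geometry import dihedral, rotate_points, wrap_angle

    quad = chemdata.CHI_ATOMS[res.resname][k - 1]
    pts = [res.coord(n) for n in quad]
    current = dihedral(*pts)
    delta = np.radians(float(wrap_angle(value - current)))
    if abs(delta) < 1e-15:
        return
    adj = _residue_adjacency(res)
    b, c = quad[1], quad[2]
    seen = {b, c}
    stack = [c]
    moving = []
    while stack:
        node = stack.pop()
        for nxt in adj[node]:
            if nxt not in seen:
                seen.add(nxt)
                moving.append(nxt)
                stack.append(nxt)
    origin = res.coord(c)
    axis = origin - res.coord(b)
    coords = np.array([res.coord(n) for n in moving])
    rotated = rotate_points(coords, origin, axis, delta)
    for name, xyz in zip(moving, rotated):
        res.atom(name).coord = xyz


def apply_rotamer(res, chis) -> None:
    if res.resname == "PRO":
        return  # the pyrrolidine ring is kept rigid
    for k, value in enumerate(chis, start=1):
        set_chi(res, k, value)


# ---------------------------------------------------------------------------
# Repacking
# ---------------------------------------------------------------------------

def _clash_stats(moving_idx, context_idx, coords, radii, excluded):
    """(count, summed overlap) between two atom-index groups."""
    if not moving_idx or not context_idx:
        return 0, 0.0
    mi = np.asarray(moving_idx)
    ci = np.asarray(context_idx)
    d = np.linalg.norm(coords[mi][:, None, :] - coords[ci][None, :, :],
                       axis=2)
    lim = radii[mi][:, None] + radii[ci][None, :] - OVERLAP_THRESHOLD
    over = lim - d
    count, total = 0, 0.0
    for a_pos, b_pos in zip(*np.nonzero(over > 0)):
        a, b = int(mi[a_pos]), int(ci[b_pos])
        pair = (min(a, b), max(a, b))
        if pair in excluded or a == b:
            continue
        count += 1
        total += float(over[a_pos, b_pos])
    return count, total


def rebuild_side_chains(model: StructureModel,
                        library: RotamerLibrary | None = None,
                        burial: BurialProfile | None = None,
                        cutoff: float = CBETA_CUTOFF) -> StructureModel:
    """Rebuild all side chains core-first from ranked rotamers.

    The backbone is never moved.  Proline rings are left at their input
    conformation.  Residues whose rebuilt side chain ends up packed outside
    the burial interval for their type and exposure class revert to the
    input conformation.
    """
    library = library or default_rotamer_library()
    burial = burial or default_burial_profile()
    out = model.copy()
    chi_bearing = [i for i, r in enumerate(out.residues) if r.n_chi > 0]
    for i in chi_bearing:
        resname = out.residues[i].resname
        if resname not in library.rotamers:
            raise KeyError(f"residue type {resname} missing from "
                           "rotamer library")
    counts = [cbeta_neighbor_count(out, i, cutoff)
              for i in range(len(out.residues))]
    order = sorted(range(len(out.residues)),
                   key=lambda i: (-counts[i], i))
    layers = np.array_split(np.array(order), min(5, len(order)))

    keys = out.atom_keys()
    index = {k: n for n, k in enumerate(keys)}
    excluded = _excluded_pairs(out)
    radii = contact_radii(out)
    input_chis = {i: model.chi(i) for i in chi_bearing}
    placed: set = set()

    def atom_groups(i):
        res = out.residues[i]
        moving, backbone = [], []
        for a in res.atoms:
            key = index[(i, a.name)]
            if a.name in ("N", "CA", "C", "O", "CB", "H", "HA",
                          "HA1", "HA2"):
                backbone.append(key)
            else:
                moving.append(key)
        return moving, backbone

    context_fixed = []
    for i, res in enumerate(out.residues):
        _, bb = atom_groups(i)
        context_fixed.extend(bb)

    for layer in layers:
        for i in layer:
            res = out.residues[i]
            if res.n_chi == 0 or res.resname == "PRO":
                placed.add(i)
                continue
            moving, _ = atom_groups(i)
            context = list(context_fixed)
            for j in placed:
                mv, _ = atom_groups(j)
                context.extend(mv)
            best = None
            for chis, _prob in library.rotamers[res.resname]:
                apply_rotamer(res, chis)
                coords = out.coords()
                n_clash, total = _clash_stats(moving, context, coords,
                                              radii, excluded)
                if n_clash == 0:
                    best = None
                    break
                if best is None or total < best[1]:
                    best = (chis, total)
            if best is not None:
                apply_rotamer(res, best[0])
            placed.add(i)

    # burial filter: revert residues packed unlike their exposure class
    for i in chi_bearing:
        res = out.residues[i]
        if res.resname == "PRO":
            continue
        klass = exposure_class(counts[i])
        interval = burial.intervals.get((res.resname, klass))
        if interval is None:
            continue
        lo, hi = interval
        sc_count = side_chain_neighbor_count(out, i, cutoff)
        if not (lo <= sc_count <= hi):
            apply_rotamer(res, input_chis[i])
    out.provenance = (model.provenance + "+repacked").strip("+")
    return out


def perturb_side_chain_cluster(model: StructureModel, seed_index: int,
                               radius: float, rng,
                               library: RotamerLibrary | None = None
                               ) -> StructureModel:
    """Give every residue whose C-beta is within `radius` of the seed's a
    randomly drawn (probability-weighted) rotamer.  Backbone untouched."""
    library = library or default_rotamer_library()
    out = model.copy()
    cb = _cbeta_array(out)
    dist = np.linalg.norm(cb - cb[seed_index], axis=1)
    for i in np.nonzero(dist <= radius)[0]:
        res = out.residues[int(i)]
        if res.n_chi == 0 or res.resname == "PRO":
            continue
        entries = library.rotamers[res.resname]
        probs = np.array([p for _, p in entries])
        probs = probs / probs.sum()
        pick = int(rng.choice(len(entries), p=probs))
        apply_rotamer(res, entries[pick][0])
    return out
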