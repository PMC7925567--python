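"""Structure-derived ground truth: distance maps, contacts and solvent
accessibility.

Couplings are validated against experimental structures through the
minimum heavy-atom inter-residue distance, taken across every available
structure (so an interface resolved in any one structure counts).
Residue-level solvent accessibility is computed by deterministic
sphere-point (Shrake-Rupley) sampling with a 1.4 Angstrom probe, and
normalized by theoretical maximum residue areas to a relative value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

import biotite.structure as struc
import biotite.structure.io as strucio

from .errors import ParameterError

#: van der Waals radii (Angstrom) for heavy elements; unknown elements
#: fall back to carbon with a warning
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "H": 1.20,
}
DEFAULT_VDW = 1.70
PROBE_RADIUS = 1.4

#: theoretical maximum residue solvent accessibility (Angstrom^2),
#: Tien-style normalization table
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

ResidueKey = tuple[str, int, str]  # (chain, residue number, insertion code)


def load_structure(path: str | Path) -> struc.AtomArray:
    """Read a PDB/mmCIF file into a heavy-atom AtomArray (first model)."""
    atoms = strucio.load_structure(str(path))
    if isinstance(atoms, struc.AtomArrayStack):
        atoms = atoms[0]
    return atoms[atoms.element != "H"]


def atoms_from_records(records) -> struc.AtomArray:
    """Build an AtomArray from (chain, resnum, resname, atom, element,
    x, y, z) tuples — convenient for toy structures."""
    arr = struc.AtomArray(len(records))
    for k, (chain, resnum, resname, atom, element, x, y, z) in enumerate(records):
        arr.chain_id[k] = chain
        arr.res_id[k] = resnum
        arr.res_name[k] = resname
        arr.atom_name[k] = atom
        arr.element[k] = element
        arr.coord[k] = (x, y, z)
    arr.ins_code[:] = ""
    return arr


def _residue_coords(atoms: struc.AtomArray) -> dict[ResidueKey, np.ndarray]:
    heavy = atoms[atoms.element != "H"]
    keys = list(zip(heavy.chain_id, heavy.res_id, heavy.ins_code))
    out: dict[ResidueKey, list[int]] = {}
    for idx, key in enumerate(keys):
        out.setdefault((str(key[0]), int(key[1]), str(key[2])), []).append(idx)
    return {k: heavy.coord[v] for k, v in out.items()}


def read_mapping_tsv(path: str | Path) -> dict[int, ResidueKey]:
    """Mapping TSV: alignment_pos (1-based), chain, resnum, icode."""
    out: dict[int, ResidueKey] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("alignment_pos"):
                continue
            parts = line.split("\t")
            pos, chain, resnum = int(parts[0]), parts[1], int(parts[2])
            icode = parts[3] if len(parts) > 3 else ""
            out[pos] = (chain, resnum, icode)
    return out


@dataclass
class DistanceMap:
    """Minimum heavy-atom distances between mapped alignment positions.

    ``dist[a, b]`` is NaN when either residue is unresolved in every
    structure.  ``L1`` (when set) splits positions into the two protein
    segments for interface bookkeeping.
    """

    positions: list[int]  # 1-based concatenated alignment positions
    dist: np.ndarray  # (P, P), NaN = unknown
    n_structures: int
    L1: int | None = None

    def get(self, i: int, j: int) -> float:
        try:
            a = self.positions.index(i)
            b = self.positions.index(j)
        except ValueError:
            return float("nan")
        return float(self.dist[a, b])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in range(len(self.positions)):
            for b in range(a + 1, len(self.positions)):
                rows.append(
                    {"i": self.positions[a], "j": self.positions[b], "distance": self.dist[a, b]}
                )
        return pd.DataFrame(rows)


def min_distance_map(
    structures, mapping: dict[int, ResidueKey], L1: int | None = None
) -> DistanceMap:
    """Per-pair minimum heavy-atom distance, minimized across structures."""
    if not mapping:
        raise ParameterError("empty alignment-to-structure mapping")
    structures = list(structures)
    if not structures:
        raise ParameterError("need at least one structure")
    positions = sorted(mapping)
    P = len(positions)
    dist = np.full((P, P), np.nan)
    for atoms in structures:
        res = _residue_coords(atoms)
        coords = [res.get(mapping[p]) for p in positions]
        for a in range(P):
            if coords[a] is None:
                continue
            for b in range(a + 1, P):
                if coords[b] is None:
                    continue
                d = float(cdist(coords[a], coords[b]).min())
                cur = dist[a, b]
                if np.isnan(cur) or d < cur:
                    dist[a, b] = dist[b, a] = d
    np.fill_diagonal(dist, 0.0)
    return DistanceMap(positions=positions, dist=dist, n_structures=len(structures), L1=L1)


def contact_labels(dmap: DistanceMap, cutoff: float = 8.0) -> dict[tuple[int, int], bool | None]:
    """(i, j) -> in contact (distance < cutoff); None where unknown."""
    out: dict[tuple[int, int], bool | None] = {}
    P = len(dmap.positions)
    for a in range(P):
        for b in range(a + 1, P):
            d = dmap.dist[a, b]
            key = (dmap.positions[a], dmap.positions[b])
            out[key] = None if np.isnan(d) else bool(d < cutoff)
    return out


def interface_pair_count(dmap: DistanceMap, cutoff: float = 5.0) -> int:
    """Number of inter-segment residue pairs closer than ``cutoff``."""
    if dmap.L1 is None:
        raise ParameterError("distance map lacks a segment boundary (L1)")
    pos = np.asarray(dmap.positions)
    in_a = pos <= dmap.L1
    sub = dmap.dist[np.ix_(in_a, ~in_a)]
    return int(np.nansum(sub < cutoff))


def ec_precision(
    table: pd.DataFrame, dmap: DistanceMap, cutoff: float = 8.0, k: int = 10,
    inter_only: bool = False,
) -> float:
    """Fraction of the top-k ranked ECs with known distance < cutoff.

    Pairs whose distance is unknown are excluded from both numerator and
    denominator; NaN if no top-k pair has a known distance.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    sub = table[table["is_inter"]] if inter_only else table
    top = sub.nsmallest(k, "rank")
    dists = [dmap.get(int(r["i"]), int(r["j"])) for _, r in top.iterrows()]
    known = [d for d in dists if not np.isnan(d)]
    if not known:
        return float("nan")
    return float(np.mean([d < cutoff for d in known]))


# ---------------------------------------------------------------------------
# Solvent accessibility
# ---------------------------------------------------------------------------

def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden-spiral
    lattice); no randomness so results are bit-reproducible."""
    k = np.arange(n_points)
    z = 1.0 - (2.0 * k + 1.0) / n_points
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * k / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _vdw_radius(element: str) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        warnings.warn(f"unknown element {element!r}: using carbon vdW radius")
        return DEFAULT_VDW
    return r


def atom_sasa(
    atoms: struc.AtomArray, probe: float = PROBE_RADIUS, n_points: int = 960
) -> np.ndarray:
    """Per-atom solvent accessible surface area by sphere-point sampling."""
    heavy = atoms[atoms.element != "H"]
    coords = heavy.coord.astype(float)
    radii = np.array([_vdw_radius(e) for e in heavy.element])
    n = len(heavy)
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    reach = radii.max() + 2 * probe
    areas = np.zeros(n)
    for a in range(n):
        r = radii[a] + probe
        pts = coords[a] + r * sphere
        neighbors = [b for b in tree.query_ball_point(coords[a], r + reach) if b != a]
        accessible = np.ones(n_points, dtype=bool)
        for b in neighbors:
            rb = radii[b] + probe
            d2 = np.sum((pts - coords[b]) ** 2, axis=1)
            accessible &= d2 > rb * rb
        areas[a] = 4.0 * np.pi * r * r * accessible.mean()
    return areas


@dataclass
class AccessibilityProfile:
    """Per-residue absolute and relative solvent accessibility, averaged
    over structures when several are given."""

    table: pd.DataFrame  # chain, resnum, icode, resname, abs_area, rel
    n_structures: int

    def rel_by_residue(self) -> dict[ResidueKey, float]:
        return {
            (r["chain"], int(r["resnum"]), r["icode"]): float(r["rel"])
            for _, r in self.table.iterrows()
        }


def relative_sasa(
    structures, probe: float = PROBE_RADIUS, n_points: int = 960
) -> AccessibilityProfile:
    """Residue relative solvent accessibility; the mean across structures
    is taken per residue to dampen incomplete models."""
    structures = list(structures) if isinstance(structures, (list, tuple)) else [structures]
    per_res: dict[ResidueKey, dict] = {}
    for atoms in structures:
        heavy = atoms[atoms.element != "H"]
        areas = atom_sasa(heavy, probe=probe, n_points=n_points)
        for key in set(zip(heavy.chain_id, heavy.res_id, heavy.ins_code)):
            mask = (
                (heavy.chain_id == key[0]) & (heavy.res_id == key[1]) & (heavy.ins_code == key[2])
            )
            abs_area = float(areas[mask].sum())
            resname = str(heavy.res_name[mask][0])
            rel = abs_area / MAX_ASA[resname] if resname in MAX_ASA else np.nan
            rk = (str(key[0]), int(key[1]), str(key[2]))
            rec = per_res.setdefault(rk, {"resname": resname, "abs": [], "rel": []})
            rec["abs"].append(abs_area)
            rec["rel"].append(rel)
    rows = [
        {
            "chain": k[0], "resnum": k[1], "icode": k[2], "resname": v["resname"],
            "abs_area": float(np.mean(v["abs"])), "rel": float(np.nanmean(v["rel"])),
        }
        for k, v in sorted(per_res.items())
    ]
    return AccessibilityProfile(table=pd.DataFrame(rows), n_structures=len(structures))


def read_dssp_rsa(path: str | Path) -> dict[tuple[str, int], tuple[float, float]]:
    """Parse a precomputed DSSP file's ACC column for parity checks.

    Returns (chain, resnum) -> (absolute area, relative area via the
    package's normalization table).
    """
    three = {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
        "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
        "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
        "Y": "TYR", "V": "VAL",
    }
    out = {}
    started = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                started = True
                continue
            if not started or len(line) < 40 or line[13] == "!":
                continue
            resnum = int(line[5:10])
            chain = line[11].strip()
            aa = line[13]
            acc = float(line[34:38])
            resname = three.get(aa)
            rel = acc / MAX_ASA[resname] if resname in MAX_ASA else float("nan")
            out[(chain, resnum)] = (acc, rel)
    return out
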