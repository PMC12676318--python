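"""Shared data model and file I/O for the hit-triage pipeline.

Containers are deliberately plain (dataclasses over numpy arrays) so every
stage — filtering, pharmacophore matching, pose comparison, trajectory
analysis — consumes the same desk-scale objects.  Chemistry-aware parsing
(SMILES, SDF) is delegated to RDKit; sequences to Biopython; coordinate
trajectories are read from multi-model PDB or multi-frame XYZ text.

Units: coordinates in Å, docking affinity in kcal/mol (negative = favorable),
LD50 in mol/kg (larger = safer), times in ns.  Residue numbering is 1-based.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "SchemaError",
    "RowParseError",
    "CompoundRecord",
    "MoleculeGraph",
    "Conformer",
    "Trajectory",
    "RankedHit",
    "REGIONS",
    "CANONICAL_COLUMNS",
    "DEFAULT_ALIASES",
    "normalize_number",
    "read_compound_table",
    "write_ranked_table",
    "read_structures",
    "read_fasta",
    "read_trajectory",
    "write_trajectory_xyz",
]

REGIONS = ("HIA", "BBB", "Out")

#: canonical compound-table schema; input headers are mapped through an alias
#: table so that e.g. a column printed "affinity (kcal/mol)" still parses.
CANONICAL_COLUMNS = (
    "id",
    "smiles",
    "affinity_kcal_mol",
    "ld50_mol_kg",
    "wlogp",
    "tpsa",
    "pgp",
    "region",
)

DEFAULT_ALIASES = {
    "mcule": "id",
    "compound": "id",
    "name": "id",
    "affinity": "affinity_kcal_mol",
    "affinity (kcal/mol)": "affinity_kcal_mol",
    "affinity_kcal/mol": "affinity_kcal_mol",
    "ld50": "ld50_mol_kg",
    "ld50 (mol/kg)": "ld50_mol_kg",
    "ld_50": "ld50_mol_kg",
    "boiled-egg region": "region",
    "boiled_egg_region": "region",
    "p-gp substrate": "pgp",
    "pgp_substrate": "pgp",
}

# Unicode dashes that show up when numbers are copied out of typeset tables.
_DASHES = {
    "−": "-",  # minus sign
    "–": "-",  # en dash
    "—": "-",  # em dash
    "‐": "-",  # hyphen
}


class SchemaError(ValueError):
    """A table is missing a required column or violates the schema."""


class RowParseError(ValueError):
    """A data row failed to parse; carries the 1-based row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


def normalize_number(text: str) -> float:
    """Parse a numeric cell, tolerating unicode minus/en-dash negatives."""
    s = text.strip()
    for bad, good in _DASHES.items():
        s = s.replace(bad, good)
    return float(s)


@dataclass(frozen=True)
class CompoundRecord:
    """One screening hit: identifiers, docking affinity and annotations."""

    id: str
    affinity: float  # kcal/mol, negative = favorable
    ld50: Optional[float] = None  # mol/kg, > 0
    smiles: Optional[str] = None
    wlogp: Optional[float] = None
    tpsa: Optional[float] = None  # Å²
    mw: Optional[float] = None  # g/mol
    pgp_substrate: Optional[bool] = None
    region: Optional[str] = None  # one of REGIONS
    is_reference: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValueError("compound id must be non-empty")
        if not math.isfinite(self.affinity):
            raise ValueError(f"{self.id}: affinity must be finite")
        if self.ld50 is not None and not self.ld50 > 0:
            raise ValueError(f"{self.id}: ld50 must be > 0")
        if self.region is not None and self.region not in REGIONS:
            raise ValueError(f"{self.id}: region must be one of {REGIONS}")

    def replace(self, **kw) -> "CompoundRecord":
        return replace(self, **kw)


@dataclass
class MoleculeGraph:
    """A molecular graph: atoms (element, formal charge), bonds (i, j, order).

    Bond order 1.5 denotes an aromatic bond.  Coordinates, when present,
    cover all atoms (Å).
    """

    elements: list[str]
    charges: list[int]
    bonds: list[tuple[int, int, float]]
    coords: Optional[np.ndarray] = None  # N x 3 Å
    name: str = ""

    def __post_init__(self):
        n = len(self.elements)
        if len(self.charges) != n:
            raise ValueError("charges must match atom count")
        for i, j, _ in self.bonds:
            if i == j:
                raise ValueError("self-bonds are not allowed")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("bond endpoint indexes an invalid atom")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise ValueError("coordinates must be N x 3 covering all atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    @classmethod
    def from_rdkit(cls, mol, name: str = "") -> "MoleculeGraph":
        from rdkit import Chem

        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
        bonds = []
        for b in mol.GetBonds():
            order = 1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble())
            bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        coords = None
        if mol.GetNumConformers():
            coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
        label = name or (mol.GetProp("_Name") if mol.HasProp("_Name") else "")
        return cls(elements, charges, bonds, coords, label)

    def to_rdkit(self, sanitize: bool = True):
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        order_map = {
            1.0: Chem.BondType.SINGLE,
            2.0: Chem.BondType.DOUBLE,
            3.0: Chem.BondType.TRIPLE,
            1.5: Chem.BondType.AROMATIC,
        }
        em = Chem.RWMol()
        for el, q in zip(self.elements, self.charges):
            a = Chem.Atom(el)
            a.SetFormalCharge(q)
            em.AddAtom(a)
        for i, j, order in self.bonds:
            em.AddBond(i, j, order_map[float(order)])
            if order == 1.5:
                em.GetAtomWithIdx(i).SetIsAromatic(True)
                em.GetAtomWithIdx(j).SetIsAromatic(True)
        mol = em.GetMol()
        if sanitize:
            Chem.SanitizeMol(mol)
        if self.coords is not None:
            conf = Chem.Conformer(self.n_atoms)
            for k, (x, y, z) in enumerate(self.coords):
                conf.SetAtomPosition(k, Point3D(x, y, z))
            mol.AddConformer(conf, assignId=True)
        return mol

    @property
    def conformer(self) -> "Conformer":
        if self.coords is None:
            raise ValueError("molecule has no 3D coordinates")
        return Conformer(self, self.coords)


@dataclass
class Conformer:
    """A molecule with one set of 3D coordinates (Å)."""

    molecule: MoleculeGraph
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.molecule.n_atoms, 3):
            raise ValueError("coordinates must be N x 3 for N atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        return Conformer(self.molecule, self.coords @ np.asarray(rotation).T + translation)


@dataclass
class Trajectory:
    """Ordered coordinate frames with per-atom metadata.

    frames: (n_frames, n_atoms, 3) Å; times strictly increasing, ns.
    """

    frames: np.ndarray
    atom_names: list[str]
    elements: list[str]
    residue_indices: list[int]  # 1-based
    residue_names: list[str]
    times: np.ndarray  # ns

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        n = self.frames.shape[1]
        for meta in (self.atom_names, self.elements, self.residue_indices, self.residue_names):
            if len(meta) != n:
                raise ValueError("atom metadata must match atom count")
        if len(self.times) != self.frames.shape[0]:
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def select(self, atom_names: Iterable[str]) -> np.ndarray:
        """Indices of atoms whose name is in ``atom_names``."""
        wanted = set(atom_names)
        return np.array([k for k, nm in enumerate(self.atom_names) if nm in wanted], dtype=int)


@dataclass(frozen=True)
class RankedHit:
    """A compound with its ideal-point distance, rank, and absorption labels."""

    record: CompoundRecord
    distance: float
    rank: int
    region: Optional[str] = None
    pgp: Optional[bool] = None


# ---------------------------------------------------------------------------
# compound tables
# ---------------------------------------------------------------------------

def _canonical_header(raw: Sequence[str], aliases: Optional[dict] = None) -> list[str]:
    amap = dict(DEFAULT_ALIASES)
    if aliases:
        amap.update({k.lower(): v for k, v in aliases.items()})
    out = []
    for h in raw:
        key = h.strip().lower()
        out.append(amap.get(key, key))
    return out


def _parse_pgp(cell: str) -> Optional[bool]:
    s = cell.strip().lower()
    for bad, good in _DASHES.items():
        s = s.replace(bad, good)
    if s in ("", "na", "nan"):
        return None
    if s in ("+", "yes", "true", "1"):
        return True
    if s in ("-", "no", "false", "0"):
        return False
    raise ValueError(f"cannot parse P-gp flag {cell!r}")


def read_compound_table(
    path,
    aliases: Optional[dict] = None,
    reference_ids: Iterable[str] = (),
) -> list[CompoundRecord]:
    """Read a CSV/TSV compound table into :class:`CompoundRecord` rows.

    The header is mapped through ``DEFAULT_ALIASES`` (plus ``aliases``) onto
    the canonical schema; ``id`` and ``affinity_kcal_mol`` are required.
    Rows whose id is in ``reference_ids`` are flagged ``is_reference``.
    Negative numbers printed with unicode minus or en-dash parse correctly.
    """
    path = Path(path)
    refset = set(reference_ids)
    text = path.read_text(encoding="utf-8")
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    reader = csv.reader(text.splitlines(), delimiter=delim)
    rows = [r for r in reader if any(c.strip() for c in r)]
    if not rows:
        raise SchemaError(f"{path}: empty file, no header")
    header = _canonical_header(rows[0], aliases)
    for required in ("id", "affinity_kcal_mol"):
        if required not in header:
            raise SchemaError(f"{path}: missing required column {required!r}")
    records = []
    for ridx, row in enumerate(rows[1:], start=1):
        cells = dict(zip(header, row))
        try:
            rid = cells["id"].strip()
            ld50_cell = cells.get("ld50_mol_kg", "").strip()
            region_cell = cells.get("region", "").strip()
            rec = CompoundRecord(
                id=rid,
                affinity=normalize_number(cells["affinity_kcal_mol"]),
                ld50=normalize_number(ld50_cell) if ld50_cell else None,
                smiles=cells.get("smiles", "").strip() or None,
                wlogp=normalize_number(cells["wlogp"]) if cells.get("wlogp", "").strip() else None,
                tpsa=normalize_number(cells["tpsa"]) if cells.get("tpsa", "").strip() else None,
                pgp_substrate=_parse_pgp(cells.get("pgp", "")),
                region=region_cell or None,
                is_reference=rid in refset,
            )
        except (ValueError, KeyError) as exc:
            raise RowParseError(ridx, str(exc)) from exc
        records.append(rec)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"{path}: duplicate ids {dupes}")
    return records


def write_ranked_table(hits: Sequence[RankedHit], path) -> None:
    """Write ranked hits in deterministic Table-3-like column order."""
    ranks = [h.rank for h in hits]
    if len(set(ranks)) != len(ranks):
        raise ValueError("duplicate ranks in ranked hits")
    if ranks and sorted(ranks) != list(range(1, len(ranks) + 1)):
        raise ValueError("ranks must be a permutation of 1..n")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["ranking", "id", "affinity_kcal_mol", "ld50_mol_kg",
                    "distance", "region", "pgp"])
        for h in sorted(hits, key=lambda h: h.rank):
            r = h.record
            w.writerow([
                h.rank,
                r.id,
                repr(r.affinity),
                "" if r.ld50 is None else repr(r.ld50),
                repr(h.distance),
                h.region or "",
                "" if h.pgp is None else ("+" if h.pgp else "-"),
            ])


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def read_structures(path, on_error: str = "raise") -> list[MoleculeGraph]:
    """Read molecules from a SMILES file (one per line) or an SDF (V2000).

    ``on_error='skip'`` drops unparseable records; ``'raise'`` (default)
    raises ``ValueError`` naming the record.
    """
    from rdkit import Chem

    path = Path(path)
    mols: list[MoleculeGraph] = []
    if path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for k, mol in enumerate(supplier):
            if mol is None:
                if on_error == "skip":
                    continue
                raise ValueError(f"{path}: SDF record {k} failed to parse")
            mols.append(MoleculeGraph.from_rdkit(mol))
    else:
        for k, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                if on_error == "skip":
                    continue
                raise ValueError(f"{path}: SMILES on line {k + 1} failed to parse: {parts[0]!r}")
            name = parts[1].strip() if len(parts) > 1 else ""
            mols.append(MoleculeGraph.from_rdkit(mol, name=name))
    return mols


def smiles_to_graph(smiles: str, name: str = "") -> MoleculeGraph:
    """Parse a single SMILES string (no coordinates)."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return MoleculeGraph.from_rdkit(mol, name=name)


def bundled_hit_table() -> list[CompoundRecord]:
    """The canonical in-package hit table: the reference ligand RGZ plus the
    12 top-ranked screening hits with their printed affinity/LD50 values and
    BOILED-Egg/P-gp annotations."""
    from importlib import resources

    with resources.as_file(resources.files("hitfunnel.data").joinpath("table3.csv")) as p:
        return read_compound_table(p, reference_ids={"RGZ"})


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

_PDB_ELEMENT_FALLBACK = {"CA": "C", "CB": "C", "OXT": "O"}


def _pdb_element(name: str, element_field: str) -> str:
    if element_field.strip():
        return element_field.strip().capitalize()
    name = name.strip()
    if name in _PDB_ELEMENT_FALLBACK:
        return _PDB_ELEMENT_FALLBACK[name]
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _read_trajectory_pdb(path: Path) -> Trajectory:
    frames: list[list[list[float]]] = []
    names: list[str] = []
    elements: list[str] = []
    res_idx: list[int] = []
    res_names: list[str] = []
    current: list[list[float]] = []
    first_model = True
    in_model = False
    for line in path.read_text().splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            current = []
            in_model = True
        elif rec == "ENDMDL":
            frames.append(current)
            first_model = False
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            if not in_model and frames:
                continue
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            current.append([x, y, z])
            if first_model:
                names.append(line[12:16].strip())
                elements.append(_pdb_element(line[12:16], line[76:78] if len(line) >= 78 else ""))
                res_idx.append(int(line[22:26]))
                res_names.append(line[17:20].strip())
    if in_model or (not frames and current):
        frames.append(current)
    if not frames:
        raise ValueError(f"{path}: no ATOM records found")
    arr = np.array(frames, dtype=float)
    times = np.arange(arr.shape[0], dtype=float)
    return Trajectory(arr, names, elements, res_idx, res_names, times)


def _read_trajectory_xyz(path: Path) -> Trajectory:
    lines = path.read_text().splitlines()
    frames = []
    elements: list[str] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos].strip())
        block = lines[pos + 2 : pos + 2 + n]
        coords = []
        frame_elems = []
        for ln in block:
            parts = ln.split()
            frame_elems.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if not elements:
            elements = frame_elems
        frames.append(coords)
        pos += 2 + n
    if not frames:
        raise ValueError(f"{path}: empty XYZ file")
    arr = np.array(frames, dtype=float)
    n = arr.shape[1]
    times = np.arange(arr.shape[0], dtype=float)
    return Trajectory(arr, list(elements), list(elements), list(range(1, n + 1)),
                      ["UNK"] * n, times)


def read_trajectory(path) -> Trajectory:
    """Read a multi-model PDB or multi-frame XYZ trajectory.

    Frame times default to 0,1,2,... ns; callers with real timing overwrite
    ``times`` after loading.
    """
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        return _read_trajectory_xyz(path)
    return _read_trajectory_pdb(path)


def write_trajectory_xyz(traj: Trajectory, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t = {traj.times[f]:.6f} ns\n")
            for el, (x, y, z) in zip(traj.elements, traj.frames[f]):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")
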