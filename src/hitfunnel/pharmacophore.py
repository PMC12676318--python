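"""Rosiglitazone-style pharmacophore modeling and alignment-free matching.

The reference model has eight typed feature spheres derived from the
rosiglitazone pose: (1) acceptor on the thiazolidinedione amide oxygen,
(2) donor on the amide nitrogen, (3) hydrophobic on the ring sulfur,
(4)+(5) aromatic and hydrophobic on the disubstituted-benzene centroid,
(6)+(7) hydrophobic and aromatic on the pyridine centroid, and
(8) hydrophobic on the tertiary-amine methyl.

Matching is by pairwise-distance consistency (a clique in the feature
correspondence graph): an injective, kind-respecting assignment σ such that
|d_model(i,j) − d_mol(σ(i),σ(j))| ≤ tol for every feature pair.  This is
rigid-motion invariant by construction — no superposition is fitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .io_model import Conformer

__all__ = [
    "FEATURE_KINDS",
    "PharmacophoreFeature",
    "PharmacophoreModel",
    "MatchResult",
    "build_reference_model",
    "perceive_features",
    "match",
]

FEATURE_KINDS = ("acceptor", "donor", "hydrophobic", "aromatic")

DEFAULT_RADIUS = 1.0  # Å, typical pharmacophore-search sphere
DEFAULT_TOLERANCE = 1.0  # Å, per feature-pair distance deviation


@dataclass(frozen=True)
class PharmacophoreFeature:
    index: int
    kind: str
    center: tuple[float, float, float]  # Å
    radius: float = DEFAULT_RADIUS

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.radius > 0:
            raise ValueError("feature radius must be positive")


@dataclass
class PharmacophoreModel:
    features: list[PharmacophoreFeature]
    name: str = "pharmacophore"

    def __post_init__(self):
        if len(self.features) < 3:
            raise ValueError("3D matching needs at least 3 features")

    @property
    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features], dtype=float)

    def to_json(self, path) -> None:
        payload = {
            "name": self.name,
            "features": [
                {"index": f.index, "kind": f.kind, "center": list(f.center), "radius": f.radius}
                for f in self.features
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PharmacophoreModel":
        with open(path) as fh:
            payload = json.load(fh)
        feats = [
            PharmacophoreFeature(d["index"], d["kind"], tuple(d["center"]), d["radius"])
            for d in payload["features"]
        ]
        return cls(feats, payload.get("name", "pharmacophore"))


@dataclass(frozen=True)
class MatchResult:
    mapping: Optional[dict[int, int]]  # model feature position -> perceived feature position
    max_deviation: float
    matched: bool


# ---------------------------------------------------------------------------
# reference model
# ---------------------------------------------------------------------------

_TZD_SMARTS = "[CX4]1[SX2][CX3](=[OX1])[NX3H1][CX3]1=[OX1]"  # C5 S C2 O2 N3 C4 O4
_N_METHYL_SMARTS = "[CH3X4][NX3;!$([NX3]=*)]"


def _aromatic_rings(rdmol):
    rings = []
    for ring in rdmol.GetRingInfo().AtomRings():
        if all(rdmol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            rings.append(tuple(ring))
    return rings


def _centroid(coords: np.ndarray, idx) -> tuple[float, float, float]:
    return tuple(np.mean(coords[list(idx)], axis=0))


def build_reference_model(rgz_conformer: Conformer, radius: float = DEFAULT_RADIUS) -> PharmacophoreModel:
    """Derive the 8-feature reference model from a rosiglitazone 3D pose.

    Substructure anchors: the thiazolidinedione ring supplies the acceptor
    oxygen, donor nitrogen and hydrophobic sulfur; the two aromatic rings
    (carbon-only benzene, pyridine) supply paired aromatic/hydrophobic
    centroid features; the N-methyl of the tertiary amine supplies the
    terminal hydrophobic feature.  Raises if an anchor is absent, naming
    the missing feature.
    """
    from rdkit import Chem

    rdmol = rgz_conformer.molecule.to_rdkit()
    coords = rgz_conformer.coords

    tzd = rdmol.GetSubstructMatch(Chem.MolFromSmarts(_TZD_SMARTS))
    if not tzd:
        # diagnose which anchor atom is missing for a useful error
        if not any(a.GetSymbol() == "S" for a in rdmol.GetAtoms()):
            raise ValueError("feature 3 (hydrophobic sulfur): no sulfur atom in conformer")
        raise ValueError("features 1-3: thiazolidinedione ring not found")
    c5, s_atom, _c2, o2, n3, _c4, _o4 = tzd

    rings = _aromatic_rings(rdmol)
    benzene = [r for r in rings if all(rdmol.GetAtomWithIdx(i).GetSymbol() == "C" for i in r)]
    pyridine = [r for r in rings
                if any(rdmol.GetAtomWithIdx(i).GetSymbol() == "N" for i in r)]
    if not benzene:
        raise ValueError("features 4/5: disubstituted benzene ring not found")
    if not pyridine:
        raise ValueError("features 6/7: pyridine ring not found")

    nme = rdmol.GetSubstructMatch(Chem.MolFromSmarts(_N_METHYL_SMARTS))
    if not nme:
        raise ValueError("feature 8: tertiary-amine methyl not found")

    benz_c = _centroid(coords, benzene[0])
    pyr_c = _centroid(coords, pyridine[0])
    feats = [
        PharmacophoreFeature(1, "acceptor", tuple(coords[o2]), radius),
        PharmacophoreFeature(2, "donor", tuple(coords[n3]), radius),
        PharmacophoreFeature(3, "hydrophobic", tuple(coords[s_atom]), radius),
        PharmacophoreFeature(4, "aromatic", benz_c, radius),
        PharmacophoreFeature(5, "hydrophobic", benz_c, radius),
        PharmacophoreFeature(6, "hydrophobic", pyr_c, radius),
        PharmacophoreFeature(7, "aromatic", pyr_c, radius),
        PharmacophoreFeature(8, "hydrophobic", tuple(coords[nme[0]]), radius),
    ]
    return PharmacophoreModel(feats, name="rosiglitazone-8pt")


# ---------------------------------------------------------------------------
# perception
# ---------------------------------------------------------------------------

def perceive_features(conf: Conformer, radius: float = DEFAULT_RADIUS) -> list[PharmacophoreFeature]:
    """Perceive candidate pharmacophore features on a 3D conformer.

    Rules (deliberately permissive — matching prunes):
    donors = N/O bearing ≥1 H; acceptors = O, plus N with an available lone
    pair (pyrrole-type aromatic NH and quaternary N excluded); aromatic =
    centroid of each aromatic ring; hydrophobic = aromatic-ring centroids,
    neutral sulfur atoms, and sp3 carbons with ≥2 hydrogens, skipping atoms
    adjacent to formal charges.
    """
    if conf.coords is None:
        raise ValueError("feature perception requires 3D coordinates")
    rdmol = conf.molecule.to_rdkit()
    coords = conf.coords
    feats: list[PharmacophoreFeature] = []
    idx = 1

    def add(kind, center):
        nonlocal idx
        feats.append(PharmacophoreFeature(idx, kind, tuple(center), radius))
        idx += 1

    def near_charge(atom):
        return any(nb.GetFormalCharge() != 0 for nb in atom.GetNeighbors())

    for atom in rdmol.GetAtoms():
        sym = atom.GetSymbol()
        k = atom.GetIdx()
        if sym in ("N", "O"):
            if atom.GetTotalNumHs() >= 1 and atom.GetFormalCharge() >= 0:
                add("donor", coords[k])
            is_pyrrole_like = sym == "N" and atom.GetIsAromatic() and atom.GetTotalNumHs() >= 1
            quaternary = sym == "N" and atom.GetTotalValence() >= 4
            if atom.GetFormalCharge() <= 0 and not is_pyrrole_like and not quaternary:
                add("acceptor", coords[k])
        elif sym == "S":
            if atom.GetFormalCharge() == 0 and not near_charge(atom):
                add("hydrophobic", coords[k])
        elif sym == "C":
            sp3 = atom.GetHybridization().name == "SP3"
            if sp3 and atom.GetTotalNumHs() >= 2 and not near_charge(atom):
                add("hydrophobic", coords[k])

    for ring in _aromatic_rings(rdmol):
        c = _centroid(coords, ring)
        add("aromatic", c)
        add("hydrophobic", c)
    return feats


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match(
    model: PharmacophoreModel,
    conf_or_features,
    tol: float = DEFAULT_TOLERANCE,
    use_radii: bool = False,
) -> MatchResult:
    """Find the injective kind-respecting assignment with minimal max
    pairwise-distance deviation; ``matched`` iff one exists within ``tol``.

    ``conf_or_features`` is a :class:`Conformer` (features are perceived) or
    a pre-perceived feature list.  ``use_radii=True`` replaces the global
    tolerance for a pair (i, j) with max(radius_i, radius_j).  Ties between
    equally deviating assignments break lexicographically, so results are
    deterministic.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if isinstance(conf_or_features, Conformer):
        mol_feats = perceive_features(conf_or_features)
    else:
        mol_feats = list(conf_or_features)

    m = len(model.features)
    mc = model.centers
    if mol_feats:
        fc = np.array([f.center for f in mol_feats], dtype=float)
        d_mol = np.linalg.norm(fc[:, None, :] - fc[None, :, :], axis=-1)
    else:
        d_mol = np.zeros((0, 0))
    d_model = np.linalg.norm(mc[:, None, :] - mc[None, :, :], axis=-1)

    def pair_tol(i: int, j: int) -> float:
        if use_radii:
            return max(model.features[i].radius, model.features[j].radius)
        return tol

    candidates = [
        [k for k, f in enumerate(mol_feats) if f.kind == model.features[i].kind]
        for i in range(m)
    ]
    if any(not c for c in candidates):
        return MatchResult(None, float("inf"), False)

    best_assign: Optional[list[int]] = None
    best_dev = float("inf")
    assign: list[int] = []
    used: set[int] = set()

    def backtrack(i: int, dev_so_far: float):
        nonlocal best_assign, best_dev
        if i == m:
            key = list(assign)
            if dev_so_far < best_dev - 1e-12 or (
                abs(dev_so_far - best_dev) <= 1e-12 and (best_assign is None or key < best_assign)
            ):
                best_dev = dev_so_far
                best_assign = key
            return
        for k in candidates[i]:
            if k in used:
                continue
            dev = dev_so_far
            ok = True
            for j in range(i):
                delta = abs(d_model[i, j] - d_mol[k, assign[j]])
                if delta > pair_tol(i, j):
                    ok = False
                    break
                dev = max(dev, delta)
            if not ok or dev > best_dev + 1e-12:
                continue
            assign.append(k)
            used.add(k)
            backtrack(i + 1, dev)
            used.discard(k)
            assign.pop()

    backtrack(0, 0.0)
    if best_assign is None:
        return MatchResult(None, float("inf"), False)
    mapping = {i: best_assign[i] for i in range(m)}
    return MatchResult(mapping, best_dev, True)
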