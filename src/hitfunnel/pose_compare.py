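"""Symmetry-corrected RMSD between two poses of the same ligand.

Redocking validation compares a docked pose against the crystallographic
pose of the same molecule.  A naive atom-by-atom RMSD over-penalizes
topologically symmetric ligands (a benzene ring rotated by 60° is the same
pose); the fix is to minimize the RMSD over all graph automorphisms of the
ligand — element- and bond-order-preserving atom permutations.

Two comparison modes are provided:

* in-place (default): coordinates compared directly in the common receptor
  frame, the docking-community convention;
* superposed: each candidate mapping is first Kabsch-aligned, which measures
  conformational rather than positional deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import Conformer, MoleculeGraph

__all__ = [
    "PoseRMSD",
    "AutomorphismLimitError",
    "kabsch_superpose",
    "automorphisms",
    "symmetry_rmsd",
]

DEFAULT_AUTOMORPHISM_CAP = 10_000


class AutomorphismLimitError(RuntimeError):
    """Raised when a molecule has more automorphisms than the configured cap."""


@dataclass(frozen=True)
class PoseRMSD:
    value: float  # Å
    mapping: tuple[int, ...]  # probe index for each ref index
    superposed: bool


def kabsch_superpose(A: np.ndarray, B: np.ndarray):
    """Least-squares rigid superposition of B onto A.

    Returns ``(rotation, translation, rmsd)`` with ``B @ R.T + t ≈ A``;
    the rotation is proper (det = +1).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("point sets must both be N x 3")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 points for a unique superposition")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - cb @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((B @ R.T + t - A) ** 2, axis=1))))
    return R, t, rmsd


def _heavy_subgraph(mol: MoleculeGraph):
    keep = [i for i, el in enumerate(mol.elements) if el != "H"]
    remap = {old: new for new, old in enumerate(keep)}
    elements = [mol.elements[i] for i in keep]
    bonds = {}
    for i, j, order in mol.bonds:
        if i in remap and j in remap:
            a, b = remap[i], remap[j]
            bonds[(min(a, b), max(a, b))] = float(order)
    return keep, elements, bonds


def automorphisms(
    mol: MoleculeGraph,
    heavy_only: bool = True,
    cap: int = DEFAULT_AUTOMORPHISM_CAP,
) -> list[tuple[int, ...]]:
    """All element- and bond-order-preserving atom permutations.

    Backtracking with element/degree pruning; always includes the identity.
    Permutations index into the (heavy-atom, by default) atom list in input
    order.  Raises :class:`AutomorphismLimitError` past ``cap`` mappings —
    highly symmetric inputs should be reduced before comparison.
    """
    if heavy_only:
        _, elements, bonds = _heavy_subgraph(mol)
    else:
        elements = list(mol.elements)
        bonds = {}
        for i, j, order in mol.bonds:
            bonds[(min(i, j), max(i, j))] = float(order)
    n = len(elements)
    adj: list[dict[int, float]] = [{} for _ in range(n)]
    for (i, j), order in bonds.items():
        adj[i][j] = order
        adj[j][i] = order
    degree = [len(a) for a in adj]

    results: list[tuple[int, ...]] = []
    assignment = [-1] * n
    used = [False] * n
    assigned: list[int] = []

    # order vertices to fail fast: rarest (element, degree) class first
    from collections import Counter

    cls = [(elements[i], degree[i]) for i in range(n)]
    freq = Counter(cls)
    order_v = sorted(range(n), key=lambda i: (freq[cls[i]], i))

    def backtrack(pos: int):
        if len(results) > cap:
            return
        if pos == n:
            results.append(tuple(assignment))
            return
        v = order_v[pos]
        for w in range(n):
            if used[w] or cls[w] != cls[v]:
                continue
            # adjacency (and non-adjacency) to every assigned vertex must match
            ok = all(adj[v].get(u) == adj[w].get(assignment[u]) for u in assigned)
            if ok:
                assignment[v] = w
                used[w] = True
                assigned.append(v)
                backtrack(pos + 1)
                assigned.pop()
                assignment[v] = -1
                used[w] = False

    backtrack(0)
    if len(results) > cap:
        raise AutomorphismLimitError(
            f"more than {cap} automorphisms; reduce symmetry or raise the cap"
        )
    return sorted(results)


def _graphs_isomorphic_identity(ref: MoleculeGraph, probe: MoleculeGraph) -> bool:
    """Check the two molecules share atom order, elements and bonds (heavy atoms)."""
    _, el_r, b_r = _heavy_subgraph(ref)
    _, el_p, b_p = _heavy_subgraph(probe)
    return el_r == el_p and b_r == b_p


def symmetry_rmsd(
    ref: Conformer,
    probe: Conformer,
    superpose: bool = False,
    cap: int = DEFAULT_AUTOMORPHISM_CAP,
) -> PoseRMSD:
    """Minimum RMSD between two poses over all ligand automorphisms.

    Both conformers must carry the same molecular graph (same heavy-atom
    ordering); heavy atoms only.  ``superpose=True`` Kabsch-aligns before
    each RMSD evaluation, ``False`` (default) compares in place.
    """
    if not _graphs_isomorphic_identity(ref.molecule, probe.molecule):
        raise ValueError("pose RMSD requires isomorphic molecular graphs in the same atom order")
    keep_r, _, _ = _heavy_subgraph(ref.molecule)
    keep_p, _, _ = _heavy_subgraph(probe.molecule)
    A = ref.coords[keep_r]
    B = probe.coords[keep_p]
    best = None
    best_perm = None
    for perm in automorphisms(ref.molecule, heavy_only=True, cap=cap):
        Bp = B[list(perm)]
        if superpose:
            _, _, val = kabsch_superpose(A, Bp)
        else:
            val = float(np.sqrt(np.mean(np.sum((Bp - A) ** 2, axis=1))))
        if best is None or val < best - 1e-15:
            best = val
            best_perm = perm
    return PoseRMSD(value=best, mapping=best_perm, superposed=superpose)
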