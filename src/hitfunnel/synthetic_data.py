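"""Deterministic synthetic-data generators with planted ground truth.

Every stage of the triage pipeline gets a generator that emulates the kind
of data the study pulled from web services — compound tables with a known
quadrant-pass composition, active/decoy score sets with a closed-form
expected AUC, toy conformer pairs with known symmetry, Gaussian-noise
trajectories with known RMSF, and sequence pairs with planted mismatches.

Each generator draws from its own counter-based random stream keyed by
``(seed, generator-name)``, so adding or reordering generators never
perturbs another generator's output, and the same spec always produces
byte-identical data.
"""

from __future__ import annotations

import hashlib
import math
from typing import Optional, Sequence

import numpy as np

from .enrichment import ScoredSet
from .io_model import CompoundRecord, Conformer, MoleculeGraph, Trajectory

__all__ = [
    "stream",
    "DEFAULT_REFERENCE",
    "gen_compound_table",
    "gen_score_sets",
    "gen_toy_conformers",
    "gen_trajectory",
    "gen_sequences",
]

#: rosiglitazone's published affinity/LD50 pair, the usual quadrant reference
DEFAULT_REFERENCE = CompoundRecord(id="RGZ", affinity=-8.5, ld50=2.713, is_reference=True)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def stream(seed: int, name: str) -> np.random.Generator:
    """Independent counter-based stream for (seed, generator-name)."""
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:8], "big") >> 1
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(tag,))
    return np.random.Generator(np.random.Philox(ss))


# ---------------------------------------------------------------------------
# compound tables
# ---------------------------------------------------------------------------

def gen_compound_table(
    n: int,
    frac_quadrant_pass: float,
    reference: CompoundRecord = DEFAULT_REFERENCE,
    seed: int = 0,
    n_duplicates: int = 0,
) -> tuple[list[CompoundRecord], dict[str, bool]]:
    """A screening table with exactly round(n·frac) quadrant passers.

    Affinities are drawn Uniform(−11.5, −6.5) kcal/mol and LD50
    Uniform(2.3, 3.0) mol/kg (the value ranges the study's 199-compound
    pool spans), then passer rows are redrawn inside the quadrant
    (affinity ≤ reference, LD50 ≥ reference) and non-passers are forced to
    a strictly worse affinity.  ``n_duplicates`` appends that many repeats
    of existing rows under the same id, for deduplication tests.  Returns
    ``(records, truth)`` with ``truth[id]`` the planted pass label.
    """
    if not 0.0 <= frac_quadrant_pass <= 1.0:
        raise ValueError("frac_quadrant_pass must be in [0, 1]")
    rng = stream(seed, "compound_table")
    k = round(n * frac_quadrant_pass)
    affin = rng.uniform(-11.5, -6.5, size=n)
    ld50 = rng.uniform(2.3, 3.0, size=n)
    passers = set(rng.choice(n, size=k, replace=False).tolist())
    records: list[CompoundRecord] = []
    truth: dict[str, bool] = {}
    for i in range(n):
        if i in passers:
            a = rng.uniform(-11.5, reference.affinity)
            l = rng.uniform(reference.ld50, 3.0)
        else:
            # strictly worse affinity guarantees quadrant failure
            a = rng.uniform(np.nextafter(reference.affinity, 0.0), -6.5)
            l = ld50[i]
        cid = f"SYN-{seed}-{i:05d}"
        records.append(CompoundRecord(id=cid, affinity=float(a), ld50=float(l)))
        truth[cid] = i in passers
    if n_duplicates:
        dup_idx = rng.choice(n, size=n_duplicates, replace=True)
        records.extend(records[int(i)] for i in dup_idx)
    return records, truth


# ---------------------------------------------------------------------------
# score sets
# ---------------------------------------------------------------------------

def gen_score_sets(
    n_act: int,
    n_dec: int,
    delta: float,
    sigma: float,
    seed: int = 0,
    mu: float = -7.2,
) -> tuple[ScoredSet, float]:
    """Normal active/decoy affinity sets with known expected AUC.

    Actives ~ N(μ−δ, σ), decoys ~ N(μ, σ), lower = better; the expected
    AUC is Φ(δ/(σ√2)), returned as the planted truth.
    """
    if n_act < 1 or n_dec < 1:
        raise ValueError("need at least one active and one decoy")
    rng = stream(seed, "score_sets")
    act = rng.normal(mu - delta, sigma, size=n_act)
    dec = rng.normal(mu, sigma, size=n_dec)
    expected_auc = 0.5 * (1.0 + math.erf(delta / (sigma * math.sqrt(2.0)) / math.sqrt(2.0)))
    return ScoredSet(act, dec, lower_is_better=True), expected_auc


# ---------------------------------------------------------------------------
# toy conformers
# ---------------------------------------------------------------------------

def _benzene_graph() -> MoleculeGraph:
    r = 1.39  # aromatic C-C ring radius, Å
    coords = np.array([
        [r * math.cos(math.pi / 3 * k), r * math.sin(math.pi / 3 * k), 0.0]
        for k in range(6)
    ])
    bonds = [(k, (k + 1) % 6, 1.5) for k in range(6)]
    return MoleculeGraph(["C"] * 6, [0] * 6, bonds, coords, name="benzene")


def _para_disubstituted_graph() -> MoleculeGraph:
    base = _benzene_graph()
    coords = np.vstack([base.coords,
                        base.coords[0] * (1.39 + 1.35) / 1.39,
                        base.coords[3] * (1.39 + 1.35) / 1.39])
    bonds = base.bonds + [(0, 6, 1.0), (3, 7, 1.0)]
    return MoleculeGraph(["C"] * 6 + ["F", "F"], [0] * 8, bonds, coords,
                         name="para-difluorobenzene")


def _rotation_z(deg: float) -> np.ndarray:
    th = math.radians(deg)
    return np.array([[math.cos(th), -math.sin(th), 0.0],
                     [math.sin(th), math.cos(th), 0.0],
                     [0.0, 0.0, 1.0]])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def gen_toy_conformers(
    kind: str,
    transform: Optional[dict] = None,
    seed: int = 0,
) -> tuple[Conformer, Conformer, dict]:
    """A (reference, probe) conformer pair with known symmetry and RMSD.

    kinds: ``benzene`` (12 graph automorphisms), ``para_disubstituted``
    (4 automorphisms), ``rgz_like`` (the bundled rosiglitazone pose).
    ``transform`` keys: ``rotation_deg_z``, ``translation`` (3-vector),
    ``random_rigid`` (bool).  Truth records the applied motion and the
    in-place / superposed symmetry-RMSD it implies for pure ring rotations
    and pure translations.
    """
    rng = stream(seed, "toy_conformers")
    if kind == "benzene":
        mol = _benzene_graph()
        n_auto = 12
    elif kind == "para_disubstituted":
        mol = _para_disubstituted_graph()
        n_auto = 4
    elif kind == "rgz_like":
        from importlib import resources

        from .io_model import read_structures

        with resources.as_file(
            resources.files("hitfunnel.data").joinpath("rgz_synthetic.sdf")
        ) as p:
            mol = read_structures(p)[0]
        n_auto = None
    else:
        raise ValueError(f"unknown toy conformer kind {kind!r}")

    ref = Conformer(mol, mol.coords)
    transform = transform or {}
    R = np.eye(3)
    t = np.zeros(3)
    if "rotation_deg_z" in transform:
        R = _rotation_z(transform["rotation_deg_z"]) @ R
    if transform.get("random_rigid"):
        R = random_rotation(rng) @ R
        t = t + rng.uniform(-5, 5, size=3)
    if "translation" in transform:
        t = t + np.asarray(transform["translation"], dtype=float)
    probe = ref.transformed(R, t)
    truth = {
        "n_automorphisms": n_auto,
        "rotation": R,
        "translation": t,
        "superposed_rmsd": 0.0,
        "inplace_rmsd_translation_only": float(np.linalg.norm(t)) if np.allclose(R, np.eye(3)) else None,
    }
    return ref, probe, truth


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def gen_trajectory(
    n_frames: int,
    n_atoms: int,
    sigma_profile,
    seed: int = 0,
    atoms_per_residue: int = 1,
    dt_ns: float = 0.01,
) -> tuple[Trajectory, np.ndarray]:
    """Base structure plus per-atom isotropic Gaussian noise.

    ``sigma_profile`` is a scalar or per-residue array of noise σ (Å); atom
    i belongs to residue i // atoms_per_residue + 1.  The planted per-atom
    RMSF truth is σ√3 (isotropic noise in three dimensions).
    """
    if n_frames < 2:
        raise ValueError("a trajectory needs at least 2 frames")
    rng = stream(seed, "trajectory")
    n_res = -(-n_atoms // atoms_per_residue)
    sig = np.broadcast_to(np.asarray(sigma_profile, dtype=float), (n_res,))
    res_idx = [i // atoms_per_residue + 1 for i in range(n_atoms)]
    sigma_atom = np.array([sig[r - 1] for r in res_idx])
    base = rng.uniform(-10.0, 10.0, size=(n_atoms, 3))
    noise = rng.normal(size=(n_frames, n_atoms, 3)) * sigma_atom[None, :, None]
    frames = base[None, :, :] + noise
    traj = Trajectory(
        frames=frames,
        atom_names=["CA"] * n_atoms,
        elements=["C"] * n_atoms,
        residue_indices=res_idx,
        residue_names=["ALA"] * n_atoms,
        times=np.arange(n_frames) * dt_ns,
    )
    truth_rmsf = sigma_atom * math.sqrt(3.0)
    return traj, truth_rmsf


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def gen_sequences(
    length: int,
    n_mismatch: int,
    window: Optional[tuple[int, int]] = None,
    seed: int = 0,
) -> tuple[str, str, dict]:
    """A target sequence and a template copy with planted substitutions.

    ``window=(start, end)`` (1-based, inclusive) truncates the template to
    that stretch of the target, emulating partial template coverage.
    Mismatches are planted inside the window.  Truth records the mismatch
    positions (target numbering), the expected identity over aligned
    columns, and the expected coverage fraction of the target.
    """
    if n_mismatch > length:
        raise ValueError("cannot plant more mismatches than residues")
    rng = stream(seed, "sequences")
    target = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
    lo, hi = (1, length) if window is None else window
    if not (1 <= lo <= hi <= length):
        raise ValueError("window out of range")
    span = hi - lo + 1
    if n_mismatch > span:
        raise ValueError("window too small for the requested mismatches")
    positions = sorted(int(p) for p in rng.choice(np.arange(lo, hi + 1), size=n_mismatch,
                                                  replace=False))
    template = list(target[lo - 1 : hi])
    for pos in positions:
        old = template[pos - lo]
        choices = [a for a in AMINO_ACIDS if a != old]
        template[pos - lo] = choices[int(rng.integers(0, len(choices)))]
    truth = {
        "mismatch_positions": positions,
        "identity": round(100.0 * (span - n_mismatch) / span, 2),
        "coverage": round(100.0 * span / length, 2),
    }
    return target, "".join(template), truth
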