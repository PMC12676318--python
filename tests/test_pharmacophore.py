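import itertools

import numpy as np
import pytest

from hitfunnel.io_model import Conformer, MoleculeGraph, smiles_to_graph
from hitfunnel.pharmacophore import (
    MatchResult,
    PharmacophoreFeature,
    PharmacophoreModel,
    build_reference_model,
    match,
    perceive_features,
)
from hitfunnel.synthetic_data import gen_toy_conformers, random_rotation, stream


def embed(smiles: str, seed: int = 11) -> Conformer:
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    mol = Chem.RemoveHs(mol)
    return MoleculeGraph.from_rdkit(mol).conformer


def brute_force_match(model, feats, tol):
    """Exhaustive assignment search: the independent oracle for match()."""
    m = len(model.features)
    mc = model.centers
    fc = np.array([f.center for f in feats])
    d_model = np.linalg.norm(mc[:, None] - mc[None, :], axis=-1)
    d_mol = np.linalg.norm(fc[:, None] - fc[None, :], axis=-1)
    cands = [[k for k, f in enumerate(feats) if f.kind == mf.kind] for mf in model.features]
    best = None
    for combo in itertools.product(*cands):
        if len(set(combo)) < m:
            continue
        dev = 0.0
        ok = True
        for i in range(m):
            for j in range(i):
                d = abs(d_model[i, j] - d_mol[combo[i], combo[j]])
                if d > tol:
                    ok = False
                    break
                dev = max(dev, d)
            if not ok:
                break
        if ok and (best is None or dev < best[0] - 1e-12):
            best = (dev, combo)
    return best


class TestReferenceModel:
    def test_eight_features_with_published_kind_counts(self, rgz_conformer):
        model = build_reference_model(rgz_conformer)
        assert len(model.features) == 8
        kinds = [f.kind for f in model.features]
        assert kinds.count("acceptor") == 1
        assert kinds.count("donor") == 1
        assert kinds.count("hydrophobic") == 4
        assert kinds.count("aromatic") == 2
        assert [f.index for f in model.features] == list(range(1, 9))

    def test_missing_sulfur_reported_as_feature_3(self):
        conf = embed("CN(CCOc1ccc(C)cc1)c1ccccn1")  # rosiglitazone minus the TZD ring
        with pytest.raises(ValueError, match="feature 3|features 1-3"):
            build_reference_model(conf)

    def test_ring_centroid_features_sit_on_atom_means(self, rgz_conformer):
        from rdkit import Chem

        model = build_reference_model(rgz_conformer)
        rdmol = rgz_conformer.molecule.to_rdkit()
        ring_centroids = []
        for ring in rdmol.GetRingInfo().AtomRings():
            if all(rdmol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
                ring_centroids.append(rgz_conformer.coords[list(ring)].mean(axis=0))
        for feat in model.features:
            if feat.kind == "aromatic":
                d = min(np.linalg.norm(np.array(feat.center) - c) for c in ring_centroids)
                assert d < 0.01


class TestPerception:
    def test_benzene_single_aromatic_feature_at_centroid(self):
        conf = embed("c1ccccc1")
        feats = perceive_features(conf)
        aromatic = [f for f in feats if f.kind == "aromatic"]
        assert len(aromatic) == 1
        np.testing.assert_allclose(aromatic[0].center, conf.coords.mean(axis=0), atol=1e-6)

    def test_methanol_donor_and_acceptor_on_oxygen(self):
        conf = embed("CO")
        feats = perceive_features(conf)
        kinds = sorted(f.kind for f in feats if f.kind in ("donor", "acceptor"))
        assert kinds == ["acceptor", "donor"]

    def test_rgz_features_cover_reference_model(self, rgz_conformer):
        model = build_reference_model(rgz_conformer)
        feats = perceive_features(rgz_conformer)
        for mf in model.features:
            dmin = min(
                np.linalg.norm(np.array(mf.center) - np.array(f.center))
                for f in feats
                if f.kind == mf.kind
            )
            assert dmin <= mf.radius, f"feature {mf.index} ({mf.kind}) uncovered"

    def test_no_coordinates_is_an_error(self):
        mol = smiles_to_graph("CCO")
        with pytest.raises(ValueError, match="coordinates"):
            mol.conformer


class TestMatching:
    def test_self_match_has_zero_deviation(self, rgz_conformer):
        model = build_reference_model(rgz_conformer)
        res = match(model, rgz_conformer, tol=0.5)
        assert res.matched
        assert res.max_deviation == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rgz_conformer):
        model = build_reference_model(rgz_conformer)
        rng = stream(5, "test-rigid")
        R = random_rotation(rng)
        t = rng.uniform(-8, 8, size=3)
        moved = rgz_conformer.transformed(R, t)
        res = match(model, moved, tol=0.5)
        assert res.matched
        assert res.max_deviation <= 1e-6

    def test_donor_free_decoys_never_match(self, rgz_conformer):
        """Kind constraints alone reject conformers lacking donor atoms."""
        model = build_reference_model(rgz_conformer)
        rng = stream(6, "test-decoys")
        n_matched = 0
        for _ in range(100):
            pts = rng.uniform(-5, 5, size=(8, 3))
            feats = [
                PharmacophoreFeature(i + 1, "hydrophobic", tuple(p)) for i, p in enumerate(pts)
            ]
            res = match(model, feats, tol=1.0)
            n_matched += res.matched
        assert n_matched == 0

    def test_agrees_with_brute_force_oracle(self):
        rng = stream(7, "test-oracle")
        kinds = ["acceptor", "donor", "hydrophobic", "hydrophobic", "aromatic"]
        centers = rng.uniform(-4, 4, size=(5, 3))
        model = PharmacophoreModel(
            [PharmacophoreFeature(i + 1, k, tuple(c)) for i, (k, c) in enumerate(zip(kinds, centers))]
        )
        for trial in range(5):
            pts = rng.uniform(-4, 4, size=(9, 3))
            fkinds = [kinds[i % 5] for i in range(9)]
            feats = [PharmacophoreFeature(i + 1, k, tuple(p)) for i, (k, p) in enumerate(zip(fkinds, pts))]
            res = match(model, feats, tol=2.0)
            oracle = brute_force_match(model, feats, 2.0)
            assert res.matched == (oracle is not None)
            if oracle is not None:
                assert res.max_deviation == pytest.approx(oracle[0], abs=1e-9)

    @pytest.mark.parametrize("tols", [(0.2, 0.5), (0.5, 1.0), (1.0, 3.0)])
    def test_matched_is_monotone_in_tolerance(self, rgz_conformer, tols):
        model = build_reference_model(rgz_conformer)
        rng = stream(8, f"test-mono-{tols[0]}")
        jitter = rng.normal(0, 0.15, size=rgz_conformer.coords.shape)
        noisy = Conformer(rgz_conformer.molecule, rgz_conformer.coords + jitter)
        lo, hi = tols
        if match(model, noisy, tol=lo).matched:
            assert match(model, noisy, tol=hi).matched

    def test_model_json_round_trip(self, rgz_conformer, tmp_path):
        model = build_reference_model(rgz_conformer)
        p = tmp_path / "rgz.json"
        model.to_json(p)
        back = PharmacophoreModel.from_json(p)
        assert back.name == model.name
        assert back.features == model.features
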