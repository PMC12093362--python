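"""Tanimoto, Butina sphere-exclusion clustering, and fold construction.

The Butina reference oracle here re-implements the documented greedy
procedure with plain python sets over an independently computed
similarity matrix, so the production (vectorized) path is checked
against a second route.
"""

from __future__ import annotations

import numpy as np
import pytest

from qsarshift.config import RunConfig
from qsarshift.descriptors import Fingerprint, compute_fingerprint
from qsarshift.splitting import (
    butina_cluster,
    make_folds,
    tanimoto,
    tanimoto_matrix,
)

from conftest import eligible_dataset


def fp(bits, key="x", n_bits=64):
    return Fingerprint(compound_key=key, bits=frozenset(bits), n_bits=n_bits)


def random_fps(rng, n, n_bits=64, density=0.25):
    out = []
    for i in range(n):
        k = max(1, rng.binomial(n_bits, density))
        out.append(fp(rng.choice(n_bits, size=k, replace=False), key=f"m{i}",
                      n_bits=n_bits))
    return out


def reference_butina(fps, threshold):
    """Independent greedy sphere-exclusion over python sets."""
    sims = {}
    n = len(fps)
    for i in range(n):
        for j in range(n):
            if i != j:
                a, b = set(fps[i].bits), set(fps[j].bits)
                u = len(a | b)
                sims[i, j] = len(a & b) / u if u else 0.0
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(1 for j in unassigned
                        if j != i and sims[i, j] >= threshold)
            if count > best_count:
                best, best_count = i, count
        members = {best} | {j for j in unassigned
                            if j != best and sims[best, j] >= threshold}
        clusters.append((best, members))
        unassigned -= members
    return clusters


class TestTanimoto:
    def test_identity_disjoint_and_set_arithmetic(self):
        a = fp({1, 2, 3})
        assert tanimoto(a, fp({1, 2, 3})) == 1.0
        assert tanimoto(a, fp({9, 10})) == 0.0
        assert tanimoto(a, fp({2, 3, 4})) == pytest.approx(0.5)

    def test_symmetry_on_random_pairs(self, rng):
        fps = random_fps(rng, 20)
        for a, b in zip(fps[:10], fps[10:]):
            assert tanimoto(a, b) == tanimoto(b, a)

    def test_both_empty_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert tanimoto(fp(set()), fp(set())) == 0.0

    def test_mixed_bit_universes_error(self):
        with pytest.raises(ValueError, match="universes"):
            tanimoto(fp({1}, n_bits=64), fp({1}, n_bits=128))

    def test_matrix_agrees_with_rdkit_on_real_molecules(self, default_study):
        from rdkit import Chem, DataStructs
        from rdkit.Chem import rdFingerprintGenerator

        smiles = sorted({r.structure for r in default_study.public_rows})[:40]
        ours = [compute_fingerprint(s) for s in smiles]
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        theirs = [gen.GetFingerprint(Chem.MolFromSmiles(s)) for s in smiles]
        S = tanimoto_matrix(ours)
        for i in range(len(smiles)):
            expected = DataStructs.BulkTanimotoSimilarity(theirs[i], theirs)
            assert np.allclose(S[i], expected, atol=1e-6)


class TestButina:
    def test_all_similar_is_one_cluster(self):
        fps = [fp({1, 2, 3, i}, key=f"m{i}") for i in range(5)]
        ca = butina_cluster(fps, 0.4)
        assert ca.n_clusters() == 1 and len(ca.cluster_of) == 5

    def test_all_dissimilar_is_all_singletons(self):
        fps = [fp({10 * i, 10 * i + 1}, key=f"m{i}") for i in range(6)]
        ca = butina_cluster(fps, 0.3)
        assert ca.n_clusters() == 6

    def test_matches_reference_oracle_on_toy_set(self):
        fps = [
            fp({1, 2, 3, 4}, "a"), fp({1, 2, 3, 5}, "b"), fp({1, 2, 6, 7}, "c"),
            fp({20, 21, 22}, "d"), fp({20, 21, 23}, "e"), fp({40, 41}, "f"),
        ]
        ca = butina_cluster(fps, 0.4)
        ref = reference_butina(fps, 0.4)
        keys = [f.compound_key for f in fps]
        ref_map = {}
        for cid, (_, members) in enumerate(ref):
            for m in members:
                ref_map[keys[m]] = cid
        assert ca.cluster_of == ref_map

    @pytest.mark.parametrize("threshold", [0.15, 0.230, 0.5])
    def test_equals_reference_on_random_sets(self, threshold, rng):
        """Vectorized clustering equals the set-based greedy reference."""
        for _ in range(25):
            n = int(rng.integers(2, 31))
            fps = random_fps(rng, n)
            ca = butina_cluster(fps, threshold)
            ref = reference_butina(fps, threshold)
            ref_map, centroids = {}, {}
            for cid, (c, members) in enumerate(ref):
                centroids[cid] = fps[c].compound_key
                for m in members:
                    ref_map[fps[m].compound_key] = cid
            assert ca.cluster_of == ref_map
            assert ca.centroids == centroids
            # validity: every member within the sphere of its centroid
            for key, cid in ca.cluster_of.items():
                if key != ca.centroids[cid]:
                    i = int(key[1:])
                    c = int(ca.centroids[cid][1:])
                    assert tanimoto(fps[i], fps[c]) >= threshold

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            butina_cluster([], 0.3)


class TestMakeFolds:
    def test_random_folds_are_near_equal_and_stratified(self):
        ds = eligible_dataset(90, 45)
        folds = make_folds(ds, k=9, scheme="random", seed=3)
        counts = np.bincount(list(folds.fold_of.values()), minlength=9)
        assert list(counts) == [10] * 9
        # class ratio per fold within one compound of even share
        labels = {rec.compound_key: lbl for rec, lbl in ds.members}
        for f in range(9):
            active = sum(1 for k, ff in folds.fold_of.items()
                         if ff == f and labels[k] == "active")
            assert abs(active - 5) <= 1

    def test_greedy_cluster_packing_matches_worked_example(self):
        # clusters sized 5,4,3,2,1 into k=2 -> sizes {8,7}: 5->A 4->B 3->B 2->A 1->A
        sizes = [5, 4, 3, 2, 1]
        fps = []
        idx = 0
        for cid, size in enumerate(sizes):
            for _ in range(size):
                fps.append(fp({100 * cid, 100 * cid + 1}, key=f"m{idx}",
                              n_bits=1024))
                idx += 1
        from qsarshift.curation import ClassifiedDataset, CompoundRecord

        members = [
            (CompoundRecord(f"m{i}", "C", f"i{i}", f"k{i}", "public_like", "T", ()),
             "active" if i % 2 else "inactive")
            for i in range(len(fps))
        ]
        ds = ClassifiedDataset("T", "public_like", members)
        folds = make_folds(ds, k=2, scheme="cluster", seed=0, fps=fps,
                           threshold=0.4)
        fold_sizes = np.bincount(list(folds.fold_of.values()))
        assert sorted(fold_sizes, reverse=True) == [8, 7]
        by_cluster = {}
        for key, cid in folds.cluster_of.items():
            by_cluster.setdefault(cid, set()).add(folds.fold_of[key])
        # no cluster spans folds
        assert all(len(v) == 1 for v in by_cluster.values())
        # largest-first greedy: cluster of 5 with clusters of 2 and 1
        cluster_sizes = {cid: sum(1 for c in folds.cluster_of.values() if c == cid)
                         for cid in set(folds.cluster_of.values())}
        fold_of_cluster = {cid: folds.fold_of[next(
            k for k, c in folds.cluster_of.items() if c == cid)]
            for cid in cluster_sizes}
        big = next(c for c, s in cluster_sizes.items() if s == 5)
        assert [fold_of_cluster[c] for c, s in cluster_sizes.items()
                if s in (2, 1)] == [fold_of_cluster[big]] * 2

    def test_cluster_integrity_over_seeds(self, rng):
        ds = eligible_dataset(40, 16)
        fps = random_fps(rng, 40, n_bits=128, density=0.15)
        for i, (rec, _) in enumerate(ds.members):
            fps[i] = Fingerprint(rec.compound_key, fps[i].bits, 128)
        for seed in range(10):
            folds = make_folds(ds, k=3, scheme="cluster", seed=seed, fps=fps,
                               threshold=0.3)
            spans = {}
            for key, cid in folds.cluster_of.items():
                spans.setdefault(cid, set()).add(folds.fold_of[key])
            assert all(len(v) == 1 for v in spans.values())

    def test_one_giant_cluster_cannot_fill_two_folds(self):
        ds = eligible_dataset(10, 4)
        fps = [Fingerprint(rec.compound_key, frozenset({1, 2, 3}), 64)
               for rec, _ in ds.members]
        with pytest.raises(ValueError):
            make_folds(ds, k=2, scheme="cluster", seed=0, fps=fps, threshold=0.4)

    def test_k_larger_than_units_errors_with_counts(self):
        ds = eligible_dataset(5, 2, config=RunConfig(min_dataset_size=2))
        with pytest.raises(ValueError, match="exceeds"):
            make_folds(ds, k=9, scheme="random", seed=0)

    def test_seeded_determinism(self):
        ds = eligible_dataset(30, 12)
        a = make_folds(ds, k=5, scheme="random", seed=42).fold_of
        b = make_folds(ds, k=5, scheme="random", seed=42).fold_of
        c = make_folds(ds, k=5, scheme="random", seed=43).fold_of
        assert a == b and a != c
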