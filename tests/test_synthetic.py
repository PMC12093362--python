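"""The two-domain study generator: chemistry, latent model, sampling."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from qsarshift.config import RunConfig
from qsarshift.curation import ClassifiedDataset, build_target_dataset
from qsarshift.descriptors import compute_fingerprint
from qsarshift.splitting import butina_cluster, tanimoto_matrix
from qsarshift.synthetic import (
    FIXTURE_SCAFFOLD_PERMUTATION,
    FIXTURE_SUBSTITUENT_IDS,
    GeneratorSpec,
    LatentActivity,
    assign_latent_activity,
    domain_scaffold_pools,
    generate_library,
    generate_study,
    sample_domains,
    write_study,
)


class TestLibrary:
    def test_library_size_is_scaffolds_times_pairs(self):
        # two asymmetric scaffolds, three substituents -> 2 x 9 products
        spec = GeneratorSpec(n_scaffolds=2, scaffold_overlap=1.0,
                             substituents_per_scaffold=9,
                             scaffold_permutation=(1, 3),
                             substituent_ids=(0, 2, 3), seed=0)
        lib = generate_library(spec)
        assert len(lib) == 18
        inchis = {Chem.MolToInchi(Chem.MolFromSmiles(c.smiles)) for c in lib}
        assert len(inchis) == 18

    def test_all_products_are_valid_and_standardizable(self):
        from qsarshift.curation import StandardizedStructure, standardize_compound

        lib = generate_library(GeneratorSpec(seed=0, n_scaffolds=3,
                                             substituents_per_scaffold=30))
        assert len(lib) > 0
        for c in lib[:60]:
            assert isinstance(standardize_compound(c.smiles),
                              StandardizedStructure)

    def test_scaffold_pools_respect_overlap(self):
        spec = GeneratorSpec(n_scaffolds=6, scaffold_overlap=1.0)
        pub, prop = domain_scaffold_pools(spec)
        assert pub == prop
        spec = GeneratorSpec(n_scaffolds=6, scaffold_overlap=0.0)
        pub, prop = domain_scaffold_pools(spec)
        assert not (pub & prop) and len(pub) == len(prop) == 6
        spec = GeneratorSpec(n_scaffolds=6, scaffold_overlap=0.5)
        pub, prop = domain_scaffold_pools(spec)
        assert len(pub & prop) == 3

    def test_overlarge_pool_request_is_rejected(self):
        with pytest.raises(ValueError, match="template"):
            GeneratorSpec(n_scaffolds=10, scaffold_overlap=0.0)

    def test_disjoint_fixture_scaffolds_cluster_without_domain_mixing(self):
        """On the designated dissimilar fixture vocabulary, Butina at 0.230
        never merges compounds from the two domains' scaffold pools."""
        spec = GeneratorSpec(
            n_scaffolds=3, scaffold_overlap=0.0, identity_overlap=0.0,
            scaffold_permutation=FIXTURE_SCAFFOLD_PERMUTATION,
            substituent_ids=FIXTURE_SUBSTITUENT_IDS,
            substituents_per_scaffold=36, seed=0,
        )
        lib = generate_library(spec)
        pub_pool, _ = domain_scaffold_pools(spec)
        domain_of = {c.compound_key: c.scaffold_id in pub_pool for c in lib}
        fps = [compute_fingerprint(c.smiles, compound_key=c.compound_key)
               for c in lib]
        # exhaustive check: every cross-pool pair below the threshold
        sims = tanimoto_matrix(fps)
        is_pub = np.array([domain_of[c.compound_key] for c in lib])
        assert sims[np.ix_(is_pub, ~is_pub)].max() < 0.230
        clusters = butina_cluster(fps, 0.230)
        for cid in clusters.centroids:
            domains = {domain_of[k] for k in clusters.members_of(cid)}
            assert len(domains) == 1


class TestLatentActivity:
    def test_noiseless_limit_is_a_deterministic_fragment_rule(self):
        spec = GeneratorSpec(seed=0, n_scaffolds=3, substituents_per_scaffold=60,
                             scaffold_effect_sd=0.0, latent_noise_sd=0.0)
        lib = generate_library(spec)
        latent = assign_latent_activity(lib, spec)
        for c in lib:
            # base 1.8 (inactive side) shifted by -2.5 when a pharmacophore
            # fragment is present
            assert latent.is_active(c) == c.has_pharmacophore

    def test_flip_inverts_the_fragment_rule(self):
        spec = GeneratorSpec(seed=0, n_scaffolds=3, substituents_per_scaffold=40,
                             scaffold_effect_sd=0.0, latent_noise_sd=0.0)
        lib = generate_library(spec)
        latent = assign_latent_activity(lib, spec)
        for c in lib[:40]:
            assert latent.is_active(c, flip=True) != latent.is_active(c)

    def test_pharmacophore_fraction_is_controlled(self):
        lib = generate_library(GeneratorSpec(seed=1))
        frac = np.mean([c.has_pharmacophore for c in lib])
        assert abs(frac - 0.42) < 0.05


class TestSampleDomains:
    def test_class_skews_and_identity_overlap_are_exact(self, default_study):
        gt = default_study.ground_truth
        pub = gt[gt.domain == "public_like"]
        prop = gt[gt.domain == "proprietary_like"]
        assert len(pub) == len(prop) == 500
        assert (pub.true_label == "active").sum() == 400
        assert (prop.true_label == "active").sum() == 100
        shared = set(pub.compound_key) & set(prop.compound_key)
        assert len(shared) == 50

    def test_conflict_rate_plants_threshold_straddling_replicates(self):
        spec = GeneratorSpec(seed=5, replicate_fraction=1.0, conflict_rate=0.2)
        study = generate_study(spec)
        by_key = {}
        for row in study.public_rows:
            by_key.setdefault(row.compound_key, []).append(row.value_um)
        conflicted = sum(
            1 for vals in by_key.values()
            if len(vals) > 1 and min(vals) <= 10.0 < max(vals)
        )
        # 20% forced conflicts plus a few measurement-noise straddles
        assert conflicted / len(by_key) > 0.15

    def test_infeasible_fractions_error_names_the_deficit(self):
        spec = GeneratorSpec(seed=0, n_scaffolds=2, substituents_per_scaffold=20,
                             n_per_domain=500)
        lib = generate_library(spec)
        latent = assign_latent_activity(lib, spec)
        with pytest.raises(ValueError, match="supplies only"):
            sample_domains(lib, latent, spec)

    def test_public_rows_carry_annotations_not_formats(self, default_study):
        for row in default_study.public_rows[:50]:
            assert row.assay_format is None
            assert row.assay_type in ("A", "B", "T", "F")
        for row in default_study.proprietary_rows[:50]:
            assert row.assay_format in ("cell_based", "cell_free")
            assert row.assay_type is None

    def test_ground_truth_is_separate_from_activity_tables(self, tmp_path,
                                                           default_study):
        paths = write_study(default_study, tmp_path)
        import pandas as pd

        for table in ("public", "proprietary"):
            frame = pd.read_csv(paths[table])
            assert "true_potency_um" not in frame.columns
            assert "true_label" not in frame.columns

    def test_write_study_is_byte_identical_across_runs(self, tmp_path):
        spec = GeneratorSpec(seed=3, n_per_domain=300)
        p1 = write_study(generate_study(spec), tmp_path / "a")
        p2 = write_study(generate_study(spec), tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_default_study_passes_curation_eligibility(self, default_study):
        config = RunConfig(seed=7)
        for rows, domain in ((default_study.public_rows, "public_like"),
                             (default_study.proprietary_rows,
                              "proprietary_like")):
            ds = build_target_dataset(rows, "TGT1", domain, config)
            assert isinstance(ds, ClassifiedDataset)
            assert len(ds) >= 250
            assert ds.minority_fraction() >= 0.15

    def test_emulated_skews_point_in_opposite_directions(self, default_study):
        config = RunConfig(seed=7)
        pub = build_target_dataset(default_study.public_rows, "TGT1",
                                   "public_like", config)
        prop = build_target_dataset(default_study.proprietary_rows, "TGT1",
                                    "proprietary_like", config)
        assert pub.n_active() > len(pub) / 2          # majority active
        assert prop.n_active() < len(prop) / 2        # majority inactive
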