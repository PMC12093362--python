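"""Mixed training-set compilation: format derivation, nesting, origins."""

from __future__ import annotations

import numpy as np
import pytest

from qsarshift.config import RunConfig
from qsarshift.curation import ClassifiedDataset, build_target_dataset
from qsarshift.descriptors import fingerprints_for
from qsarshift.mixing import (
    MixingSpec,
    compile_mixed,
    derive_assay_format_public,
    evaluate_mixing,
)
from qsarshift.splitting import tanimoto

from conftest import alcohol_series, eligible_dataset, make_row


class TestAssayFormatDerivation:
    def test_retained_type_with_cell_name_is_cell_based(self):
        rows, _ = derive_assay_format_public(
            [make_row("A", "CCO", 1.0, assay_type="B", cell_name="HEK293")]
        )
        assert rows[0].assay_format == "cell_based"

    def test_retained_type_without_cell_name_is_cell_free(self):
        rows, _ = derive_assay_format_public(
            [make_row("A", "CCO", 1.0, assay_type="B")]
        )
        assert rows[0].assay_format == "cell_free"

    @pytest.mark.parametrize("assay_type", ["F", "U", None])
    def test_other_assay_types_are_excluded_and_logged(self, assay_type):
        rows, excluded = derive_assay_format_public(
            [make_row("A", "CCO", 1.0, assay_type=assay_type)]
        )
        assert rows == [] and len(excluded) == 1

    def test_explicit_format_is_preserved(self):
        rows, _ = derive_assay_format_public(
            [make_row("A", "CCO", 1.0, assay_format="cell_based")]
        )
        assert rows[0].assay_format == "cell_based"

    @pytest.mark.parametrize("atype", ["A", "B", "T"])
    def test_all_three_retained_codes(self, atype):
        rows, _ = derive_assay_format_public(
            [make_row("A", "CCO", 1.0, assay_type=atype)]
        )
        assert rows and rows[0].assay_format == "cell_free"


def curated(rows, domain, target="TGT1"):
    ds = build_target_dataset(rows, target, domain,
                              RunConfig(min_dataset_size=2))
    assert isinstance(ds, ClassifiedDataset)
    return ds


class TestCompileMixed:
    def build_sets(self, n_base=10, n_public=20, fmt_split=0.5):
        smiles = alcohol_series(n_base + n_public)
        base_rows = [
            make_row(f"B{i}", smi, 1.0 if i % 3 else 100.0,
                     domain="proprietary_like", assay_format="cell_based")
            for i, smi in enumerate(smiles[:n_base])
        ]
        n_cell = int(n_public * fmt_split)
        public_rows = [
            make_row(f"P{i}", smi, 1.0 if i % 3 else 100.0,
                     assay_type="B",
                     cell_name="HeLa" if i < n_cell else None)
            for i, smi in enumerate(smiles[n_base:])
        ]
        public_rows, _ = derive_assay_format_public(public_rows)
        return (curated(base_rows, "proprietary_like"),
                curated(public_rows, "public_like"))

    def test_approach_a_is_the_disjoint_union(self):
        base, public = self.build_sets(10, 20)
        mixed = compile_mixed(base, public,
                              MixingSpec("a_target_only", "cell_based"))
        assert len(mixed.dataset) == 30 and mixed.n_added() == 20

    def test_approach_b_counts_match_the_format_split(self):
        base, public = self.build_sets(10, 20, fmt_split=0.5)
        mixed = compile_mixed(base, public,
                              MixingSpec("b_plus_assay_format", "cell_based"))
        assert mixed.n_added() == 10  # exactly the cell-based half
        added = [k for k, o in mixed.origin_of.items() if o == "added_public"]
        assert all(int(k[1:]) < 10 for k in added)

    def test_approach_c_matches_exhaustive_similarity_oracle(self, curated_small):
        pub, prop, config = curated_small
        base = prop.subset(range(40))
        public = pub.subset(range(40))
        # give every public compound a known format matching the base
        spec = MixingSpec("c_plus_similarity", "cell_based",
                          similarity_threshold=0.230)
        # rebuild members with explicit formats on measurements
        from qsarshift.curation import CompoundRecord, Measurement

        def with_format(ds):
            members = []
            for rec, lbl in ds.members:
                ms = tuple(
                    Measurement(m.measurement_type, m.value_um, m.relation,
                                m.assay_type, m.cell_name, "cell_based")
                    for m in rec.measurements
                )
                members.append((CompoundRecord(
                    rec.compound_key, rec.canonical_smiles, rec.inchi,
                    rec.inchikey, rec.domain, rec.target_id, ms), lbl))
            return ClassifiedDataset(ds.target_id, ds.domain, members)

        base_f, public_f = with_format(base), with_format(public)
        mixed = compile_mixed(base_f, public_f, spec, config)

        base_fps = fingerprints_for(base_f)
        base_inchis = base_f.inchis
        expected = set()
        for rec, _ in public_f.members:
            if rec.inchi in base_inchis:
                continue
            from qsarshift.descriptors import compute_fingerprint

            q = compute_fingerprint(rec)
            if max(tanimoto(q, b) for b in base_fps) >= 0.230:
                expected.add(rec.compound_key)
        added = {k for k, o in mixed.origin_of.items() if o == "added_public"}
        assert added == expected

    def test_nesting_and_origin_conservation(self):
        base, public = self.build_sets(12, 24, fmt_split=0.5)
        sets = {}
        for approach in ("a_target_only", "b_plus_assay_format",
                         "c_plus_similarity"):
            mixed = compile_mixed(base, public,
                                  MixingSpec(approach, "cell_based"))
            sets[approach] = mixed.inchi_set()
            base_keys = {rec.compound_key for rec, _ in base.members}
            out_keys = [rec.compound_key for rec, _ in mixed.dataset.members]
            assert all(out_keys.count(k) == 1 for k in base_keys)
        assert sets["c_plus_similarity"] <= sets["b_plus_assay_format"]
        assert sets["b_plus_assay_format"] <= sets["a_target_only"]

    def test_inchi_collision_resolves_toward_base(self):
        smiles = alcohol_series(12)
        base_rows = [make_row(f"B{i}", smi, 1.0 if i < 8 else 100.0,
                              domain="proprietary_like",
                              assay_format="cell_based")
                     for i, smi in enumerate(smiles)]
        # public copy of molecule 0 with the opposite label, plus one
        # genuinely new compound so the public set is curatable
        public_rows = [
            make_row("PDUP", smiles[0], 500.0, assay_type="B"),
            make_row("PNEW", "OCC(C)C", 500.0, assay_type="B"),
            make_row("PNEW2", "OCC(C)CC", 1.0, assay_type="B"),
        ]
        public_rows, _ = derive_assay_format_public(public_rows)
        base = curated(base_rows, "proprietary_like")
        public = curated(public_rows, "public_like")
        mixed = compile_mixed(base, public,
                              MixingSpec("a_target_only", "cell_based"))
        assert mixed.n_added() == 2
        assert "PDUP" not in mixed.origin_of
        assert ("PDUP", "dropped", "duplicate of base compound") in \
            mixed.compilation_log
        labels = {rec.compound_key: lbl for rec, lbl in mixed.dataset.members}
        assert labels["B0"] == "active"

    def test_empty_base_set_errors(self):
        _, public = self.build_sets()
        empty = ClassifiedDataset("TGT1", "proprietary_like", [])
        with pytest.raises(ValueError, match="base"):
            compile_mixed(empty, public, MixingSpec("a_target_only", "cell_based"))


class TestEvaluateMixing:
    def test_record_count_is_approaches_by_schemes_by_folds(self, curated_small):
        pub, prop, config = curated_small
        records = evaluate_mixing(
            prop, pub, assay_format="cell_based", config=config,
            algorithm_tag="svm", grid=[{"C": 1, "kernel": "rbf"}],
            approaches=("a_target_only",), schemes=("random", "cluster"),
        )
        assert len(records) == 1 * 2 * 9
        assert {r["scheme"] for r in records} == {"random", "cluster"}
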