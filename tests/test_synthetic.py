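import numpy as np
import pandas as pd
import pytest

from lncnet import (
    LNCRNA,
    MRNA,
    SyntheticConfig,
    find_cis_pairs_bruteforce,
    generate_annotation,
    generate_expression,
    generate_gene_sets,
    generate_qpcr,
)
from lncnet.containers import ValidationError

SMALL = dict(
    n_lnc=120, n_mrna=150, n_de_lnc=12, n_de_mrna=14,
    n_linked_pairs=8, n_cis_pairs=3, seed=11,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("n_lnc", -1),
            ("n_de_lnc", 500),
            ("n_cis_pairs", 99),
            ("planted_rho", 1.0),
            ("planted_rho", -0.1),
            ("noise_sd", 0.0),
            ("genome", ()),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        cfg = SyntheticConfig(**{**SMALL, field: value})
        with pytest.raises(ValidationError):
            cfg.validate()


class TestGenerateExpression:
    def test_shape_and_labels(self):
        cfg = SyntheticConfig(**SMALL)
        matrix, truth = generate_expression(cfg)
        assert matrix.values.shape == (270, 22)
        assert (matrix.biotype == LNCRNA).sum() == 120
        assert len(matrix.case_ids) == 13 and len(matrix.control_ids) == 9
        assert len(truth.de) == 12 + 14
        assert len(truth.linked) == 8
        assert truth.cis_pairs["is_cis"].all() and len(truth.cis_pairs) == 3

    def test_determinism_same_seed_identical(self):
        cfg = SyntheticConfig(**SMALL)
        m1, t1 = generate_expression(cfg)
        m2, t2 = generate_expression(cfg)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1.de, t2.de)
        pd.testing.assert_frame_equal(t1.linked, t2.linked)

    def test_seed_variation_differs(self):
        m1, t1 = generate_expression(SyntheticConfig(**{**SMALL, "seed": 1}))
        m2, t2 = generate_expression(SyntheticConfig(**{**SMALL, "seed": 2}))
        assert not m1.values.equals(m2.values)
        assert set(t1.de.index) != set(t2.de.index)

    def test_planted_log2fc_recovered_within_3se(self):
        cfg = SyntheticConfig(
            n_lnc=300, n_mrna=300, n_de_lnc=100, n_de_mrna=100,
            n_linked_pairs=0, n_cis_pairs=0, planted_log2fc=1.5, noise_sd=0.5, seed=5,
        )
        matrix, truth = generate_expression(cfg)
        case = matrix.values[matrix.case_ids].mean(axis=1)
        ctrl = matrix.values[matrix.control_ids].mean(axis=1)
        observed = (case - ctrl).loc[truth.de.index] * truth.de["direction"]
        se_one = 0.5 * np.sqrt(1 / 13 + 1 / 9)
        se_mean = se_one / np.sqrt(len(observed))
        assert abs(observed.mean() - 1.5) <= 3 * se_mean

    def test_planted_correlation_concentrates(self):
        cfg = SyntheticConfig(
            n_lnc=500, n_mrna=500, n_de_lnc=0, n_de_mrna=0,
            n_linked_pairs=500, planted_rho=0.85, seed=9,
        )
        matrix, truth = generate_expression(cfg)
        rs = []
        for row in truth.linked.itertuples(index=False):
            x = matrix.values.loc[row.lnc_id]
            y = matrix.values.loc[row.mrna_id]
            rs.append(np.corrcoef(x, y)[0, 1])
        assert abs(np.mean(rs) - 0.85) <= 0.05

    def test_null_config_probes_are_null(self):
        cfg = SyntheticConfig(
            n_lnc=200, n_mrna=200, n_de_lnc=0, n_de_mrna=0, n_linked_pairs=0, n_cis_pairs=0, seed=2
        )
        matrix, truth = generate_expression(cfg)
        assert truth.de.empty and truth.linked.empty
        # group means should not differ systematically
        diff = (
            matrix.values[matrix.case_ids].mean(axis=1)
            - matrix.values[matrix.control_ids].mean(axis=1)
        )
        assert abs(diff.mean()) < 0.05


class TestGenerateAnnotation:
    def test_truth_cis_labels_match_bruteforce_scan(self):
        cfg = SyntheticConfig(**SMALL)
        matrix, truth = generate_expression(cfg)
        loci = {l.probe_id: l for l in generate_annotation(cfg, truth)}
        lnc_loci = [loci[p] for p in truth.linked["lnc_id"]]
        mrna_loci = [loci[p] for p in truth.linked["mrna_id"]]
        found = find_cis_pairs_bruteforce(lnc_loci, mrna_loci, cfg.window_bp)
        found_pairs = set(zip(found["lnc_id"], found["mrna_id"]))
        truth_pairs = set(zip(truth.cis_pairs["lnc_id"], truth.cis_pairs["mrna_id"]))
        assert found_pairs == truth_pairs

    def test_no_cis_pairs_when_none_planted(self):
        cfg = SyntheticConfig(**{**SMALL, "n_cis_pairs": 0})
        _, truth = generate_expression(cfg)
        loci = {l.probe_id: l for l in generate_annotation(cfg, truth)}
        lnc_loci = [loci[p] for p in truth.linked["lnc_id"]]
        mrna_loci = [loci[p] for p in truth.linked["mrna_id"]]
        found = find_cis_pairs_bruteforce(lnc_loci, mrna_loci, cfg.window_bp)
        assert found.empty

    def test_every_interval_inside_chromosome(self):
        cfg = SyntheticConfig(**SMALL)
        _, truth = generate_expression(cfg)
        lengths = dict(cfg.genome)
        loci = generate_annotation(cfg, truth)
        assert len(loci) == cfg.n_lnc + cfg.n_mrna
        for l in loci:
            assert 0 <= l.start < l.end <= lengths[l.chrom]

    def test_capacity_error_on_tiny_genome(self):
        cfg = SyntheticConfig(**{**SMALL, "genome": (("chr1", 1000), ("chr2", 1000))})
        _, truth = generate_expression(cfg)
        with pytest.raises(ValidationError, match="genome"):
            generate_annotation(cfg, truth)

    def test_deterministic(self):
        cfg = SyntheticConfig(**SMALL)
        _, truth = generate_expression(cfg)
        assert generate_annotation(cfg, truth) == generate_annotation(cfg, truth)


class TestGenerateQpcr:
    def test_noise_free_exact_fold_two(self):
        cfg = SyntheticConfig(**{**SMALL, "planted_log2fc": 1.0})
        _, truth = generate_expression(cfg)
        up = truth.de.index[truth.de["direction"] > 0][0]
        records = generate_qpcr(cfg, truth, [up], noise_sd=0.0)
        from lncnet import delta_delta_ct

        rel = delta_delta_ct(records, "ACTB")
        case_folds = rel.loc[rel["group"] == "case", "fold"]
        assert (case_folds == 2.0).all()

    def test_null_target_fold_one(self):
        cfg = SyntheticConfig(**SMALL)
        _, truth = generate_expression(cfg)
        null_probe = next(p for p in [f"LNC{i:06d}" for i in range(1, 121)]
                          if p not in truth.de.index)
        records = generate_qpcr(cfg, truth, [null_probe], noise_sd=0.0)
        from lncnet import delta_delta_ct

        rel = delta_delta_ct(records, "ACTB")
        assert (rel["fold"] == 1.0).all()

    def test_mean_recovered_fold_within_20pct_over_seeds(self):
        # noisy recovery: mean of -ddCt in cases estimates planted log2fc
        recovered = []
        for seed in range(100):
            cfg = SyntheticConfig(**{**SMALL, "seed": seed, "planted_log2fc": 1.0})
            _, truth = generate_expression(cfg)
            target = truth.de.index[truth.de["direction"] > 0]
            if len(target) == 0:
                continue
            records = generate_qpcr(cfg, truth, [target[0]], noise_sd=0.2)
            from lncnet import delta_delta_ct

            rel = delta_delta_ct(records, "ACTB")
            recovered.append(rel.loc[rel["group"] == "case", "fold"].mean())
        mean_fold = np.mean(recovered)
        assert abs(mean_fold - 2.0) / 2.0 <= 0.2

    def test_unknown_target_rejected(self):
        cfg = SyntheticConfig(**SMALL)
        _, truth = generate_expression(cfg)
        with pytest.raises(ValidationError, match="NOPE"):
            generate_qpcr(cfg, truth, ["NOPE"])

    def test_default_validation_cohort_sizes(self):
        cfg = SyntheticConfig(**SMALL)
        _, truth = generate_expression(cfg)
        records = generate_qpcr(cfg, truth, [truth.de.index[0]])
        groups = records.drop_duplicates("sample_id")["group"].value_counts()
        assert groups["case"] == 9 and groups["control"] == 12


class TestGenerateGeneSets:
    def test_planted_sets_contain_de_genes(self):
        cfg = SyntheticConfig(**SMALL)
        _, truth = generate_expression(cfg)
        sets = {s.set_id: s for s in generate_gene_sets(cfg, truth)}
        de_mrna = set(truth.de.index[truth.de["biotype"] == MRNA])
        up = {p for p in de_mrna if truth.de.loc[p, "direction"] > 0}
        if up:
            assert sets["SET_UP"].members & up
        assert len(sets) == 20
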