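import numpy as np
import pandas as pd
import pytest

from autoab.localization import classify_localization, organ_specificity
from autoab.mimicry import mimicry_screen
from autoab.prevalence import StudyCount, weighted_prevalence
from autoab.synth import (
    REFERENCE_MIMICRY_PEPTIDES,
    SimulationConfig,
    gen_annotations,
    gen_proteomes,
    gen_response_matrices,
    gen_tpm_table,
    joint_bernoulli_probs,
)


class TestConfig:
    def test_seed_mandatory(self):
        with pytest.raises((ValueError, TypeError)):
            SimulationConfig(seed=None)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, n_studies=0)

    def test_invalid_planted_phi_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, planted_pairs=[((0, 1), 1.0)])


class TestJointBernoulli:
    def test_cells_sum_to_one_and_match_marginals(self):
        p11, p10, p01, p00 = joint_bernoulli_probs(0.3, 0.4, 0.5)
        assert p11 + p10 + p01 + p00 == pytest.approx(1.0)
        assert p11 + p10 == pytest.approx(0.3)
        assert p11 + p01 == pytest.approx(0.4)

    def test_phi_roundtrip(self):
        p11, p10, p01, p00 = joint_bernoulli_probs(0.2, 0.35, 0.6)
        phi = (p11 * p00 - p10 * p01) / np.sqrt(0.2 * 0.8 * 0.35 * 0.65)
        assert phi == pytest.approx(0.6)

    def test_infeasible_target_rejected(self):
        # phi = 0.9 with marginals 0.05 and 0.95 is outside the Frechet bounds
        with pytest.raises(ValueError, match="feasible range"):
            joint_bernoulli_probs(0.05, 0.95, 0.9)


class TestResponseMatrices:
    def test_determinism(self):
        cfg = SimulationConfig(seed=7, n_studies=3, subjects_per_study=20, n_antibodies=10)
        a = gen_response_matrices(cfg)
        b = gen_response_matrices(cfg)
        for sa, sb in zip(a, b):
            assert sa.study_id == sb.study_id
            np.testing.assert_array_equal(sa.responses, sb.responses)
            assert [s.subject_id for s in sa.subjects] == [s.subject_id for s in sb.subjects]

    def test_shapes_and_values(self):
        cfg = SimulationConfig(seed=2, n_studies=4, subjects_per_study=30, n_antibodies=12)
        studies = gen_response_matrices(cfg)
        assert len(studies) == 4
        for s in studies:
            assert s.responses.shape == (12, 30)
            assert set(np.unique(s.responses)) <= {0.0, 1.0}

    def test_zero_heterogeneity_calibration(self):
        # with sd = 0 every study draws Bernoulli at the same true prevalence:
        # the pooled estimate concentrates on it, and Q behaves like a
        # chi-square with k-1 df (tau2 truncates to zero whenever Q <= k-1,
        # which happens ~59% of the time at k = 5; far more often than under
        # real heterogeneity)
        from scipy.stats import chi2

        cfg = SimulationConfig(
            seed=13, n_studies=5, subjects_per_study=400, n_antibodies=30,
            true_prevalences=0.2, between_study_sd=0.0,
        )
        studies = gen_response_matrices(cfg)
        estimates = []
        n_tau_zero = 0
        n_rejected = 0
        crit = chi2.ppf(0.99, df=4)
        for ab in studies[0].antibodies:
            counts = [StudyCount(*s.counts(ab), study_id=s.study_id) for s in studies]
            res = weighted_prevalence(counts)
            estimates.append(res.p_hat)
            if res.tau2 == 0.0:
                n_tau_zero += 1
            if res.Q > crit:
                n_rejected += 1
        assert abs(np.mean(estimates) - 0.2) < 0.02
        assert 0.3 * 30 <= n_tau_zero  # truncation common under homogeneity
        assert n_rejected <= 0.05 * 30 + 2  # homogeneity rarely rejected at alpha = 0.01

    def test_heterogeneity_inflates_tau2(self):
        # tau2 truncates to zero far less often when real between-study
        # variance is present
        def tau_zero_rate(sd, seed):
            cfg = SimulationConfig(
                seed=seed, n_studies=5, subjects_per_study=400, n_antibodies=30,
                true_prevalences=0.2, between_study_sd=sd,
            )
            studies = gen_response_matrices(cfg)
            zero = 0
            for ab in studies[0].antibodies:
                counts = [StudyCount(*s.counts(ab), study_id=s.study_id) for s in studies]
                if weighted_prevalence(counts).tau2 == 0.0:
                    zero += 1
            return zero / 30

        assert tau_zero_rate(0.6, 13) < tau_zero_rate(0.0, 13)

    def test_probed_fraction_masks_antibodies(self):
        cfg = SimulationConfig(
            seed=4, n_studies=3, subjects_per_study=10, n_antibodies=20, probed_fraction=0.5
        )
        studies = gen_response_matrices(cfg)
        for s in studies:
            probed = sum(s.counts(ab) is not None for ab in s.antibodies)
            assert probed == 10

    def test_planted_pair_marginals_shared(self):
        cfg = SimulationConfig(
            seed=8, n_studies=2, subjects_per_study=5000, n_antibodies=4,
            true_prevalences=0.3, planted_pairs=[((0, 2), 0.7)],
        )
        for s in gen_response_matrices(cfg):
            x0, n = s.counts("AB0000")
            x2, _ = s.counts("AB0002")
            # the planted members draw from one shared study marginal
            assert abs(x0 - x2) / n < 0.03


class TestProteomes:
    def test_truth_table_shape(self):
        hosts, virals, truth = gen_proteomes(SimulationConfig(seed=1))
        assert len(truth) == 29
        assert truth["host_id"].nunique() == 21
        assert truth["viral_id"].nunique() == 29
        assert sorted(truth["length"].tolist()).count(7) == 28
        assert truth["length"].max() == 8

    def test_planted_peptides_present_at_coordinates(self):
        hosts, virals, truth = gen_proteomes(SimulationConfig(seed=3))
        host_by_id = {h.id: h for h in hosts}
        viral_by_id = {v.id: v for v in virals}
        for row in truth.itertuples():
            h = host_by_id[row.host_id].sequence
            v = viral_by_id[row.viral_id].sequence
            assert h[row.host_start : row.host_start + row.length] == row.peptide
            assert v[row.viral_start : row.viral_start + row.length] == row.peptide

    def test_determinism(self):
        a = gen_proteomes(SimulationConfig(seed=5))
        b = gen_proteomes(SimulationConfig(seed=5))
        assert [(h.id, h.sequence) for h in a[0]] == [(h.id, h.sequence) for h in b[0]]
        assert [(v.id, v.sequence) for v in a[1]] == [(v.id, v.sequence) for v in b[1]]
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_screen_recovers_exactly_the_plants(self):
        hosts, virals, truth = gen_proteomes(SimulationConfig(seed=1))
        matches = mimicry_screen(hosts, virals, threshold=7)
        got = {(m.host_id, m.host_start, m.length) for m in matches}
        want = {(r.host_id, r.host_start, r.length) for r in truth.itertuples()}
        assert got == want

    def test_no_plants_no_matches(self):
        cfg = SimulationConfig(seed=9, planted_peptides=[], n_background_proteins=8)
        hosts, virals, truth = gen_proteomes(cfg)
        assert truth.empty
        assert len(hosts) == 8
        assert virals == []

    def test_repeat_run_peptide_rejected(self):
        cfg = SimulationConfig(seed=1, planted_peptides=[("H", "V", "AAACDEF")])
        with pytest.raises(ValueError, match="3-run"):
            gen_proteomes(cfg)

    def test_reference_set_composition(self):
        lengths = [len(p) for _, _, p in REFERENCE_MIMICRY_PEPTIDES]
        assert len(REFERENCE_MIMICRY_PEPTIDES) == 29
        assert lengths.count(7) == 28 and lengths.count(8) == 1
        assert len({h for h, _, _ in REFERENCE_MIMICRY_PEPTIDES}) == 21


class TestTpmTable:
    def test_planted_gene_recovered(self):
        cfg = SimulationConfig(seed=6, tpm_planted={"PMFBP1": "testis"})
        tpm = gen_tpm_table(cfg)
        spec = {s.gene_id: s for s in organ_specificity(tpm)}
        assert spec["PMFBP1"].specific_organs == ["testis"]

    def test_null_genes_mostly_nonspecific(self):
        tpm = gen_tpm_table(SimulationConfig(seed=10))
        n_specific = sum(bool(s.specific_organs) for s in organ_specificity(tpm))
        assert n_specific / tpm.shape[1] <= 0.05

    def test_fold_change_is_honored(self):
        cfg = SimulationConfig(seed=2, tpm_planted={"G0003": "brain"}, tpm_fold_change=16.0)
        tpm = gen_tpm_table(cfg)
        others = tpm["G0003"].drop("brain").mean()
        assert tpm.loc["brain", "G0003"] == pytest.approx(16.0 * others)

    def test_determinism_and_unknown_organ(self):
        a = gen_tpm_table(SimulationConfig(seed=3))
        b = gen_tpm_table(SimulationConfig(seed=3))
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            gen_tpm_table(SimulationConfig(seed=3, tpm_planted={"G0001": "gills"}))


class TestAnnotations:
    def test_exact_allocation(self):
        cfg = SimulationConfig(
            seed=1,
            ann_n_proteins=70,
            ann_group_fractions={"intracellular only": 55 / 70, "secreted only": 15 / 70},
        )
        table, truth = gen_annotations(cfg)
        from collections import Counter

        counts = Counter(truth.values())
        assert counts["intracellular only"] == 55
        assert counts["secreted only"] == 15
        assert len(table.localization) == 70

    def test_terms_classify_back_to_truth_group(self):
        cfg = SimulationConfig(
            seed=1,
            ann_n_proteins=40,
            ann_group_fractions={
                "intracellular & cell membrane": 0.5,
                "cell membrane & secreted": 0.25,
                "unannotated": 0.25,
            },
        )
        table, truth = gen_annotations(cfg)
        for pid, terms in table.localization.items():
            call = classify_localization(pid, terms)
            if truth[pid] == "unannotated":
                assert call.group is None
            else:
                assert call.group == truth[pid]

    def test_largest_remainder_sums_to_n(self):
        cfg = SimulationConfig(
            seed=1,
            ann_n_proteins=10,
            ann_group_fractions={
                "intracellular only": 1 / 3,
                "secreted only": 1 / 3,
                "cell membrane only": 1 / 3,
            },
        )
        table, truth = gen_annotations(cfg)
        assert len(truth) == 10

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            gen_annotations(
                SimulationConfig(seed=1, ann_n_proteins=10, ann_group_fractions={"intracellular only": 0.5})
            )
        with pytest.raises(ValueError):
            gen_annotations(
                SimulationConfig(seed=1, ann_n_proteins=10, ann_group_fractions={"mitochondrial only": 1.0})
            )

    def test_empty_config_empty_output(self):
        table, truth = gen_annotations(SimulationConfig(seed=1))
        assert truth == {}
        assert table.localization == {}
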