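import numpy as np
import pandas as pd
import pytest

from cllmeth.datatypes import BetaMatrix, ConfigError
from cllmeth.qc_norm import (
    ProbeFilterRules,
    beta_to_m,
    combat,
    filter_probes,
    filter_samples,
    m_to_beta,
    normalize,
    run_qc,
    sex_check,
)
from cllmeth.synthdata import (
    MethylationEffects,
    generate_annotation,
    generate_methylation,
    make_sample_design,
)
from conftest import tiny_beta


class TestFilterSamples:
    def test_clean_input_keeps_everything(self):
        bm = tiny_beta(np.full((100, 4), 0.5), detection_p=np.zeros((100, 4)))
        out, report = filter_samples(bm)
        assert list(out.sample_ids) == list(bm.sample_ids)
        assert report.counts()["samples"].get("detection", 0) == 0

    def test_two_percent_failed_sample_dropped(self):
        det = np.zeros((100, 4))
        det[:2, 1] = 0.1  # 2% of probes above 0.05 in sample S1
        bm = tiny_beta(np.full((100, 4), 0.5), detection_p=det)
        out, report = filter_samples(bm, max_failed_fraction=0.01)
        assert "S1" not in out.sample_ids
        assert report.excluded_samples["detection"] == ["S1"]

    def test_vacuous_threshold(self):
        det = np.full((50, 3), 0.9)
        bm = tiny_beta(np.full((50, 3), 0.5), detection_p=det)
        out, _ = filter_samples(bm, max_failed_fraction=1.0)
        assert list(out.sample_ids) == list(bm.sample_ids)

    def test_missing_detection_p_errors(self):
        bm = tiny_beta(np.full((10, 3), 0.5))
        with pytest.raises(ConfigError):
            filter_samples(bm)


@pytest.fixture(scope="module")
def sexed_dataset():
    ann = generate_annotation(800, chromosomes=["1", "X"], seed=31)
    design = make_sample_design(20, 16, seed=31)
    bm, _, _ = generate_methylation(ann, design,
                                    MethylationEffects(sex_effect_x=0.25), seed=31)
    return ann, design, bm


class TestSexCheck:
    def test_correct_labels_no_flags(self, sexed_dataset):
        ann, design, bm = sexed_dataset
        report = sex_check(bm, ann, design)
        assert report.all_excluded_samples == set()
        assert not report.notes

    def test_label_swap_flags_exactly_that_sample(self, sexed_dataset):
        ann, design, bm = sexed_dataset
        swapped = design.copy()
        male = design.index[design["sex"] == "M"][0]
        swapped.loc[male, "sex"] = "F"
        report = sex_check(bm, ann, swapped)
        assert report.excluded_samples.get("sex_mismatch") == [male]

    def test_identical_sexes_indeterminate(self, sexed_dataset):
        ann, design, _ = sexed_dataset
        rng = np.random.default_rng(0)
        flat = tiny_beta(np.clip(rng.normal(0.5, 0.01, (800, len(design))), 0, 1))
        flat.values.index = ann.index
        flat.values.columns = design.index
        report = sex_check(BetaMatrix(flat.values), ann, design)
        assert report.all_excluded_samples == set()
        assert any("indeterminate" in n for n in report.notes)

    def test_no_x_probes_errors(self, sexed_dataset):
        _, design, bm = sexed_dataset
        ann_auto = generate_annotation(800, chromosomes=["1"], seed=31)
        with pytest.raises(ConfigError):
            sex_check(bm, ann_auto, design)


class TestFilterProbes:
    @pytest.fixture()
    def annotated_beta(self):
        ann = generate_annotation(300, chromosomes=["1", "2", "X", "Y"], seed=41,
                                  snp_frac=0.0, crossreactive_frac=0.0)
        n = len(ann)
        det = np.zeros((n, 20))
        beads = np.full((n, 20), 10)
        vals = np.full((n, 20), 0.5)
        bm = BetaMatrix(
            pd.DataFrame(vals, index=ann.index, columns=[f"S{i}" for i in range(20)]),
            detection_p=pd.DataFrame(det, index=ann.index, columns=[f"S{i}" for i in range(20)]),
            bead_count=pd.DataFrame(beads, index=ann.index, columns=[f"S{i}" for i in range(20)]),
        )
        return ann, bm

    def test_sex_chrom_excluded(self, annotated_beta):
        ann, bm = annotated_beta
        out, report = filter_probes(bm, ann)
        y_probe = ann.index[ann["chrom"] == "Y"][0]
        assert y_probe in report.excluded_probes["sex_chrom"]
        assert y_probe not in out.probe_ids

    def test_low_beads_excluded(self, annotated_beta):
        ann, bm = annotated_beta
        victim = ann.index[ann["chrom"] == "1"][0]
        bm.bead_count.loc[victim, bm.sample_ids[:2]] = 2  # 10% of 20 samples > 5%
        out, report = filter_probes(bm, ann)
        assert victim in report.excluded_probes["beads"]
        assert victim not in out.probe_ids

    def test_clean_autosomal_retained(self, annotated_beta):
        ann, bm = annotated_beta
        clean = ann.index[(ann["chrom"] == "1")][1]
        out, _ = filter_probes(bm, ann)
        assert clean in out.probe_ids

    def test_multi_reason_counted_twice_excluded_once(self, annotated_beta):
        ann, bm = annotated_beta
        ann = ann.copy()
        x_probe = ann.index[ann["chrom"] == "X"][0]
        ann.loc[x_probe, "snp_flag"] = True
        out, report = filter_probes(bm, ann)
        assert x_probe in report.excluded_probes["sex_chrom"]
        assert x_probe in report.excluded_probes["snp_crossreactive"]
        assert (~out.probe_ids.duplicated()).all()
        assert x_probe not in out.probe_ids

    def test_qc_idempotent(self, annotated_beta):
        ann, bm = annotated_beta
        once, _ = filter_probes(bm, ann)
        twice, rep2 = filter_probes(once, ann)
        assert list(twice.probe_ids) == list(once.probe_ids)
        assert rep2.all_excluded_probes == set()


class TestBetaMTransforms:
    def test_half_maps_to_zero(self):
        assert beta_to_m(np.array([0.5]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_point_eight_maps_to_two(self):
        assert beta_to_m(np.array([0.8]))[0] == pytest.approx(2.0, abs=1e-12)

    def test_round_trip(self):
        eps = 1e-3
        beta = np.linspace(eps, 1 - eps, 1001)
        back = m_to_beta(beta_to_m(beta, epsilon=eps))
        assert np.max(np.abs(back - beta)) < 1e-12

    def test_epsilon_validation(self):
        with pytest.raises(ConfigError):
            beta_to_m(np.array([0.5]), epsilon=0.7)

    def test_dataframe_round_trip_keeps_axes(self):
        df = pd.DataFrame([[0.2, 0.8]], index=["p"], columns=["a", "b"])
        out = m_to_beta(beta_to_m(df))
        pd.testing.assert_frame_equal(out, df)


class TestNormalize:
    @pytest.fixture()
    def ann(self):
        return generate_annotation(400, seed=51)

    def test_identical_samples_fixed_point(self, ann):
        rng = np.random.default_rng(1)
        col = rng.random(len(ann))
        vals = np.column_stack([col, col, col])
        bm = BetaMatrix(pd.DataFrame(vals, index=ann.index, columns=list("abc")))
        out = normalize(bm, annotation=ann)
        assert np.max(np.abs(out.values.to_numpy() - vals)) < 1e-12

    def test_sorted_vectors_identical_per_type(self, ann):
        rng = np.random.default_rng(2)
        vals = rng.random((len(ann), 5))
        bm = BetaMatrix(pd.DataFrame(vals, index=ann.index,
                                     columns=[f"s{i}" for i in range(5)]))
        out = normalize(bm, annotation=ann)
        for t in ("I", "II"):
            sub = out.values.loc[ann.index[ann["design_type"] == t]].to_numpy()
            ref = np.sort(sub[:, 0])
            for j in range(1, sub.shape[1]):
                assert np.allclose(np.sort(sub[:, j]), ref, atol=1e-12)

    def test_rank_order_preserved(self, ann):
        # oracle: ranks via naive argsort before and after must agree per type
        rng = np.random.default_rng(3)
        vals = rng.random((len(ann), 4))
        bm = BetaMatrix(pd.DataFrame(vals, index=ann.index,
                                     columns=[f"s{i}" for i in range(4)]))
        out = normalize(bm, annotation=ann)
        for t in ("I", "II"):
            rows = ann.index[ann["design_type"] == t]
            before = bm.values.loc[rows].to_numpy()
            after = out.values.loc[rows].to_numpy()
            for j in range(4):
                assert (np.argsort(before[:, j], kind="stable")
                        == np.argsort(after[:, j], kind="stable")).all()

    def test_intensity_route_recomputes_beta(self, ann):
        rng = np.random.default_rng(4)
        shape = (len(ann), 4)
        meth = pd.DataFrame(rng.lognormal(8, 0.3, shape), index=ann.index,
                            columns=[f"s{i}" for i in range(4)])
        unmeth = pd.DataFrame(rng.lognormal(8, 0.3, shape), index=ann.index,
                              columns=meth.columns)
        out = normalize(intensities=(meth, unmeth), annotation=ann)
        assert out.values.to_numpy().min() >= 0
        assert out.values.to_numpy().max() <= 1

    def test_unknown_method(self, ann):
        bm = BetaMatrix(pd.DataFrame(np.full((len(ann), 2), 0.5), index=ann.index,
                                     columns=["a", "b"]))
        with pytest.raises(ConfigError):
            normalize(bm, annotation=ann, method="loess")


class TestCombat:
    def _dataset(self, batch_shift=1.0, delta=0.0, noise=0.1, seed=61, n_probes=1500):
        ann = generate_annotation(n_probes, seed=seed)
        design = make_sample_design(24, 20, seed=seed)
        probes = {}
        if delta:
            body = ann.index[ann["feature"] == "Body"][:200]
            probes = {p: delta for p in body}
        eff = MethylationEffects(batch_shifts={"B2": batch_shift} if batch_shift else {},
                                 probe_deltas=probes, noise_sd_m=noise,
                                 baseline_params=((6.0, 14.0), (14.0, 6.0)))
        bm, _, _ = generate_methylation(ann, design, eff, seed=seed)
        return design, beta_to_m(bm.values), list(probes)

    def test_single_batch_identity(self):
        design, m, _ = self._dataset(batch_shift=0.0)
        single = pd.Series("B1", index=m.columns)
        out = combat(m, single)
        assert np.max(np.abs(out.to_numpy() - m.to_numpy())) < 1e-10

    def test_batch_offset_removed(self):
        design, m, _ = self._dataset(batch_shift=1.0)
        out = combat(m, design["batch"], design[["group"]])
        b1 = design.index[design["batch"] == "B1"]
        b2 = design.index[design["batch"] == "B2"]
        diff = (out[b2].mean(axis=1) - out[b1].mean(axis=1)).abs()
        assert (diff < 0.05).mean() >= 0.99

    def test_group_effect_preserved(self):
        design, m, probes = self._dataset(batch_shift=1.0, delta=0.3)
        out = combat(m, design["batch"], design[["group"]])
        cll = design.index[design["group"] == "CLL"]
        ctl = design.index[design["group"] == "control"]
        pre = (m.loc[probes, cll].mean(axis=1) - m.loc[probes, ctl].mean(axis=1)).mean()
        post = (out.loc[probes, cll].mean(axis=1) - out.loc[probes, ctl].mean(axis=1)).mean()
        assert abs(post / pre - 1.0) < 0.10

    def test_confounded_batch_errors(self):
        design, m, _ = self._dataset(batch_shift=0.0)
        confounded = design.copy()
        confounded["batch"] = np.where(confounded["group"] == "CLL", "B1", "B2")
        with pytest.raises(ConfigError, match="confounded"):
            combat(m, confounded["batch"], confounded[["group"]])

    def test_small_batch_errors(self):
        design, m, _ = self._dataset(batch_shift=0.0)
        lopsided = pd.Series("B1", index=m.columns)
        lopsided.iloc[0] = "B2"
        with pytest.raises(ConfigError, match=">= 2 samples"):
            combat(m, lopsided)

    def test_null_data_roughly_unchanged(self):
        design, m, _ = self._dataset(batch_shift=0.0)
        out = combat(m, design["batch"], design[["group"]])
        # no batch signal: adjustment only reshuffles within shrinkage tolerance
        assert np.abs(out.to_numpy() - m.to_numpy()).mean() < 0.1


class TestRunQC:
    def test_merged_report_and_axes(self):
        ann = generate_annotation(600, chromosomes=["1", "X"], seed=71)
        design = make_sample_design(16, 12, seed=71)
        victim = design.index[0]
        eff = MethylationEffects(sex_effect_x=0.25,
                                 failed_sample_rates={victim: 0.05})
        bm, _, _ = generate_methylation(ann, design, eff, seed=71)
        out, report = run_qc(bm, ann, design)
        assert victim in report.excluded_samples["detection"]
        assert victim not in out.sample_ids
        assert not out.probe_ids.isin(ann.index[ann["chrom"] == "X"]).any()
        # surviving axes = input minus exclusions
        assert len(out.sample_ids) == len(bm.sample_ids) - len(report.all_excluded_samples)
        assert len(out.probe_ids) == len(bm.probe_ids) - len(report.all_excluded_probes)
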