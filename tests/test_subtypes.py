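import numpy as np
import pandas as pd
import pytest

from cllmeth.datatypes import ConfigError
from cllmeth.qc_norm import beta_to_m
from cllmeth.subtypes import (
    bcell_differentiation_dmps,
    classify_subtypes,
    dmp_overlap_fraction,
    subtract_and_rescreen,
    subtype_counts,
    subtype_dmps,
    train_subtype_model,
)
from cllmeth.synthdata import (
    SimConfig,
    simulate_dataset,
)

PROBES = [f"cg{i}" for i in range(5)]
CENTROIDS = {"n-CLL": -3.0, "i-CLL": 0.0, "m-CLL": 3.0}


def cluster_reference(n_per_class=12, sd=0.2, seed=0):
    """Well-separated 3-cluster training matrix on an M-value-like scale."""
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    for label, centre in CENTROIDS.items():
        for i in range(n_per_class):
            cols.append(rng.normal(centre, sd, 5))
            labels.append(label)
    samples = [f"R{i}" for i in range(len(cols))]
    ref = pd.DataFrame(np.column_stack(cols), index=PROBES, columns=samples)
    return ref, pd.Series(labels, index=samples)


class TestTrainAndClassify:
    def test_separable_clusters_resubstitute_perfectly(self):
        ref, labels = cluster_reference()
        model = train_subtype_model(ref, labels)
        calls = classify_subtypes(model, ref)
        assert (calls == labels).all()

    def test_single_class_errors(self):
        ref, labels = cluster_reference()
        with pytest.raises(ConfigError, match="2 classes"):
            train_subtype_model(ref, pd.Series("n-CLL", index=labels.index))

    def test_duplicated_training_sample_same_predictions(self):
        ref, labels = cluster_reference()
        dup = pd.concat([ref, ref.iloc[:, [0]].rename(columns={"R0": "R0b"})], axis=1)
        dup_labels = pd.concat([labels, pd.Series({"R0b": labels["R0"]})])
        a = classify_subtypes(train_subtype_model(ref, labels), ref)
        b = classify_subtypes(train_subtype_model(dup, dup_labels), ref)
        assert (a == b).all()

    def test_wrong_feature_count_errors(self):
        ref, labels = cluster_reference()
        with pytest.raises(ConfigError, match="exactly 5"):
            train_subtype_model(ref.iloc[:4], labels)

    def test_missing_feature_probe_listed(self):
        ref, labels = cluster_reference()
        model = train_subtype_model(ref, labels)
        with pytest.raises(ConfigError, match="cg4"):
            classify_subtypes(model, ref.iloc[:4])

    def test_training_point_gets_its_label(self):
        ref, labels = cluster_reference()
        model = train_subtype_model(ref, labels)
        one = ref.iloc[:, [0]]
        assert classify_subtypes(model, one).iloc[0] == labels.iloc[0]

    def test_sample_order_invariance(self):
        ref, labels = cluster_reference()
        model = train_subtype_model(ref, labels)
        perm = list(np.random.default_rng(1).permutation(ref.columns))
        a = classify_subtypes(model, ref)
        b = classify_subtypes(model, ref[perm])
        assert (a.loc[perm] == b).all()

    def test_generated_test_points_agree(self):
        ref, labels = cluster_reference(seed=2)
        model = train_subtype_model(ref, labels)
        rng = np.random.default_rng(3)
        cols, truth = [], []
        for label, centre in CENTROIDS.items():
            for i in range(40):
                cols.append(rng.normal(centre, 0.3, 5))
                truth.append(label)
        test = pd.DataFrame(np.column_stack(cols), index=PROBES,
                            columns=[f"T{i}" for i in range(len(cols))])
        calls = classify_subtypes(model, test)
        assert (calls.to_numpy() == np.array(truth)).mean() >= 0.95

    def test_nan_feature_sample_skipped(self):
        ref, labels = cluster_reference()
        model = train_subtype_model(ref, labels)
        test = ref.iloc[:, :3].copy()
        test.iloc[0, 1] = np.nan
        with pytest.warns(UserWarning, match="NaN"):
            calls = classify_subtypes(model, test)
        assert calls.iloc[1] is pd.NA
        assert calls.drop(calls.index[1]).notna().all()

    def test_counts_helper(self):
        ref, labels = cluster_reference()
        model = train_subtype_model(ref, labels)
        counts = subtype_counts(classify_subtypes(model, ref))
        assert counts.to_dict() == {"n-CLL": 12, "i-CLL": 12, "m-CLL": 12}

    def test_model_json_serializes(self):
        ref, labels = cluster_reference()
        model = train_subtype_model(ref, labels)
        blob = model.to_json()
        assert "support_vectors" in blob and '"C": 10' in blob


@pytest.fixture(scope="module")
def subtype_study():
    cfg = SimConfig(n_probes=4000, n_subtype_probes=200, n_random_dmps=100,
                    n_dmeg_up=3, n_dmeg_down=2)
    return simulate_dataset(cfg, seed=9)


class TestSubtypeDMPs:
    def test_injected_effect_recovered(self, subtype_study):
        study = subtype_study
        m = beta_to_m(study.beta.values)
        calls = pd.Series(study.ledger.subtype_labels)
        table = subtype_dmps(m[calls.index], calls, study.sample_design,
                             beta=study.beta.values[calls.index])
        called = set(table.index[table["is_dmp"]])
        truth = set(study.ledger.subtype_probes)
        assert len(called & truth) / len(truth) >= 0.9

    def test_null_yields_nearly_nothing(self):
        study = simulate_dataset(SimConfig(n_probes=2000, n_subtype_probes=0,
                                           n_random_dmps=0, n_dmeg_up=2,
                                           n_dmeg_down=1), seed=10)
        m = beta_to_m(study.beta.values)
        calls = pd.Series(study.ledger.subtype_labels)
        table = subtype_dmps(m[calls.index], calls, study.sample_design,
                             beta=study.beta.values[calls.index])
        assert table["is_dmp"].sum() <= 2

    def test_overlap_fraction_set_arithmetic(self):
        a = pd.DataFrame({"is_dmp": [True, True, True, False]},
                         index=["p1", "p2", "p3", "p4"])
        b = pd.DataFrame({"is_dmp": [True, False, True, True]},
                         index=["p1", "p2", "p3", "p4"])
        assert dmp_overlap_fraction(a, b) == pytest.approx(100.0 * 2 / 3)

    def test_too_few_per_subtype_errors(self, subtype_study):
        study = subtype_study
        m = beta_to_m(study.beta.values)
        calls = pd.Series(study.ledger.subtype_labels).iloc[:4]
        with pytest.raises(ConfigError):
            subtype_dmps(m[calls.index], calls, study.sample_design)


@pytest.fixture(scope="module")
def bcell_study():
    cfg = SimConfig(n_probes=3000, n_bcell_samples=3, n_bcell_probes=120,
                    n_random_dmps=150, n_dmeg_up=3, n_dmeg_down=2,
                    n_subtype_probes=0)
    return simulate_dataset(cfg, seed=12)


class TestBcellDifferentiation:
    def test_identical_groups_empty_union(self):
        cfg = SimConfig(n_probes=2000, n_bcell_samples=3, n_bcell_probes=0,
                        n_random_dmps=0, n_dmeg_up=2, n_dmeg_down=1)
        study = simulate_dataset(cfg, seed=13)
        ids = study.sample_design.index[
            study.sample_design["group"].isin(["mixture", "NBC", "CD5+NBC",
                                               "csMBC", "ncsMBC"])]
        m = beta_to_m(study.beta.values[ids])
        union, petals = bcell_differentiation_dmps(m, study.sample_design,
                                                   beta=study.beta.values[ids])
        assert len(union) == 0

    def test_shifted_probes_land_in_right_petal(self, bcell_study):
        study = bcell_study
        ids = study.sample_design.index[
            study.sample_design["group"].isin(["mixture", "NBC", "CD5+NBC",
                                               "csMBC", "ncsMBC"])]
        m = beta_to_m(study.beta.values[ids])
        union, petals = bcell_differentiation_dmps(m, study.sample_design,
                                                   beta=study.beta.values[ids])
        for probe, per_group in study.ledger.bcell_probes.items():
            (subtype,) = per_group
            if probe in set(union):
                assert probe in set(petals[subtype])
        # union equals inclusion-exclusion over petals
        assert set(union) == set().union(*map(set, petals.values()))
        # most injected probes are recovered
        assert len(set(union) & set(study.ledger.bcell_probes)) \
            >= 0.8 * len(study.ledger.bcell_probes)

    def test_small_subtype_skipped(self, bcell_study):
        study = bcell_study
        design = study.sample_design.copy()
        nbc = design.index[design["group"] == "NBC"]
        design.loc[nbc[1:], "group"] = "parked"
        ids = design.index[design["group"].isin(["mixture", "NBC", "CD5+NBC",
                                                 "csMBC", "ncsMBC"])]
        m = beta_to_m(study.beta.values[ids])
        with pytest.warns(UserWarning, match="NBC"):
            _, petals = bcell_differentiation_dmps(m, design,
                                                   beta=study.beta.values[ids])
        assert "NBC" not in petals

    def test_missing_mixture_errors(self, bcell_study):
        study = bcell_study
        design = study.sample_design.copy()
        design.loc[design["group"] == "mixture", "group"] = "parked"
        ids = design.index[design["group"].isin(["NBC", "CD5+NBC"])]
        with pytest.raises(ConfigError, match="mixture"):
            bcell_differentiation_dmps(beta_to_m(study.beta.values[ids]), design)


class TestSubtractAndRescreen:
    def _setup(self, study):
        cohort = study.sample_design.index[
            study.sample_design["group"].isin(["CLL", "control"])]
        m = beta_to_m(study.beta.values[cohort])
        auto = study.annotation.index[~study.annotation["chrom"].isin(["X", "Y"])]
        return m, auto

    def test_empty_bcell_set_is_identity(self, bcell_study):
        from cllmeth.dmp_stats import fit_dmp

        study = bcell_study
        m, auto = self._setup(study)
        res = subtract_and_rescreen(auto, pd.Index([]), m, study.sample_design,
                                    beta=study.beta.values)
        direct = fit_dmp(m.loc[auto], study.sample_design,
                         beta=study.beta.values.loc[auto])
        pd.testing.assert_frame_equal(res["dmp_table"], direct)

    def test_full_subtraction_empties_calls(self, bcell_study):
        from cllmeth.dmp_stats import fit_dmp

        study = bcell_study
        m, auto = self._setup(study)
        full = fit_dmp(m.loc[auto], study.sample_design, beta=study.beta.values.loc[auto])
        dmp_probes = full.index[full["is_dmp"]]
        res = subtract_and_rescreen(auto, dmp_probes, m, study.sample_design,
                                    beta=study.beta.values)
        assert len(res["cll_specific_probes"]) == 0
        assert res["bcell_overlap_pct"] == pytest.approx(100.0) or np.isnan(
            res["bcell_overlap_pct"])

    def test_disjoint_partition_recovered(self, bcell_study):
        study = bcell_study
        m, auto = self._setup(study)
        bcell = pd.Index(sorted(study.ledger.bcell_probes))
        res = subtract_and_rescreen(auto, bcell, m, study.sample_design,
                                    beta=study.beta.values)
        specific = set(res["cll_specific_probes"])
        truth = {p for p in study.ledger.dmp_probes if p in set(auto)}
        jaccard = len(specific & truth) / len(specific | truth)
        assert jaccard >= 0.95
        assert not specific & set(bcell)

    def test_bcell_overlap_near_zero_when_disjoint(self, bcell_study):
        """CLL effects and B-cell effects injected on disjoint probes."""
        from cllmeth.dmp_stats import fit_dmp

        study = bcell_study
        m, auto = self._setup(study)
        full = fit_dmp(m.loc[auto], study.sample_design, beta=study.beta.values.loc[auto])
        bcell = pd.Index(sorted(study.ledger.bcell_probes))
        res = subtract_and_rescreen(auto, bcell, m, study.sample_design,
                                    dmp_table=full, beta=study.beta.values)
        assert res["bcell_overlap_pct"] < 2.0

    def test_probe_reordering_commutes(self, bcell_study):
        study = bcell_study
        m, auto = self._setup(study)
        bcell = pd.Index(sorted(study.ledger.bcell_probes)[:50])
        rng = np.random.default_rng(4)
        shuffled = pd.Index(rng.permutation(auto))
        a = subtract_and_rescreen(auto, bcell, m, study.sample_design,
                                  beta=study.beta.values)
        b = subtract_and_rescreen(shuffled, bcell, m, study.sample_design,
                                  beta=study.beta.values)
        assert set(a["cll_specific_probes"]) == set(b["cll_specific_probes"])

    def test_empty_residual_errors(self, bcell_study):
        study = bcell_study
        m, auto = self._setup(study)
        with pytest.raises(ConfigError, match="residual"):
            subtract_and_rescreen(auto, auto, m, study.sample_design)
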