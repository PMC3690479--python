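import numpy as np
import pandas as pd
import pytest
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from phosphodyn import kinase_prediction as kp
from phosphodyn import motif, synthetic_data as sd, temporal
from phosphodyn.io_tables import InhibitorScreenRecord, PhosphoSiteRecord
from phosphodyn.temporal import TIMEPOINTS_MIN, TimeCourseProfile


def _features_and_truth(cohort):
    records, gt, _ = cohort
    rng = np.random.default_rng(0)
    gt_idx = gt.set_index("site_id")
    akt_windows = [
        r.sequence_window
        for r in records
        if gt_idx.loc[r.site_id, "true_kinase"] == "Akt"
    ]
    pssms = {"Akt": motif.build_pssm(akt_windows or [sd.sample_window(
        sd.KINASE_MOTIFS["Akt"], "S", rng) for _ in range(20)])}
    features, _ = kp.assemble_features(records, pssms)
    truth = gt.set_index("site_id").reindex(features.index)
    return features, truth


@pytest.fixture(scope="module")
def akt_setup(cohort_2k):
    return _features_and_truth(cohort_2k)


class TestAssembleFeatures:
    def _record(self, profile, ins=1.0, mk=0.5, ly=0.2, window="AAAAAASAAAAAA"):
        return PhosphoSiteRecord(
            site_id="x1",
            protein_id="P",
            position=10,
            residue="S",
            localization_prob=0.9,
            sequence_window=window,
            inhibitor_quant=InhibitorScreenRecord(
                ins_log2=[ins], mk_log2=[mk], ly_log2=[ly]
            ),
            timecourse_quant=TimeCourseProfile(replicate_log2=profile[:, None]),
        )

    def test_manual_assembly_oracle(self, rng):
        profile = 1.5 * sd.template_curve(sd.ARCH_FAST)
        rec = self._record(profile)
        pssm = motif.build_pssm(
            [sd.sample_window(None, "S", rng) for _ in range(20)]
        )
        features, excluded = kp.assemble_features([rec], {"Akt": pssm})
        assert excluded == {
            "no_timecourse": 0, "sparse_timecourse": 0, "no_inhibitor": 0
        }
        row = features.loc["x1"]
        scaled, _ = temporal.scale_profile(profile)
        np.testing.assert_allclose(row[kp.SCALED_FEATURES].to_numpy(), scaled)
        assert row["auc"] == pytest.approx(temporal.compute_auc(scaled))
        np.testing.assert_allclose(
            row[["poly_quad", "poly_lin", "poly_const"]].to_numpy(),
            temporal.fit_poly2(scaled),
        )
        assert row["mean_log2"] == pytest.approx(profile.mean())
        assert row["ins_log2"] == 1.0 and row["mk_log2"] == 0.5
        assert row["pssm_Akt"] == pytest.approx(
            motif.score_window(pssm, rec.sequence_window)
        )

    def test_flat_profile_degenerate_convention(self, rng):
        rec = self._record(np.zeros(9))
        pssm = motif.build_pssm([sd.sample_window(None, "S", rng) for _ in range(20)])
        features, _ = kp.assemble_features([rec], {"Akt": pssm})
        row = features.loc["x1"]
        np.testing.assert_allclose(row[kp.SCALED_FEATURES].to_numpy(), 0.5)
        assert row["auc"] == pytest.approx(0.5)

    def test_sites_missing_data_excluded_with_count(self, rng):
        pssm = motif.build_pssm([sd.sample_window(None, "S", rng) for _ in range(20)])
        good = self._record(1.5 * sd.template_curve(sd.ARCH_FAST))
        no_tc = self._record(np.zeros(9))
        no_tc.site_id = "x2"
        no_tc.timecourse_quant = None
        sparse = self._record(np.r_[[1.0, 2.0], np.full(7, np.nan)])
        sparse.site_id = "x3"
        features, excluded = kp.assemble_features(
            [good, no_tc, sparse], {"Akt": pssm}
        )
        assert list(features.index) == ["x1"]
        assert excluded["no_timecourse"] == 1
        assert excluded["sparse_timecourse"] == 1

    def test_row_order_follows_input(self, akt_setup):
        features, _ = akt_setup
        assert features.index.is_unique


class TestDeltaScores:
    def test_arithmetic_oracle(self):
        scores = pd.DataFrame(
            {"Akt": [0.9], "mTORC1": [0.2], "PKA": [0.1]}, index=["s"]
        )
        deltas = kp.delta_scores(scores)
        np.testing.assert_allclose(
            deltas.loc["s"].to_numpy(), [0.7, -0.7, -0.8], atol=1e-12
        )

    def test_equal_scores_zero_delta(self):
        scores = pd.DataFrame({"A": [0.4, 0.2], "B": [0.4, 0.2]})
        assert (kp.delta_scores(scores).to_numpy() == 0).all()

    def test_two_kinases_antisymmetric(self, rng):
        scores = pd.DataFrame({"A": rng.random(20), "B": rng.random(20)})
        d = kp.delta_scores(scores)
        np.testing.assert_allclose(d["A"].to_numpy(), -d["B"].to_numpy())

    def test_single_kinase_raises(self):
        with pytest.raises(ValueError):
            kp.delta_scores(pd.DataFrame({"A": [0.1]}))


def _brute_force_fronts(points):
    """O(n^2) non-dominated sorting oracle (maximize both coordinates)."""
    remaining = set(range(len(points)))
    fronts = np.zeros(len(points), dtype=int)
    level = 0
    while remaining:
        level += 1
        front = set()
        for i in remaining:
            dominated = any(
                j != i
                and points[j][0] >= points[i][0]
                and points[j][1] >= points[i][1]
                and (points[j][0] > points[i][0] or points[j][1] > points[i][1])
                for j in remaining
            )
            if not dominated:
                front.add(i)
        for i in front:
            fronts[i] = level
        remaining -= front
    return fronts


class TestParetoRank:
    def test_dominated_point_on_second_front(self):
        df = kp.pareto_rank([1.0, 0.0], [1.0, 0.0], ["a", "b"])
        assert df.set_index("site_id")["pareto_front"].to_dict() == {"a": 1, "b": 2}

    def test_antichain_shares_front_one(self):
        df = kp.pareto_rank([0.9, 0.1], [0.1, 0.9], ["a", "b"])
        assert (df["pareto_front"] == 1).all()

    def test_matches_brute_force_on_random_points(self, rng):
        # coarse grid values force ties and duplicates
        scores = rng.integers(0, 10, size=200) / 10.0
        deltas = rng.integers(-5, 6, size=200) / 10.0
        ids = [f"s{i:03d}" for i in range(200)]
        df = kp.pareto_rank(scores, deltas, ids).set_index("site_id")
        oracle = _brute_force_fronts(list(zip(scores, deltas)))
        got = df.loc[ids, "pareto_front"].to_numpy()
        np.testing.assert_array_equal(got, oracle)

    def test_front_one_contains_max_score(self, rng):
        scores, deltas = rng.random(100), rng.random(100)
        ids = [f"s{i}" for i in range(100)]
        df = kp.pareto_rank(scores, deltas, ids)
        best = ids[int(np.argmax(scores))]
        assert df.set_index("site_id").loc[best, "pareto_front"] == 1

    def test_ranks_ordered_by_front_then_score(self, rng):
        scores, deltas = rng.random(50), rng.random(50)
        df = kp.pareto_rank(scores, deltas, [f"s{i}" for i in range(50)])
        assert (df["rank"].to_numpy() == np.arange(1, 51)).all()
        assert df["pareto_front"].is_monotonic_increasing

    def test_non_finite_points_raise(self):
        with pytest.raises(ValueError):
            kp.pareto_rank([np.nan], [0.0], ["a"])


class TestTrainEnsemble:
    def test_single_member_equals_direct_fit(self, akt_setup):
        features, truth = akt_setup
        pos = truth.index[truth["true_kinase"] == "Akt"].tolist()
        cfg = kp.SVMConfig(n_members=1)
        clf = kp.train_ensemble("Akt", pos, features, config=cfg, seed=5)
        # replicate the member's negative draw and fit directly
        pool = np.asarray([i for i in features.index if i not in set(pos)])
        rng = np.random.default_rng(5)
        neg = rng.choice(pool, size=int(round(5.0 * len(pos))), replace=False)
        x = np.vstack([features.loc[pos].to_numpy(), features.loc[neg].to_numpy()])
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        direct = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="auto"))
        direct.fit(x, y)
        np.testing.assert_allclose(
            kp.ensemble_decision_values(clf, features),
            direct.decision_function(features.to_numpy()),
            rtol=1e-10,
        )

    def test_deterministic_for_fixed_seed(self, akt_setup):
        features, truth = akt_setup
        pos = truth.index[truth["true_kinase"] == "Akt"].tolist()
        cfg = kp.SVMConfig(n_members=3)
        s1 = kp.predict_scores(
            kp.train_ensemble("Akt", pos, features, cfg, seed=2), features
        )
        s2 = kp.predict_scores(
            kp.train_ensemble("Akt", pos, features, cfg, seed=2), features
        )
        pd.testing.assert_series_equal(s1, s2)

    def test_planted_substrates_outscore_background(self, akt_setup):
        from scipy.stats import mannwhitneyu

        features, truth = akt_setup
        pos = truth.index[truth["true_kinase"] == "Akt"].tolist()
        clf = kp.train_ensemble(
            "Akt", pos, features, kp.SVMConfig(n_members=5), seed=3
        )
        scores = kp.predict_scores(clf, features)
        bg = scores[truth["true_kinase"] == "none"]
        res = mannwhitneyu(scores[pos], bg, alternative="greater")
        assert res.pvalue < 0.01

    def test_missing_positives_raise_with_ids(self, akt_setup):
        features, truth = akt_setup
        pos = truth.index[truth["true_kinase"] == "Akt"].tolist()
        with pytest.raises(ValueError, match="ghost"):
            kp.train_ensemble("Akt", pos + ["ghost"], features)

    def test_feature_layout_mismatch_raises(self, akt_setup):
        features, truth = akt_setup
        pos = truth.index[truth["true_kinase"] == "Akt"].tolist()
        clf = kp.train_ensemble(
            "Akt", pos, features, kp.SVMConfig(n_members=1), seed=1
        )
        with pytest.raises(ValueError, match="layout"):
            kp.ensemble_decision_values(clf, features.iloc[:, ::-1])


class TestNegativePool:
    def test_excludes_positives_and_neighbors(self, cohort_2k):
        records = cohort_2k[0]
        positive_ids = {records[0].site_id}
        prot, pos = records[0].protein_id, records[0].position
        pool = set(kp.select_negative_pool(records, positive_ids))
        assert records[0].site_id not in pool
        for r in records:
            if r.protein_id == prot and abs(r.position - pos) <= 13:
                assert r.site_id not in pool


class TestScoreNormalization:
    def test_minmax_law(self, rng):
        v = rng.normal(size=50)
        norm = kp.minmax_normalize(v)
        assert norm[np.argmax(v)] == 1.0 and norm[np.argmin(v)] == 0.0
        assert (norm >= 0).all() and (norm <= 1).all()

    def test_single_site_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = kp.minmax_normalize(np.array([3.7]))
        assert out[0] == 0.5


class TestTopRankedKinetics:
    def test_top50_akt_predictions_are_rapidly_phosphorylated(self, cohort_2k):
        """Top-ranked Akt candidates share the fast kinetics of known
        substrates: the mean scaled profile is near plateau by 1 min."""
        records, gt, _ = cohort_2k
        gt_idx = gt.set_index("site_id")
        by_id = {r.site_id: r for r in records}
        pssms, positives = {}, {}
        for kin in ("Akt", "PKA"):
            ids = gt_idx.index[gt_idx["true_kinase"] == kin].tolist()
            pssms[kin] = motif.build_pssm([by_id[i].sequence_window for i in ids])
            positives[kin] = ids
        features, _ = kp.assemble_features(records, pssms)
        cfg = kp.SVMConfig(n_members=5)
        scores = pd.DataFrame(
            {
                kin: kp.predict_scores(
                    kp.train_ensemble(
                        kin,
                        [i for i in positives[kin] if i in features.index],
                        features,
                        cfg,
                        seed=21,
                    ),
                    features,
                )
                for kin in pssms
            }
        )
        ranked = kp.rank_predictions(scores)
        top = ranked[ranked["kinase"] == "Akt"].nsmallest(50, "rank")["site_id"]
        profiles = []
        for s in top:
            med = by_id[s].timecourse_quant.log2_ratios
            scaled, _ = temporal.scale_profile(med)
            profiles.append(scaled)
        mean_profile = np.mean(profiles, axis=0)
        at_1min = mean_profile[TIMEPOINTS_MIN == 1.0][0]
        assert at_1min >= 0.9 * mean_profile.max()


class TestEvaluateCv:
    def test_perfectly_separable_metrics(self):
        rng = np.random.default_rng(1)
        n_pos, n_neg = 30, 320
        y = np.r_[np.ones(n_pos), np.zeros(n_neg)]
        x = rng.normal(size=(len(y), 3))
        x[:, 0] += 8 * y  # fully separated
        features = pd.DataFrame(
            x, index=[f"s{i}" for i in range(len(y))], columns=list("abc")
        )
        res = kp.evaluate_cv(
            features, pd.Series(y, index=features.index),
            folds=3, seed=0, config=kp.SVMConfig(n_members=3),
        )
        assert res["sensitivity"] == 1.0
        assert res["specificity"] == 1.0
        assert res["auroc"] == 1.0

    def test_too_few_positives_raise(self):
        features = pd.DataFrame(np.zeros((20, 2)), index=[f"s{i}" for i in range(20)])
        labels = pd.Series([1] * 4 + [0] * 16, index=features.index)
        with pytest.raises(ValueError):
            kp.evaluate_cv(features, labels, folds=5)
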