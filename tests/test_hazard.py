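"""Hazard panel construction, transforms, and partial-likelihood fitting."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_corpus, ts
from edtribes.hazard import (
    HazardFitError,
    build_hazard_panel,
    feature_columns,
    fit_hazard_model,
    transform_features,
)
from edtribes.labels import ClassLabel
from edtribes.synth import simulate_hazard_panel

PA, PR = ClassLabel.PRO_ANA, ClassLabel.PRO_RECOVERY


def _panel_fixture():
    """Five users, hand-checkable photo/comment schedule."""
    photos = [
        {"photo_id": "p1", "owner_id": "a", "day": 0, "tags": ["bones"], "view_count": 10},
        {"photo_id": "p2", "owner_id": "a", "day": 25, "tags": ["cat"], "view_count": 4},
        {"photo_id": "p3", "owner_id": "a", "day": 41, "tags": ["bones"], "view_count": 6},
        {"photo_id": "p4", "owner_id": "b", "day": 5, "tags": ["cat"], "view_count": 2},
        {"photo_id": "p5", "owner_id": "c", "day": 15, "tags": ["bones"], "view_count": 8},
    ]
    comments = [
        {"photo_id": "p1", "commenter_id": "b", "day": 3},   # other-class for a
        {"photo_id": "p1", "commenter_id": "c", "day": 12},  # same-class for a
        {"photo_id": "p4", "commenter_id": "a", "day": 35},  # other-class for b
        {"photo_id": "p5", "commenter_id": "n", "day": 16},  # neutral: not counted
    ]
    corpus = build_corpus(
        users=["a", "b", "c", "n"],
        photos=photos,
        comments=comments,
        observation_end=ts(60),
    )
    labels = {"a": PA, "b": PR, "c": PA, "n": ClassLabel.NEUTRAL}
    flags = pd.Series(
        corpus.photos["tags"].map(lambda t: "bones" in t).to_numpy(),
        index=corpus.photos["photo_id"],
    )
    return corpus, labels, flags


class TestPanel:
    def test_events_and_covariates_hand_checked(self):
        corpus, labels, flags = _panel_fixture()
        panel = build_hazard_panel(corpus, labels, flags)
        a = panel[panel["user_id"] == "a"].set_index("interval")
        # grid anchored at day 0; user a active from interval 0 to 6
        assert list(a.index) == [0, 1, 2, 3, 4, 5, 6]
        assert a.loc[0, "event"] and a.loc[4, "event"]  # relevant photos day 0, 41
        assert not a.loc[2, "event"]
        # strictly-before semantics: interval 1 sees day-0 photo and day-3 comment
        assert a.loc[1, "cum_relevant_photos"] == 1
        assert a.loc[1, "cum_views"] == 10
        assert a.loc[1, "cum_comments_other"] == 1
        assert a.loc[1, "cum_comments_same"] == 0
        # the day-12 same-class comment appears from interval 2 on
        assert a.loc[2, "cum_comments_same"] == 1
        assert a.loc[2, "cum_frac_comments_same"] == pytest.approx(0.5)
        # recent window (30 days = 3 intervals): day-0 photo gone by interval 4
        assert a.loc[4, "recent_relevant_photos"] == 0
        assert a.loc[4, "recent_views"] == 4  # only the day-25 photo
        # user with no comments received: fraction defined as 0
        c = panel[panel["user_id"] == "c"].set_index("interval")
        assert (c["cum_frac_comments_same"] == 0).all()

    def test_matches_windowed_recount_oracle(self):
        corpus, labels, flags = _panel_fixture()
        panel = build_hazard_panel(corpus, labels, flags)
        photos = corpus.photos
        comments = corpus.comments
        owner = photos.set_index("photo_id")["owner_id"]
        anchor = photos["posted_at"].min()
        for row in panel.itertuples():
            start = row.interval_start
            mine = photos[photos["owner_id"] == row.user_id]
            before = mine[mine["posted_at"] < start]
            rel_before = before[before["photo_id"].map(flags)]
            assert row.cum_relevant_photos == len(rel_before)
            assert row.cum_views == before["view_count"].sum()
            assert row.cum_views_relevant == rel_before["view_count"].sum()
            win_lo = start - pd.Timedelta(days=30)
            recent = mine[(mine["posted_at"] >= win_lo) & (mine["posted_at"] < start)]
            assert row.recent_views == recent["view_count"].sum()
            received = comments[comments["photo_id"].map(owner) == row.user_id]
            received = received[received["commented_at"] < start]
            same = sum(
                labels.get(c) is labels[row.user_id] for c in received["commenter_id"]
            )
            comm = sum(labels.get(c) in (PA, PR) for c in received["commenter_id"])
            assert row.cum_comments_same == same
            assert row.cum_comments_other == comm - same

    def test_cumulative_covariates_monotone(self, small_synthetic, small_labels):
        corpus, truth = small_synthetic
        flags = pd.Series(
            corpus.photos["photo_id"].isin(truth.relevant_photos).to_numpy(),
            index=corpus.photos["photo_id"],
        )
        panel = build_hazard_panel(corpus, small_labels, flags)
        for col in feature_columns("cumulative")[:5]:
            diffs = panel.groupby("user_id")[col].diff().dropna()
            assert (diffs >= -1e-9).all(), col

    def test_user_without_photos_has_no_rows(self):
        corpus, labels, flags = _panel_fixture()
        panel = build_hazard_panel(corpus, labels, flags)
        assert "n" not in set(panel["user_id"])


class TestTransform:
    def test_zscore_and_log1p_conventions(self):
        panel = simulate_hazard_panel(50, 20, [0.0] * 6, seed=1, feature_set="recent")
        out, record = transform_features(panel, "recent")
        for col in record.columns:
            assert out[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert out[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert np.log1p(0) == 0.0

    def test_constant_covariate_dropped_and_recorded(self):
        panel = simulate_hazard_panel(30, 10, [0.0] * 6, seed=2, feature_set="recent")
        panel["recent_views"] = 7.0
        out, record = transform_features(panel, "recent")
        assert "recent_views" in record.dropped
        assert "recent_views" not in out.columns


class TestFit:
    def test_breslow_matches_independent_reference(self):
        """Coefficients frozen from R survival::coxph(ties="breslow") on the
        identical panel (counting-process Surv(start, stop, event), log1p
        covariates, no standardisation)."""
        panel = simulate_hazard_panel(
            60, 30, [0.3, -0.2, 0, 0, 0, 0], seed=7, feature_set="recent"
        )
        fit = fit_hazard_model(panel, "pro_ana", feature_set="recent", standardize=False)
        reference = np.array(
            [0.466276, -0.251861, -0.056269, -0.130154, 0.403032, 0.543316]
        )
        assert np.allclose(fit.params.to_numpy(), reference, atol=5e-6)
        assert fit.converged

    def test_duplicating_rows_preserves_breslow_estimates(self):
        panel = simulate_hazard_panel(40, 20, [0.2, 0, 0, 0, 0, 0], seed=3, feature_set="recent")
        fit1 = fit_hazard_model(panel, "pro_ana", feature_set="recent", standardize=False)
        doubled = pd.concat([panel, panel], ignore_index=True)
        fit2 = fit_hazard_model(doubled, "pro_ana", feature_set="recent", standardize=False)
        assert np.allclose(fit1.params.to_numpy(), fit2.params.to_numpy(), atol=1e-6)

    def test_efron_available_and_close_to_breslow(self):
        panel = simulate_hazard_panel(60, 25, [0.3, 0, 0, 0, 0, 0], seed=9, feature_set="recent")
        fb = fit_hazard_model(panel, "pro_ana", feature_set="recent", standardize=False)
        fe = fit_hazard_model(
            panel, "pro_ana", feature_set="recent", standardize=False, ties_method="efron"
        )
        diff = np.abs(fb.params.to_numpy() - fe.params.to_numpy())
        assert diff.max() < 0.15  # heavy ties: close but not identical
        assert diff.max() > 0  # genuinely different tie handling

    def test_null_covariates_within_two_se(self):
        hits = 0
        for seed in range(10):
            panel = simulate_hazard_panel(400, 40, [0.0] * 6, seed=seed, feature_set="recent")
            fit = fit_hazard_model(panel, "pro_ana", feature_set="recent", standardize=False)
            within = np.abs(fit.params.to_numpy()) < 2 * fit.standard_errors.to_numpy()
            hits += within.sum()
        assert hits / (10 * 6) >= 0.9

    def test_no_events_rejected(self):
        panel = simulate_hazard_panel(10, 5, [0.0] * 6, seed=4, feature_set="recent")
        panel["event"] = False
        with pytest.raises(HazardFitError):
            fit_hazard_model(panel, "pro_ana", feature_set="recent")

    def test_summary_table_shape(self):
        panel = simulate_hazard_panel(50, 20, [0.0] * 6, seed=5, feature_set="recent")
        fit = fit_hazard_model(panel, "pro_ana", feature_set="recent")
        table = fit.summary()
        assert list(table.columns) == ["coef", "exp(coef)", "se(coef)", "z", "p"]
        assert len(table) == len(fit.transform.columns)
        assert fit.n_events == int(panel["event"].sum())
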