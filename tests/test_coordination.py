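"""Leave-one-trial-out strengths, cross-region coupling, and the
median-split mixed-effects model."""

import numpy as np
import pandas as pd
import pytest

from navrsa.coordination import (RandomInterceptLMM, cross_trial_correlation,
                                 lagged_correlation, lead_lag_summary,
                                 loto_strength, median_split,
                                 median_split_lme)
from navrsa.rsa import SimilarityTensor, WindowScheme, contrast, pairwise_similarity


def _sim_from_pairs(z_pairs, labels, n_windows=1):
    n = len(labels)
    pi, pj = np.triu_indices(n, k=1)
    z = np.array([[z_pairs[(i, j)]] * n_windows for i, j in zip(pi, pj)],
                 dtype=float)
    epochs = pd.DataFrame({"session": [1] * n, "environment": labels,
                           "object": labels, "trial_id": np.arange(n),
                           "is_good": [True] * n})
    return SimilarityTensor(z=z, pair_i=pi, pair_j=pj,
                            session=np.ones(len(pi), dtype=int),
                            epochs=epochs, scheme=WindowScheme())


class TestLotoStrength:
    def test_toy_example(self):
        z_pairs = {(0, 1): 0.6, (0, 2): 0.1, (0, 3): 0.2,
                   (1, 2): 0.3, (1, 3): 0.1, (2, 3): 0.5}
        sim = _sim_from_pairs(z_pairs, ["A", "A", "B", "B"])
        s = loto_strength(sim, "context")
        assert np.allclose(s.values[:, 0], [0.45, 0.40, 0.30, 0.35])

    def test_perfect_separation(self):
        z_pairs = {(i, j): 1.0 if (i < 2) == (j < 2) else 0.0
                   for i in range(4) for j in range(i + 1, 4)}
        sim = _sim_from_pairs(z_pairs, ["A", "A", "B", "B"])
        assert np.allclose(loto_strength(sim, "context").values, 1.0)

    def test_uniform_z_gives_zero_strength(self):
        z_pairs = {(i, j): 0.7 for i in range(4) for j in range(i + 1, 4)}
        sim = _sim_from_pairs(z_pairs, ["A", "A", "B", "B"])
        assert np.allclose(loto_strength(sim, "context").values, 0.0, atol=1e-12)

    def test_trial_without_partner_flagged(self):
        z_pairs = {(0, 1): 0.5, (0, 2): 0.2, (1, 2): 0.1}
        sim = _sim_from_pairs(z_pairs, ["A", "B", "B"])
        s = loto_strength(sim, "context")
        assert np.isnan(s.values[0, 0])  # the lone A trial has no same-label pair
        assert np.isfinite(s.values[1:, 0]).all()

    def test_mean_strength_equals_contrast_difference(self):
        """With balanced labels the trial-average LOTO strength equals the
        Same-Different contrast (algebraic identity)."""
        rng = np.random.default_rng(0)
        z_power = rng.normal(size=(8, 2, 3, 40))
        scheme = WindowScheme(width_ms=40, step_ms=20, epoch_s=0.08, rate=500.0)
        epochs = pd.DataFrame({"session": [1] * 4 + [2] * 4,
                               "environment": list("aabb") * 2,
                               "object": list("xyxy") * 2,
                               "trial_id": np.arange(8),
                               "is_good": [True] * 8})
        sim = pairwise_similarity(z_power, epochs, scheme)
        s = loto_strength(sim, "context")
        c = contrast(sim, "context")
        # average within session, then across sessions, matching the contrast
        sess = epochs["session"].to_numpy()
        per_sess = [s.values[sess == k].mean(axis=0) for k in (1, 2)]
        assert np.allclose(np.mean(per_sess, axis=0), c.difference, atol=1e-12)


def _strength(values, trial_ids=None, good=None):
    from navrsa.coordination import StrengthMatrix
    n = values.shape[0]
    epochs = pd.DataFrame({
        "trial_id": trial_ids if trial_ids is not None else np.arange(n),
        "is_good": good if good is not None else [True] * n,
        "session": [1] * n,
    })
    return StrengthMatrix(values=values, kind="context", epochs=epochs)


class TestCrossTrialCorrelation:
    def test_identical_strengths_give_clipped_unity(self):
        v = np.random.default_rng(0).normal(size=(12, 5))
        z = cross_trial_correlation(_strength(v), _strength(v.copy()))
        assert np.allclose(z, np.arctanh(1 - 1e-10), rtol=1e-6)

    def test_independent_strengths_near_zero(self):
        rng = np.random.default_rng(1)
        zs = [cross_trial_correlation(_strength(rng.normal(size=(40, 3))),
                                      _strength(rng.normal(size=(40, 3))))
              for _ in range(30)]
        assert abs(np.mean(zs)) < 0.08

    def test_too_few_trials_skipped(self):
        v = np.zeros((2, 3))
        with pytest.warns(UserWarning):
            assert cross_trial_correlation(_strength(v), _strength(v)) is None

    def test_good_trial_restriction(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(10, 2))
        good = [True] * 5 + [False] * 5
        a = _strength(v, good=good)
        b = _strength(np.vstack([v[:5], rng.normal(size=(5, 2))]), good=good)
        z = cross_trial_correlation(a, b, good_only=True)
        assert np.allclose(z, np.arctanh(1 - 1e-10), rtol=1e-6)


class TestLaggedCorrelation:
    def test_identical_series_peak_on_diagonal(self):
        v = np.random.default_rng(3).normal(size=(30, 8))
        m = lagged_correlation(_strength(v), _strength(v.copy()))
        assert np.all(np.diag(m) >= m.max(axis=1) - 1e-9)

    def test_shift_recovered(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(40, 12))
        shifted = np.roll(base, 4, axis=1)  # EC repeats HC 4 windows later
        m = lagged_correlation(_strength(base), _strength(shifted))
        i, j = np.unravel_index(np.argmax(m), m.shape)
        assert j - i == 4  # HC leads EC by 4 windows

    def test_white_noise_lead_lag_balanced(self):
        rng = np.random.default_rng(5)
        mats = [lagged_correlation(_strength(rng.normal(size=(30, 8))),
                                   _strength(rng.normal(size=(30, 8))))
                for _ in range(12)]
        res = lead_lag_summary(mats)
        assert abs(res["t"]) < 4.0


class TestMedianSplit:
    def test_strict_median_ties_go_low(self):
        df = pd.DataFrame({"subject_id": ["s"] * 5,
                           "x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        high = median_split(df, "x")
        assert high.tolist() == [False, False, False, True, True]

    def test_group_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"subject_id": np.repeat(list("abc"), 21),
                           "x": rng.normal(size=63)})
        df["high"] = median_split(df, "x")
        for _, g in df.groupby("subject_id"):
            assert abs(g["high"].sum() - (~g["high"]).sum()) <= 1


def _lme_data(n_sub=12, n_trial=80, delta=3.0, noise=2.0, tau=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        off = rng.normal(0, tau)
        sc = rng.normal(size=n_trial)
        so = rng.normal(size=n_trial)
        hi_c = sc > np.median(sc)
        hi_o = so > np.median(so)
        y = 8.0 + off - delta * (hi_c & hi_o) + rng.normal(0, noise, n_trial)
        for t in range(n_trial):
            rows.append(dict(subject_id=f"s{s}", strength_context=sc[t],
                             strength_object=so[t], drop_error=y[t]))
    return pd.DataFrame(rows)


class TestLme:
    def test_constant_response_gives_zero_f(self):
        df = _lme_data(n_sub=6, n_trial=20, delta=0.0, noise=0.0, tau=0.0)
        df["drop_error"] = 5.0
        res = median_split_lme(df)
        assert res["interaction"]["F"] == pytest.approx(0.0, abs=1e-6)

    def test_zero_random_variance_matches_ols(self):
        df = _lme_data(n_sub=8, n_trial=40, delta=2.0, noise=1.0, tau=0.0,
                       seed=3)
        res = median_split_lme(df)
        # direct least squares on the same design
        x1 = median_split(df, "strength_context").astype(float) - 0.5
        x2 = median_split(df, "strength_object").astype(float) - 0.5
        X = np.column_stack([np.ones(len(df)), x1, x2, x1 * x2])
        beta = np.linalg.lstsq(X, df["drop_error"].to_numpy(), rcond=None)[0]
        assert np.allclose(res["beta"], beta, atol=0.02)

    def test_interaction_recovery(self):
        res = median_split_lme(_lme_data(delta=3.0, seed=1))
        assert res["interaction"]["p"] < 0.05
        assert res["simple_object_within_high_context"]["estimate"] < 0

    def test_matches_lmertest_via_r(self, tmp_path):
        """Satterthwaite dfs and F statistics agree with lmerTest."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        df = _lme_data(n_sub=10, n_trial=30, delta=2.0, seed=7)
        df = df.assign(
            x1=median_split(df, "strength_context").astype(int),
            x2=median_split(df, "strength_object").astype(int))
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "m.R"
        script.write_text(f"""
suppressMessages(library(lmerTest))
d <- read.csv("{csv}")
d$x1 <- d$x1 - 0.5; d$x2 <- d$x2 - 0.5
m <- lmer(drop_error ~ 1 + x1*x2 + (1|subject_id), data=d)
a <- anova(m, type=3)
write.csv(data.frame(eff=rownames(a), F=a[,"F value"], df=a[,"DenDF"]),
          "{tmp_path}/out.csv", row.names=FALSE)
""")
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        r = pd.read_csv(tmp_path / "out.csv").set_index("eff")
        ours = median_split_lme(df)
        for eff, key in [("x1", "context"), ("x2", "object"),
                         ("x1:x2", "interaction")]:
            assert ours[key]["F"] == pytest.approx(r.loc[eff, "F"], rel=1e-2)
            assert ours[key]["df"] == pytest.approx(r.loc[eff, "df"], rel=0.05)


class TestRandomInterceptLMM:
    def test_recovers_variance_components(self):
        rng = np.random.default_rng(9)
        n_sub, n_per = 30, 40
        groups = np.repeat(np.arange(n_sub), n_per)
        b = rng.normal(0, 2.0, n_sub)
        X = np.column_stack([np.ones(n_sub * n_per),
                             rng.normal(size=n_sub * n_per)])
        y = X @ [1.0, 0.5] + b[groups] + rng.normal(0, 1.0, len(groups))
        fit = RandomInterceptLMM(y, X, groups).fit()
        assert np.sqrt(fit.tau2) == pytest.approx(2.0, rel=0.3)
        assert np.sqrt(fit.sigma2) == pytest.approx(1.0, rel=0.1)
        assert fit.beta[1] == pytest.approx(0.5, abs=0.05)
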