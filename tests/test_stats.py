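"""Group-level aggregation and inference."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulselock.montage import ELECTRODE_CLUSTERS, ElectrodeClusters
from pulselock.stats import (
    bootstrap_ci,
    cluster_means,
    fit_level_group_model,
    grand_average,
    holm_correct,
    ks_two_sample,
)
from pulselock.stats import _fallback_contrasts


def long_table(rows):
    return pd.DataFrame(
        rows, columns=["participant", "group", "recording", "channel", "level", "plv"]
    )


class TestGrandAverage:
    def test_constant_table_returns_the_constant(self):
        rows = [("p1", "YA", r, c, "pulse", 0.42) for r in "ab" for c in ("O1", "O2")]
        ga = grand_average(long_table(rows))
        assert ga["plv"].iloc[0] == pytest.approx(0.42)

    def test_two_recordings_average(self):
        rows = [("p1", "YA", "a", c, "pulse", 0.2) for c in ("O1", "O2")]
        rows += [("p1", "YA", "b", c, "pulse", 0.4) for c in ("O1", "O2")]
        assert grand_average(long_table(rows))["plv"].iloc[0] == pytest.approx(0.3)

    def test_missing_channel_mean_over_present_cells(self):
        rows = [("p1", "YA", "a", "O1", "pulse", 0.2),
                ("p1", "YA", "a", "O2", "pulse", 0.4),
                ("p1", "YA", "b", "O1", "pulse", 0.6)]
        ga = grand_average(long_table(rows))
        assert ga["plv"].iloc[0] == pytest.approx((0.2 + 0.4 + 0.6) / 3)
        assert ga["n_cells"].iloc[0] == 3

    def test_order_invariance(self, rng):
        rows = [("p1", "YA", f"r{r}", f"c{c}", "pulse", rng.random())
                for r in range(3) for c in range(4)]
        a = grand_average(long_table(rows))
        b = grand_average(long_table(rows[::-1]))
        assert a["plv"].iloc[0] == pytest.approx(b["plv"].iloc[0])


class TestClusters:
    def test_table_structure(self):
        assert len(ELECTRODE_CLUSTERS) == 9
        chans = [c for v in ELECTRODE_CLUSTERS.values() for c in v]
        assert len(chans) == 54 and len(set(chans)) == 54
        assert ELECTRODE_CLUSTERS["O"] == ("PO3", "POz", "PO4", "O1", "Oz", "O2")
        assert ELECTRODE_CLUSTERS["MC"] == ("FC1", "FCz", "FC2", "C1", "Cz", "C2")

    def test_duplicate_assignment_rejected(self):
        with pytest.raises(ValueError, match="two clusters"):
            ElectrodeClusters({"A": ("O1",), "B": ("O1",)})

    def test_indicator_pattern(self):
        rows = [("p1", "YA", "a", c, "pulse", 1.0 if c in ELECTRODE_CLUSTERS["O"] else 0.0)
                for v in ELECTRODE_CLUSTERS.values() for c in v]
        cm = cluster_means(long_table(rows))
        assert cm.loc[cm.cluster == "O", "plv"].iloc[0] == 1.0
        assert np.allclose(cm.loc[cm.cluster != "O", "plv"], 0.0)

    def test_matches_brute_force_mean(self, rng):
        vals = {c: rng.random() for v in ELECTRODE_CLUSTERS.values() for c in v}
        rows = [("p1", "YA", "a", c, "pulse", v) for c, v in vals.items()]
        cm = cluster_means(long_table(rows))
        for name, chans in ELECTRODE_CLUSTERS.items():
            expect = np.mean([vals[c] for c in chans])
            assert cm.loc[cm.cluster == name, "plv"].iloc[0] == pytest.approx(expect)


class TestBootstrap:
    def test_constant_sample_zero_width(self):
        lo, hi = bootstrap_ci(np.full(10, 0.3), n_boot=500, seed=0)
        assert lo == pytest.approx(0.3) and hi == pytest.approx(0.3)

    def test_width_scales_with_spread(self, rng):
        x = rng.standard_normal(40)
        w1 = np.diff(bootstrap_ci(x, 2000, seed=1))[0]
        w2 = np.diff(bootstrap_ci(3 * x, 2000, seed=1))[0]
        assert w2 == pytest.approx(3 * w1, rel=0.05)

    def test_coverage_near_nominal(self, rng):
        hits = 0
        sims = 300
        for _ in range(sims):
            x = rng.normal(1.0, 1.0, 50)
            lo, hi = bootstrap_ci(x, 500, seed=int(rng.integers(2**31)))
            hits += lo <= 1.0 <= hi
        assert 0.90 <= hits / sims <= 0.99

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([1.0]))


class TestKS:
    def test_identical_samples(self):
        d, _ = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, p = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_ecdf_supremum(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, rng.integers(3, 20)).astype(float)
        b = rng.integers(0, 10, rng.integers(3, 20)).astype(float)
        d, _ = ks_two_sample(a, b)
        grid = np.concatenate([a, b])
        brute = max(abs((a <= x).mean() - (b <= x).mean()) for x in grid)
        assert d == pytest.approx(brute, abs=1e-12)

    def test_small_example(self):
        a, b = [1, 2, 3], [1, 2, 3, 4]
        d, _ = ks_two_sample(a, b)
        brute = max(abs(np.mean(np.array(a) <= x) - np.mean(np.array(b) <= x))
                    for x in [1, 2, 3, 4])
        assert d == pytest.approx(brute)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestHolm:
    def test_hand_worked_case(self):
        assert np.allclose(holm_correct([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_correct([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert np.allclose(holm_correct([1.0, 1.0, 1.0]), 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_properties_and_statsmodels_agreement(self, ps):
        from statsmodels.stats.multitest import multipletests

        adj = holm_correct(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)
        _, sm_adj, _, _ = multipletests(ps, method="holm")
        assert np.allclose(adj, sm_adj, atol=1e-12)

    def test_familywise_error_control_under_global_null(self, rng):
        alpha, reps, m = 0.05, 1000, 5
        p = rng.uniform(size=(reps, m))
        rejected_any = 0
        for row in p:
            rejected_any += np.any(holm_correct(row) < alpha)
        assert rejected_any / reps <= 0.06

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_correct([0.5, 1.5])


def simulated_grand_table(rng, n_ya=16, n_oa=15, level_mu=(0.10, 0.07), group_shift=0.0):
    rows = []
    for g, n in (("YA", n_ya), ("OA", n_oa)):
        for p in range(n):
            b = rng.normal(0, 0.012)
            gs = group_shift if g == "OA" else 0.0
            for lv, mu in zip(("pulse", "off_pulse"), level_mu):
                rows.append(dict(participant=f"{g}{p}", group=g, level=lv,
                                 plv=mu + b + gs + rng.normal(0, 0.008)))
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_level_effect_recovered_group_null(self, rng):
        res = fit_level_group_model(simulated_grand_table(rng))
        assert res.effect("level")["p"] < 1e-4
        assert res.effect("group")["p"] > 0.05
        assert res.effect("level:group")["p"] > 0.05

    def test_group_shift_detected(self, rng):
        res = fit_level_group_model(simulated_grand_table(rng, group_shift=0.05))
        assert res.effect("group")["p"] < 0.01

    def test_matches_r_lmer_satterthwaite(self, rng, tmp_path):
        """Independent oracle: lme4/lmerTest type-III F tests on the same
        table agree with the delegated fit."""
        df = simulated_grand_table(rng)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rcode = f"""
suppressMessages({{library(lme4); library(lmerTest)}})
d <- read.csv("{csv}")
d$level <- factor(d$level); d$group <- factor(d$group)
contrasts(d$level) <- contr.sum; contrasts(d$group) <- contr.sum
m <- lmer(plv ~ level*group + (1|participant), data=d)
a <- anova(m, type=3)
cat(sprintf("%.6f %.6f %.6f\\n", a$"F value"[1], a$"F value"[2], a$"F value"[3]))
"""
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True,
                             timeout=120)
        assert out.returncode == 0, out.stderr
        f_lmer = dict(zip(("level", "group", "level:group"),
                          map(float, out.stdout.split())))
        res = fit_level_group_model(df)
        assert res.method == "mixed"
        for eff, f_r in f_lmer.items():
            assert res.effect(eff)["F"] == pytest.approx(f_r, rel=0.02)

    def test_three_way_interaction_recovered(self, rng):
        rows = []
        for g, n in (("YA", 8), ("OA", 8)):
            for p in range(n):
                b = rng.normal(0, 0.01)
                for cl in ELECTRODE_CLUSTERS:
                    for lv, mu in (("pulse", 0.10), ("off_pulse", 0.07)):
                        boost = 0.04 if (g == "YA" and cl == "O" and lv == "pulse") else 0.0
                        rows.append(dict(participant=f"{g}{p}", group=g, cluster=cl,
                                         level=lv, plv=mu + b + boost + rng.normal(0, 0.008)))
        res = fit_level_group_model(pd.DataFrame(rows))
        assert res.effect("cluster:group:level")["p_holm"] < 0.01

    def test_fallback_contrasts_match_paired_tests(self, rng):
        from scipy import stats as sps

        df = simulated_grand_table(rng, n_ya=6, n_oa=6)
        tab = _fallback_contrasts(df)
        wide = df.pivot_table(index=["participant", "group"], columns="level",
                              values="plv").reset_index()
        d = wide["off_pulse"] - wide["pulse"]
        t, p = sps.ttest_1samp(d, 0.0)
        lv = tab[tab.effect == "level"].iloc[0]
        assert lv["F"] == pytest.approx(t**2)
        assert lv["p"] == pytest.approx(p)
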