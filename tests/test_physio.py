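"""Physiology statistics: C:N, Brown-Forsythe, ANOVA + LSD, t-test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orthostress import (
    PipelineConfig,
    anova_lsd,
    brown_forsythe,
    cn_ratio,
    load_reference_physiology,
    run_physio_stats,
    unpaired_t,
)


class TestCNRatio:
    @pytest.mark.parametrize(
        "species,treatment,expected",
        [
            ("A_monilatum", "replete", 4.5),
            ("A_monilatum", "lowN", 7.1),
            ("G_oceanica", "replete", 9.6),
        ],
    )
    def test_reference_means_reproduce_printed_ratios(
        self, species, treatment, expected
    ):
        ref = load_reference_physiology()
        sel = ref[(ref.species == species) & (ref.treatment == treatment)]
        poc = float(sel[sel.variable == "POC"]["mean"].iloc[0])
        pon = float(sel[sel.variable == "PON"]["mean"].iloc[0])
        assert round(cn_ratio(poc, pon), 1) == expected

    def test_equal_pools_give_unit_ratio(self):
        assert cn_ratio(10.0, 10.0) == 1.0

    def test_nonpositive_pon_rejected(self):
        with pytest.raises(ValueError):
            cn_ratio(10.0, 0.0)


class TestBrownForsythe:
    def test_identical_groups(self):
        w, p = brown_forsythe([np.array([1.0, 2.0, 3.0])] * 2)
        assert (w, p) == (0.0, 1.0)

    def test_matches_hand_computed_deviation_anova(self):
        """Groups (1,2,3) vs (1,2,30): ANOVA on |x - median| by hand."""
        g1 = np.array([1.0, 2.0, 3.0])
        g2 = np.array([1.0, 2.0, 30.0])
        z1 = np.abs(g1 - 2.0)  # (1, 0, 1)
        z2 = np.abs(g2 - 2.0)  # (1, 0, 28)
        zbar = np.concatenate([z1, z2]).mean()
        num = 3 * (z1.mean() - zbar) ** 2 + 3 * (z2.mean() - zbar) ** 2
        den = ((z1 - z1.mean()) ** 2).sum() + ((z2 - z2.mean()) ** 2).sum()
        w_hand = (4.0 / 1.0) * num / den
        w, p = brown_forsythe([g1, g2])
        assert w == pytest.approx(w_hand)
        assert p == pytest.approx(stats.f.sf(w_hand, 1, 4))

    def test_location_invariance(self):
        g1 = np.array([1.0, 4.0, 2.0])
        g2 = np.array([0.0, 9.0, 5.0])
        w0, _ = brown_forsythe([g1, g2])
        w1, _ = brown_forsythe([g1 + 100.0, g2 + 100.0])
        assert w0 == pytest.approx(w1)

    def test_scale_invariance_of_p(self):
        g1 = np.array([1.0, 4.0, 2.0])
        g2 = np.array([0.0, 9.0, 5.0])
        _, p0 = brown_forsythe([g1, g2])
        _, p1 = brown_forsythe([g1 * 1e3, g2 * 1e3])
        assert p0 == pytest.approx(p1)


class TestAnovaLSD:
    def _groups(self, rep, lowN, lowP):
        return {
            "replete": np.asarray(rep, dtype=float),
            "lowN": np.asarray(lowN, dtype=float),
            "lowP": np.asarray(lowP, dtype=float),
        }

    def test_identical_groups_are_null(self):
        g = self._groups([1, 2, 3], [1, 2, 3], [1, 2, 3])
        f, p, contrasts = anova_lsd(g)
        assert (f, p) == (0.0, 1.0)
        assert not contrasts["significant"].any()

    def test_matches_sum_of_squares_oracle(self):
        """Groups (1,2,3),(1,2,3),(7,8,9): SSB=72, SSW=6, F=36."""
        g = self._groups([1, 2, 3], [1, 2, 3], [7, 8, 9])
        f, p, _ = anova_lsd(g)
        assert f == pytest.approx(36.0)
        assert p == pytest.approx(stats.f.sf(36.0, 2, 6))

    def test_lsd_equals_pooled_t_with_mse_df(self):
        rng = np.random.default_rng(1)
        g = self._groups(rng.normal(0, 1, 4), rng.normal(1, 1, 4), rng.normal(0, 1, 4))
        _, _, contrasts = anova_lsd(g)
        arrays = [g["replete"], g["lowN"], g["lowP"]]
        sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
        mse = sse / (12 - 3)
        t_hand = (g["lowN"].mean() - g["replete"].mean()) / np.sqrt(mse * (2 / 4))
        p_hand = 2 * stats.t.sf(abs(t_hand), 9)
        rec = contrasts[contrasts.contrast == "lowN-replete"].iloc[0]
        assert rec.t == pytest.approx(t_hand)
        assert rec.p == pytest.approx(p_hand)

    def test_unit_rescaling_leaves_f_unchanged(self):
        rng = np.random.default_rng(2)
        g = self._groups(rng.normal(5, 1, 3), rng.normal(6, 1, 3), rng.normal(5, 1, 3))
        f0, _, _ = anova_lsd(g)
        g2 = {k: v * 1e-6 for k, v in g.items()}
        f1, _, _ = anova_lsd(g2)
        assert f0 == pytest.approx(f1)

    def test_detection_power_for_three_sd_shift(self):
        """A 3-SD shifted treatment is flagged >= 95% of the time (n=4)."""
        rng = np.random.default_rng(42)
        hits = 0
        reps = 500
        for _ in range(reps):
            g = self._groups(
                rng.normal(0, 1, 4), rng.normal(3, 1, 4), rng.normal(0, 1, 4)
            )
            _, _, contrasts = anova_lsd(g)
            hits += bool(
                contrasts[contrasts.contrast == "lowN-replete"]["significant"].iloc[0]
            )
        assert hits / reps >= 0.95

    def test_degenerate_zero_variance_rejected(self):
        g = self._groups([1, 1], [2, 2], [3, 3])
        with pytest.raises(ValueError):
            anova_lsd(g)


class TestUnpairedT:
    def test_identical_samples(self):
        assert unpaired_t([1.0, 2.0], [1.0, 2.0])[0] == pytest.approx(0.0)

    def test_matches_pooled_variance_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 5.0, 6.0])
        t, p = unpaired_t(a, b)
        sp2 = (((a - 2) ** 2).sum() + ((b - 5) ** 2).sum()) / 4
        t_hand = (2.0 - 5.0) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), 4))

    def test_antisymmetric_in_sample_order(self):
        a = np.array([1.0, 2.0, 4.0])
        b = np.array([3.0, 5.0, 6.0])
        assert unpaired_t(a, b)[0] == pytest.approx(-unpaired_t(b, a)[0])

    def test_constant_equal_samples_convention(self):
        assert unpaired_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)


class TestRunPhysioStats:
    def _table(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for t, shift in (("replete", 0.0), ("lowN", 5.0), ("lowP", 0.0)):
            for r, v in enumerate(rng.normal(10 + shift, 1, 3), start=1):
                rows.append(("spA", t, r, "POC", v))
                rows.append(("spA", t, r, "PON", v / 2 + rng.normal(0, 0.01)))
        for t in ("replete", "lowP"):
            for r, v in enumerate(
                rng.normal(1.0 if t == "replete" else 5.0, 0.1, 3), start=1
            ):
                rows.append(("spA", t, r, "APA", v))
        return pd.DataFrame(
            rows, columns=["species", "treatment", "replicate", "variable", "value"]
        )

    def test_full_stats_table(self):
        out = run_physio_stats(self._table(), PipelineConfig())
        tests_run = set(out["test"])
        assert {"brown_forsythe", "anova", "lsd", "unpaired_t"} <= tests_run
        # the shifted POC lowN contrast must be flagged
        rec = out[
            (out.variable == "POC") & (out.test == "lsd") & (out.contrast == "lowN-replete")
        ].iloc[0]
        assert bool(rec.significant)
        # APA handled by the t-test only
        apa = out[out.variable == "APA"]
        assert set(apa["test"]) == {"unpaired_t"}
        assert bool(apa.iloc[0].significant)

    def test_cn_derived_per_replicate(self):
        out = run_physio_stats(self._table(), PipelineConfig())
        assert "CN" in set(out["variable"])

    def test_all_p_values_in_unit_interval(self):
        out = run_physio_stats(self._table(), PipelineConfig())
        assert ((out["p"] > 0) & (out["p"] <= 1)).all()
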