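"""TPM, tri-treatment normalization, and exact KS gene-set tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orthostress import (
    AnnotationTable,
    CountTable,
    PipelineConfig,
    compute_tpm,
    gene_set_enrichment,
    ks_statistic,
    ks_two_sample_exact,
    normalize_enrichment,
)


def _count_table(counts: dict, species="spA"):
    df = pd.DataFrame(counts)
    df.index = pd.Index([f"c{i}" for i in range(len(df))], name="contig_id")
    return CountTable(species_id=species, counts=df)


def _annotation(n, lengths=None, modules=None):
    lengths = lengths if lengths is not None else [500] * n
    modules = modules if modules is not None else [""] * n
    df = pd.DataFrame(
        {
            "length_bp": lengths,
            "kegg_ko": ["K00001" if m else "" for m in modules],
            "kegg_module": modules,
            "function_label": [""] * n,
        },
        index=pd.Index([f"c{i}" for i in range(n)], name="contig_id"),
    )
    return AnnotationTable(df)


class TestTPM:
    def test_single_contig_gets_the_whole_million(self):
        ct = _count_table({"replete": [7], "lowN": [3], "lowP": [1]})
        tpm = compute_tpm(ct, _annotation(1))
        assert np.allclose(tpm.to_numpy(), 1e6)

    def test_length_normalization_arithmetic(self):
        ct = _count_table({"replete": [10, 20], "lowN": [10, 20], "lowP": [10, 20]})
        tpm = compute_tpm(ct, _annotation(2, lengths=[200, 800]))
        assert tpm["replete"].to_numpy() == pytest.approx(
            [666666.67, 333333.33], abs=0.01
        )

    def test_columns_sum_to_a_million(self, small_bundle):
        tables, annotations, _, _ = small_bundle
        sp = "dia1"
        tpm = compute_tpm(tables[sp], annotations[sp])
        assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-3)

    def test_all_zero_column_rejected(self):
        ct = _count_table({"replete": [1], "lowN": [0], "lowP": [1]})
        with pytest.raises(ValueError, match="all-zero"):
            compute_tpm(ct, _annotation(1))


class TestNormalizeEnrichment:
    def test_forced_arithmetic(self):
        tpm = pd.DataFrame(
            {"replete": [10.0], "lowN": [20.0], "lowP": [30.0]},
            index=["c0"],
        )
        e = normalize_enrichment(tpm)
        assert e.loc["c0"].tolist() == [0.5, 1.0, 1.5]

    def test_mean_over_treatments_is_one(self, small_bundle):
        tables, annotations, _, _ = small_bundle
        e = normalize_enrichment(compute_tpm(tables["hap1"], annotations["hap1"]))
        assert np.allclose(e.mean(axis=1), 1.0)

    def test_all_zero_contig_dropped(self):
        tpm = pd.DataFrame(
            {"replete": [1.0, 0.0], "lowN": [2.0, 0.0], "lowP": [3.0, 0.0]},
            index=["c0", "c1"],
        )
        e = normalize_enrichment(tpm)
        assert e.index.tolist() == ["c0"]


class TestKSExact:
    def test_identical_samples(self):
        d, p = ks_two_sample_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == 1.0

    def test_fully_separated_pairs_enumerated(self):
        """a=(1,2) vs b=(3,4): D=1 and exact p = 2/6 by enumeration."""
        d, p = ks_two_sample_exact([1.0, 2.0], [3.0, 4.0])
        assert d == 1.0
        assert p == pytest.approx(1.0 / 3.0)

    def test_enumeration_matches_monte_carlo(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.8, 1, 6)
        _, p_enum = ks_two_sample_exact(a, b, enum_limit=20_000)
        _, p_mc = ks_two_sample_exact(a, b, seed=2, enum_limit=1, n_permutations=10_000)
        assert p_mc == pytest.approx(p_enum, abs=0.02)

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.integers(0, 5, 12).astype(float)  # heavy ties
            b = rng.integers(0, 5, 9).astype(float)
            assert ks_statistic(a, b) == pytest.approx(
                stats.ks_2samp(a, b).statistic
            )

    def test_statistic_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        a = rng.gamma(2, 1, 15)
        b = rng.gamma(3, 1, 10)
        base = ks_statistic(a, b)
        for f in (np.log, np.sqrt, lambda v: v**3, lambda v: 5 * v - 2):
            assert ks_statistic(f(a), f(b)) == pytest.approx(base)

    def test_tied_data_matches_bruteforce_sup(self):
        a = np.array([1.0, 1.0, 2.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 2.0, 4.0])
        sup = 0.0
        for z in np.concatenate([a, b]):
            sup = max(sup, abs((a <= z).mean() - (b <= z).mean()))
        assert ks_statistic(a, b) == pytest.approx(sup)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample_exact([], [1.0])

    def test_permutation_p_reproducible_under_seed(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.3, 1, 30)
        _, p1 = ks_two_sample_exact(a, b, seed=9)
        _, p2 = ks_two_sample_exact(a, b, seed=9)
        assert p1 == p2


class TestGeneSetEnrichment:
    def _e_table(self, e_rep, e_trt, n):
        # build an e-like table with prescribed lowN values; lowP mirrors
        # replete so only the lowN contrast is interesting
        idx = pd.Index([f"c{i}" for i in range(n)], name="contig_id")
        return pd.DataFrame(
            {"replete": e_rep, "lowN": e_trt, "lowP": e_rep}, index=idx
        )

    def test_identical_distributions_are_not_called(self):
        n = 10
        e = self._e_table(np.ones(n), np.ones(n), n)
        ann = _annotation(n, modules=["M1"] * n)
        out = gene_set_enrichment(e, ann, "spA", PipelineConfig(), seed=0)
        lowN = out[out["treatment"] == "lowN"].iloc[0]
        assert lowN.D == 0.0
        assert lowN.direction == "none"

    def test_coordinated_shift_detected_as_enriched(self):
        n = 20
        rng = np.random.default_rng(0)
        rep = rng.uniform(0.4, 0.6, n)
        e = self._e_table(rep, rep * 4, n)
        ann = _annotation(n, modules=["M1"] * n)
        out = gene_set_enrichment(e, ann, "spA", PipelineConfig(), seed=0)
        lowN = out[out["treatment"] == "lowN"].iloc[0]
        assert lowN.p_exact <= 0.05
        assert lowN.direction == "enriched"
        assert not lowN.bidirectional_warning

    def test_bidirectional_set_triggers_warning(self):
        n = 20
        rep = np.ones(n)
        trt = np.concatenate([np.full(n // 2, 4.0), np.full(n // 2, 0.25)])
        e = self._e_table(rep, trt, n)
        ann = _annotation(n, modules=["M1"] * n)
        out = gene_set_enrichment(e, ann, "spA", PipelineConfig(), seed=0)
        lowN = out[out["treatment"] == "lowN"].iloc[0]
        assert bool(lowN.bidirectional_warning)

    def test_small_sets_skipped(self):
        n = 4
        e = self._e_table(np.ones(n), np.ones(n) * 4, n)
        ann = _annotation(n, modules=["M1"] * n)
        out = gene_set_enrichment(e, ann, "spA", PipelineConfig(), seed=0)
        assert out.empty

    def test_asymptotic_p_reported_alongside_exact(self):
        n = 12
        rng = np.random.default_rng(2)
        rep = rng.uniform(0.5, 1.5, n)
        e = self._e_table(rep, rep * 2, n)
        ann = _annotation(n, modules=["M1"] * n)
        out = gene_set_enrichment(e, ann, "spA", PipelineConfig(), seed=0)
        assert {"p_exact", "p_asymptotic"} <= set(out.columns)
        assert ((out["p_asymptotic"] > 0) & (out["p_asymptotic"] <= 1)).all()
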