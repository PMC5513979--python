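"""Gene-set enrichment by Kolmogorov-Smirnov tests on tri-treatment
normalized expression.

Per-contig TPM is computed per treatment, then each contig's TPM is
divided by its mean across the three treatments, so every contig
contributes on an equal footing regardless of its baseline abundance
(the mean of the normalized enrichment ``e`` over treatments is 1).  For
each gene set (KEGG module or pathway) the distribution of ``e`` in a
stress treatment is compared with the replete distribution by a
two-sample KS test whose p-value is exact: full enumeration of pooled
relabelings when feasible, otherwise seeded Monte-Carlo permutations.
The KS statistic is direction-blind, so a significant set is annotated
as enriched or depleted from the medians of the two samples, and sets
with strong opposing contig-level movements carry a bidirectionality
warning (such sets can defeat the test even with large per-contig
changes).
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .types import CountTable, AnnotationTable, TREATMENTS, STRESS_TREATMENTS

logger = logging.getLogger(__name__)


def compute_tpm(count_table: CountTable, annotation: AnnotationTable) -> pd.DataFrame:
    """Transcripts-per-million per contig and treatment.

    TPM_i = 1e6 * (c_i / L_i) / sum_j (c_j / L_j), per treatment column.
    """
    counts = count_table.counts
    lengths = annotation.lengths(counts.index).to_numpy(dtype=float)
    rate = counts.to_numpy(dtype=float) / lengths[:, None]
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = [t for t, z in zip(counts.columns, zero) if z]
        raise ValueError(f"{count_table.species_id}: all-zero treatment column(s) {bad}")
    tpm = 1e6 * rate / totals[None, :]
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def normalize_enrichment(tpm: pd.DataFrame) -> pd.DataFrame:
    """Divide each contig's TPM by its mean across the three treatments.

    Contigs with zero mean (no reads anywhere) are dropped; the count of
    dropped contigs is logged.
    """
    mean = tpm.mean(axis=1)
    keep = mean > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("normalize_enrichment: dropped %d all-zero contig(s)", n_dropped)
    return tpm.loc[keep].div(mean[keep], axis=0)


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """sup |ECDF_a - ECDF_b|, evaluated at the pooled observed points."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def _perm_statistics(
    pooled_sorted: np.ndarray, labels: np.ndarray, n: int, m: int
) -> np.ndarray:
    """KS statistics for a batch of label permutations.

    ``labels`` is (reps, n+m) boolean (True = sample a) aligned with the
    sorted pooled values; ties are handled by only taking the sup at the
    last index of each tied run.
    """
    csum = np.cumsum(labels, axis=1)
    ranks = np.arange(1, n + m + 1)
    diff = np.abs(csum / n - (ranks - csum) / m)
    valid = np.ones(n + m, dtype=bool)
    valid[:-1] = pooled_sorted[:-1] != pooled_sorted[1:]
    return diff[:, valid].max(axis=1)


def ks_two_sample_exact(
    a: np.ndarray,
    b: np.ndarray,
    seed: int | np.random.Generator = 0,
    enum_limit: int = 20_000,
    n_permutations: int = 10_000,
) -> tuple[float, float]:
    """Two-sample KS statistic with an exact/permutation p-value.

    When the number of pooled relabelings C(n+m, n) is at most
    ``enum_limit`` the p-value is exact by full enumeration
    (p = #{D* >= D} / C(n+m, n)); otherwise it is estimated from
    ``n_permutations`` seeded Monte-Carlo relabelings with the add-one
    estimator p = (1 + #{D* >= D}) / (1 + reps).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    d_obs = ks_statistic(a, b)
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    pooled_sorted = pooled[order]
    eps = 1e-12
    if comb(n + m, n) <= enum_limit:
        count = 0
        total = comb(n + m, n)
        idx = np.arange(n + m)
        for chosen in combinations(range(n + m), n):
            labels = np.zeros(n + m, dtype=bool)
            labels[list(chosen)] = True
            d = _perm_statistics(
                pooled_sorted, labels[order][None, :], n, m
            )[0]
            if d >= d_obs - eps:
                count += 1
        return d_obs, count / total
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    base = np.zeros(n + m, dtype=bool)
    base[:n] = True
    labels = np.tile(base, (n_permutations, 1))
    labels = rng.permuted(labels, axis=1)
    d_perm = _perm_statistics(pooled_sorted, labels, n, m)
    count = int((d_perm >= d_obs - eps).sum())
    return d_obs, (1 + count) / (1 + n_permutations)


def gene_set_enrichment(
    e_table: pd.DataFrame,
    annotation: AnnotationTable,
    species_id: str,
    config: PipelineConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """KS enrichment of every gene set, per stress treatment.

    Gene sets are contigs sharing a non-empty label in the configured
    annotation column (KEGG module by default, pathway-style groupings
    through the same interface); only sets with at least
    ``min_gene_set_size`` contigs present in the normalized table are
    tested.  Direction is assigned from the sample medians when the
    exact p <= alpha.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sets = annotation.table[config.gene_set_column]
    sets = sets[sets != ""]
    rows = []
    for gene_set, contigs in sets.groupby(sets):
        members = contigs.index.intersection(e_table.index)
        if len(members) < config.min_gene_set_size:
            continue
        sub = e_table.loc[members]
        e_rep = sub["replete"].to_numpy()
        for t in STRESS_TREATMENTS:
            e_t = sub[t].to_numpy()
            d, p_exact = ks_two_sample_exact(
                e_t, e_rep, rng, config.enum_limit, config.n_permutations
            )
            p_asym = float(stats.ks_2samp(e_t, e_rep, method="asymp").pvalue)
            med_t = float(np.median(e_t))
            med_r = float(np.median(e_rep))
            if p_exact <= config.alpha and med_t > med_r:
                direction = "enriched"
            elif p_exact <= config.alpha and med_t < med_r:
                direction = "depleted"
            else:
                direction = "none"
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(e_rep > 0, e_t / np.where(e_rep > 0, e_rep, 1.0), np.inf)
                ratio = np.where((e_rep == 0) & (e_t == 0), 1.0, ratio)
            frac_up = float(np.mean(ratio >= 2.0))
            frac_down = float(np.mean(ratio <= 0.5))
            bidirectional = bool(min(frac_up, frac_down) >= 0.25)
            rows.append(
                (
                    species_id,
                    gene_set,
                    t,
                    len(members),
                    d,
                    p_exact,
                    p_asym,
                    med_t,
                    med_r,
                    direction,
                    bidirectional,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "gene_set",
            "treatment",
            "n_contigs",
            "D",
            "p_exact",
            "p_asymptotic",
            "median_enrichment_treatment",
            "median_enrichment_replete",
            "direction",
            "bidirectional_warning",
        ],
    )
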