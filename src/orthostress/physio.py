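"""Statistics on replicate physiology measurements.

For every (species, variable) with all three treatment groups the block
runs a Brown-Forsythe homogeneity-of-variance check, a one-way ANOVA,
and Fisher's LSD contrasts of each stress treatment against the replete
reference (unadjusted pooled-variance t-tests on the ANOVA error df).
Alkaline phosphatase activity, measured only under replete and low P, is
compared with an unpaired pooled-variance t-test.  Molar C:N is derived
per replicate from POC and PON and tested like any other variable.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .types import TREATMENTS, STRESS_TREATMENTS


def cn_ratio(poc: float, pon: float) -> float:
    """Molar carbon-to-nitrogen ratio from per-cell POC and PON (pmol/cell)."""
    if pon <= 0:
        raise ValueError("PON must be positive to form a C:N ratio")
    return poc / pon


def brown_forsythe(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Levene-type test on absolute deviations from group medians.

    Returns (W, p).  When every group has zero spread the statistic is 0
    and p = 1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(g) == 0 for g in groups):
        return 0.0, 1.0
    w, p = stats.levene(*groups, center="median")
    return float(w), float(p)


def anova_lsd(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA followed by Fisher's LSD contrasts vs replete.

    ``groups`` maps the three treatment labels to replicate arrays.
    Returns (F, p, contrasts) where contrasts has one row per stress
    treatment with the mean difference, pooled-MSE t statistic on N - k
    df, its unadjusted two-sided p, and a significance flag at alpha.
    """
    if set(groups) != set(TREATMENTS):
        raise ValueError(f"need exactly the groups {TREATMENTS}")
    arrays = {t: np.asarray(groups[t], dtype=float) for t in TREATMENTS}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs >= 2 replicates")
    k = len(arrays)
    n_total = sum(a.size for a in arrays.values())
    df_error = n_total - k
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    mse = sse / df_error
    if mse == 0:
        grand = np.mean(np.concatenate(list(arrays.values())))
        if all(np.isclose(a.mean(), grand) for a in arrays.values()):
            f_stat, p = 0.0, 1.0
        else:
            raise ValueError("zero within-group variance with unequal means")
    else:
        f_stat, p = stats.f_oneway(*arrays.values())
        f_stat, p = float(f_stat), float(p)
    rows = []
    ref = arrays["replete"]
    for t in STRESS_TREATMENTS:
        a = arrays[t]
        diff = a.mean() - ref.mean()
        if mse == 0:
            t_stat, p_c = 0.0, 1.0
        else:
            se = np.sqrt(mse * (1.0 / a.size + 1.0 / ref.size))
            t_stat = diff / se
            p_c = 2.0 * stats.t.sf(abs(t_stat), df_error)
        rows.append(
            (f"{t}-replete", diff, float(t_stat), float(p_c), bool(p_c <= alpha))
        )
    contrasts = pd.DataFrame(
        rows, columns=["contrast", "mean_diff", "t", "p", "significant"]
    )
    return f_stat, p, contrasts


def unpaired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance t-test.

    Returns (t, p); zero pooled variance with equal means gives (0, 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per sample")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t_stat), float(p)


def derive_cn(physio: pd.DataFrame) -> pd.DataFrame:
    """Append per-replicate molar C:N rows computed from POC and PON."""
    wide = physio[physio["variable"].isin(["POC", "PON"])]
    if wide.empty:
        return physio
    piv = wide.pivot_table(
        index=["species", "treatment", "replicate"], columns="variable", values="value"
    )
    if not {"POC", "PON"} <= set(piv.columns):
        return physio
    piv = piv.dropna()
    piv = piv[piv["PON"] > 0]
    cn = (piv["POC"] / piv["PON"]).reset_index()
    cn["variable"] = "CN"
    cn = cn.rename(columns={0: "value"})
    return pd.concat([physio, cn[physio.columns.tolist()]], ignore_index=True)


def run_physio_stats(physio: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Full statistics table for a replicate physiology table.

    Output columns: species, variable, test, statistic, p, contrast,
    significant.  APA gets the unpaired t-test (replete vs lowP); every
    other variable with all three treatments gets Brown-Forsythe, ANOVA
    and the two LSD contrasts.
    """
    physio = derive_cn(physio)
    rows = []
    for (sp, var), grp in physio.groupby(["species", "variable"], sort=True):
        by_t = {t: g["value"].to_numpy() for t, g in grp.groupby("treatment")}
        if var == "APA":
            if {"replete", "lowP"} <= set(by_t) and all(
                by_t[t].size >= 2 for t in ("replete", "lowP")
            ):
                t_stat, p = unpaired_t(by_t["lowP"], by_t["replete"])
                rows.append(
                    (sp, var, "unpaired_t", t_stat, p, "lowP-replete", p <= config.alpha)
                )
            continue
        if set(by_t) != set(TREATMENTS) or any(v.size < 2 for v in by_t.values()):
            continue
        w, p_bf = brown_forsythe(list(by_t.values()))
        rows.append((sp, var, "brown_forsythe", w, p_bf, "", p_bf <= config.alpha))
        try:
            f_stat, p_f, contrasts = anova_lsd(by_t, config.alpha)
        except ValueError:
            continue
        rows.append((sp, var, "anova", f_stat, p_f, "", p_f <= config.alpha))
        for rec in contrasts.itertuples(index=False):
            rows.append((sp, var, "lsd", rec.t, rec.p, rec.contrast, rec.significant))
    return pd.DataFrame(
        rows,
        columns=["species", "variable", "test", "statistic", "p", "contrast", "significant"],
    )
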