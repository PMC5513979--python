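"""Empirical-Bayes differential abundance for single-replicate count pairs.

Each unit (contig or ortholog) contributes one treatment count ``x`` and
one replete count ``y`` from libraries of size ``s_x`` and ``s_y``.  With
Poisson sampling in each library, conditioning on the pair total
``n = x + y`` reduces the likelihood to a binomial,

    x | n, delta  ~  Binomial(n, p(delta)),
    p(delta) = s_x * 2**delta / (s_x * 2**delta + s_y),

where ``delta`` is the log2 fold change of the normalized abundance
(treatment over replete).  The prior on ``delta`` is estimated from the
data itself rather than from replicate-based dispersion: a two-component
zero-centered normal mixture

    g(delta) = pi0 * N(0, tau0**2) + (1 - pi0) * N(0, tau1**2)

with a narrow fixed null scale ``tau0 = 0.05`` and (pi0, tau1) chosen to
maximize the marginal likelihood over a small grid.  Posterior summaries
are computed by trapezoid quadrature on a fixed delta grid: the posterior
mean ``delta_hat`` and the posterior probability

    post_p = P(|delta| >= t | x, y)

that the fold change exceeds the calling threshold (t = 1, i.e. 2-fold).
A unit is called differentially abundant when post_p exceeds 0.95 and the
posterior-mean |log2FC| is at least 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import PipelineConfig

logger = logging.getLogger(__name__)

#: Fixed scale of the null mixture component (kept narrow so that the
#: null stays identifiable on the (pi0, tau1) grid).
TAU0 = 0.05

#: Fallback prior used when too few non-zero pairs are available to fit.
DEFAULT_PI0 = 0.9
DEFAULT_TAU1 = 2.0

#: Minimum number of non-zero pairs required to fit the prior.
MIN_FIT_UNITS = 200

#: Search grids for the prior hyperparameters.
PI0_GRID = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2)) + (0.99,)
TAU1_GRID = tuple(np.round(np.arange(0.25, 4.001, 0.25), 2))


class DEError(ValueError):
    pass


def make_grid(lo: float = -10.0, hi: float = 10.0, step: float = 0.01) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.linspace(lo, hi, n)


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    step = grid[1] - grid[0]
    w = np.full(grid.shape, step)
    w[0] = w[-1] = step / 2.0
    return w


def _region_weights(grid: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Trapezoid weights restricted to the grid points where mask holds.

    Endpoints of each contiguous run get half weight, so the result is
    the composite trapezoid rule applied separately to every run.
    """
    step = grid[1] - grid[0]
    w = np.where(mask, step, 0.0)
    m = mask.astype(int)
    starts = np.flatnonzero(np.diff(np.concatenate(([0], m))) == 1)
    ends = np.flatnonzero(np.diff(np.concatenate((m, [0]))) == -1)
    w[starts] *= 0.5
    w[ends] *= 0.5
    return w


@dataclass
class PriorModel:
    """Two-component zero-mean normal mixture prior on log2 fold change."""

    pi0: float
    tau1: float
    tau0: float = TAU0
    grid: np.ndarray = field(default_factory=make_grid)
    fitted: bool = True

    def density(self, delta: np.ndarray) -> np.ndarray:
        d = np.asarray(delta, dtype=float)
        null = np.exp(-0.5 * (d / self.tau0) ** 2) / (
            self.tau0 * np.sqrt(2.0 * np.pi)
        )
        alt = np.exp(-0.5 * (d / self.tau1) ** 2) / (
            self.tau1 * np.sqrt(2.0 * np.pi)
        )
        return self.pi0 * null + (1.0 - self.pi0) * alt

    def grid_integral(self) -> float:
        """Mixture density integrated over the grid (should be ~1)."""
        return float(self.density(self.grid) @ _trapezoid_weights(self.grid))


def _log_binom_matrix(
    x: np.ndarray, n: np.ndarray, s_x: float, s_y: float, grid: np.ndarray
) -> np.ndarray:
    """log Binomial(x | n, p(delta_k)) for every unit x grid point."""
    r = np.log(s_x / s_y) + grid * np.log(2.0)  # logit of p(delta)
    log_p = -np.logaddexp(0.0, -r)
    log_q = -np.logaddexp(0.0, r)
    const = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    return const[:, None] + np.outer(x, log_p) + np.outer(n - x, log_q)


def fit_prior(
    x: np.ndarray,
    y: np.ndarray,
    s_x: float,
    s_y: float,
    grid: np.ndarray | None = None,
) -> PriorModel:
    """Estimate (pi0, tau1) by marginal maximum likelihood on a grid.

    Only pairs with ``x + y > 0`` inform the fit.  With fewer than
    ``MIN_FIT_UNITS`` such pairs a default prior (pi0=0.9, tau1=2) is
    returned with a warning; with no such pairs at all this is an error.
    """
    if grid is None:
        grid = make_grid()
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    n = x + y
    keep = n > 0
    if not keep.any():
        raise DEError("cannot fit prior: all count pairs are zero")
    if keep.sum() < MIN_FIT_UNITS:
        warnings.warn(
            f"only {int(keep.sum())} non-zero pairs (< {MIN_FIT_UNITS}); "
            f"using default prior pi0={DEFAULT_PI0}, tau1={DEFAULT_TAU1}",
            stacklevel=2,
        )
        return PriorModel(DEFAULT_PI0, DEFAULT_TAU1, grid=grid, fitted=False)
    x, n = x[keep], n[keep]

    w = _trapezoid_weights(grid)
    loglik = _log_binom_matrix(x, n, s_x, s_y, grid)
    row_max = loglik.max(axis=1)
    lik = np.exp(loglik - row_max[:, None])  # units x grid, scaled

    # per-component weighted prior columns: null + one per tau1 candidate
    scales = np.array((TAU0,) + TAU1_GRID)
    comps = np.exp(-0.5 * (grid[:, None] / scales[None, :]) ** 2) / (
        scales[None, :] * np.sqrt(2.0 * np.pi)
    )
    integrals = lik @ (comps * w[:, None])  # units x (1 + n_tau1)
    null_int = integrals[:, 0]
    alt_int = integrals[:, 1:]

    best = (-np.inf, DEFAULT_PI0, DEFAULT_TAU1)
    for pi0 in PI0_GRID:
        mix = pi0 * null_int[:, None] + (1.0 - pi0) * alt_int
        with np.errstate(divide="ignore"):
            ll = np.log(mix).sum(axis=0)  # row_max sum is a shared constant
        j = int(np.argmax(ll))
        if ll[j] > best[0]:
            best = (float(ll[j]), float(pi0), float(TAU1_GRID[j]))
    _, pi0_hat, tau1_hat = best
    logger.info("fitted prior: pi0=%.2f tau1=%.2f", pi0_hat, tau1_hat)
    return PriorModel(pi0_hat, tau1_hat, grid=grid)


def posterior_fold_change(
    x: np.ndarray,
    y: np.ndarray,
    s_x: float,
    s_y: float,
    prior: PriorModel,
    fc_threshold_log2: float = 1.0,
) -> pd.DataFrame:
    """Posterior mean log2FC and post_p for a batch of count pairs.

    Returns a frame with columns ``x, y, s_x, s_y, delta_hat, post_p``
    aligned with the inputs.  Pairs with ``x + y == 0`` are untestable
    and carry NaN summaries (callers drop and record them).
    """
    if s_x <= 0 or s_y <= 0:
        raise DEError("library sizes must be positive")
    x = np.atleast_1d(np.asarray(x, dtype=np.int64))
    y = np.atleast_1d(np.asarray(y, dtype=np.int64))
    n = x + y
    grid = prior.grid
    w = _trapezoid_weights(grid)
    # small tolerance so the threshold grid point survives float drift
    mask = np.abs(grid) >= fc_threshold_log2 - 1e-12
    w_tail = _region_weights(grid, mask)
    with np.errstate(divide="ignore"):  # density underflow far in the tails
        log_g = np.log(prior.density(grid))

    delta_hat = np.full(x.shape, np.nan)
    post_p = np.full(x.shape, np.nan)
    testable = n > 0
    idx = np.flatnonzero(testable)
    # chunked to bound the units x grid matrix size
    for start in range(0, idx.size, 2048):
        sel = idx[start : start + 2048]
        lp = _log_binom_matrix(x[sel], n[sel], s_x, s_y, grid) + log_g[None, :]
        lp -= lp.max(axis=1, keepdims=True)
        u = np.exp(lp)
        z = u @ w
        delta_hat[sel] = (u @ (w * grid)) / z
        post_p[sel] = np.clip((u @ w_tail) / z, 0.0, 1.0)

    return pd.DataFrame(
        {
            "x": x,
            "y": y,
            "s_x": float(s_x),
            "s_y": float(s_y),
            "delta_hat": delta_hat,
            "post_p": post_p,
        }
    )


def call_differential(results: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Apply the joint calling rule and set the direction column.

    called <=> post_p > postp_threshold AND |fold-change estimate| >=
    fc_threshold_log2, where the fold-change clause uses the posterior
    mean (default) or the raw normalized count ratio per configuration.
    """
    out = results.copy()
    if config.fc_clause == "raw":
        with np.errstate(divide="ignore"):
            fc = np.log2(
                (out["x"] / out["s_x"]).to_numpy()
            ) - np.log2((out["y"] / out["s_y"]).to_numpy())
    else:
        fc = out["delta_hat"].to_numpy()
    called = (out["post_p"].to_numpy() > config.postp_threshold) & (
        np.abs(fc) >= config.fc_threshold_log2
    )
    called &= np.isfinite(out["post_p"].to_numpy())
    direction = np.where(
        called, np.where(out["delta_hat"].to_numpy() > 0, "up", "down"), "none"
    )
    out["called"] = called
    out["direction"] = direction
    return out


def de_table(
    unit_ids: np.ndarray,
    level: str,
    treatment: str,
    x: np.ndarray,
    y: np.ndarray,
    s_x: float,
    s_y: float,
    prior: PriorModel,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, list[str]]:
    """Full DE table for one species x treatment contrast.

    Returns the table of testable units (columns: unit_id, level,
    treatment, x, y, s_x, s_y, delta_hat, post_p, called, direction) and
    the list of untestable unit ids (x + y == 0).
    """
    res = posterior_fold_change(x, y, s_x, s_y, prior, config.fc_threshold_log2)
    res.insert(0, "unit_id", np.asarray(unit_ids))
    res.insert(1, "level", level)
    res.insert(2, "treatment", treatment)
    untestable = res.loc[res["post_p"].isna(), "unit_id"].tolist()
    res = res.dropna(subset=["post_p"]).reset_index(drop=True)
    res = call_differential(res, config)
    return res, untestable
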