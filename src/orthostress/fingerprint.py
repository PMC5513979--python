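"""KEGG-module metabolic fingerprint and its ordination.

The fingerprint row for one (species, treatment) library is the
proportion of reads on KEGG-annotated contigs falling in each KEGG
module; rows sum to one, making the fingerprint invariant to sequencing
depth.  Ordination is PCA of those proportions (restricted to modules
present in all species) with a 95% confidence ellipse per species
computed from the within-species covariance of the first two component
scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.decomposition import PCA

from .types import CountTable, AnnotationTable, TREATMENTS

logger = logging.getLogger(__name__)


def module_proportions(
    count_table: CountTable, annotation: AnnotationTable
) -> pd.DataFrame:
    """Per-treatment proportion of KEGG-assigned reads in each module.

    Contigs without a KEGG module are excluded from both numerator and
    denominator.  Returns rows indexed by (species, treatment) with one
    column per module; each row sums to 1.
    """
    ann = annotation.table.loc[count_table.counts.index]
    has_module = ann["kegg_module"] != ""
    counts = count_table.counts.loc[has_module]
    modules = ann.loc[has_module, "kegg_module"]
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = [t for t in TREATMENTS if totals[t] == 0]
        raise ValueError(
            f"{count_table.species_id}: no KEGG-annotated reads in treatment(s) {bad}"
        )
    per_module = counts.groupby(modules).sum()
    props = (per_module / totals).T  # treatments x modules
    props.index = pd.MultiIndex.from_product(
        [[count_table.species_id], props.index], names=["species", "treatment"]
    )
    return props


def stack_fingerprint(rows: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-species proportion blocks, filling absent modules with 0."""
    matrix = pd.concat(rows).fillna(0.0)
    return matrix[sorted(matrix.columns)]


def restrict_common_modules(matrix: pd.DataFrame) -> pd.DataFrame:
    """Keep modules observed in every species; re-normalize rows to 1.

    A module counts as observed in a species when its proportion is
    nonzero in at least one treatment of that species.
    """
    species = matrix.index.get_level_values("species").unique()
    keep = []
    for mod in matrix.columns:
        col = matrix[mod]
        present = all(
            (col.xs(sp, level="species") > 0).any() for sp in species
        )
        if present:
            keep.append(mod)
    if not keep:
        raise ValueError("no KEGG module is present in all species")
    reduced = matrix[keep]
    return reduced.div(reduced.sum(axis=1), axis=0)


@dataclass
class Ellipse:
    """95% confidence ellipse of (PC1, PC2) scores for one species."""

    species: str
    center_x: float
    center_y: float
    semi_major: float
    semi_minor: float
    angle_deg: float


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # rows aligned with the input, PC1..PCk + group
    variance_explained: np.ndarray
    loadings: pd.DataFrame  # modules x components
    ellipses: list[Ellipse]

    @property
    def ellipse_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    e.species,
                    e.center_x,
                    e.center_y,
                    e.semi_major,
                    e.semi_minor,
                    e.angle_deg,
                )
                for e in self.ellipses
            ],
            columns=[
                "species",
                "center_x",
                "center_y",
                "semi_major",
                "semi_minor",
                "angle_deg",
            ],
        )


def _confidence_ellipse(scores: np.ndarray, species: str, level: float = 0.95) -> Ellipse:
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    scale = chi2.ppf(level, df=2)
    # eigh returns ascending order; the major axis is the last eigenvector
    major, minor = np.sqrt(vals[1] * scale), np.sqrt(vals[0] * scale)
    angle = float(np.degrees(np.arctan2(vecs[1, 1], vecs[0, 1])))
    return Ellipse(species, float(center[0]), float(center[1]), float(major), float(minor), angle)


def pca_with_ellipses(
    matrix: pd.DataFrame,
    scale_columns: bool = True,
    n_components: int = 5,
    ellipse_level: float = 0.95,
) -> OrdinationResult:
    """PCA of the fingerprint matrix with per-species confidence ellipses.

    Columns are centered and (by default) scaled to unit variance, the
    common behavior of ordination tools applied to closed compositional
    rows.  Species with fewer than 3 rows have their ellipse omitted with
    a warning.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 3 rows and 2 columns")
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scale_columns:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0  # constant modules carry no information
        X = X / sd
    k = min(n_components, matrix.shape[0] - 1, matrix.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    # deterministic sign: force the largest-|loading| entry positive
    for j in range(k):
        i = int(np.argmax(np.abs(pca.components_[j])))
        if pca.components_[j, i] < 0:
            pca.components_[j] *= -1
            scores[:, j] *= -1
    pc_cols = [f"PC{j + 1}" for j in range(k)]
    coords = pd.DataFrame(scores, index=matrix.index, columns=pc_cols)
    coords["group"] = matrix.index.get_level_values("species")
    loadings = pd.DataFrame(pca.components_.T, index=matrix.columns, columns=pc_cols)
    ellipses = []
    for sp, grp in coords.groupby("group", sort=True):
        if len(grp) < 3:
            logger.warning("species %s has <3 rows; ellipse omitted", sp)
            continue
        ellipses.append(
            _confidence_ellipse(grp[["PC1", "PC2"]].to_numpy(), str(sp), ellipse_level)
        )
    return OrdinationResult(
        coordinates=coords,
        variance_explained=pca.explained_variance_ratio_,
        loadings=loadings,
        ellipses=ellipses,
    )
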