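"""End-to-end driver: DE at contig and ortholog level, conservation
screen, KS enrichment, KEGG fingerprint with ordination, physiology
statistics, all written as TSV to an output directory.

Outputs are a pure function of (inputs, config, seed): all randomness
(prior-fit subsampling, Monte-Carlo KS permutations) flows from child
streams of the configured seed in a fixed stage order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.metadata import version, PackageNotFoundError
from pathlib import Path

import numpy as np
import pandas as pd

from . import de
from .config import PipelineConfig, focal_species_for
from .conservation import (
    aggregate_ortholog_counts,
    screen_conserved,
    find_universal,
    partition_sharing,
)
from .enrichment import compute_tpm, normalize_enrichment, gene_set_enrichment
from .fingerprint import (
    module_proportions,
    stack_fingerprint,
    restrict_common_modules,
    pca_with_ellipses,
)
from .io import write_tsv
from .physio import run_physio_stats
from .types import CountTable, AnnotationTable, OrthologMap, STRESS_TREATMENTS

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass
class InputBundle:
    count_tables: dict[str, CountTable]
    annotations: dict[str, AnnotationTable]
    ortholog_map: OrthologMap
    physiology: pd.DataFrame | None = None

    @property
    def species(self) -> list[str]:
        return sorted(self.count_tables)

    @property
    def dino_species(self) -> list[str]:
        return sorted(
            sp for sp, ct in self.count_tables.items() if ct.is_dino
        )


@dataclass
class PipelineResult:
    de_contig: dict[str, pd.DataFrame] = field(default_factory=dict)
    de_ortholog: dict[str, pd.DataFrame] = field(default_factory=dict)
    conserved: pd.DataFrame | None = None
    universal: pd.DataFrame | None = None
    sharing: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    fingerprint: pd.DataFrame | None = None
    pca: pd.DataFrame | None = None
    ellipses: pd.DataFrame | None = None
    physio_stats: pd.DataFrame | None = None


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def run_de_for_species(
    count_table: CountTable,
    level: str,
    config: PipelineConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[str]]:
    """Both stress-vs-replete contrasts for one species at one level.

    The prior is fitted per contrast on (at most) a seeded subsample of
    ``max_prior_fit_units`` count pairs, then posteriors are computed for
    every testable unit.
    """
    counts = count_table.counts
    libsize = count_table.effective_library_size
    grid = de.make_grid(config.grid_lo, config.grid_hi, config.grid_step)
    y = counts["replete"].to_numpy()
    s_y = float(libsize["replete"])
    tables = []
    untestable: list[str] = []
    for t in STRESS_TREATMENTS:
        x = counts[t].to_numpy()
        s_x = float(libsize[t])
        nz = np.flatnonzero(x + y > 0)
        if nz.size > config.max_prior_fit_units:
            sel = rng.choice(nz, config.max_prior_fit_units, replace=False)
        else:
            sel = nz
        prior = de.fit_prior(x[sel], y[sel], s_x, s_y, grid)
        tab, skipped = de.de_table(
            counts.index.to_numpy(), level, t, x, y, s_x, s_y, prior, config
        )
        tables.append(tab)
        untestable.extend(skipped)
    return pd.concat(tables, ignore_index=True), untestable


def run_pipeline(
    config: PipelineConfig, inputs: InputBundle, out_dir: str | Path
) -> PipelineResult:
    config.validate()
    if not inputs.count_tables:
        raise PipelineError("stage 'inputs' failed: no species provided")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    species = inputs.species
    focal = focal_species_for(config, species, inputs.dino_species)
    seed_seq = np.random.SeedSequence(config.seed)
    # fixed spawn order keeps outputs a pure function of (inputs, config)
    child = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("de_contig", "de_ortholog", "enrichment"), seed_seq.spawn(3)
        )
    }

    omap, dropped = inputs.ortholog_map.restrict_to(inputs.count_tables)
    if dropped:
        logger.warning("ortholog map: dropped %d unknown member contig(s)", len(dropped))

    for sp in species:
        ct = inputs.count_tables[sp]
        tab, skipped = _stage("de_contig")(
            run_de_for_species, ct, "contig", config, child["de_contig"]
        )
        logger.info("%s: %d untestable contigs", sp, len(skipped))
        result.de_contig[sp] = tab
        write_tsv(tab, out / f"de_contig_{sp}.tsv")

        agg = _stage("aggregate")(aggregate_ortholog_counts, ct, omap)
        tab_o, skipped_o = _stage("de_ortholog")(
            run_de_for_species, agg, "ortholog", config, child["de_ortholog"]
        )
        result.de_ortholog[sp] = tab_o
        write_tsv(tab_o, out / f"de_ortholog_{sp}.tsv")

    if len(focal) >= config.min_species_conserved:
        conserved = _stage("conserve")(
            screen_conserved, result.de_ortholog, config, focal
        )
        universal = _stage("conserve")(find_universal, conserved, focal)
        result.conserved = conserved
        result.universal = universal
        parts = [t for t in (conserved, universal) if not t.empty]
        combined = (
            pd.concat(parts, ignore_index=True) if parts else conserved
        )
        write_tsv(combined, out / "conserved.tsv")
    if len(species) >= 2:
        sharing = _stage("partition")(partition_sharing, omap, species)
        result.sharing = sharing.per_species.reset_index()
        write_tsv(result.sharing, out / "sharing.tsv")
        write_tsv(sharing.venn_frame, out / "sharing_venn.tsv")

    enrich_tables = []
    for sp in species:
        ann = inputs.annotations[sp]
        tpm = _stage("enrich")(compute_tpm, inputs.count_tables[sp], ann)
        e_tab = _stage("enrich")(normalize_enrichment, tpm)
        enrich_tables.append(
            _stage("enrich")(
                gene_set_enrichment, e_tab, ann, sp, config, child["enrichment"]
            )
        )
    non_empty = [t for t in enrich_tables if not t.empty]
    result.enrichment = (
        pd.concat(non_empty, ignore_index=True) if non_empty else enrich_tables[0]
    )
    write_tsv(result.enrichment, out / "enrichment.tsv")

    blocks = [
        _stage("fingerprint")(
            module_proportions, inputs.count_tables[sp], inputs.annotations[sp]
        )
        for sp in species
    ]
    matrix = stack_fingerprint(blocks)
    if len(species) >= 2:
        matrix = _stage("fingerprint")(restrict_common_modules, matrix)
    long = matrix.stack().rename("proportion").reset_index()
    long.columns = ["species", "treatment", "module", "proportion"]
    result.fingerprint = long
    write_tsv(long, out / "fingerprint.tsv")
    ord_res = _stage("ordination")(
        pca_with_ellipses, matrix, config.scale_columns, config.n_components
    )
    pca_df = ord_res.coordinates.reset_index()
    pca_df.insert(0, "row", pca_df["species"] + ":" + pca_df["treatment"])
    result.pca = pca_df
    write_tsv(pca_df, out / "pca.tsv")
    result.ellipses = ord_res.ellipse_frame
    write_tsv(result.ellipses, out / "pca_ellipses.tsv")

    if inputs.physiology is not None:
        result.physio_stats = _stage("physio")(
            run_physio_stats, inputs.physiology, config
        )
        write_tsv(result.physio_stats, out / "physio_stats.tsv")

    try:
        pkg_version = version("orthostress")
    except PackageNotFoundError:  # running from a source tree
        pkg_version = "unknown"
    (out / "run_log.txt").write_text(
        "orthostress run\n"
        f"version: {pkg_version}\n"
        f"seed: {config.seed}\n"
        f"fc_threshold_log2: {config.fc_threshold_log2}\n"
        f"postp_threshold: {config.postp_threshold}\n"
        f"alpha: {config.alpha}\n"
        f"min_species_conserved: {config.min_species_conserved}\n"
        f"min_gene_set_size: {config.min_gene_set_size}\n"
        f"focal_species: {','.join(focal)}\n"
        f"species: {','.join(species)}\n",
        encoding="utf-8",
    )
    return result
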