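"""Ortholog-level aggregation, the conserved-response screen, and the
core/shared/unique sharing partition.

A *conserved response* is an ortholog called differentially abundant in
the same treatment (lowN or lowP, vs replete) in at least two focal
species; a *universal response* is an ortholog called in both treatments
in every focal species.  Direction classes record whether the called
species all moved up, all down, or in mixed directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .types import CountTable, OrthologMap, TREATMENTS, STRESS_TREATMENTS


def aggregate_ortholog_counts(
    count_table: CountTable, ortholog_map: OrthologMap
) -> CountTable:
    """Sum non-normalized member-contig counts per ortholog.

    One row per ortholog with at least one member contig in this species.
    Library sizes are carried over from the contig-level table, because
    the fraction of reads on unassigned contigs still belongs to the
    library.
    """
    df = ortholog_map.to_frame()
    df = df[df["species_id"] == count_table.species_id]
    if df.empty:
        empty = pd.DataFrame(
            columns=list(TREATMENTS),
            index=pd.Index([], name="ortholog_id"),
            dtype=np.int64,
        )
        return CountTable(
            species_id=count_table.species_id,
            counts=empty,
            library_size=count_table.effective_library_size,
            is_dino=count_table.is_dino,
        )
    known = count_table.counts.index
    df = df[df["contig_id"].isin(known)]
    summed = (
        count_table.counts.loc[df["contig_id"]]
        .set_axis(df["ortholog_id"].to_numpy(), axis=0)
        .groupby(level=0)
        .sum()
    )
    summed.index.name = "ortholog_id"
    return CountTable(
        species_id=count_table.species_id,
        counts=summed.sort_index(),
        library_size=count_table.effective_library_size,
        is_dino=count_table.is_dino,
    )


def _direction_class(directions: Sequence[str]) -> str:
    s = set(directions)
    if s == {"up"}:
        return "up"
    if s == {"down"}:
        return "down"
    return "mixed"


def screen_conserved(
    de_ortholog_by_species: Mapping[str, pd.DataFrame],
    config: PipelineConfig,
    focal_species: Sequence[str],
) -> pd.DataFrame:
    """Find orthologs called in >= min_species_conserved focal species.

    ``de_ortholog_by_species`` maps species id to an ortholog-level DE
    table (both treatments stacked) with columns unit_id, treatment,
    called, direction.  Returns one row per (ortholog, treatment) with
    columns ortholog_id, treatment, n_species, species_directions
    (``sp:dir`` semicolon list), direction_class, universal (False here;
    set by :func:`find_universal`).
    """
    missing = [sp for sp in focal_species if sp not in de_ortholog_by_species]
    if missing:
        raise ValueError(f"no DE results for focal species {missing}")
    calls: dict[str, dict[str, dict[str, str]]] = {
        t: {} for t in STRESS_TREATMENTS
    }  # treatment -> ortholog -> species -> direction
    for sp in focal_species:
        de = de_ortholog_by_species[sp]
        hit = de[de["called"]]
        for rec in hit.itertuples(index=False):
            calls[rec.treatment].setdefault(rec.unit_id, {})[sp] = rec.direction
    rows = []
    for t in STRESS_TREATMENTS:
        for og in sorted(calls[t]):
            by_sp = calls[t][og]
            if len(by_sp) < config.min_species_conserved:
                continue
            ordered = [sp for sp in focal_species if sp in by_sp]
            rows.append(
                (
                    og,
                    t,
                    len(by_sp),
                    ";".join(f"{sp}:{by_sp[sp]}" for sp in ordered),
                    _direction_class([by_sp[sp] for sp in ordered]),
                    False,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "ortholog_id",
            "treatment",
            "n_species",
            "species_directions",
            "direction_class",
            "universal",
        ],
    )


def find_universal(
    conserved: pd.DataFrame, focal_species: Sequence[str]
) -> pd.DataFrame:
    """Orthologs called in both treatments for every focal species.

    Returns rows in the conserved-table schema with ``treatment='both'``
    and ``universal=True``; direction_class is computed over all
    (species, treatment) call directions.
    """
    if conserved.empty:
        return conserved.iloc[0:0].copy()
    n_focal = len(focal_species)
    rows = []
    for og, grp in conserved.groupby("ortholog_id"):
        by_t = {rec.treatment: rec for rec in grp.itertuples(index=False)}
        if set(by_t) != set(STRESS_TREATMENTS):
            continue
        if any(by_t[t].n_species < n_focal for t in STRESS_TREATMENTS):
            continue
        directions = []
        for t in STRESS_TREATMENTS:
            directions.extend(
                pair.split(":")[1] for pair in by_t[t].species_directions.split(";")
            )
        sp_dirs = ";".join(
            f"{t}={by_t[t].species_directions}" for t in STRESS_TREATMENTS
        )
        rows.append(
            (og, "both", n_focal, sp_dirs, _direction_class(directions), True)
        )
    return pd.DataFrame(rows, columns=conserved.columns.tolist())


@dataclass
class SharingPartition:
    """Core/shared/unique ortholog counts per species plus Venn counts."""

    per_species: pd.DataFrame  # index species, columns core/shared/unique/total
    venn: dict[frozenset[str], int]

    @property
    def venn_frame(self) -> pd.DataFrame:
        rows = [
            (";".join(sorted(k)), len(k), v) for k, v in sorted(
                self.venn.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["species_subset", "subset_size", "n_orthologs"])


def partition_sharing(
    ortholog_map: OrthologMap, species_list: Sequence[str]
) -> SharingPartition:
    """Partition orthologs into core / shared / unique per species.

    Core: present in every listed species; unique: present in exactly
    one; shared: a proper subset of size >= 2.  Orthologs with no member
    in any listed species are ignored.  The result is invariant to the
    ordering of ``species_list``.
    """
    if len(species_list) < 2:
        raise ValueError("partition needs >= 2 species")
    all_sp = frozenset(species_list)
    venn: dict[frozenset[str], int] = {}
    counts = {
        sp: {"core": 0, "shared": 0, "unique": 0} for sp in sorted(species_list)
    }
    for og in ortholog_map.ortholog_ids:
        span = ortholog_map.species_span(og) & all_sp
        if not span:
            continue
        venn[span] = venn.get(span, 0) + 1
        if span == all_sp:
            cat = "core"
        elif len(span) == 1:
            cat = "unique"
        else:
            cat = "shared"
        for sp in span:
            counts[sp][cat] += 1
    per = pd.DataFrame(counts).T
    per.index.name = "species"
    per["total"] = per.sum(axis=1)
    for cat in ("core", "shared", "unique"):
        per[f"{cat}_pct"] = np.where(
            per["total"] > 0, 100.0 * per[cat] / per["total"], 0.0
        )
    return SharingPartition(per_species=per, venn=venn)
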