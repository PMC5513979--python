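"""Readers and writers for the pipeline's tab-separated table formats.

All tables are UTF-8 TSV with a header row and no quoting, matching the
count-matrix idiom of RSEM-style outputs.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .types import CountTable, AnnotationTable, OrthologMap, ValidationError, TREATMENTS

logger = logging.getLogger(__name__)

_TSV_KW = dict(sep="\t", encoding="utf-8")


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8", **kw)


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    """Write a data frame as unquoted UTF-8 TSV without the index."""
    df.to_csv(
        path,
        index=False,
        float_format=float_format,
        quoting=csv.QUOTE_NONE,
        lineterminator="\n",
        **_TSV_KW,
    )


def read_count_table(
    path: str | Path, species_id: str, is_dino: bool = False
) -> CountTable:
    """Read a ``contig_id  replete  lowN  lowP`` count table.

    Treatment columns are matched case-insensitively.  Raises
    :class:`ValidationError` for negative or non-integer counts,
    duplicate contig ids, or a missing treatment column.
    """
    df = _read_tsv(path)
    if "contig_id" not in df.columns:
        raise ValidationError(f"{path}: missing contig_id column")
    df = df.set_index("contig_id")
    return CountTable(species_id=species_id, counts=df, is_dino=is_dino)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.counts.reset_index(names="contig_id")
    write_tsv(df, path)


def read_annotation_table(path: str | Path) -> AnnotationTable:
    df = _read_tsv(path, dtype={"kegg_ko": str, "kegg_module": str, "function_label": str})
    if "contig_id" not in df.columns:
        raise ValidationError(f"{path}: missing contig_id column")
    df = df.set_index("contig_id")
    return AnnotationTable(df)


def write_annotation_table(ann: AnnotationTable, path: str | Path) -> None:
    write_tsv(ann.table.reset_index(names="contig_id"), path)


def read_ortholog_map(
    path: str | Path, count_tables: Mapping[str, CountTable] | None = None
) -> OrthologMap:
    """Read ``ortholog_id  species_id  contig_id`` membership rows.

    A contig listed under two orthologs is an error.  When
    ``count_tables`` is given, member contigs absent from the loaded
    tables are dropped with a warning.
    """
    df = _read_tsv(path)
    required = {"ortholog_id", "species_id", "contig_id"}
    if df.empty and not required <= set(df.columns):
        logger.warning("%s: empty ortholog map", path)
        return OrthologMap({})
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        logger.warning("%s: empty ortholog map", path)
        return OrthologMap({})
    dup = df.groupby(["species_id", "contig_id"])["ortholog_id"].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index.tolist()[:5]
        raise ValidationError(f"{path}: contig(s) in multiple orthologs: {bad}")
    omap = OrthologMap.from_frame(df)
    if count_tables is not None:
        omap, dropped = omap.restrict_to(count_tables)
        if dropped:
            logger.warning(
                "%s: dropped %d member contig(s) absent from count tables "
                "(first: %s)",
                path,
                len(dropped),
                dropped[0],
            )
    return omap


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    write_tsv(omap.to_frame(), path)


def read_physiology_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format replicate measurement table.

    Columns: species, treatment, replicate, variable, value.
    """
    df = _read_tsv(path)
    required = {"species", "treatment", "replicate", "variable", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    bad = set(df["treatment"].unique()) - set(TREATMENTS)
    if bad:
        raise ValidationError(f"{path}: unknown treatment label(s) {sorted(bad)}")
    return df
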