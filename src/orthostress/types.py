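"""Core domain containers for the cross-species nutrient-stress pipeline.

The primary unit of data is a per-species table of read counts per contig
under three nutrient treatments (replete, low nitrogen, low phosphorus),
each treatment a single pooled sequencing library.  Contigs are annotated
with length and (for a minority) KEGG orthology, and grouped across species
into orthologous groups that support conservation screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Closed, ordered set of treatment labels. ``replete`` is always the
#: reference condition; contrasts are treatment vs replete.
TREATMENTS: tuple[str, str, str] = ("replete", "lowN", "lowP")

#: The two stress treatments tested against the replete reference.
STRESS_TREATMENTS: tuple[str, str] = ("lowN", "lowP")

#: Minimum contig length retained by the upstream assembly filter.
MIN_CONTIG_LENGTH = 150


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class CountTable:
    """Read counts per contig x treatment for one species.

    Parameters
    ----------
    species_id:
        Species label.
    counts:
        DataFrame indexed by contig id with exactly the columns
        ``("replete", "lowN", "lowP")`` holding non-negative integer
        read counts.
    library_size:
        Optional per-treatment library sizes.  When omitted (the normal
        case for contig-level input) library sizes are the treatment
        column sums.  Ortholog-level tables produced by aggregation carry
        the contig-level totals here, which must dominate their own
        column sums.
    is_dino:
        Tag for dinoflagellate-like species whose transcriptional
        modulation is known to be minimal; used to pick the default focal
        set for the conservation screen.
    """

    species_id: str
    counts: pd.DataFrame
    library_size: pd.Series | None = None
    is_dino: bool = False

    def __post_init__(self) -> None:
        df = self.counts
        cols = [str(c) for c in df.columns]
        if cols != list(TREATMENTS):
            # allow any column order / case, but require all three treatments
            lower = {c.lower(): c for c in df.columns}
            try:
                ordered = [lower[t.lower()] for t in TREATMENTS]
            except KeyError as exc:
                raise ValidationError(
                    f"{self.species_id}: missing treatment column {exc}; "
                    f"expected {TREATMENTS}, got {tuple(df.columns)}"
                ) from None
            df = df[ordered]
            df.columns = list(TREATMENTS)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(
                f"{self.species_id}: duplicate contig id(s) {dups[:5]}"
            )
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError(f"{self.species_id}: non-numeric counts")
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            bad = df.index[np.any(~np.isfinite(values) | (values < 0), axis=1)]
            raise ValidationError(
                f"{self.species_id}: negative or non-finite count in row(s) "
                f"{bad.tolist()[:5]}"
            )
        if np.any(values != np.floor(values)):
            bad = df.index[np.any(values != np.floor(values), axis=1)]
            raise ValidationError(
                f"{self.species_id}: non-integer count in row(s) {bad.tolist()[:5]}"
            )
        df = df.astype(np.int64)
        object.__setattr__(self, "counts", df)
        if self.library_size is not None:
            ls = pd.Series(self.library_size, dtype=np.int64)[list(TREATMENTS)]
            colsum = df.sum(axis=0)
            if (ls < colsum).any():
                raise ValidationError(
                    f"{self.species_id}: library_size below column sum"
                )
            object.__setattr__(self, "library_size", ls)

    @property
    def contig_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def effective_library_size(self) -> pd.Series:
        """Per-treatment library size (column sums unless overridden)."""
        if self.library_size is not None:
            return self.library_size
        return self.counts.sum(axis=0)


@dataclass
class AnnotationTable:
    """Per-contig annotation: length, optional KEGG KO / module, label.

    ``table`` is indexed by contig id with columns ``length_bp``,
    ``kegg_ko``, ``kegg_module`` and ``function_label``; missing
    annotations are empty strings.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"length_bp", "kegg_ko", "kegg_module", "function_label"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"annotation missing column(s) {sorted(missing)}")
        if df.index.has_duplicates:
            raise ValidationError("annotation has duplicate contig ids")
        lengths = df["length_bp"].to_numpy()
        if np.any(lengths < MIN_CONTIG_LENGTH):
            bad = df.index[lengths < MIN_CONTIG_LENGTH].tolist()
            raise ValidationError(
                f"contig(s) shorter than {MIN_CONTIG_LENGTH} bp: {bad[:5]}"
            )
        for col in ("kegg_ko", "kegg_module", "function_label"):
            df[col] = df[col].fillna("").astype(str)
        has_module = df["kegg_module"] != ""
        has_ko = df["kegg_ko"] != ""
        if (has_module & ~has_ko).any():
            bad = df.index[has_module & ~has_ko].tolist()
            raise ValidationError(
                f"kegg_module without kegg_ko for contig(s) {bad[:5]}"
            )

    @property
    def contig_ids(self) -> pd.Index:
        return self.table.index

    def lengths(self, contig_ids: Iterable[str]) -> pd.Series:
        return self.table.loc[list(contig_ids), "length_bp"]


@dataclass
class OrthologMap:
    """Ortholog -> species -> set of member contigs.

    A contig belongs to at most one ortholog.  Construction validates
    that constraint; validation against loaded count tables is done by
    :meth:`validate_against`.
    """

    members: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for og, by_sp in self.members.items():
            for sp, contigs in by_sp.items():
                for c in contigs:
                    key = (sp, c)
                    if key in seen and seen[key] != og:
                        raise ValidationError(
                            f"contig {c} ({sp}) assigned to both {seen[key]} and {og}"
                        )
                    seen[key] = og

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OrthologMap":
        members: dict[str, dict[str, set[str]]] = {}
        for og, sp, contig in df[["ortholog_id", "species_id", "contig_id"]].itertuples(
            index=False
        ):
            members.setdefault(og, {}).setdefault(sp, set()).add(contig)
        frozen = {
            og: {sp: frozenset(cs) for sp, cs in by_sp.items()}
            for og, by_sp in members.items()
        }
        return cls(frozen)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (og, sp, contig)
            for og in sorted(self.members)
            for sp in sorted(self.members[og])
            for contig in sorted(self.members[og][sp])
        ]
        return pd.DataFrame(rows, columns=["ortholog_id", "species_id", "contig_id"])

    @property
    def ortholog_ids(self) -> list[str]:
        return sorted(self.members)

    def species_span(self, ortholog_id: str) -> frozenset[str]:
        return frozenset(self.members[ortholog_id])

    def contigs(self, ortholog_id: str, species_id: str) -> frozenset[str]:
        return self.members[ortholog_id].get(species_id, frozenset())

    def restrict_to(
        self, count_tables: Mapping[str, CountTable]
    ) -> tuple["OrthologMap", list[tuple[str, str, str]]]:
        """Drop member contigs absent from the given count tables.

        Returns the restricted map and the dropped ``(ortholog, species,
        contig)`` triples so callers can log them.
        """
        dropped: list[tuple[str, str, str]] = []
        new: dict[str, dict[str, frozenset[str]]] = {}
        for og, by_sp in self.members.items():
            kept_sp: dict[str, frozenset[str]] = {}
            for sp, contigs in by_sp.items():
                if sp not in count_tables:
                    dropped.extend((og, sp, c) for c in sorted(contigs))
                    continue
                known = set(count_tables[sp].contig_ids)
                keep = frozenset(c for c in contigs if c in known)
                dropped.extend((og, sp, c) for c in sorted(contigs - keep))
                if keep:
                    kept_sp[sp] = keep
            if kept_sp:
                new[og] = kept_sp
        return OrthologMap(new), dropped
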