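"""Synthetic multi-species nutrient-stress experiments with planted truth.

The generator mirrors the structure of a pooled-library design: five
species (two dinoflagellate-like, with strongly suppressed transcriptional
responses), three treatments (replete, lowN, lowP) with one library each,
contigs generated inside orthologous groups partitioned into core / shared
/ unique, log-normal baseline expression, Poisson (or negative-binomial)
count noise, and KEGG annotation for a minority of contigs.  Every effect
is recorded in a :class:`TruthLedger` so downstream screens can be scored
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig, ConfigError
from .types import CountTable, AnnotationTable, OrthologMap, TREATMENTS, STRESS_TREATMENTS


@dataclass
class TruthLedger:
    """Ground truth for a simulated experiment.

    ``contig_effects``: one row per (species, treatment, contig) with the
    true log2 fold change (0 rows for unperturbed units are included so
    the frame is dense over stress treatments).

    ``ortholog_truth``: one row per planted conserved ortholog with its
    designated species subset, treatments and direction.
    """

    contig_effects: pd.DataFrame
    ortholog_truth: pd.DataFrame

    def true_log2fc(self, species: str, treatment: str) -> pd.Series:
        sub = self.contig_effects
        sub = sub[(sub["species_id"] == species) & (sub["treatment"] == treatment)]
        return sub.set_index("contig_id")["log2fc"]

    def responsive_orthologs(
        self, treatment: str, focal: tuple[str, ...], min_species: int = 2
    ) -> pd.DataFrame:
        """Orthologs whose true effect is nonzero in >= min_species focal species.

        Returns a frame indexed by ortholog_id with columns ``n_species``
        and ``direction_class`` (up/down/mixed from the true effect signs).
        This is the ground-truth analogue of the conservation screen and
        includes both planted blocks and background effects that happen to
        co-occur.
        """
        sub = self.contig_effects
        sub = sub[
            (sub["treatment"] == treatment)
            & (sub["species_id"].isin(focal))
            & (sub["log2fc"] != 0.0)
        ]
        # member contigs of an ortholog share one effect per species
        per = (
            sub.groupby(["ortholog_id", "species_id"])["log2fc"].mean().reset_index()
        )
        rows = []
        for og, grp in per.groupby("ortholog_id"):
            if len(grp) < min_species:
                continue
            signs = set(np.sign(grp["log2fc"]))
            cls = "up" if signs == {1.0} else "down" if signs == {-1.0} else "mixed"
            rows.append((og, len(grp), cls))
        return pd.DataFrame(
            rows, columns=["ortholog_id", "n_species", "direction_class"]
        ).set_index("ortholog_id")


def _build_orthologs(cfg: SimulationConfig, rng: np.random.Generator):
    """Assign each ortholog a species span: core / shared / unique."""
    species = list(cfg.species)
    spans: list[tuple[str, ...]] = []
    for _ in range(cfg.n_core):
        spans.append(tuple(species))
    n_sp = len(species)
    for _ in range(cfg.n_shared):
        if n_sp < 3:
            raise ConfigError("shared orthologs need >= 3 species")
        k = int(rng.integers(2, n_sp))  # proper subset of size 2..n-1
        idx = rng.choice(n_sp, size=k, replace=False)
        spans.append(tuple(species[i] for i in sorted(idx)))
    for sp in species:
        spans.extend([(sp,)] * cfg.n_unique_per_species)
    og_ids = [f"OG{i:06d}" for i in range(len(spans))]
    return og_ids, spans


def _plant_effects(
    cfg: SimulationConfig,
    og_ids: list[str],
    spans: list[tuple[str, ...]],
    rng: np.random.Generator,
):
    """Assign true log2FC per (ortholog, species, treatment).

    Planted conserved blocks get a shared signed magnitude across their
    designated species; remaining (ortholog, species, treatment) slots
    receive independent background effects with probability
    ``de_fraction`` (suppressed for dinoflagellate-like species).
    """
    span_of = dict(zip(og_ids, spans))
    effects: dict[tuple[str, str, str], float] = {}  # (og, sp, treat) -> delta
    baselines: dict[str, float] = {}  # planted ortholog -> fixed replete mean
    planted_rows = []
    used: set[str] = set()
    for spec in cfg.conserved_planted:
        eligible = [
            og
            for og, span in span_of.items()
            if og not in used and set(spec.species) <= set(span)
        ]
        if len(eligible) < spec.n:
            raise ConfigError(
                f"cannot plant {spec.n} conserved orthologs spanning "
                f"{spec.species}: only {len(eligible)} eligible"
            )
        chosen = [eligible[i] for i in rng.choice(len(eligible), spec.n, replace=False)]
        for og in chosen:
            used.add(og)
            if spec.direction == "up":
                sign = 1.0
            elif spec.direction == "down":
                sign = -1.0
            else:  # stress responses skew toward decreased abundance
                sign = -1.0 if rng.random() < 0.7 else 1.0
            delta = sign * spec.magnitude
            if spec.baseline is not None:
                baselines[og] = spec.baseline
            for sp in spec.species:
                for t in spec.treatments:
                    effects[(og, sp, t)] = delta
            planted_rows.append(
                (
                    og,
                    ";".join(spec.species),
                    ";".join(spec.treatments),
                    "up" if sign > 0 else "down",
                    delta,
                )
            )
    lo, hi = cfg.effect_size_range
    for og, span in span_of.items():
        for sp in span:
            frac = cfg.de_fraction_for(sp)
            for t in STRESS_TREATMENTS:
                if (og, sp, t) in effects:
                    continue
                if rng.random() < frac:
                    mag = rng.uniform(lo, hi)
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    effects[(og, sp, t)] = sign * mag
    ortholog_truth = pd.DataFrame(
        planted_rows,
        columns=["ortholog_id", "species", "treatments", "direction", "log2fc"],
    )
    return effects, ortholog_truth, baselines


def generate_experiment(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[dict[str, CountTable], dict[str, AnnotationTable], OrthologMap, TruthLedger]:
    """Simulate count tables, annotations, ortholog map and truth ledger."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    og_ids, spans = _build_orthologs(cfg, rng)
    effects, ortholog_truth, planted_baseline = _plant_effects(cfg, og_ids, spans, rng)

    # per-ortholog shared baseline and annotation
    base_mu = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, len(og_ids))
    annotated = rng.random(len(og_ids)) < cfg.kegg_annotated_fraction
    module_of = rng.integers(0, cfg.n_kegg_modules, len(og_ids))

    lo_c, hi_c = cfg.contigs_per_ortholog
    count_tables: dict[str, CountTable] = {}
    annotations: dict[str, AnnotationTable] = {}
    map_rows = []
    truth_rows = []
    for sp in cfg.species:
        contig_ids: list[str] = []
        mus: list[float] = []
        deltas = {t: [] for t in STRESS_TREATMENTS}
        ann_rows = []
        k = 0
        for j, (og, span) in enumerate(zip(og_ids, spans)):
            if sp not in span:
                continue
            n_contigs = int(rng.integers(lo_c, hi_c + 1))
            for _ in range(n_contigs):
                cid = f"{sp}_c{k:06d}"
                k += 1
                contig_ids.append(cid)
                if og in planted_baseline:
                    # designated ortholog-level replete mean, split evenly
                    mus.append(planted_baseline[og] / n_contigs)
                else:
                    mus.append(base_mu[j] * rng.uniform(0.2, 1.0))
                for t in STRESS_TREATMENTS:
                    deltas[t].append(effects.get((og, sp, t), 0.0))
                length = max(
                    float(rng.lognormal(cfg.length_meanlog, cfg.length_sdlog)), 150.0
                )
                if annotated[j]:
                    ko = f"K{10000 + j % 90000:05d}"
                    mod = f"M{module_of[j] + 1:05d}"
                    label = f"{ko}-family protein"
                else:
                    ko, mod, label = "", "", "hypothetical protein"
                ann_rows.append((cid, int(round(length)), ko, mod, label))
                map_rows.append((og, sp, cid))
                for t in STRESS_TREATMENTS:
                    truth_rows.append((sp, t, cid, og, effects.get((og, sp, t), 0.0)))
        mus_arr = np.asarray(mus)
        cols = {}
        for t in TREATMENTS:
            depth = cfg.depth_multiplier.get(t, 1.0)
            if t == "replete":
                lam = mus_arr * depth
            else:
                lam = mus_arr * np.exp2(np.asarray(deltas[t])) * depth
            if cfg.noise == "poisson":
                cols[t] = rng.poisson(lam)
            else:
                shape = 1.0 / cfg.nb_dispersion
                lam_g = rng.gamma(shape, lam * cfg.nb_dispersion)
                cols[t] = rng.poisson(lam_g)
        counts = pd.DataFrame(cols, index=pd.Index(contig_ids, name="contig_id"))
        count_tables[sp] = CountTable(
            species_id=sp, counts=counts, is_dino=sp in cfg.dino_species
        )
        ann = pd.DataFrame(
            ann_rows,
            columns=["contig_id", "length_bp", "kegg_ko", "kegg_module", "function_label"],
        ).set_index("contig_id")
        annotations[sp] = AnnotationTable(ann)

    omap = OrthologMap.from_frame(
        pd.DataFrame(map_rows, columns=["ortholog_id", "species_id", "contig_id"])
    )
    ledger = TruthLedger(
        contig_effects=pd.DataFrame(
            truth_rows,
            columns=["species_id", "treatment", "contig_id", "ortholog_id", "log2fc"],
        ),
        ortholog_truth=ortholog_truth,
    )
    return count_tables, annotations, omap, ledger


#: Variables that must have strictly positive means in replicate draws.
POSITIVE_VARIABLES = frozenset(
    {"growth_rate", "POC", "PON", "pCHO", "chl_a", "FvFm", "APA"}
)


def generate_physiology(
    means: pd.DataFrame, n_reps: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Draw replicate measurements around published-style means.

    ``means`` is long format with columns species, treatment, variable,
    mean, cv (cv as a fraction, so 0.08 for 8%).  Each (species,
    treatment, variable) yields ``n_reps`` draws from
    Normal(mean, mean * cv).  Rows with missing means are skipped.
    """
    required = {"species", "treatment", "variable", "mean", "cv"}
    missing = required - set(means.columns)
    if missing:
        raise ValueError(f"means table missing column(s) {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in means.itertuples(index=False):
        if pd.isna(rec.mean):
            continue
        if rec.variable in POSITIVE_VARIABLES and rec.mean < 0:
            raise ValueError(
                f"negative mean for strictly positive variable {rec.variable}"
            )
        if rec.cv < 0:
            raise ValueError("CV must be >= 0")
        draws = rng.normal(rec.mean, rec.mean * rec.cv, n_reps)
        for i, v in enumerate(draws, start=1):
            rows.append((rec.species, rec.treatment, i, rec.variable, v))
    return pd.DataFrame(
        rows, columns=["species", "treatment", "replicate", "variable", "value"]
    )
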