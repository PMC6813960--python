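"""Biogeochemical-cycle reconstruction from KO-annotated gene tables.

The genetic potential of a conversion step (e.g. nitrite -> N2O) is the summed
abundance of its marker-gene combination: every gene whose KO belongs to the
step's KO list contributes its abundance once. Bidirectional markers (aprA/dsrA
between dissimilatory sulfate reduction and sulfide oxidation; amoA/pmoA
between ammonia and methane oxidation) are disambiguated by phylogeny before
aggregation, so each gene lands in exactly one step and within-cycle totals
are conserved.

Step potentials are expressed as within-cycle percentages ("potential flux");
stress-adaptation themes instead use percent of *total* gene abundance, since
they are not closed cycles. Taxon contributions per step feed the row-scaled
heatmap with the >1%-contribution retention filter.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .io import RANKS, UNCLASSIFIED, GeneTable, ValidationError, lineage_rank

logger = logging.getLogger(__name__)

_KO_RE = re.compile(r"^K\d{5}$")
UNASSIGNED = "unassigned"

CYCLES = ("carbon", "nitrogen", "sulfur")


@dataclass
class MarkerStep:
    """One conversion step: a named KO combination within a cycle."""

    cycle: str
    name: str
    kos: tuple[str, ...]
    aerobicity: str = "n/a"
    ambiguous: bool = False
    clades: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for ko in self.kos:
            if not _KO_RE.match(ko):
                raise ValidationError(
                    f"step {self.cycle}/{self.name}: malformed KO id {ko!r}"
                )
        if self.aerobicity not in {"aerobic", "anaerobic", "n/a"}:
            raise ValidationError(
                f"step {self.cycle}/{self.name}: bad aerobicity {self.aerobicity!r}"
            )
        if self.ambiguous and not self.clades:
            raise ValidationError(
                f"step {self.cycle}/{self.name}: ambiguous step lacks routing clades"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.cycle, self.name)


@dataclass
class MarkerConfig:
    """Cycle -> step -> KO-combination map with clade-routing rules."""

    steps: list[MarkerStep]
    version: int | str = 1
    _by_ko: dict[str, list[MarkerStep]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        by_ko: dict[str, list[MarkerStep]] = {}
        for step in self.steps:
            if step.key in seen:
                raise ValidationError(
                    f"duplicate step name {step.name!r} in cycle {step.cycle!r}"
                )
            seen.add(step.key)
            for ko in step.kos:
                by_ko.setdefault(ko, []).append(step)
        for ko, owners in by_ko.items():
            if len(owners) > 1 and not all(s.ambiguous for s in owners):
                names = ", ".join("/".join(s.key) for s in owners)
                raise ValidationError(
                    f"KO {ko} appears in multiple steps ({names}) but not all "
                    "are flagged ambiguous"
                )
        self._by_ko = by_ko

    @property
    def cycles(self) -> list[str]:
        out: list[str] = []
        for step in self.steps:
            if step.cycle not in out:
                out.append(step.cycle)
        return out

    def cycle_steps(self, cycle: str) -> list[MarkerStep]:
        return [s for s in self.steps if s.cycle == cycle]

    def steps_for_ko(self, ko: str) -> list[MarkerStep]:
        return self._by_ko.get(ko, [])

    @property
    def ambiguous_kos(self) -> set[str]:
        return {ko for ko, owners in self._by_ko.items() if len(owners) > 1}


def load_marker_config(path=None) -> MarkerConfig:
    """Load a marker config from YAML; default is the packaged curation.

    Schema::

        version: 1
        cycles:
          <cycle name>:
            - name: <step>
              kos: [K#####, ...]
              aerobicity: aerobic|anaerobic|n/a
              ambiguous: true          # optional, requires clades
              clades: [pattern, ...]   # ordered lineage substrings
    """
    if path is None:
        text = resources.files("biogeocycler.data").joinpath("markers.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # yaml reports line numbers itself
        raise ValidationError(f"marker config parse error: {exc}") from exc
    if not isinstance(raw, dict) or "cycles" not in raw:
        raise ValidationError("marker config must contain a 'cycles' mapping")
    steps: list[MarkerStep] = []
    for cycle, entries in raw["cycles"].items():
        cycle = str(cycle)
        if not (cycle in CYCLES or cycle.startswith("stress:")):
            raise ValidationError(f"unknown cycle name {cycle!r}")
        for entry in entries:
            try:
                steps.append(
                    MarkerStep(
                        cycle=cycle,
                        name=str(entry["name"]),
                        kos=tuple(str(k) for k in entry["kos"]),
                        aerobicity=str(entry.get("aerobicity", "n/a")),
                        ambiguous=bool(entry.get("ambiguous", False)),
                        clades=tuple(str(c) for c in entry.get("clades", ())),
                    )
                )
            except KeyError as exc:
                raise ValidationError(
                    f"cycle {cycle!r}: step entry missing field {exc}"
                ) from exc
    return MarkerConfig(steps=steps, version=raw.get("version", 1))


def write_marker_config(config: MarkerConfig, path) -> None:
    """Serialize a config back to the YAML schema (round-trips)."""
    cycles: dict[str, list[dict]] = {}
    for step in config.steps:
        entry: dict = {"name": step.name, "kos": list(step.kos),
                       "aerobicity": step.aerobicity}
        if step.ambiguous:
            entry["ambiguous"] = True
            entry["clades"] = list(step.clades)
        cycles.setdefault(step.cycle, []).append(entry)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"version": config.version, "cycles": cycles}, fh,
                       sort_keys=False)


# ---------------------------------------------------------------------------
# Routing of bidirectional markers
# ---------------------------------------------------------------------------

RESOLVED_COLUMN = "resolved_step"


def _lineage_matches(lineage: str, patterns: tuple[str, ...]) -> bool:
    ranks = [r.lower() for r in lineage.split(";")]
    return any(p.lower() in rank for p in patterns for rank in ranks
               if rank != UNCLASSIFIED)


def route_ambiguous(genes: GeneTable, config: MarkerConfig) -> GeneTable:
    """Resolve bidirectional markers to a single step by phylogeny.

    Each gene whose KO belongs to several steps is assigned to the first step
    (config order) whose clade-pattern list matches any rank of the gene's
    lineage, case-insensitively. Genes with no matching clade become
    ``unassigned`` — a reported outcome, not an error. The result carries a
    ``resolved_step`` column ('cycle/step' or 'unassigned'; empty for genes
    whose KO is unambiguous).
    """
    df = genes.frame.copy()
    resolved = pd.Series("", index=df.index, dtype=object)
    ambiguous = config.ambiguous_kos
    n_unassigned = 0
    for idx, row in df[df["ko"].isin(ambiguous)].iterrows():
        owners = config.steps_for_ko(row["ko"])
        target = UNASSIGNED
        for step in owners:
            if _lineage_matches(row["lineage"], step.clades):
                target = "/".join(step.key)
                break
        if target == UNASSIGNED:
            n_unassigned += 1
        resolved.at[idx] = target
    if n_unassigned:
        logger.info("routing: %d ambiguous-marker genes left unassigned",
                    n_unassigned)
    df[RESOLVED_COLUMN] = resolved
    out = GeneTable.__new__(GeneTable)  # frame already validated; keep column
    out.frame = df.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Aggregation engine
# ---------------------------------------------------------------------------

@dataclass
class StepPotential:
    """Summed marker abundance for one conversion step.

    ``percent`` is within-cycle for C/N/S cycles and percent-of-total-gene-
    abundance for stress themes. ``taxa`` maps taxon (at the attribution rank)
    to (abundance, fraction of the step).
    """

    cycle: str
    step: str
    abundance: float
    percent: float
    taxa: dict[str, tuple[float, float]]
    n_genes: int


def _assign_steps(genes: GeneTable, config: MarkerConfig) -> pd.DataFrame:
    """Per-gene step assignment; auto-routes if the resolved column is absent."""
    df = genes.frame
    if RESOLVED_COLUMN not in df.columns and (
        df["ko"].isin(config.ambiguous_kos).any()
    ):
        logger.info("ambiguous markers present but not routed; routing now")
        df = route_ambiguous(genes, config).frame
    assignment = pd.Series("", index=df.index, dtype=object)
    for idx, row in df.iterrows():
        owners = config.steps_for_ko(row["ko"]) if row["ko"] else []
        if not owners:
            continue
        if len(owners) == 1:
            assignment.at[idx] = "/".join(owners[0].key)
        else:
            assignment.at[idx] = row.get(RESOLVED_COLUMN, UNASSIGNED)
    return df.assign(step_key=assignment)


def reconstruct_cycles(
    genes: GeneTable,
    config: MarkerConfig,
    rank: str = "genus",
    cycles: tuple[str, ...] | None = None,
) -> list[StepPotential]:
    """Sum marker-gene abundances per conversion step with taxon attribution.

    After routing, each gene contributes to exactly one step; a cycle's step
    abundances therefore partition the total abundance of genes matched to
    that cycle (conservation). Percentages are within-cycle; a cycle with
    zero total abundance reports 0 percents with a warning rather than NaN.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    df = _assign_steps(genes, config)
    wanted = [c for c in config.cycles if not c.startswith("stress:")]
    if cycles is not None:
        wanted = [c for c in wanted if c in cycles]
    out: list[StepPotential] = []
    for cycle in wanted:
        steps = config.cycle_steps(cycle)
        keys = ["/".join(s.key) for s in steps]
        sub = df[df["step_key"].isin(keys)]
        cycle_total = float(sub["abundance"].sum())
        if cycle_total == 0:
            logger.warning("cycle %s: zero total marker abundance", cycle)
        for step, key in zip(steps, keys):
            rows = sub[sub["step_key"] == key]
            abund = float(rows["abundance"].sum())
            percent = 100.0 * abund / cycle_total if cycle_total > 0 else 0.0
            out.append(
                StepPotential(
                    cycle=cycle,
                    step=step.name,
                    abundance=abund,
                    percent=percent,
                    taxa=_taxa_contributions(rows, rank),
                    n_genes=len(rows),
                )
            )
    return out


def _taxa_contributions(rows: pd.DataFrame, rank: str) -> dict[str, tuple[float, float]]:
    if rows.empty:
        return {}
    taxa = rows["lineage"].map(lambda l: lineage_rank(l, rank))
    sums = rows.groupby(taxa)["abundance"].sum()
    total = float(sums.sum())
    return {
        str(t): (float(a), float(a) / total if total > 0 else 0.0)
        for t, a in sums.items()
    }


def unused_genes(genes: GeneTable, config: MarkerConfig) -> GeneTable:
    """Genes contributing to no step: no/unknown KO, or unroutable markers."""
    df = _assign_steps(genes, config)
    mask = df["step_key"].isin({"", UNASSIGNED})
    out = GeneTable.__new__(GeneTable)
    out.frame = df.loc[mask, list(genes.frame.columns)].reset_index(drop=True)
    return out


def stress_profile(
    genes: GeneTable,
    config: MarkerConfig,
    rank: str = "genus",
) -> list[StepPotential]:
    """Profile stress-adaptation themes (DNA repair, antioxidation, ...).

    Same aggregation engine as :func:`reconstruct_cycles`, but ``percent`` is
    relative to the TOTAL gene abundance of the input table — stress themes
    are open-ended gene inventories, not closed cycles, so their percentages
    need not (and do not) sum to 100.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    df = _assign_steps(genes, config)
    total = float(df["abundance"].sum())
    out: list[StepPotential] = []
    for cycle in [c for c in config.cycles if c.startswith("stress:")]:
        for step in config.cycle_steps(cycle):
            key = "/".join(step.key)
            rows = df[df["step_key"] == key]
            abund = float(rows["abundance"].sum())
            out.append(
                StepPotential(
                    cycle=cycle,
                    step=step.name,
                    abundance=abund,
                    percent=100.0 * abund / total if total > 0 else 0.0,
                    taxa=_taxa_contributions(rows, rank),
                    n_genes=len(rows),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Heatmap table
# ---------------------------------------------------------------------------

@dataclass
class HeatmapTable:
    """Row-scaled (z-score) taxon x step contribution matrix.

    Rows are taxa that contributed strictly more than the retention threshold
    to at least one step; each row has mean 0 and population sd 1, except
    constant rows which are all zeros.
    """

    values: pd.DataFrame  # taxa x steps


def taxa_heatmap(
    steps: list[StepPotential],
    min_contribution: float = 1.0,
    per_cycle: bool = False,
) -> HeatmapTable:
    """Build the row-scaled heatmap of taxon contributions across steps.

    A taxon is retained when its fraction of some step (or, with
    ``per_cycle=True``, of some cycle's whole marker mixture) exceeds
    ``min_contribution`` percent — strictly, so exactly-at-threshold taxa are
    excluded. Retained rows are z-scored across steps using the population
    standard deviation; constant rows become all zeros.
    """
    if not steps:
        return HeatmapTable(values=pd.DataFrame())
    cols = [f"{s.cycle}/{s.step}" for s in steps]
    taxa = sorted({t for s in steps for t in s.taxa})
    abund = pd.DataFrame(0.0, index=taxa, columns=cols)
    frac = pd.DataFrame(0.0, index=taxa, columns=cols)
    for s, col in zip(steps, cols):
        for taxon, (a, f) in s.taxa.items():
            abund.loc[taxon, col] = a
            frac.loc[taxon, col] = f
    if per_cycle:
        keep_frac = pd.DataFrame(index=taxa, dtype=float)
        for cycle in {s.cycle for s in steps}:
            ccols = [c for s, c in zip(steps, cols) if s.cycle == cycle]
            total = abund[ccols].to_numpy().sum()
            keep_frac[cycle] = abund[ccols].sum(axis=1) / total if total > 0 else 0.0
        keep = (keep_frac > min_contribution / 100.0).any(axis=1)
    else:
        keep = (frac > min_contribution / 100.0).any(axis=1)
    retained = abund.loc[keep[keep].index]
    if retained.empty:
        logger.warning("no taxon passed the >%s%% contribution filter",
                       min_contribution)
        return HeatmapTable(values=pd.DataFrame(columns=cols))
    values = retained.apply(_zscore_row, axis=1)
    return HeatmapTable(values=values)


def _zscore_row(row: pd.Series) -> pd.Series:
    sd = float(np.std(row.to_numpy()))  # population sd (ddof=0)
    if sd == 0:
        return pd.Series(0.0, index=row.index)
    return (row - row.mean()) / sd


def step_potentials_frame(steps: list[StepPotential]) -> pd.DataFrame:
    """Flatten step potentials to a tidy table (one row per step)."""
    return pd.DataFrame(
        [{"cycle": s.cycle, "step": s.step, "abundance": s.abundance,
          "percent": s.percent, "n_genes": s.n_genes} for s in steps]
    )


def taxa_contributions_frame(steps: list[StepPotential]) -> pd.DataFrame:
    """Flatten per-taxon step contributions (one row per step x taxon)."""
    rows = [
        {"cycle": s.cycle, "step": s.step, "taxon": t, "abundance": a,
         "fraction_of_step": f}
        for s in steps for t, (a, f) in sorted(s.taxa.items())
    ]
    return pd.DataFrame(rows, columns=["cycle", "step", "taxon", "abundance",
                                       "fraction_of_step"])
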