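"""Readers, writers and validated containers for every external format.

All tabular formats are UTF-8 TSV. Lineages are canonicalised on ingest to a
fixed six-rank, prefix-free form (``domain;phylum;class;order;family;genus``)
so that RDP-style (bare names) and GTDB-style (``p__Proteobacteria``) inputs
behave identically downstream. Readers never silently coerce: every repaired
or dropped record is logged with its identifier.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"

_KO_RE = re.compile(r"^K\d{5}$")
_RANK_PREFIX_RE = re.compile(r"^[dkpcofgs]__")
_MISSING_TOKENS = {"", "n.a.", "na", "n/a", "nan", "none", "-"}


class ValidationError(ValueError):
    """An input violated a container invariant; the message names the record."""


def canonical_lineage(lineage: str) -> str:
    """Normalise a semicolon-delimited lineage to six prefix-free ranks.

    Rank prefixes (``p__`` style) are stripped, surplus ranks beyond genus are
    dropped, and missing ranks are padded with ``unclassified``. ``unassigned``
    or empty input maps to a fully unclassified lineage.
    """
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        lineage = ""
    parts = [p.strip() for p in str(lineage).split(";")]
    parts = [_RANK_PREFIX_RE.sub("", p) for p in parts]
    parts = [p if p and p.lower() not in {"unassigned", UNCLASSIFIED} else UNCLASSIFIED
             for p in parts]
    if all(p == UNCLASSIFIED for p in parts):
        parts = []
    parts = parts[: len(RANKS)]
    parts += [UNCLASSIFIED] * (len(RANKS) - len(parts))
    return ";".join(parts)


def lineage_rank(lineage: str, rank: str) -> str:
    """Extract one rank name from a canonical lineage string."""
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    return canonical_lineage(lineage).split(";")[RANKS.index(rank)]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Samples x OTUs count table with a per-OTU taxonomic lineage.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, index = sample ids, columns = OTU ids.
    lineage : pandas.Series
        Canonical six-rank lineage per OTU (index = OTU ids).
    """

    counts: pd.DataFrame
    lineage: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate OTU id {dup!r}")
        values = self.counts.to_numpy()
        if np.isnan(values.astype(float)).any():
            raise ValidationError("count table contains missing values")
        neg = np.argwhere(values.astype(float) < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"OTU {self.counts.columns[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        lin = pd.Series(self.lineage, dtype=object)
        missing = [o for o in self.counts.columns if o not in lin.index]
        if missing:
            raise ValidationError(f"OTU {missing[0]!r} has no lineage entry")
        self.lineage = lin.reindex(self.counts.columns).map(canonical_lineage)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative(self) -> pd.DataFrame:
        """Counts converted to within-sample relative abundances."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0][0]
            raise ValidationError(f"sample {empty!r} has zero total count")
        return self.counts.div(totals, axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.lineage.equals(other.lineage)


GENE_COLUMNS = ["gene_id", "ko", "lineage", "abundance"]


@dataclass
class GeneTable:
    """Per-gene functional annotation records: (gene_id, KO, lineage, abundance)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in GENE_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"gene table missing column {col!r}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene_id {dup!r}")
        df["ko"] = df["ko"].fillna("").astype(str)
        bad_ko = df["ko"].map(lambda k: bool(k) and not _KO_RE.match(k))
        if bad_ko.any():
            for gid in df.loc[bad_ko, "gene_id"]:
                logger.warning("gene %s: malformed KO id cleared", gid)
            df.loc[bad_ko, "ko"] = ""
        df["lineage"] = df["lineage"].map(canonical_lineage)
        df["abundance"] = df["abundance"].astype(float)
        if (df["abundance"] < 0).any():
            gid = df.loc[df["abundance"] < 0, "gene_id"].iloc[0]
            raise ValidationError(f"gene {gid!r} has negative abundance")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total_abundance(self) -> float:
        return float(self.frame["abundance"].sum())


@dataclass
class CopyNumberTable:
    """qPCR 16S rRNA gene copy numbers per gram (wet weight) of soil.

    Missing measurements (``n.a.`` in the source tables) are explicit NaN,
    never zero.
    """

    frame: pd.DataFrame  # columns: sample_id, bacteria_copies, archaea_copies

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in ("sample_id", "bacteria_copies", "archaea_copies"):
            if col not in df.columns:
                raise ValidationError(f"copy-number table missing column {col!r}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        # bacteria strictly positive (a qPCR run that detected nothing is a
        # missing value, not a zero); archaea may be 0 — true absence.
        for col, lo in (("bacteria_copies", 0.0), ("archaea_copies", -1.0)):
            df[col] = df[col].astype(float)
            bad = df[col].notna() & (df[col] <= lo)
            if bad.any():
                sid = df.loc[bad, "sample_id"].iloc[0]
                raise ValidationError(f"sample {sid!r}: invalid {col} value")
        self.frame = df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

def read_otu_table(path, dialect: str = "tsv") -> OtuTable:
    """Read a TSV OTU table; orientation is detected from a 'taxonomy' header.

    The usual layout is OTUs as rows, samples as columns, plus one column named
    ``taxonomy`` (case-insensitive). The transposed layout (samples as rows,
    taxonomy carried in a row) is detected and handled. ``dialect='biom-tsv'``
    additionally tolerates leading ``#`` comment lines and a ``#OTU ID``
    header as emitted by ``biom convert --to-tsv``.
    """
    if dialect not in {"tsv", "biom-tsv"}:
        raise ValidationError(f"unknown OTU table dialect {dialect!r}")
    kwargs = {"sep": "\t", "index_col": 0, "dtype": object, "encoding": "utf-8"}
    if dialect == "biom-tsv":
        with open(path, encoding="utf-8") as fh:
            lines = fh.readlines()
        body = [ln for ln in lines if not ln.startswith("#") or ln.startswith("#OTU ID")]
        if body and body[0].startswith("#OTU ID"):
            body[0] = body[0][1:]
        from io import StringIO

        df = pd.read_csv(StringIO("".join(body)), **kwargs)
    else:
        df = pd.read_csv(path, **kwargs)

    cols_lower = [str(c).lower() for c in df.columns]
    if "taxonomy" in cols_lower:
        tax_col = df.columns[cols_lower.index("taxonomy")]
        lineage = df[tax_col]
        counts = df.drop(columns=[tax_col]).T  # -> samples x otus
    elif "taxonomy" in [str(i).lower() for i in df.index]:
        tax_row = [i for i in df.index if str(i).lower() == "taxonomy"][0]
        lineage = df.loc[tax_row]
        counts = df.drop(index=[tax_row]).astype(object)
    else:
        raise ValidationError(
            f"{path}: no 'taxonomy' column or row; cannot orient the table"
        )
    counts = counts.apply(_to_counts)
    return OtuTable(counts=counts, lineage=pd.Series(lineage, dtype=object))


def _to_counts(col: pd.Series) -> pd.Series:
    try:
        as_float = col.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric count in column {col.name!r}: {exc}") from exc
    if "," in "".join(col.astype(str)):
        raise ValidationError(f"decimal comma rejected in column {col.name!r}")
    return as_float.astype(np.int64) if (as_float % 1 == 0).all() else as_float


def write_otu_table(table: OtuTable, path) -> None:
    """Write OTUs-as-rows TSV with a trailing taxonomy column (round-trips)."""
    out = table.counts.T.copy()
    out.insert(len(out.columns), "taxonomy", table.lineage)
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t", encoding="utf-8")


# ---------------------------------------------------------------------------
# Gene tables (GhostKOALA-style annotation + Salmon-style quantification)
# ---------------------------------------------------------------------------

SALMON_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]


def read_gene_table(
    annotation_path,
    quant_path=None,
    abundance: str = "TPM",
) -> GeneTable:
    """Join a 2-3 column annotation TSV with an optional Salmon quant table.

    The annotation file carries ``gene_id<TAB>ko[<TAB>lineage]`` with no
    header (a header row is detected and skipped). When a quant file is given,
    abundance is its ``TPM`` column (or ``NumReads`` via *abundance*); quant
    rows whose gene id is absent from the annotation are dropped with a
    warning. Without a quant file every abundance is 1.0 — presence/absence
    mode, which is logged.
    """
    ann = pd.read_csv(annotation_path, sep="\t", header=None, dtype=object,
                      encoding="utf-8")
    if ann.shape[1] not in (2, 3):
        raise ValidationError(
            f"{annotation_path}: expected 2-3 columns, found {ann.shape[1]}"
        )
    if str(ann.iloc[0, 0]).lower() in {"gene_id", "gene", "name"}:
        ann = ann.iloc[1:]
    ann.columns = ["gene_id", "ko", "lineage"][: ann.shape[1]]
    if "lineage" not in ann.columns:
        ann["lineage"] = UNCLASSIFIED
    ann["ko"] = ann["ko"].fillna("")

    if quant_path is not None:
        if abundance not in {"TPM", "NumReads"}:
            raise ValidationError(f"abundance must be TPM or NumReads, got {abundance!r}")
        quant = pd.read_csv(quant_path, sep="\t", encoding="utf-8")
        missing = [c for c in SALMON_COLUMNS if c not in quant.columns]
        if missing:
            raise ValidationError(f"{quant_path}: missing quant columns {missing}")
        orphans = set(quant["Name"]) - set(ann["gene_id"])
        for gid in sorted(orphans):
            logger.warning("quant row %s has no annotation; dropped", gid)
        quant = quant[quant["Name"].isin(set(ann["gene_id"]))]
        merged = ann.merge(
            quant[["Name", abundance]].rename(
                columns={"Name": "gene_id", abundance: "abundance"}
            ),
            on="gene_id",
            how="left",
        )
        unquant = merged["abundance"].isna()
        for gid in merged.loc[unquant, "gene_id"]:
            logger.warning("gene %s absent from quant file; abundance set to 0", gid)
        merged["abundance"] = merged["abundance"].fillna(0.0)
    else:
        logger.info("no quant file given; presence/absence mode (abundance = 1.0)")
        merged = ann.assign(abundance=1.0)
    return GeneTable(frame=merged[GENE_COLUMNS])


def write_gene_table(table: GeneTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_gene_table_tsv(path) -> GeneTable:
    """Read a gene table previously written by :func:`write_gene_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "ko": str,
                                            "lineage": str}, encoding="utf-8")
    return GeneTable(frame=df)


# ---------------------------------------------------------------------------
# Copy-number tables
# ---------------------------------------------------------------------------

def read_copy_numbers(path) -> CopyNumberTable:
    """Read a qPCR copy-number TSV; 'n.a.'-style tokens become explicit NaN."""
    df = pd.read_csv(path, sep="\t", dtype=object, encoding="utf-8")
    df.columns = [str(c).strip().lower() for c in df.columns]
    rename = {"sample": "sample_id", "bacteria": "bacteria_copies",
              "archaea": "archaea_copies"}
    df = df.rename(columns=rename)
    for col in ("bacteria_copies", "archaea_copies"):
        df[col] = df[col].map(_parse_copies)
    return CopyNumberTable(frame=df[["sample_id", "bacteria_copies", "archaea_copies"]])


def _parse_copies(token) -> float:
    if token is None or str(token).strip().lower() in _MISSING_TOKENS:
        return np.nan
    return float(str(token).replace("×", "e").replace(" ", ""))


def write_copy_numbers(table: CopyNumberTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, na_rep="n.a.", encoding="utf-8")


# ---------------------------------------------------------------------------
# Correlation networks
# ---------------------------------------------------------------------------

@dataclass
class CorrelationNetwork:
    """Genus-level co-occurrence network with thresholded SparCC edges.

    Nodes carry ``phylum`` and ``degree``; edges carry ``correlation``,
    ``p_value`` and ``sign`` ('positive'/'negative'). Undirected, no
    self-edges; isolated genera are not kept.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-edge on node {u!r}")
            rho = float(data.get("correlation", np.nan))
            if not -1.0 <= rho <= 1.0:
                raise ValidationError(f"edge {u}-{v}: correlation {rho} outside [-1,1]")
            data["sign"] = "negative" if rho < 0 else "positive"
        for node in self.graph.nodes:
            self.graph.nodes[node]["degree"] = self.graph.degree[node]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"genus_a": u, "genus_b": v, "correlation": d["correlation"],
             "p_value": d["p_value"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["genus_a", "genus_b", "correlation",
                                           "p_value", "sign"])


def write_network(net: CorrelationNetwork, path, format: str = "graphml") -> None:
    """Export a network as GraphML or GEXF (both Gephi-ingestible)."""
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "gexf":
        nx.write_gexf(net.graph, path)
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path, format: str = "graphml") -> CorrelationNetwork:
    if format == "graphml":
        g = nx.read_graphml(path)
    elif format == "gexf":
        g = nx.read_gexf(path)
    else:
        raise ValidationError(f"unknown network format {format!r}")
    return CorrelationNetwork(graph=nx.Graph(g))
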