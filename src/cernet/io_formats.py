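"""Tabular input/output for the ceRNA pipeline.

Every table the pipeline consumes or emits is tab-separated UTF-8 text with a
header row, mirroring the conventions of GDC expression dumps and
StarBase-style interaction lists:

* count matrices      — first column ``gene_id``, remaining columns samples;
  a companion two-column table maps ``sample_id`` to ``group``
  (``tumour``/``normal``)
* gene annotation     — ``gene_id``, ``biotype``
* interaction tables  — ``mirna``, ``target`` (one directed edge per row)
* clinical tables     — ``sample_id``, ``time``, ``event``

Networks are exported in Cytoscape-compatible SIF and GraphML.  Gene
identifiers are opaque strings throughout; no symbol/accession mapping is
attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, UsageError

logger = logging.getLogger(__name__)

TUMOUR = "tumour"
NORMAL = "normal"
VALID_GROUPS = (TUMOUR, NORMAL)

PROTEIN_CODING = "protein_coding"
LNCRNA = "lncRNA"
MIRNA = "miRNA"
BIOTYPES = (PROTEIN_CODING, LNCRNA, MIRNA)


# ---------------------------------------------------------------------------
# In-memory containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw integer counts, genes x samples, with tumour/normal sample labels.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample.  Values must
        be non-negative integers (integral floats are cast).
    sample_groups
        Series mapping every sample id in ``counts`` to ``tumour`` or
        ``normal``.
    """

    counts: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if self.counts.empty:
            raise FormatError("count matrix is empty")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r} in count matrix")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r} in count matrix")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("count matrix contains non-numeric values")
        if np.isnan(values.astype(float)).any():
            raise FormatError("count matrix contains missing values")
        neg = values < 0
        if neg.any():
            g, s = np.argwhere(neg)[0]
            raise FormatError(
                f"negative count for gene {self.counts.index[g]!r} in sample "
                f"{self.counts.columns[s]!r}"
            )
        if not np.allclose(values, np.round(values.astype(float))):
            raise FormatError("count matrix contains non-integral values")
        self.counts = self.counts.astype(np.int64)

        groups = pd.Series(self.sample_groups)
        missing = set(self.counts.columns) - set(groups.index)
        if missing:
            raise FormatError(f"missing group label for sample(s) {sorted(missing)}")
        groups = groups.reindex(self.counts.columns)
        bad = groups[~groups.isin(VALID_GROUPS)]
        if len(bad):
            raise FormatError(
                f"invalid group {bad.iloc[0]!r} for sample {bad.index[0]!r}; "
                f"expected one of {VALID_GROUPS}"
            )
        self.sample_groups = groups

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        if group not in VALID_GROUPS:
            raise UsageError(f"unknown group {group!r}")
        return list(self.sample_groups.index[self.sample_groups == group])


@dataclass
class GeneAnnotation:
    """Map from gene id to biotype (protein_coding / lncRNA / miRNA)."""

    biotypes: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.biotypes)
        if s.index.duplicated().any():
            dup = s.index[s.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r} in annotation")
        bad = s[~s.isin(BIOTYPES)]
        if len(bad):
            raise FormatError(
                f"invalid biotype {bad.iloc[0]!r} for gene {bad.index[0]!r}"
            )
        self.biotypes = s

    def biotype_of(self, gene_id: str) -> str:
        try:
            return self.biotypes[gene_id]
        except KeyError:
            raise UsageError(f"gene {gene_id!r} absent from annotation") from None

    def genes_of(self, biotype: str) -> list[str]:
        if biotype not in BIOTYPES:
            raise UsageError(f"unknown biotype {biotype!r}")
        return list(self.biotypes.index[self.biotypes == biotype])

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.biotypes.index


@dataclass
class InteractionTable:
    """Directed miRNA -> target edges (targets are lncRNAs or mRNAs)."""

    edges: pd.DataFrame  # columns: mirna, target
    _targets_of: dict = field(default_factory=dict, repr=False)
    _mirnas_targeting: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.edges, columns=["mirna", "target"]).astype(str)
        if (df["mirna"] == df["target"]).any():
            row = df[df["mirna"] == df["target"]].iloc[0]
            raise FormatError(f"self-interaction {row['mirna']!r} -> itself")
        n_before = len(df)
        df = df.drop_duplicates(ignore_index=True)
        if len(df) < n_before:
            logger.warning(
                "collapsed %d duplicate interaction row(s)", n_before - len(df)
            )
        self.edges = df
        self._targets_of = {
            m: set(sub["target"]) for m, sub in df.groupby("mirna")
        }
        self._mirnas_targeting = {
            t: set(sub["mirna"]) for t, sub in df.groupby("target")
        }

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def mirnas(self) -> set[str]:
        return set(self._targets_of)

    def targets_of(self, mirna: str) -> set[str]:
        return set(self._targets_of.get(mirna, set()))

    def mirnas_targeting(self, target: str) -> set[str]:
        return set(self._mirnas_targeting.get(target, set()))


@dataclass
class ClinicalTable:
    """Per-patient overall survival: time (> 0) and event (1=death, 0=censored)."""

    records: pd.DataFrame  # columns: sample_id, time, event

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=["sample_id", "time", "event"])
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate clinical record for sample {dup!r}")
        times = pd.to_numeric(df["time"], errors="coerce")
        if times.isna().any() or (times <= 0).any():
            bad = df.loc[times.isna() | (times <= 0), "sample_id"].iloc[0]
            raise FormatError(f"non-positive or missing time for sample {bad!r}")
        events = pd.to_numeric(df["event"], errors="coerce")
        if not events.isin([0, 1]).all():
            bad = df.loc[~events.isin([0, 1]), "sample_id"].iloc[0]
            raise FormatError(f"event not in {{0,1}} for sample {bad!r}")
        df = df.assign(time=times.astype(float), event=events.astype(int))
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records["sample_id"])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty file")
    return df


def _check_header_duplicates(path: Path) -> None:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise FormatError(f"{path}: duplicate column {name!r}")
        seen.add(name)


def read_count_matrix(
    counts_path: str | Path,
    groups: str | Path | Mapping[str, str] | pd.Series,
    annotation: GeneAnnotation | None = None,
) -> CountMatrix:
    """Read a genes-x-samples count TSV plus its sample-group table.

    ``groups`` may be a path to a two-column ``sample_id``/``group`` TSV or an
    in-memory mapping.  When an annotation is supplied, every gene in the
    matrix must be annotated.
    """
    counts_path = Path(counts_path)
    _check_header_duplicates(counts_path)
    df = _read_tsv(counts_path, index_col=0)
    if df.empty:
        raise FormatError(f"{counts_path}: no data rows")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            gene = df.index[coerced.isna()][0]
            raise FormatError(
                f"{counts_path}: non-numeric count for gene {gene!r} in sample {col!r}"
            )
        df[col] = coerced
    if isinstance(groups, (str, Path)):
        gdf = _read_tsv(groups)
        _require_columns(gdf, ["sample_id", "group"], groups)
        groups = pd.Series(gdf["group"].values, index=gdf["sample_id"].values)
    cm = CountMatrix(df, pd.Series(groups))
    if annotation is not None:
        missing = [g for g in cm.gene_ids if g not in annotation]
        if missing:
            raise FormatError(
                f"{counts_path}: gene(s) missing from annotation, e.g. {missing[0]!r}"
            )
    return cm


def write_count_matrix(
    matrix: CountMatrix, counts_path: str | Path, groups_path: str | Path
) -> None:
    matrix.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    matrix.sample_groups.rename_axis("sample_id").rename("group").to_csv(
        groups_path, sep="\t"
    )


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    df = _read_tsv(path)
    _require_columns(df, ["gene_id", "biotype"], path)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate annotation for gene {dup!r}")
    return GeneAnnotation(pd.Series(df["biotype"].values, index=df["gene_id"].values))


def write_gene_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    annotation.biotypes.rename_axis("gene_id").rename("biotype").to_csv(
        path, sep="\t"
    )


def read_interaction_table(path: str | Path) -> InteractionTable:
    df = _read_tsv(path)
    _require_columns(df, ["mirna", "target"], path)
    return InteractionTable(df[["mirna", "target"]])


def write_interaction_table(table: InteractionTable, path: str | Path) -> None:
    table.edges.to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "time", "event"], path)
    return ClinicalTable(df[["sample_id", "time", "event"]])


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Network export (Cytoscape SIF / GraphML)
# ---------------------------------------------------------------------------

SIF = "sif"
GRAPHML = "graphml"


def _as_graph(network) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    graph = getattr(network, "graph", None)
    if isinstance(graph, nx.Graph):
        return graph
    raise UsageError("write_network expects a networkx graph or a CeRNANetwork")


def write_network(network, path: str | Path, fmt: str = SIF) -> None:
    """Export a ceRNA network as Cytoscape SIF or GraphML.

    SIF rows are ``source<TAB>relation<TAB>target`` with relations ``lnc_mir``
    and ``mir_mrna``; GraphML carries a ``biotype`` node attribute and
    ``kind``/``evidence`` edge attributes.
    """
    graph = _as_graph(network)
    path = Path(path)
    if fmt == SIF:
        lines = []
        for u, v, data in sorted(graph.edges(data=True)):
            kind = data.get("kind", "interacts")
            # SIF convention: write lnc->mir and mir->mrna left to right
            if kind == "mir_mrna" and graph.nodes[v].get("biotype") == MIRNA:
                u, v = v, u
            if kind == "lnc_mir" and graph.nodes[u].get("biotype") == MIRNA:
                u, v = v, u
            lines.append(f"{u}\t{kind}\t{v}")
        path.write_text("".join(line + "\n" for line in sorted(lines)), encoding="utf-8")
    elif fmt == GRAPHML:
        nx.write_graphml(graph, path, named_key_ids=True)
    else:
        raise UsageError(f"unknown network format {fmt!r}; use 'sif' or 'graphml'")


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(path))
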