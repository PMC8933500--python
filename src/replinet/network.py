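"""Replication-network inference from pairwise fold-replication assays.

A translation-uncoupled replication assay measures how much of a template
RNA *i* is synthesized by the replicase translated from a host RNA *j*:
the fold replication is the concentration ratio after versus before the
replication incubation, normalized by a template-only negative control.
Mean folds above a threshold (default 1.5) define the directed replicator
graph (edge: replicase source j -> replicated template i, display width
log2 of the fold). Treating replication as a first-order reaction, the
simulator's rate constants are ``k_ij = ln(fold) / reaction_time``, with
parasite columns structurally zero because parasites encode no replicase.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Collection
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FoldReplicationTable",
    "RateMatrix",
    "fold_replication",
    "normalize_rna2_fold",
    "build_graph",
    "rates_from_folds",
    "write_dot",
    "write_graphml",
]


def fold_replication(conc_t0: float, conc_t2: float) -> float:
    """Fold replication of one template over one incubation.

    ``conc_t0`` and ``conc_t2`` are the template concentrations before and
    after the replication step. A fold of 0 (complete loss) is legal but
    flagged as degradation, since the replication model has no decay term.
    """
    if conc_t0 <= 0:
        raise ValueError("conc_t0 must be > 0")
    if conc_t2 < 0:
        raise ValueError("conc_t2 must be >= 0")
    if conc_t2 == 0:
        warnings.warn("fold replication 0: template fully degraded", stacklevel=2)
    return conc_t2 / conc_t0


def normalize_rna2_fold(measured_fold: float, control_fold: float) -> float:
    """Divide a measured fold by the template-only negative-control fold."""
    if control_fold <= 0:
        raise ValueError("control_fold must be > 0")
    return measured_fold / control_fold


@dataclass(frozen=True)
class FoldReplicationTable:
    """Tidy table of fold-replication measurements.

    ``data`` columns: template, source, replicate, fold (alternatively
    conc_t0/conc_t2, converted at load). ``normalized`` records whether the
    folds are already control-divided.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = {"template", "source", "fold"} - set(self.data.columns)
        if missing:
            raise ValueError(f"fold table missing columns: {sorted(missing)}")
        if (self.data["fold"] < 0).any():
            raise ValueError("fold values must be >= 0")

    @classmethod
    def from_csv(cls, path, normalized: bool = False) -> "FoldReplicationTable":
        df = pd.read_csv(path)
        if "fold" not in df.columns:
            if not {"conc_t0", "conc_t2"} <= set(df.columns):
                raise ValueError("need either a 'fold' column or conc_t0/conc_t2")
            df["fold"] = [
                fold_replication(t0, t2) for t0, t2 in zip(df["conc_t0"], df["conc_t2"])
            ]
        if "replicate" not in df.columns:
            df["replicate"] = 1
        return cls(data=df[["template", "source", "replicate", "fold"]], normalized=normalized)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def mean_folds(self) -> pd.DataFrame:
        """Mean fold per (template, source) over replicates (wide layout)."""
        wide = self.data.pivot_table(
            index="template", columns="source", values="fold", aggfunc="mean"
        )
        return wide.reindex(
            index=sorted(self.data["template"].unique()),
            columns=sorted(self.data["source"].unique()),
        )


def build_graph(table: FoldReplicationTable, threshold: float = 1.5) -> nx.DiGraph:
    """Directed replicator graph from mean folds.

    An edge replicase-source ``j`` -> template ``i`` exists iff the mean
    fold strictly exceeds ``threshold``; edge attributes carry the mean
    fold (``fold``) and its binary logarithm (``width``). Pairs measured
    but below threshold are kept as the graph-level ``undetected``
    annotation rather than edges.
    """
    graph = nx.DiGraph()
    if table.data.empty:
        graph.graph["undetected"] = []
        return graph
    means = table.mean_folds()
    graph.add_nodes_from(sorted(set(means.index) | set(means.columns)))
    undetected = []
    for template in means.index:
        for source in means.columns:
            fold = means.loc[template, source]
            if pd.isna(fold):
                continue
            if fold > threshold:
                graph.add_edge(source, template, fold=float(fold), width=math.log2(fold))
            else:
                undetected.append((source, template))
    graph.graph["undetected"] = undetected
    return graph


@dataclass(frozen=True)
class RateMatrix:
    """First-order replication rate constants k_ij (template i, source j)."""

    values: pd.DataFrame
    replicase_sources: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("rate constants must be >= 0")
        silent = [c for c in self.values.columns if c not in self.replicase_sources]
        if silent and self.values[silent].to_numpy().any():
            raise ValueError("non-replicase (parasite) columns must be zero")

    def to_csv(self, path) -> None:
        self.values.to_csv(path)

    @classmethod
    def from_csv(cls, path, replicase_sources: Collection[str] | None = None) -> "RateMatrix":
        df = pd.read_csv(path, index_col=0)
        if replicase_sources is None:
            replicase_sources = [c for c in df.columns if df[c].to_numpy().any()]
        return cls(values=df, replicase_sources=tuple(replicase_sources))

    def to_array(self, species: Collection[str] | None = None) -> np.ndarray:
        order = list(species) if species is not None else list(self.values.index)
        return self.values.reindex(index=order, columns=order).fillna(0.0).to_numpy()


def rates_from_folds(
    table: FoldReplicationTable,
    reaction_time: float = 1.0,
    replicase_sources: Collection[str] | None = None,
) -> RateMatrix:
    """Rate matrix from mean folds: ``k_ij = ln(mean fold) / reaction_time``.

    Folds in (0, 1] map to k = 0 with a warning — the replication model has
    no decay term, so apparent shrinkage carries no rate information.
    Columns outside ``replicase_sources`` (parasites, which show no
    translation activity) are structurally zero regardless of the measured
    folds; ``None`` treats every source as replicase-encoding.
    """
    if reaction_time <= 0:
        raise ValueError("reaction_time must be > 0")
    means = table.mean_folds()
    if (means.to_numpy() <= 0).any():
        raise ValueError("mean folds must be > 0 to infer rates")
    if (means.to_numpy() <= 1).any():
        warnings.warn(
            "mean folds <= 1 mapped to rate 0 (no decay term in the model)",
            stacklevel=2,
        )
    k = np.log(means.to_numpy()) / reaction_time
    k = np.clip(k, 0.0, None)
    values = pd.DataFrame(k, index=means.index, columns=means.columns)
    if replicase_sources is None:
        replicase_sources = tuple(means.columns)
    else:
        replicase_sources = tuple(replicase_sources)
        silent = [c for c in values.columns if c not in replicase_sources]
        values[silent] = 0.0
    return RateMatrix(values=values, replicase_sources=replicase_sources)


def write_graphml(graph: nx.DiGraph, path) -> None:
    """GraphML export (the undetected-pair annotation becomes a string)."""
    g = graph.copy()
    g.graph["undetected"] = ";".join(f"{s}->{t}" for s, t in g.graph.get("undetected", []))
    nx.write_graphml(g, str(path))


def write_dot(graph: nx.DiGraph, path) -> None:
    """Minimal DOT export with penwidth proportional to log2 fold."""
    lines = ["digraph replicators {"]
    for node in graph.nodes:
        lines.append(f'    "{node}";')
    for u, v, attrs in graph.edges(data=True):
        width = attrs.get("width", 1.0)
        fold = attrs.get("fold", float("nan"))
        lines.append(f'    "{u}" -> "{v}" [penwidth={width:.3f}, label="{fold:.2f}"];')
    for s, t in graph.graph.get("undetected", []):
        lines.append(f'    "{s}" -> "{t}" [style=dashed, color=gray];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
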