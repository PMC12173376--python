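"""Stage-wise perturbation dynamics and network centrality.

Each disease stage is contrasted against control with the moderated-t
pipeline; a gene's *onset* is the earliest stage at which its adjusted p
falls below alpha.  Pathway-level stage proportions partition the affected
genes of a pathway by onset stage.  Centrality of stage-annotated interaction
networks uses exact degree and unnormalized betweenness over unordered node
pairs (endpoints excluded, co-minimal shortest paths share credit equally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .annotation_io import ExpressionStudy, InteractionNetwork
from .diffexp import de_table

logger = logging.getLogger("proteosig.progression")


@dataclass
class StageResult:
    """Per-stage DE tables plus the per-gene onset stage (or None)."""

    stages: list[str]
    tables: dict[str, pd.DataFrame]
    onset: dict[str, Optional[str]]

    def affected(self) -> set[str]:
        return {g for g, s in self.onset.items() if s is not None}


def stagewise_de(study: ExpressionStudy, stages: Sequence[str], control: str,
                 alpha: float = 0.05) -> StageResult:
    """One stage-vs-control moderated-t contrast per stage; onset = earliest hit."""
    for lab in [*stages, control]:
        if lab not in study.conditions:
            raise ValueError(f"stage/condition {lab!r} absent from metadata")
    tables = {s: de_table(study, (s, control), direction_alpha=alpha) for s in stages}
    onset: dict[str, Optional[str]] = {}
    for g in study.genes:
        onset[g] = None
        for s in stages:
            tab = tables[s]
            if g in tab.index and tab.at[g, "adj_p"] < alpha:
                onset[g] = s
                break
    return StageResult(stages=list(stages), tables=tables, onset=onset)


def stage_proportions(result: StageResult, pathway_genes,
                      mode: str = "onset") -> pd.Series:
    """Proportion of a pathway's affected genes attributed to each stage.

    ``mode="onset"`` (default) partitions genes by first-significant stage so
    proportions sum to 1; ``mode="any-stage"`` counts a gene at every stage
    where it is significant (denominator = number of affected genes).
    Returns all-NaN when no pathway gene is affected.
    """
    if mode not in ("onset", "any-stage"):
        raise ValueError("mode must be 'onset' or 'any-stage'")
    pathway_genes = set(pathway_genes)
    if not pathway_genes:
        raise ValueError("pathway_genes is empty")
    affected = result.affected() & pathway_genes
    if not affected:
        logger.warning("no affected pathway genes; proportions reported missing")
        return pd.Series(np.nan, index=result.stages)
    if mode == "onset":
        counts = {s: sum(1 for g in affected if result.onset[g] == s)
                  for s in result.stages}
    else:
        counts = {}
        for s in result.stages:
            tab = result.tables[s]
            counts[s] = sum(1 for g in affected
                            if g in tab.index and tab.at[g, "direction"] != 0)
    return pd.Series({s: counts[s] / len(affected) for s in result.stages})


def _to_graph(net: InteractionNetwork) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(sorted(net.nodes))
    G.add_edges_from(sorted(net.edges))
    return G


def centrality(net: InteractionNetwork) -> pd.DataFrame:
    """Exact degree and unnormalized betweenness (unordered-pair counts).

    Disconnected graphs are fine: unreachable pairs contribute nothing.
    A star center with L leaves scores betweenness C(L, 2); nodes on a
    4-cycle score 0.5 each.
    """
    G = _to_graph(net)
    deg = dict(G.degree())
    btw = nx.betweenness_centrality(G, normalized=False)
    nodes = sorted(net.nodes)
    return pd.DataFrame({
        "degree": [deg[n] for n in nodes],
        "betweenness": [float(btw[n]) for n in nodes],
    }, index=pd.Index(nodes, name="node"))


def stage_centrality_summary(
    net: InteractionNetwork,
    metrics: Sequence[str] = ("degree", "betweenness"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stage quartiles of node centrality plus pairwise rank-sum tests.

    Quartiles use linear interpolation.  The two-sided Mann-Whitney
    comparisons between stage groups are exploratory descriptors of the
    boxplot separation, not confirmatory tests.  Stages with no nodes are
    omitted with a warning.
    """
    if net.stage_of is None:
        raise ValueError("network carries no stage annotation")
    cent = centrality(net)
    staged = {n: s for n, s in net.stage_of.items() if n in cent.index}
    stage_labels = sorted(set(staged.values()))
    groups = {s: [n for n, lab in staged.items() if lab == s] for s in stage_labels}
    groups = {s: ns for s, ns in groups.items() if ns}
    if len(groups) < len(stage_labels):
        logger.warning("omitting empty stage group(s)")

    rows = []
    for s, nodes in groups.items():
        for m in metrics:
            v = cent.loc[nodes, m].to_numpy(float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append({"stage": s, "metric": m, "n": len(nodes),
                         "q1": q1, "median": med, "q3": q3})
    quart = pd.DataFrame(rows)

    tests = []
    labels = list(groups)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            for m in metrics:
                va = cent.loc[groups[a], m].to_numpy(float)
                vb = cent.loc[groups[b], m].to_numpy(float)
                p = float(mannwhitneyu(va, vb, alternative="two-sided").pvalue)
                tests.append({"stage_a": a, "stage_b": b, "metric": m,
                              "p": p, "exploratory": True})
    return quart, pd.DataFrame(tests)
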