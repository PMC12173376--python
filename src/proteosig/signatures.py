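"""Disease similarity, hierarchical clustering and gene-wise consensus signatures.

Similarity between diseases is the Jaccard index of their gene sets; the
resulting matrix is clustered agglomeratively on distance 1 - J with complete
linkage.  A consensus signature summarizes, per proteostasis pathway, the mean
perturbation sign of each gene across a cluster of signed disease sets.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .annotation_io import DiseaseGeneSet, PNAnnotation

logger = logging.getLogger("proteosig.signatures")


def jaccard(a, b) -> float:
    """|a ∩ b| / |a ∪ b|; 0 when both sets are empty (logged)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        logger.info("jaccard of two empty sets defined as 0")
        return 0.0
    return len(a & b) / len(union)


def similarity_matrix(sets: Sequence[DiseaseGeneSet]) -> pd.DataFrame:
    """Symmetric disease x disease Jaccard matrix with unit diagonal."""
    ids = [s.disease_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate disease ids")
    members = [s.gene_set() for s in sets]
    m = len(ids)
    vals = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            vals[i, j] = vals[j, i] = jaccard(members[i], members[j])
    return pd.DataFrame(vals, index=ids, columns=ids)


def cluster_diseases(sim: pd.DataFrame, n_clusters: int,
                     method: str = "complete") -> dict[str, int]:
    """Cut an agglomerative tree on distance 1 - J into ``n_clusters`` groups.

    Ids are processed in lexicographic order so the result is independent of
    input order; cluster ids are 1..n_clusters in order of first appearance.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > sim.shape[0]:
        raise ValueError("more clusters than diseases")
    ids = sorted(sim.index)
    dist = 1.0 - sim.loc[ids, ids].to_numpy()
    np.fill_diagonal(dist, 0.0)
    if len(ids) == 1:
        return {ids[0]: 1}
    Z = linkage(squareform(dist, checks=False), method=method)
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for d, c in zip(ids, raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        out[d] = relabel[c]
    return out


def consensus_signature(cluster_sets: Sequence[DiseaseGeneSet],
                        ann: PNAnnotation, pathway: str) -> pd.DataFrame:
    """Gene-wise mean perturbation sign over a cluster, for one PN pathway.

    Returns a DataFrame indexed by gene (sorted) with columns ``value`` (mean
    of available signs, in [-1, 1]) and ``support`` (number of sets carrying
    the gene).  Only genes of ``pathway`` appearing in >= 1 set are included.
    """
    signed = [s for s in cluster_sets if s.sign_of]
    if not signed:
        raise ValueError("no signed gene sets in cluster")
    if pathway not in ann.pathway_vocab:
        raise ValueError(f"unknown pathway {pathway!r}")
    members = ann.pathway_genes(pathway)
    acc: dict[str, list[int]] = {}
    for s in signed:
        for g in s.genes:
            if g in members and g in s.sign_of:
                acc.setdefault(g, []).append(s.sign_of[g])
    genes = sorted(acc)
    return pd.DataFrame({
        "value": [float(np.mean(acc[g])) for g in genes],
        "support": [len(acc[g]) for g in genes],
    }, index=pd.Index(genes, name="gene"))


def directional_similarity(signs_a: Mapping[str, int],
                           signs_b: Mapping[str, int]) -> tuple[float | None, int]:
    """Fraction of shared signed genes perturbed in the same direction.

    Returns ``(ds, overlap)``; ``ds`` is None (missing) when the overlap is
    empty.  Zero signs are rejected — directions must be called upstream.
    """
    for m in (signs_a, signs_b):
        bad = set(m.values()) - {-1, 1}
        if bad:
            raise ValueError(f"signs must be -1/+1, got {sorted(bad)}")
    overlap = set(signs_a) & set(signs_b)
    if not overlap:
        return None, 0
    agree = sum(1 for g in overlap if signs_a[g] == signs_b[g])
    return agree / len(overlap), len(overlap)
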