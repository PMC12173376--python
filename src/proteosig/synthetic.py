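"""Seeded synthetic-data generators with planted, recoverable structure.

Every pipeline input has a generator here: an annotated gene universe with
control protein groups, top-k disease gene sets with planted pathway
enrichment and signed perturbation directions, block-structured disease
panels for clustering, staged expression matrices with "early" or
"progressive" effect schedules, exposure studies with tunable directional
concordance, and interaction graphs with designated hub stages.

Defaults echo the scale of real pan-disease analyses: a 20,000-gene
annotated universe with a 2,500-gene proteostasis network split into four
pathways, 500-gene disease sets, and an oversampling multiplier of 3 for a
disease state's enriched pathways.  Expression defaults (log2 effect 1.0,
noise SD 0.5, 10 samples per group) represent a clearly-powered microarray
contrast; DE calibration simulations use 3+3 samples to probe the
small-cohort regime.

Determinism: every generator call draws from its own RNG stream derived from
``(seed, call-name)``, so adding a generator never perturbs another's output
and the same (spec, seed) reproduces outputs exactly.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_io import (DiseaseGeneSet, ExpressionStudy, GeneUniverse,
                            InteractionNetwork, PNAnnotation)
from .profiling import ALP, EXTRACELLULAR, UPS, StateLabel

PROTEOSTASIS_REGULATION = "PROTEOSTASIS_REGULATION"

#: functional classes nested inside each synthetic pathway
PATHWAY_CLASSES: dict[str, tuple[str, ...]] = {
    ALP: ("AUTOPHAGY_MACHINERY", "LYSOSOMAL_ENZYMES"),
    UPS: ("UPS_E3_LIGASES", "UPS_UBIQUITIN_BINDING", "UPS_PROTEASOME"),
    EXTRACELLULAR: ("EXTRACELLULAR_CHAPERONES", "EXTRACELLULAR_PROTEASES"),
    PROTEOSTASIS_REGULATION: ("MOLECULAR_CHAPERONES", "STRESS_RESPONSE_TFS"),
}

#: pathways planted as enriched for each proteostasis state (ALP always)
STATE_PATHWAYS: dict[StateLabel, frozenset[str]] = {
    StateLabel.STATE_I_ALP_UPS_ERneg: frozenset({ALP, UPS}),
    StateLabel.STATE_II_ALP_UPS_ERpos: frozenset({ALP, UPS, EXTRACELLULAR}),
    StateLabel.STATE_III_ALP_ERpos: frozenset({ALP, EXTRACELLULAR}),
}

#: sign orientation of each state's perturbation relative to the shared base
#: signature; neurodegeneration (state II) runs opposite to cancers (state I)
STATE_ORIENTATION: dict[StateLabel, int] = {
    StateLabel.STATE_I_ALP_UPS_ERneg: +1,
    StateLabel.STATE_II_ALP_UPS_ERpos: -1,
    StateLabel.STATE_III_ALP_ERpos: +1,
}

STATE_GROUP: dict[StateLabel, str] = {
    StateLabel.STATE_I_ALP_UPS_ERneg: "CANCER",
    StateLabel.STATE_II_ALP_UPS_ERpos: "NEURODEGENERATIVE",
    StateLabel.STATE_III_ALP_ERpos: "OTHER",
}


@dataclass
class SyntheticSpec:
    """Study conditions for all generators; every output is a function of (spec, seed)."""

    n_genes: int = 20000
    pn_size: int = 2500
    pathway_sizes: dict[str, int] = field(default_factory=lambda: {
        ALP: 800, UPS: 700, EXTRACELLULAR: 500, PROTEOSTASIS_REGULATION: 500})
    group_sizes: dict[str, int] = field(default_factory=lambda: {
        "KINASE": 500, "TF": 1400, "ION_CHANNEL": 330})
    k: int = 500                    # disease gene set size
    enrich_rate: float = 3.0        # sampling weight of enriched-pathway genes
    c_intra: float = 0.9            # within-cluster sign concordance
    effect_size: float = 1.0        # log2 expression shift of affected genes
    noise_sd: float = 0.5           # residual log2 SD
    n_per_group: int = 10           # samples per condition in staged/exposure studies
    n_stages: int = 3
    expr_genes: int = 2000          # gene panel size of simulated matrices
    var_prior_df: float = 4.0       # d0 of the gene-wise variance prior in DE sims
    seed: int = 0

    def __post_init__(self):
        if sum(self.pathway_sizes.values()) > self.pn_size:
            raise ValueError("pathway sizes exceed pn_size")
        if self.pn_size + sum(self.group_sizes.values()) > self.n_genes:
            raise ValueError("group sizes exceed the universe")
        if self.enrich_rate < 1:
            raise ValueError("enrich_rate must be >= 1")
        if not (0.0 <= self.c_intra <= 1.0):
            raise ValueError("c_intra must lie in [0,1]")
        if self.k > self.n_genes:
            raise ValueError("k exceeds the universe")


def _rng(spec: SyntheticSpec, name: str) -> np.random.Generator:
    """Independent stream for one generator call, keyed by (seed, call-name)."""
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed & 0x7FFFFFFF, zlib.crc32(name.encode())]))


def _symbols(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def make_universe(spec: SyntheticSpec) -> tuple[GeneUniverse, PNAnnotation,
                                                dict[str, frozenset[str]]]:
    """Annotated universe, PN annotation and disjoint control-group lists."""
    rng = _rng(spec, "make_universe")
    genes = _symbols(spec.n_genes)
    order = rng.permutation(spec.n_genes)
    pn = [genes[i] for i in order[:spec.pn_size]]
    cursor = spec.pn_size
    groups: dict[str, frozenset[str]] = {}
    for gname, size in spec.group_sizes.items():
        groups[gname] = frozenset(genes[i] for i in order[cursor:cursor + size])
        cursor += size

    pathway_of: dict[str, frozenset[str]] = {}
    class_of: dict[str, frozenset[str]] = {}
    c2p: dict[str, str] = {}
    cvocab: list[str] = []
    start = 0
    for pw, size in spec.pathway_sizes.items():
        members = pn[start:start + size]
        start += size
        classes = PATHWAY_CLASSES.get(pw, (f"{pw}_CLASS_A", f"{pw}_CLASS_B"))
        splits = np.array_split(np.arange(len(members)), len(classes))
        for cls, idx in zip(classes, splits):
            cvocab.append(cls)
            c2p[cls] = pw
            for i in idx:
                g = members[i]
                pathway_of[g] = frozenset({pw})
                class_of[g] = frozenset({cls})
    # PN genes beyond the explicit pathway partition (if any) go to regulation
    for g in pn[start:]:
        pathway_of[g] = frozenset({PROTEOSTASIS_REGULATION})

    labels: dict[str, frozenset[str]] = {g: frozenset({"PN"}) for g in pn}
    for gname, members in groups.items():
        for g in members:
            labels[g] = frozenset({gname})
    universe = GeneUniverse(genes=frozenset(genes), group_labels=labels)
    ann = PNAnnotation(pathway_of=pathway_of, class_of=class_of,
                       pathway_vocab=tuple(spec.pathway_sizes),
                       class_vocab=tuple(cvocab), class_to_pathway=c2p)
    return universe, ann, groups


def base_signature(spec: SyntheticSpec, ann: PNAnnotation) -> dict[str, int]:
    """Shared +-1 reference sign per PN gene; states orient it via STATE_ORIENTATION."""
    rng = _rng(spec, "base_signature")
    return {g: int(s) for g, s in
            zip(sorted(ann.genes), rng.choice([-1, 1], size=len(ann.genes)))}


def _weighted_sample_without_replacement(rng: np.random.Generator,
                                         items: Sequence[str],
                                         weights: np.ndarray, k: int) -> list[str]:
    """Efraimidis-Spirakis reservoir keys: k smallest Exp(1)/w."""
    keys = rng.exponential(1.0, size=len(items)) / weights
    idx = np.argsort(keys, kind="stable")[:k]
    return [items[i] for i in idx]


def make_disease_set(spec: SyntheticSpec, disease_id: str, state: StateLabel,
                     universe: GeneUniverse, ann: PNAnnotation,
                     base_signs: Optional[Mapping[str, int]] = None) -> DiseaseGeneSet:
    """Top-k disease set with the state's pathways oversampled and signed genes.

    Genes of the state's enriched pathways carry sampling weight
    ``enrich_rate``; all other genes weight 1.  PN gene signs follow the
    state-oriented base signature, flipped independently with probability
    (1 - c_intra)/2; non-PN genes get random signs.
    """
    if state not in STATE_PATHWAYS:
        raise ValueError(f"state {state} has no planted-pathway definition")
    rng = _rng(spec, f"make_disease_set:{disease_id}")
    if base_signs is None:
        base_signs = base_signature(spec, ann)
    enriched = set()
    for pw in STATE_PATHWAYS[state]:
        enriched |= ann.pathway_genes(pw)
    genes = sorted(universe.genes)
    weights = np.where(np.isin(genes, sorted(enriched)), spec.enrich_rate, 1.0)
    chosen = _weighted_sample_without_replacement(rng, genes, weights, spec.k)
    orient = STATE_ORIENTATION[state]
    flip_p = (1.0 - spec.c_intra) / 2.0
    signs: dict[str, int] = {}
    for g in chosen:
        if g in base_signs:
            s = base_signs[g] * orient
            if rng.random() < flip_p:
                s = -s
        else:
            s = int(rng.choice([-1, 1]))
        signs[g] = int(s)
    return DiseaseGeneSet(disease_id=disease_id, genes=chosen,
                          disease_group=STATE_GROUP[state], sign_of=signs)


def default_state_plan(n_per_state: int = 10) -> dict[str, StateLabel]:
    """30 diseases, 10 per proteostasis state, D01..D30."""
    plan: dict[str, StateLabel] = {}
    states = [StateLabel.STATE_I_ALP_UPS_ERneg, StateLabel.STATE_II_ALP_UPS_ERpos,
              StateLabel.STATE_III_ALP_ERpos]
    i = 1
    for st in states:
        for _ in range(n_per_state):
            plan[f"D{i:02d}"] = st
            i += 1
    return plan


def make_disease_panel(spec: SyntheticSpec, universe: GeneUniverse,
                       ann: PNAnnotation,
                       state_plan: Optional[Mapping[str, StateLabel]] = None
                       ) -> list[DiseaseGeneSet]:
    """One signed disease set per entry of ``state_plan`` (default 30, 10/state)."""
    plan = dict(state_plan) if state_plan is not None else default_state_plan()
    base = base_signature(spec, ann)
    return [make_disease_set(spec, did, st, universe, ann, base)
            for did, st in plan.items()]


def make_cluster_panel(spec: SyntheticSpec, universe: GeneUniverse,
                       ann: PNAnnotation, n_clusters: int = 4,
                       per_cluster: int = 4, core_frac: float = 0.6
                       ) -> tuple[list[DiseaseGeneSet], dict[str, int]]:
    """Disease panel with planted block structure in gene membership.

    Each cluster shares a core of ``core_frac * k`` genes; the remainder of
    every member set is drawn uniformly.  Within-cluster Jaccard is therefore
    >= roughly core_frac/(2 - core_frac) (~0.43 at the default 0.6) while
    between-cluster similarity stays near zero.  Cluster sign orientations
    alternate (+, -, +, -, ...) around the shared base signature, so
    consecutive clusters have opposing consensus signatures.
    """
    if not (0.0 < core_frac <= 1.0):
        raise ValueError("core_frac must lie in (0, 1]")
    rng = _rng(spec, "make_cluster_panel")
    base = base_signature(spec, ann)
    genes = sorted(universe.genes)
    core_n = int(round(core_frac * spec.k))
    sets: list[DiseaseGeneSet] = []
    labels: dict[str, int] = {}
    flip_p = (1.0 - spec.c_intra) / 2.0
    for ci in range(n_clusters):
        core = [genes[i] for i in rng.choice(len(genes), size=core_n, replace=False)]
        core_set = set(core)
        remaining = [g for g in genes if g not in core_set]
        orient = 1 if ci % 2 == 0 else -1
        for mi in range(per_cluster):
            did = f"C{ci + 1}_{mi + 1}"
            extra_idx = rng.choice(len(remaining), size=spec.k - core_n, replace=False)
            members = core + [remaining[i] for i in extra_idx]
            signs: dict[str, int] = {}
            for g in members:
                if g in base:
                    s = base[g] * orient
                    if rng.random() < flip_p:
                        s = -s
                else:
                    s = int(rng.choice([-1, 1]))
                signs[g] = int(s)
            sets.append(DiseaseGeneSet(disease_id=did, genes=members,
                                       disease_group=f"CLUSTER_{ci + 1}",
                                       sign_of=signs))
            labels[did] = ci + 1
    return sets, labels


# ---------------------------------------------------------------------------
# expression simulators
# ---------------------------------------------------------------------------

def _gene_panel(spec: SyntheticSpec, universe: GeneUniverse,
                affected: Sequence[str]) -> list[str]:
    """Affected genes first, padded with unaffected universe genes to expr_genes."""
    affected = list(affected)
    fill = [g for g in sorted(universe.genes) if g not in set(affected)]
    need = max(0, spec.expr_genes - len(affected))
    return affected + fill[:need]


def make_staged_expression(spec: SyntheticSpec, affected_signs: Mapping[str, int],
                           universe: GeneUniverse, schedule: str,
                           n_stages: Optional[int] = None) -> ExpressionStudy:
    """Staged log2 expression with an "early" or "progressive" effect schedule.

    Baselines are mu_g ~ U(4, 12) with N(0, noise_sd) residuals; an affected
    gene g is shifted in stage s by ``sign_g * effect_size * w_s`` where
    w_s = 1 for "early" and w_s = s/S for "progressive".  Controls are
    unshifted.  Residual SD is constant across genes here so that schedule
    recovery reflects the planted effect sizes alone.
    """
    if schedule not in ("early", "progressive"):
        raise ValueError(f"unknown schedule {schedule!r}")
    S = n_stages or spec.n_stages
    rng = _rng(spec, f"make_staged_expression:{schedule}")
    panel = _gene_panel(spec, universe, sorted(affected_signs))
    G = len(panel)
    n = spec.n_per_group
    conditions = ["CONTROL"] + [f"STAGE_{s}" for s in range(1, S + 1)]
    mu = rng.uniform(4.0, 12.0, size=G)
    cols: dict[str, np.ndarray] = {}
    cond_map: dict[str, str] = {}
    sign_vec = np.array([affected_signs.get(g, 0) for g in panel], dtype=float)
    for ci, cond in enumerate(conditions):
        w = 0.0 if cond == "CONTROL" else (
            1.0 if schedule == "early" else (ci / S))
        shift = sign_vec * spec.effect_size * w
        for r in range(n):
            sample = f"{cond}_{r + 1}"
            cols[sample] = mu + shift + rng.normal(0.0, spec.noise_sd, size=G)
            cond_map[sample] = cond
    matrix = pd.DataFrame(cols, index=pd.Index(panel, name="gene"))
    return ExpressionStudy(matrix=matrix, sample_condition=cond_map)


def make_de_study(spec: SyntheticSpec, n_genes: Optional[int] = None,
                  n_a: int = 3, n_b: int = 3, frac_de: float = 0.0,
                  effect_sd_units: float = 2.0, heteroskedastic: bool = True,
                  stream: str = "make_de_study"
                  ) -> tuple[ExpressionStudy, dict[str, int]]:
    """Two-group study for DE calibration: null (frac_de=0) or planted DE.

    Gene-wise residual variances follow the scaled inverse-chi-square prior
    (df ``var_prior_df``, scale ``noise_sd**2``) when ``heteroskedastic``;
    affected genes are shifted by ``effect_sd_units * noise_sd`` with random
    sign.  Returns the study and the truth map gene -> planted sign.
    """
    rng = _rng(spec, stream)
    G = n_genes or spec.expr_genes
    genes = _symbols(G)
    d0 = spec.var_prior_df
    if heteroskedastic:
        sigma2 = spec.noise_sd ** 2 * d0 / rng.chisquare(d0, size=G)
    else:
        sigma2 = np.full(G, spec.noise_sd ** 2)
    n_de = int(round(frac_de * G))
    de_idx = rng.choice(G, size=n_de, replace=False) if n_de else np.array([], int)
    signs = np.zeros(G)
    signs[de_idx] = rng.choice([-1.0, 1.0], size=n_de)
    delta = signs * effect_sd_units * spec.noise_sd
    mu = rng.uniform(4.0, 12.0, size=G)
    cols: dict[str, np.ndarray] = {}
    cond: dict[str, str] = {}
    sd = np.sqrt(sigma2)
    for r in range(n_a):
        s = f"A_{r + 1}"
        cols[s] = mu + delta + rng.normal(0.0, 1.0, size=G) * sd
        cond[s] = "A"
    for r in range(n_b):
        s = f"B_{r + 1}"
        cols[s] = mu + rng.normal(0.0, 1.0, size=G) * sd
        cond[s] = "B"
    matrix = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    truth = {genes[i]: int(signs[i]) for i in de_idx}
    return ExpressionStudy(matrix=matrix, sample_condition=cond), truth


def make_exposure_study(spec: SyntheticSpec, target_signs: Mapping[str, int],
                        universe: GeneUniverse, concordance: float,
                        perturb_frac: float = 0.8, n_extra: int = 200,
                        stream: str = "make_exposure_study"
                        ) -> tuple[ExpressionStudy, dict[str, int]]:
    """Exposure-vs-control study perturbing a fraction of a disease's PN genes.

    Each perturbed target gene moves in the disease's direction with
    probability ``concordance``, opposite otherwise; ``n_extra`` additional
    random universe genes are perturbed with random signs (they feed control
    baselines).  Returns the study and the truth map of planted signs.
    """
    if not (0.0 <= concordance <= 1.0):
        raise ValueError("concordance must lie in [0,1]")
    rng = _rng(spec, stream)
    targets = sorted(target_signs)
    n_hit = int(round(perturb_frac * len(targets)))
    hit = [targets[i] for i in rng.choice(len(targets), size=n_hit, replace=False)]
    truth: dict[str, int] = {}
    for g in hit:
        agree = rng.random() < concordance
        truth[g] = int(target_signs[g] if agree else -target_signs[g])
    pool = [g for g in sorted(universe.genes) if g not in truth]
    extra_idx = rng.choice(len(pool), size=min(n_extra, len(pool)), replace=False)
    for i in extra_idx:
        truth[pool[i]] = int(rng.choice([-1, 1]))

    panel = _gene_panel(spec, universe, sorted(truth))
    G = len(panel)
    mu = rng.uniform(4.0, 12.0, size=G)
    shift = np.array([truth.get(g, 0) for g in panel], float) * spec.effect_size
    cols: dict[str, np.ndarray] = {}
    cond: dict[str, str] = {}
    for r in range(spec.n_per_group):
        s = f"EXPOSED_{r + 1}"
        cols[s] = mu + shift + rng.normal(0.0, spec.noise_sd, size=G)
        cond[s] = "EXPOSED"
    for r in range(spec.n_per_group):
        s = f"CONTROL_{r + 1}"
        cols[s] = mu + rng.normal(0.0, spec.noise_sd, size=G)
        cond[s] = "CONTROL"
    matrix = pd.DataFrame(cols, index=pd.Index(panel, name="gene"))
    return ExpressionStudy(matrix=matrix, sample_condition=cond), truth


def make_risk_panel(spec: SyntheticSpec, universe: GeneUniverse, ann: PNAnnotation,
                    n_at_risk: int = 4, n_reduced: int = 4,
                    c_at_risk: float = 0.8, c_reduced: float = 0.2,
                    exposure_size: int = 300, n_shared: int = 150
                    ) -> tuple[dict[str, int], list[DiseaseGeneSet], dict[str, float]]:
    """Exposure sign map plus a disease panel with planted per-disease concordance.

    The exposure perturbs ``exposure_size`` PN genes (signs from the base
    signature).  Every disease set embeds ``n_shared`` of those genes; each
    embedded gene carries the exposure's sign with the disease's planted
    concordance (``c_at_risk`` for the first ``n_at_risk`` diseases,
    ``c_reduced`` for the rest).  Remaining genes are drawn uniformly with
    random signs.  Returns (exposure_signs, diseases, concordance_of).
    """
    rng = _rng(spec, "make_risk_panel")
    base = base_signature(spec, ann)
    pn = sorted(ann.genes & universe.genes)
    if exposure_size > len(pn) or n_shared > exposure_size:
        raise ValueError("exposure_size/n_shared infeasible for this PN")
    expo = [pn[i] for i in rng.choice(len(pn), size=exposure_size, replace=False)]
    exposure_signs = {g: base[g] for g in expo}
    others = [g for g in sorted(universe.genes) if g not in exposure_signs]
    diseases: list[DiseaseGeneSet] = []
    conc: dict[str, float] = {}
    cs = [("AT_RISK", c_at_risk)] * n_at_risk + [("REDUCED_RISK", c_reduced)] * n_reduced
    for i, (grp, c) in enumerate(cs):
        did = f"{grp}_{i + 1}"
        shared = [expo[j] for j in rng.choice(len(expo), size=n_shared, replace=False)]
        fill_idx = rng.choice(len(others), size=spec.k - n_shared, replace=False)
        members = shared + [others[j] for j in fill_idx]
        signs: dict[str, int] = {}
        for g in members:
            if g in exposure_signs:
                agree = rng.random() < c
                signs[g] = int(exposure_signs[g] if agree else -exposure_signs[g])
            else:
                signs[g] = int(rng.choice([-1, 1]))
        diseases.append(DiseaseGeneSet(disease_id=did, genes=members,
                                       disease_group=grp, sign_of=signs))
        conc[did] = c
    return exposure_signs, diseases, conc


def make_concordant_signs(spec: SyntheticSpec, n_overlap: int, concordance: float,
                          stream: str = "make_concordant_signs"
                          ) -> tuple[dict[str, int], dict[str, int]]:
    """Two sign maps over a shared gene list agreeing with probability ``concordance``."""
    rng = _rng(spec, stream)
    genes = _symbols(n_overlap)
    a = {g: int(s) for g, s in zip(genes, rng.choice([-1, 1], size=n_overlap))}
    agree = rng.random(n_overlap) < concordance
    b = {g: (a[g] if ok else -a[g]) for g, ok in zip(genes, agree)}
    return a, b


def make_hub_network(spec: SyntheticSpec, node_stages: Mapping[str, str],
                     hub_stage: str = "MID", m_base: int = 2, m_hub: int = 8
                     ) -> InteractionNetwork:
    """Preferential-attachment graph where ``hub_stage`` nodes get extra stubs.

    Nodes arrive in random order; each new node attaches ``m_hub`` (if its
    stage is ``hub_stage``) or ``m_base`` edges to distinct existing nodes
    with probability proportional to current degree (+1 smoothing).
    """
    rng = _rng(spec, "make_hub_network")
    nodes = sorted(node_stages)
    order = [nodes[i] for i in rng.permutation(len(nodes))]
    edges: set[tuple[str, str]] = set()
    degree: dict[str, int] = {}
    existing: list[str] = []
    for v in order:
        m = m_hub if node_stages[v] == hub_stage else m_base
        m = min(m, len(existing))
        if m:
            w = np.array([degree[u] + 1.0 for u in existing])
            targets = _weighted_sample_without_replacement(rng, existing, w, m)
            for u in targets:
                edges.add((u, v) if u < v else (v, u))
                degree[u] = degree.get(u, 0) + 1
                degree[v] = degree.get(v, 0) + 1
        degree.setdefault(v, 0)
        existing.append(v)
    return InteractionNetwork(nodes=set(nodes), edges=edges,
                              stage_of=dict(node_stages))
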