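"""Score an exposure (e.g. smoking) against disease gene sets.

An exposure's perturbed proteostasis set — significant differentially
expressed genes intersected with the PN — is compared to each disease's PN
subset by Jaccard overlap (min-max normalized across the disease panel for
plotting) and by directional similarity on the shared signed genes.  The same
overlap computation on the exposure's kinase/TF subsets and on a size-matched
random sample of significant genes provides control baselines.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_io import DiseaseGeneSet, PNAnnotation
from .signatures import directional_similarity, jaccard

logger = logging.getLogger("proteosig.riskfactor")


def exposure_pn_set(de: pd.DataFrame, ann: PNAnnotation) -> dict[str, int]:
    """Signed PN gene set of an exposure: called directions intersected with PN.

    ``de`` is a moderated-t table with a ``direction`` column (see
    :func:`proteosig.diffexp.moderated_t`).
    """
    if "direction" not in de.columns:
        raise ValueError("DE table has no direction calls")
    sig = de[de["direction"] != 0]
    out = {g: int(s) for g, s in sig["direction"].items() if g in ann.genes}
    if not out:
        logger.warning("exposure has no significant PN genes")
    return out


def _minmax(values: pd.Series) -> pd.Series:
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        logger.warning("all raw similarities equal; normalized values missing")
        return pd.Series(np.nan, index=values.index)
    return (values - lo) / (hi - lo)


def score_exposure(
    exposure_signs: Mapping[str, int],
    diseases: Sequence[DiseaseGeneSet],
    ann: PNAnnotation,
    controls: Optional[Mapping[str, frozenset[str] | set[str]]] = None,
    significant_genes: Optional[Sequence[str]] = None,
    rng_seed: int = 0,
    disease_pn_mode: str = "full",
) -> pd.DataFrame:
    """Compare an exposure's signed PN set against a panel of diseases.

    Per disease: raw Jaccard between the exposure PN set and the disease's PN
    subset, its min-max normalization across the panel, and the directional
    similarity (with overlap size) on shared signed genes.  ``controls`` maps
    group names (e.g. KINASE, TF) to that group's gene universe; the control
    baseline is the Jaccard of the exposure's significant genes within the
    group versus the disease set within the group.  When ``significant_genes``
    is given, a RANDOM control of the same size as the exposure PN set is
    sampled from it with ``rng_seed``.

    ``disease_pn_mode="full"`` (default) uses the whole PN subset of each
    disease set; ``"signed"`` restricts it to PN genes carrying a sign.
    """
    if len(diseases) < 2:
        raise ValueError("normalization needs a panel of >= 2 diseases")
    if disease_pn_mode not in ("full", "signed"):
        raise ValueError("disease_pn_mode must be 'full' or 'signed'")
    exp_set = set(exposure_signs)
    rows = {}
    for d in diseases:
        pn_subset = d.gene_set() & ann.genes
        if disease_pn_mode == "signed":
            pn_subset &= set(d.sign_of or {})
        row = {"jaccard_pn": jaccard(exp_set, pn_subset)}
        if d.sign_of:
            ds, ov = directional_similarity(
                exposure_signs, {g: s for g, s in d.sign_of.items() if g in pn_subset})
            row["ds"], row["overlap"] = ds, ov
        else:
            row["ds"], row["overlap"] = None, 0
        rows[d.disease_id] = row
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "disease"
    report["jaccard_pn_norm"] = _minmax(report["jaccard_pn"])

    controls = controls or {}
    for name, members in controls.items():
        members = set(members)
        # control subsets come from all significant exposure genes when given;
        # the exposure PN set itself excludes non-PN genes
        source = set(significant_genes) if significant_genes is not None else exp_set
        exp_ctl = source & members
        col = []
        for d in diseases:
            col.append(jaccard(exp_ctl, d.gene_set() & members))
        report[f"jaccard_{name}"] = col
        report[f"jaccard_{name}_norm"] = _minmax(report[f"jaccard_{name}"])

    if significant_genes is not None:
        rng = np.random.default_rng(rng_seed)
        pool = sorted(set(significant_genes))
        size = min(len(exp_set), len(pool))
        sample = set(rng.choice(pool, size=size, replace=False)) if size else set()
        col = [jaccard(sample, d.gene_set() & ann.genes) for d in diseases]
        report["jaccard_RANDOM"] = col
        report["jaccard_RANDOM_norm"] = _minmax(report["jaccard_RANDOM"])
    return report
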