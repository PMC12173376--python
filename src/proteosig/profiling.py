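"""Per-disease proteostasis profiles and three-way proteostasis states.

A disease profile records (i) the fraction of the disease gene set that is
proteostasis-network (PN) annotated and (ii) which PN pathways and functional
classes are over-represented in the disease gene set at a raw hypergeometric
p < alpha (default 0.01).

Diseases are then classified by their (UPS, extracellular) flag pattern:

* state I   — UPS enriched, extracellular not (typical of cancers)
* state II  — UPS and extracellular both enriched (neurodegeneration)
* state III — extracellular enriched, UPS not (other disease groups)

The ALP flag is recorded but not discriminative: it is enriched in all three
states.  The UPS-/ER- cell has no named state and maps to UNCLASSIFIED.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotation_io import DiseaseGeneSet, GeneUniverse, PNAnnotation
from .enrichment import hypergeom_upper_tail

logger = logging.getLogger("proteosig.profiling")

UPS = "UPS"
ALP = "ALP"
EXTRACELLULAR = "EXTRACELLULAR"


class StateLabel(enum.Enum):
    """Three-way proteostasis state (plus the unnamed UPS-/ER- residual cell)."""

    STATE_I_ALP_UPS_ERneg = "STATE_I_ALP_UPS_ERneg"
    STATE_II_ALP_UPS_ERpos = "STATE_II_ALP_UPS_ERpos"
    STATE_III_ALP_ERpos = "STATE_III_ALP_ERpos"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class DiseaseProfile:
    """PN fraction plus pathway/class enrichment flags for one disease."""

    disease_id: str
    pn_fraction: float
    pathway_flags: dict[str, bool]
    pathway_p: dict[str, float]
    class_flags: dict[str, bool] = field(default_factory=dict)
    class_p: dict[str, float] = field(default_factory=dict)
    alpha: float = 0.01

    def __post_init__(self):
        if not (0.0 <= self.pn_fraction <= 1.0):
            raise ValueError("pn_fraction out of [0,1]")
        for name, flag in self.pathway_flags.items():
            if flag != (self.pathway_p[name] < self.alpha):
                raise ValueError(f"flag/p mismatch for pathway {name}")


def profile_disease(
    disease_set: DiseaseGeneSet,
    ann: PNAnnotation,
    universe: GeneUniverse,
    alpha: float = 0.01,
    test_universe: str = "global",
) -> DiseaseProfile:
    """Profile one disease gene set against the PN annotation.

    ``pn_fraction`` is |set ∩ PN| / |set ∩ universe| (genes outside the
    universe are ignored).  Pathway/class flags test, at raw p < ``alpha``,
    whether each pathway or class is over-represented:

    * ``test_universe="global"`` (default): query = disease set within the
      whole annotated universe.  This reproduces differential flags — a PN
      branch sampled at background rate stays unflagged even when the PN as
      a whole is over-represented.
    * ``test_universe="pn"``: query = the PN subset of the disease set,
      universe = PN genes; tests the internal composition of the PN subset.
    """
    if test_universe not in ("global", "pn"):
        raise ValueError("test_universe must be 'global' or 'pn'")
    uni = set(universe.genes)
    members = disease_set.gene_set() & uni
    if not members:
        raise ValueError(f"{disease_set.disease_id}: no genes inside the universe")
    pn_genes = ann.genes & uni
    pn_subset = members & pn_genes
    pn_fraction = len(pn_subset) / len(members)

    if test_universe == "global":
        query, bg = members, uni
    else:
        query, bg = pn_subset, pn_genes
    n, N = len(query), len(bg)

    def flags_for(db: Mapping[str, frozenset[str]]):
        flags: dict[str, bool] = {}
        pvals: dict[str, float] = {}
        for name, cat in db.items():
            cat_in = set(cat) & bg
            if n == 0:
                pvals[name], flags[name] = 1.0, False
                continue
            k = len(query & cat_in)
            p = hypergeom_upper_tail(k, len(cat_in), n, N)
            pvals[name] = p
            flags[name] = p < alpha
        return flags, pvals

    if not pn_subset:
        logger.warning("%s: empty PN subset; all flags not-enriched",
                       disease_set.disease_id)
        pflags = {p: False for p in ann.pathway_vocab}
        pp = {p: 1.0 for p in ann.pathway_vocab}
        cflags = {c: False for c in ann.class_vocab}
        cp = {c: 1.0 for c in ann.class_vocab}
        return DiseaseProfile(disease_set.disease_id, 0.0, pflags, pp, cflags, cp, alpha)

    pflags, pp = flags_for(ann.pathway_db())
    cflags, cp = flags_for(ann.class_db())
    return DiseaseProfile(disease_set.disease_id, pn_fraction, pflags, pp, cflags, cp, alpha)


def classify_state(profile: DiseaseProfile) -> StateLabel:
    """Map the (UPS, extracellular) flag pattern to a proteostasis state."""
    for needed in (UPS, EXTRACELLULAR):
        if needed not in profile.pathway_flags:
            raise ValueError(f"profile lacks pathway flag {needed!r}")
    ups = profile.pathway_flags[UPS]
    er = profile.pathway_flags[EXTRACELLULAR]
    if ups and not er:
        return StateLabel.STATE_I_ALP_UPS_ERneg
    if ups and er:
        return StateLabel.STATE_II_ALP_UPS_ERpos
    if er:
        return StateLabel.STATE_III_ALP_ERpos
    return StateLabel.UNCLASSIFIED


def profile_matrix(profiles: Sequence[DiseaseProfile]) -> pd.DataFrame:
    """Binary diseases x (pathways + classes) flag matrix, in vocab order."""
    if not profiles:
        raise ValueError("no profiles")
    pv = list(profiles[0].pathway_flags)
    cv = list(profiles[0].class_flags)
    for pr in profiles[1:]:
        if list(pr.pathway_flags) != pv or list(pr.class_flags) != cv:
            raise ValueError(f"profile {pr.disease_id} has a mismatched vocabulary")
    data = {}
    for pr in profiles:
        data[pr.disease_id] = [int(pr.pathway_flags[p]) for p in pv] + \
                              [int(pr.class_flags[c]) for c in cv]
    return pd.DataFrame.from_dict(data, orient="index", columns=pv + cv)
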