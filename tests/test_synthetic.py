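"""Generator properties: determinism, planted structure, limiting behaviour."""

import numpy as np
import pytest

from proteosig.diffexp import de_table
from proteosig.profiling import StateLabel
from proteosig.riskfactor import exposure_pn_set
from proteosig.signatures import directional_similarity, jaccard
from proteosig.synthetic import (SyntheticSpec, make_concordant_signs,
                                 make_de_study, make_disease_set,
                                 make_exposure_study, make_hub_network,
                                 make_risk_panel, make_staged_expression,
                                 make_universe)

STATE_I = StateLabel.STATE_I_ALP_UPS_ERneg


class TestUniverse:
    def test_default_sizes(self, default_world7):
        _, universe, ann, groups = default_world7
        assert len(universe) == 20000
        assert len(ann.genes) == 2500
        assert len(groups["KINASE"]) == 500

    def test_pathway_partition_sums(self, small_world):
        _, ann, _ = small_world
        sizes = {pw: len(ann.pathway_genes(pw)) for pw in ann.pathway_vocab}
        assert sum(sizes.values()) == 250
        # classes nest inside their pathway
        for cls in ann.class_vocab:
            assert ann.class_genes(cls) <= ann.pathway_genes(ann.class_to_pathway[cls])

    def test_control_groups_disjoint_from_pn(self, small_world):
        universe, ann, groups = small_world
        for members in groups.values():
            assert not (members & ann.genes)

    def test_determinism_same_seed_identical(self, small_spec):
        u1, a1, g1 = make_universe(small_spec)
        u2, a2, g2 = make_universe(small_spec)
        assert u1.genes == u2.genes
        assert a1.pathway_of == a2.pathway_of
        assert g1 == g2

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_genes=100, pn_size=90,
                          group_sizes={"KINASE": 50, "TF": 0, "ION_CHANNEL": 0})


class TestDiseaseSets:
    def test_determinism(self, small_spec, small_world):
        universe, ann, _ = small_world
        a = make_disease_set(small_spec, "D", STATE_I, universe, ann)
        b = make_disease_set(small_spec, "D", STATE_I, universe, ann)
        assert a.genes == b.genes and a.sign_of == b.sign_of

    def test_uniform_rate_matches_binomial_expectation(self, small_world):
        """With enrich_rate=1 the PN fraction matches pn_size/n_genes."""
        universe, ann, _ = small_world
        fracs = []
        for seed in range(40):
            spec = SyntheticSpec(n_genes=2000, pn_size=250,
                                 pathway_sizes={"ALP": 80, "UPS": 70,
                                                "EXTRACELLULAR": 50,
                                                "PROTEOSTASIS_REGULATION": 50},
                                 group_sizes={"KINASE": 60, "TF": 120,
                                              "ION_CHANNEL": 40},
                                 k=200, enrich_rate=1.0, seed=seed)
            s = make_disease_set(spec, "D", STATE_I, universe, ann)
            fracs.append(len(s.gene_set() & ann.genes) / len(s))
        assert np.mean(fracs) == pytest.approx(250 / 2000, abs=0.02)

    def test_extreme_rate_includes_all_pathway_genes(self, small_world):
        universe, ann, _ = small_world
        spec = SyntheticSpec(n_genes=2000, pn_size=250,
                             pathway_sizes={"ALP": 80, "UPS": 70,
                                            "EXTRACELLULAR": 50,
                                            "PROTEOSTASIS_REGULATION": 50},
                             group_sizes={"KINASE": 60, "TF": 120,
                                          "ION_CHANNEL": 40},
                             k=200, enrich_rate=1e9, seed=1)
        s = make_disease_set(spec, "D", STATE_I, universe, ann)
        enriched = ann.pathway_genes("ALP") | ann.pathway_genes("UPS")  # 150 < k
        assert enriched <= s.gene_set()

    def test_signs_cover_all_genes(self, small_spec, small_world):
        universe, ann, _ = small_world
        s = make_disease_set(small_spec, "D", STATE_I, universe, ann)
        assert set(s.sign_of) == set(s.genes)
        assert set(s.sign_of.values()) <= {-1, 1}


class TestExpressionGenerators:
    def test_null_schedule_effect_zero(self, small_world):
        """delta=0: nothing beyond FDR-level false positives is called."""
        universe, ann, _ = small_world
        spec = SyntheticSpec(n_genes=2000, pn_size=250,
                             pathway_sizes={"ALP": 80, "UPS": 70,
                                            "EXTRACELLULAR": 50,
                                            "PROTEOSTASIS_REGULATION": 50},
                             group_sizes={"KINASE": 60, "TF": 120,
                                          "ION_CHANNEL": 40},
                             k=200, expr_genes=400, effect_size=0.0, seed=2)
        signs = {g: 1 for g in sorted(ann.genes)[:40]}
        study = make_staged_expression(spec, signs, universe, "early")
        tab = de_table(study, ("STAGE_1", "CONTROL"))
        assert (tab["adj_p"] < 0.05).sum() <= 2

    def test_unknown_schedule_rejected(self, small_spec, small_world):
        universe, _, _ = small_world
        with pytest.raises(ValueError, match="schedule"):
            make_staged_expression(small_spec, {}, universe, "sometimes")

    def test_de_study_truth_size(self, small_spec):
        study, truth = make_de_study(small_spec, n_genes=500, frac_de=0.1)
        assert len(truth) == 50
        assert study.matrix.shape == (500, 6)

    def test_full_concordance_recovered(self, small_world):
        """c=1 exposure: recovered directions match the target's exactly."""
        universe, ann, _ = small_world
        spec = SyntheticSpec(n_genes=2000, pn_size=250,
                             pathway_sizes={"ALP": 80, "UPS": 70,
                                            "EXTRACELLULAR": 50,
                                            "PROTEOSTASIS_REGULATION": 50},
                             group_sizes={"KINASE": 60, "TF": 120,
                                          "ION_CHANNEL": 40},
                             k=200, expr_genes=400, seed=3)
        target = {g: (1 if i % 2 else -1)
                  for i, g in enumerate(sorted(ann.genes)[:100])}
        study, truth = make_exposure_study(spec, target, universe,
                                           concordance=1.0, perturb_frac=1.0)
        de = de_table(study, ("EXPOSED", "CONTROL"))
        rec = exposure_pn_set(de, ann)
        shared = set(rec) & set(target)
        assert len(shared) >= 90
        ds, _ = directional_similarity({g: rec[g] for g in shared},
                                       {g: target[g] for g in shared})
        assert ds > 0.98


class TestConcordanceAndRisk:
    def test_concordant_signs_hit_target(self):
        spec = SyntheticSpec(seed=29)
        for c in (0.2, 0.5, 0.8):
            a, b = make_concordant_signs(spec, 1000, c, stream=f"t:{c}")
            ds, ov = directional_similarity(a, b)
            assert ov == 1000
            assert abs(ds - c) <= 0.05

    def test_risk_panel_planted_concordance(self, small_world):
        universe, ann, _ = small_world
        spec = SyntheticSpec(n_genes=2000, pn_size=250,
                             pathway_sizes={"ALP": 80, "UPS": 70,
                                            "EXTRACELLULAR": 50,
                                            "PROTEOSTASIS_REGULATION": 50},
                             group_sizes={"KINASE": 60, "TF": 120,
                                          "ION_CHANNEL": 40},
                             k=200, seed=4)
        expo, diseases, conc = make_risk_panel(spec, universe, ann,
                                               exposure_size=120, n_shared=80)
        for d in diseases:
            shared = {g: d.sign_of[g] for g in d.genes if g in expo}
            ds, ov = directional_similarity(expo, shared)
            assert ov == 80
            assert abs(ds - conc[d.disease_id]) <= 0.15


class TestHubNetwork:
    def test_small_graph_valid_and_deterministic(self, small_spec):
        stages = {f"N{i}": ("MID" if i < 3 else "EARLY") for i in range(10)}
        a = make_hub_network(small_spec, stages)
        b = make_hub_network(small_spec, stages)
        assert a.edges == b.edges
        assert all(x != y for x, y in a.edges)

    def test_equal_stub_counts_no_planted_effect(self, small_spec):
        stages = {f"N{i}": ("MID" if i % 2 else "EARLY") for i in range(60)}
        net = make_hub_network(small_spec, stages, m_base=3, m_hub=3)
        from proteosig.progression import stage_centrality_summary
        quart, tests = stage_centrality_summary(net)
        med = {(r.stage, r.metric): r.median for r in quart.itertuples()}
        # no stage should dominate by an order of magnitude
        assert med[("MID", "degree")] < 3 * med[("EARLY", "degree")]
        assert med[("EARLY", "degree")] < 3 * med[("MID", "degree")]
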