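"""End-to-end orchestration: run every analysis stage from one config.

A run executes enrich -> profile -> states -> cluster -> signature ->
progression -> riskfactor over either user-supplied inputs (GMT/TSV paths)
or, when ``simulate`` is set, a self-generated synthetic cohort.  Every
output TSV carries a header comment with the tool version, a hash of the
config and the seed, so reruns are byte-identical and attributable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .annotation_io import (DiseaseGeneSet, attach_signs, read_gene_sets,
                            read_pn_annotation, read_signs, read_universe)
from .enrichment import overrepresentation_table, rows_to_frame
from .profiling import classify_state, profile_disease, profile_matrix
from .progression import stage_centrality_summary, stage_proportions, stagewise_de
from .riskfactor import exposure_pn_set, score_exposure
from .signatures import cluster_diseases, consensus_signature, similarity_matrix
from .synthetic import (SyntheticSpec, make_disease_panel, make_exposure_study,
                        make_hub_network, make_staged_expression, make_universe)
from .diffexp import de_table
from .profiling import ALP, UPS

logger = logging.getLogger("proteosig.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    out_dir: str = "proteosig_out"
    seed: int = 0
    simulate: bool = True
    sets_path: Optional[str] = None
    pn_path: Optional[str] = None
    universe_path: Optional[str] = None
    signs_path: Optional[str] = None
    k: int = 500
    alpha_profile: float = 0.01
    direction_alpha: float = 0.05
    fdr_cut: float = 0.05
    n_clusters: int = 4

    def __post_init__(self):
        for name in ("alpha_profile", "direction_alpha", "fdr_cut"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0,1)")
        if not self.simulate:
            for name in ("sets_path", "pn_path", "universe_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} required when simulate is false")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: no such file: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, **kw) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# proteosig {__version__} config={config.hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", **kw)


def run_all(config: RunConfig) -> dict:
    """Execute all stages; returns a manifest of written artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config_hash": config.hash(),
                      "seed": config.seed, "outputs": {}, "rows": {}}

    def record(stage: str, path: Path, nrows: int):
        manifest["outputs"][stage] = str(path)
        manifest["rows"][stage] = nrows
        logger.info("stage %s: wrote %d rows to %s", stage, nrows, path)

    def run_stage(stage, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - abort with stage name
            manifest["failed_stage"] = stage
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(stage, exc) from exc

    # ---- inputs ----
    def load_inputs():
        if config.simulate:
            spec = SyntheticSpec(seed=config.seed, k=config.k)
            universe, ann, groups = make_universe(spec)
            sets = make_disease_panel(spec, universe, ann)
            return spec, universe, ann, groups, sets
        universe = read_universe(config.universe_path)
        ann = read_pn_annotation(config.pn_path)
        sets = read_gene_sets(config.sets_path, k=config.k)
        if config.signs_path:
            attach_signs(sets, read_signs(config.signs_path))
        groups = {lab: universe.group(lab) for lab in ("KINASE", "TF", "ION_CHANNEL")}
        groups = {lab: g for lab, g in groups.items() if g}
        spec = SyntheticSpec(seed=config.seed, k=config.k)
        return spec, universe, ann, groups, sets

    spec, universe, ann, groups, sets = run_stage("inputs", load_inputs)

    # ---- enrich: protein-group over-representation per disease ----
    def stage_enrich():
        cats = {"PN": ann.genes & universe.genes, **groups}
        rows = overrepresentation_table(sets, cats, universe)
        df = rows_to_frame(rows)
        path = out / "enrich.tsv"
        _write_tsv(df, path, config, index=False)
        record("enrich", path, len(df))
        return rows

    run_stage("enrich", stage_enrich)

    # ---- profile + states ----
    def stage_profile():
        profiles = [profile_disease(s, ann, universe, alpha=config.alpha_profile)
                    for s in sets]
        mat = profile_matrix(profiles)
        mat.insert(0, "pn_fraction", [p.pn_fraction for p in profiles])
        path = out / "profiles.tsv"
        _write_tsv(mat, path, config, index_label="disease")
        record("profile", path, len(mat))
        return profiles

    profiles = run_stage("profile", stage_profile)

    def stage_states():
        df = pd.DataFrame({
            "disease": [p.disease_id for p in profiles],
            "state": [classify_state(p).value for p in profiles]})
        path = out / "states.tsv"
        _write_tsv(df, path, config, index=False)
        record("states", path, len(df))

    run_stage("states", stage_states)

    # ---- cluster + signatures ----
    def stage_cluster():
        sim = similarity_matrix(sets)
        clusters = cluster_diseases(sim, n_clusters=config.n_clusters)
        df = pd.DataFrame(sorted(clusters.items()), columns=["disease", "cluster"])
        path = out / "clusters.tsv"
        _write_tsv(df, path, config, index=False)
        record("cluster", path, len(df))
        return clusters

    clusters = run_stage("cluster", stage_cluster)

    def stage_signature():
        frames = []
        signed = [s for s in sets if s.sign_of]
        for cid in sorted(set(clusters.values())):
            members = [s for s in signed if clusters[s.disease_id] == cid]
            if not members:
                continue
            for pw in ann.pathway_vocab:
                sig = consensus_signature(members, ann, pw)
                sig = sig.reset_index()
                sig.insert(0, "pathway", pw)
                sig.insert(0, "cluster", cid)
                frames.append(sig)
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["cluster", "pathway", "gene", "value", "support"])
        path = out / "signatures.tsv"
        _write_tsv(df, path, config, index=False)
        record("signature", path, len(df))

    run_stage("signature", stage_signature)

    # ---- progression: staged DE demo + stage-annotated centrality ----
    def stage_progression():
        target = sets[0]
        pn_signs = {g: target.sign_of[g] for g in target.genes
                    if g in ann.genes and target.sign_of and g in target.sign_of}
        frames = []
        stage_of_affected: dict[str, str] = {}
        for schedule in ("early", "progressive"):
            study = make_staged_expression(spec, pn_signs, universe, schedule)
            stage_labels = [f"STAGE_{s}" for s in range(1, spec.n_stages + 1)]
            result = stagewise_de(study, stage_labels, "CONTROL",
                                  alpha=config.direction_alpha)
            for pw in (ALP, UPS):
                props = stage_proportions(result, ann.pathway_genes(pw))
                frames.append(pd.DataFrame({
                    "schedule": schedule, "pathway": pw,
                    "stage": props.index, "proportion": props.values}))
            if schedule == "progressive":
                names = ["EARLY", "MID", "LATE"]
                for g, onset in result.onset.items():
                    if onset is not None and g in ann.genes:
                        idx = min(stage_labels.index(onset), 2)
                        stage_of_affected[g] = names[idx]
        df = pd.concat(frames, ignore_index=True)
        path = out / "progression.tsv"
        _write_tsv(df, path, config, index=False)
        record("progression", path, len(df))
        return stage_of_affected

    stage_of = run_stage("progression", stage_progression)

    def stage_centrality():
        if len(stage_of) < 6:  # too few affected PN genes for a graph
            logger.warning("too few staged genes for a network; skipping plot data")
            df = pd.DataFrame(columns=["stage", "metric", "n", "q1", "median", "q3"])
        else:
            net = make_hub_network(spec, stage_of)
            quart, tests = stage_centrality_summary(net)
            df = quart
            _write_tsv(tests, out / "centrality_tests.tsv", config, index=False)
        path = out / "centrality.tsv"
        _write_tsv(df, path, config, index=False)
        record("centrality", path, len(df))

    run_stage("centrality", stage_centrality)

    # ---- riskfactor ----
    def stage_risk():
        target = sets[0]
        pn_signs = {g: s for g, s in (target.sign_of or {}).items() if g in ann.genes}
        study, _truth = make_exposure_study(spec, pn_signs, universe, concordance=0.8)
        de = de_table(study, ("EXPOSED", "CONTROL"),
                      direction_alpha=config.direction_alpha)
        exposure = exposure_pn_set(de, ann)
        sig_genes = list(de.index[de["direction"] != 0])
        panel = sets[: max(2, min(8, len(sets)))]
        report = score_exposure(exposure, panel, ann, controls=groups,
                                significant_genes=sig_genes, rng_seed=config.seed)
        path = out / "risk.tsv"
        _write_tsv(report, path, config)
        record("riskfactor", path, len(report))

    run_stage("riskfactor", stage_risk)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
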