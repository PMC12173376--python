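"""Data model and I/O for gene universes, proteostasis annotations, gene sets,
expression studies and interaction networks.

The proteostasis network (PN) is represented as a two-level hierarchy: genes
belong to one or more *pathways* (autophagy-lysosome pathway, ubiquitin-
proteasome system, extracellular proteostasis, proteostasis regulation, ...)
and to *functional classes* nested within a single parent pathway (molecular
chaperones, E3 ligases, ...).  Disease gene sets are rank-ordered top-k lists,
optionally carrying a per-gene perturbation sign.

Gene identity throughout the package is the uppercased symbol string; no alias
resolution is attempted.  All file formats are UTF-8, tab-delimited text:
GMT for gene sets, simple TSVs for everything else.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("proteosig.annotation_io")

#: canonical protein-group labels used for control-group benchmarking
GROUP_LABELS = ("PN", "KINASE", "TF", "ION_CHANNEL")


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol.  Idempotent."""
    s = str(symbol).strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    return s


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneUniverse:
    """The annotated gene universe: N of the hypergeometric test.

    ``group_labels`` maps a gene to the subset of protein groups
    (PN / KINASE / TF / ION_CHANNEL) it belongs to; unlabelled genes simply
    count toward the background.
    """

    genes: frozenset[str]
    group_labels: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        for g in self.genes:
            if not g or g != g.upper():
                raise ValueError(f"gene symbol not normalized: {g!r}")
        extra = set(self.group_labels) - set(self.genes)
        if extra:
            raise ValueError(f"labelled genes missing from universe: {sorted(extra)[:5]}")
        for g, labs in self.group_labels.items():
            bad = set(labs) - set(GROUP_LABELS)
            if bad:
                raise ValueError(f"unknown group labels for {g}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.genes)

    def group(self, label: str) -> frozenset[str]:
        """All genes carrying ``label`` (one of GROUP_LABELS)."""
        if label not in GROUP_LABELS:
            raise ValueError(f"unknown group label {label!r}")
        return frozenset(g for g, labs in self.group_labels.items() if label in labs)


@dataclass(frozen=True)
class PNAnnotation:
    """Many-to-many gene -> pathway and gene -> functional-class maps.

    Every functional class nests under exactly one pathway
    (``class_to_pathway``); every annotated gene carries at least one pathway.
    """

    pathway_of: Mapping[str, frozenset[str]]
    class_of: Mapping[str, frozenset[str]]
    pathway_vocab: tuple[str, ...]
    class_vocab: tuple[str, ...]
    class_to_pathway: Mapping[str, str]

    def __post_init__(self):
        for g, pws in self.pathway_of.items():
            if not pws:
                raise ValueError(f"annotated gene {g} has no pathway")
            bad = set(pws) - set(self.pathway_vocab)
            if bad:
                raise ValueError(f"pathways missing from vocab: {sorted(bad)}")
        for c, pw in self.class_to_pathway.items():
            if c not in self.class_vocab:
                raise ValueError(f"class missing from vocab: {c}")
            if pw not in self.pathway_vocab:
                raise ValueError(f"class {c} maps to unknown pathway {pw}")
        for g, cls in self.class_of.items():
            bad = set(cls) - set(self.class_vocab)
            if bad:
                raise ValueError(f"classes missing from vocab: {sorted(bad)}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.pathway_of)

    def pathway_genes(self, pathway: str) -> frozenset[str]:
        return frozenset(g for g, pws in self.pathway_of.items() if pathway in pws)

    def class_genes(self, cls: str) -> frozenset[str]:
        return frozenset(g for g, cs in self.class_of.items() if cls in cs)

    def pathway_db(self) -> dict[str, frozenset[str]]:
        """Mapping pathway -> member genes, in vocab order."""
        return {p: self.pathway_genes(p) for p in self.pathway_vocab}

    def class_db(self) -> dict[str, frozenset[str]]:
        return {c: self.class_genes(c) for c in self.class_vocab}


@dataclass
class DiseaseGeneSet:
    """A named, rank-ordered disease gene list (rank 1..k), optionally signed."""

    disease_id: str
    genes: list[str]
    disease_group: str = "UNKNOWN"
    sign_of: Optional[dict[str, int]] = None

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{self.disease_id}: duplicate genes in set")
        if self.sign_of is not None:
            extra = set(self.sign_of) - set(self.genes)
            if extra:
                raise ValueError(f"{self.disease_id}: signed genes not in set: {sorted(extra)[:5]}")
            bad = set(self.sign_of.values()) - {-1, 1}
            if bad:
                raise ValueError(f"{self.disease_id}: signs must be -1/+1, got {bad}")

    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ExpressionStudy:
    """A genes x samples matrix of log2-scale expression with condition labels."""

    matrix: pd.DataFrame
    sample_condition: dict[str, str]

    def __post_init__(self):
        missing = set(self.matrix.columns) - set(self.sample_condition)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)[:5]}")
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.matrix.columns if self.sample_condition[s] == condition]

    @property
    def conditions(self) -> set[str]:
        return set(self.sample_condition[s] for s in self.matrix.columns)


@dataclass
class InteractionNetwork:
    """An undirected gene graph; edges stored as canonically sorted tuples."""

    nodes: set[str]
    edges: set[tuple[str, str]]
    stage_of: Optional[dict[str, str]] = None

    def __post_init__(self):
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a},{b}) references unknown node")
            canon.add((a, b) if a < b else (b, a))
        self.edges = canon
        if self.stage_of is not None:
            extra = set(self.stage_of) - self.nodes
            if extra:
                raise ValueError(f"staged nodes not in network: {sorted(extra)[:5]}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_lines(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return fh.read().splitlines()


def read_gene_sets(path, k: int = 500) -> list[DiseaseGeneSet]:
    """Read disease gene sets from GMT or TSV, truncated to the top ``k``.

    GMT: ``name<TAB>description<TAB>gene1<TAB>gene2...`` with genes already in
    rank order.  TSV: header with columns ``set``, ``gene`` and optionally
    ``score`` (rank by score descending, ties broken by symbol ascending) and
    ``group``.  Symbols are uppercased; duplicates within a set keep the first
    occurrence.
    """
    if k < 1:
        raise ValueError("k must be positive")
    text = _read_lines(path)
    name = str(path)
    if name.endswith(".gmt"):
        return _read_gmt(text, k)
    if text and "\t" in text[0]:
        header = text[0].split("\t")
        if "set" in header and "gene" in header:
            return _read_sets_tsv(text, k)
    return _read_gmt(text, k)


def _dedupe_truncate(disease_id: str, symbols: Iterable[str], k: int,
                     groups: Optional[str] = None) -> DiseaseGeneSet:
    seen: list[str] = []
    have = set()
    for s in symbols:
        s = normalize_symbol(s)
        if s not in have:
            have.add(s)
            seen.append(s)
        if len(seen) == k:
            break
    if not seen:
        raise ParseError(f"gene set {disease_id!r} is empty")
    return DiseaseGeneSet(disease_id=disease_id, genes=seen,
                          disease_group=groups or "UNKNOWN")


def _read_gmt(lines: Sequence[str], k: int) -> list[DiseaseGeneSet]:
    sets = []
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"line {i}: GMT line needs >=3 tab-separated fields")
        name = fields[0].strip()
        if not name:
            raise ParseError(f"line {i}: empty set name")
        desc = fields[1].strip()
        genes = [f for f in fields[2:] if f.strip()]
        if not genes:
            raise ParseError(f"line {i}: gene set {name!r} is empty")
        sets.append(_dedupe_truncate(name, genes, k,
                                     desc if desc not in ("", "NA") else None))
    return sets


def _read_sets_tsv(lines: Sequence[str], k: int) -> list[DiseaseGeneSet]:
    header = lines[0].split("\t")
    idx = {c: j for j, c in enumerate(header)}
    rows: dict[str, list[tuple[float, str]]] = {}
    groups: dict[str, str] = {}
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < len(header):
            raise ParseError(f"line {i}: expected {len(header)} fields")
        sid = fields[idx["set"]].strip()
        gene = fields[idx["gene"]].strip()
        if not sid or not gene:
            raise ParseError(f"line {i}: empty set or gene field")
        score = float(fields[idx["score"]]) if "score" in idx else -float(i)
        rows.setdefault(sid, []).append((score, normalize_symbol(gene)))
        if "group" in idx and fields[idx["group"]].strip():
            groups[sid] = fields[idx["group"]].strip()
    out = []
    for sid, pairs in rows.items():
        # rank by score descending, symbol ascending on ties
        pairs.sort(key=lambda t: (-t[0], t[1]))
        out.append(_dedupe_truncate(sid, (g for _, g in pairs), k, groups.get(sid)))
    return out


def write_gene_sets(sets: Sequence[DiseaseGeneSet], path) -> None:
    """Write gene sets as GMT (description field = disease group or NA)."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            desc = s.disease_group if s.disease_group != "UNKNOWN" else "NA"
            fh.write("\t".join([s.disease_id, desc, *s.genes]) + "\n")


def read_signs(path) -> dict[str, dict[str, int]]:
    """Read a sign sidecar TSV (columns set, gene, sign) -> {set: {gene: +-1}}."""
    lines = _read_lines(path)
    if not lines:
        return {}
    header = lines[0].split("\t")
    idx = {c: j for j, c in enumerate(header)}
    for col in ("set", "gene", "sign"):
        if col not in idx:
            raise ParseError(f"sign file missing column {col!r}")
    out: dict[str, dict[str, int]] = {}
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        f = line.split("\t")
        sign = int(f[idx["sign"]])
        if sign not in (-1, 1):
            raise ParseError(f"line {i}: sign must be -1 or +1")
        out.setdefault(f[idx["set"]].strip(), {})[normalize_symbol(f[idx["gene"]])] = sign
    return out


def write_signs(sets: Sequence[DiseaseGeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("set\tgene\tsign\n")
        for s in sets:
            if s.sign_of:
                for g in s.genes:
                    if g in s.sign_of:
                        fh.write(f"{s.disease_id}\t{g}\t{s.sign_of[g]:+d}\n")


def attach_signs(sets: Sequence[DiseaseGeneSet], signs: Mapping[str, Mapping[str, int]]) -> None:
    """Attach sidecar signs to gene sets in place (unknown genes ignored)."""
    for s in sets:
        if s.disease_id in signs:
            members = set(s.genes)
            s.sign_of = {g: v for g, v in signs[s.disease_id].items() if g in members}


def read_pn_annotation(path) -> PNAnnotation:
    """Read a gene/pathway/class TSV into a :class:`PNAnnotation`.

    Vocabulary is accumulated in first-seen order; a class assigned to two
    different pathways is a consistency error naming both rows.
    """
    lines = [ln for ln in _read_lines(path) if ln.strip()]
    if not lines:
        raise ParseError("annotation file is empty")
    header = lines[0].split("\t")
    idx = {c: j for j, c in enumerate(header)}
    for col in ("gene", "pathway", "class"):
        if col not in idx:
            raise ParseError(f"annotation file missing column {col!r}")
    pathway_of: dict[str, set[str]] = {}
    class_of: dict[str, set[str]] = {}
    pvocab: list[str] = []
    cvocab: list[str] = []
    c2p: dict[str, str] = {}
    c2p_line: dict[str, int] = {}
    for i, line in enumerate(lines[1:], start=2):
        f = line.split("\t")
        if len(f) < len(header):
            raise ParseError(f"line {i}: expected {len(header)} fields")
        gene = normalize_symbol(f[idx["gene"]])
        pw = f[idx["pathway"]].strip()
        cls = f[idx["class"]].strip()
        if not pw:
            raise ParseError(f"line {i}: empty pathway")
        if pw not in pvocab:
            pvocab.append(pw)
        pathway_of.setdefault(gene, set()).add(pw)
        if cls:
            if cls in c2p and c2p[cls] != pw:
                raise ParseError(
                    f"class {cls!r} assigned to pathway {c2p[cls]!r} (line "
                    f"{c2p_line[cls]}) and {pw!r} (line {i})")
            if cls not in cvocab:
                cvocab.append(cls)
                c2p[cls] = pw
                c2p_line[cls] = i
            class_of.setdefault(gene, set()).add(cls)
    if not pathway_of:
        raise ParseError("annotation file has no data rows")
    return PNAnnotation(
        pathway_of={g: frozenset(v) for g, v in pathway_of.items()},
        class_of={g: frozenset(v) for g, v in class_of.items()},
        pathway_vocab=tuple(pvocab), class_vocab=tuple(cvocab),
        class_to_pathway=c2p)


def write_pn_annotation(ann: PNAnnotation, path) -> None:
    """Write an annotation TSV whose read-back reproduces ``ann`` exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tpathway\tclass\n")
        # vocab order first so first-seen order on re-read matches the vocab
        for pw in ann.pathway_vocab:
            for cls in [c for c in ann.class_vocab if ann.class_to_pathway[c] == pw]:
                for g in sorted(ann.class_genes(cls)):
                    fh.write(f"{g}\t{pw}\t{cls}\n")
            for g in sorted(ann.pathway_genes(pw)):
                if not any(ann.class_to_pathway[c] == pw for c in ann.class_of.get(g, ())):
                    fh.write(f"{g}\t{pw}\t\n")


def read_universe(path) -> GeneUniverse:
    """Read a universe TSV (columns gene, groups; groups comma-separated)."""
    lines = [ln for ln in _read_lines(path) if ln.strip()]
    if not lines:
        raise ParseError("universe file is empty")
    header = lines[0].split("\t")
    idx = {c: j for j, c in enumerate(header)}
    if "gene" not in idx:
        raise ParseError("universe file missing column 'gene'")
    genes = set()
    labels: dict[str, frozenset[str]] = {}
    for i, line in enumerate(lines[1:], start=2):
        f = line.split("\t")
        g = normalize_symbol(f[idx["gene"]])
        genes.add(g)
        if "groups" in idx and len(f) > idx["groups"] and f[idx["groups"]].strip():
            labels[g] = frozenset(x.strip() for x in f[idx["groups"]].split(",") if x.strip())
    return GeneUniverse(genes=frozenset(genes), group_labels=labels)


def write_universe(universe: GeneUniverse, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tgroups\n")
        for g in sorted(universe.genes):
            labs = ",".join(sorted(universe.group_labels.get(g, ())))
            fh.write(f"{g}\t{labs}\n")


def read_expression(expr_path, meta_path) -> ExpressionStudy:
    """Read an expression TSV (gene rows, sample columns) and a sample/condition TSV."""
    matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
    matrix.index = [normalize_symbol(g) for g in matrix.index]
    meta = pd.read_csv(meta_path, sep="\t")
    for col in ("sample", "condition"):
        if col not in meta.columns:
            raise ParseError(f"metadata missing column {col!r}")
    cond = dict(zip(meta["sample"].astype(str), meta["condition"].astype(str)))
    return ExpressionStudy(matrix=matrix, sample_condition=cond)


def write_expression(study: ExpressionStudy, expr_path, meta_path) -> None:
    study.matrix.to_csv(expr_path, sep="\t", index_label="gene")
    with open(meta_path, "w", encoding="utf-8") as fh:
        fh.write("sample\tcondition\n")
        for s in study.matrix.columns:
            fh.write(f"{s}\t{study.sample_condition[s]}\n")


def read_edge_list(path) -> InteractionNetwork:
    """Read a two-column edge TSV; drops self-loops (logged) and duplicate edges."""
    lines = _read_lines(path)
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    dropped = 0
    start = 0
    if lines and lines[0].split("\t")[:2] in (["node_a", "node_b"], ["source", "target"]):
        start = 1
    for i, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) < 2 or not f[0].strip() or not f[1].strip():
            raise ParseError(f"line {i}: expected two non-empty node columns")
        a, b = normalize_symbol(f[0]), normalize_symbol(f[1])
        nodes.update((a, b))
        if a == b:
            dropped += 1
            continue
        edges.add((a, b) if a < b else (b, a))
    if dropped:
        logger.info("dropped %d self-loop(s) while reading %s", dropped, path)
    return InteractionNetwork(nodes=nodes, edges=edges)


def write_edge_list(net: InteractionNetwork, path) -> None:
    # isolated nodes are not representable in a pure edge list
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def read_stage_map(path) -> dict[str, str]:
    """Read a node/stage TSV into a mapping."""
    lines = [ln for ln in _read_lines(path) if ln.strip()]
    if not lines:
        return {}
    header = lines[0].split("\t")
    idx = {c: j for j, c in enumerate(header)}
    gcol = idx.get("gene", idx.get("node", 0))
    scol = idx.get("stage", 1)
    return {normalize_symbol(ln.split("\t")[gcol]): ln.split("\t")[scol].strip()
            for ln in lines[1:]}
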