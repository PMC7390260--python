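"""Knowledge-driven functional grouping of metabolites and genes.

Each metabolite (ChEBI id) is mapped to pathways.  If the id itself has a
pathway annotation the mapping is direct; otherwise the ChEBI ontology is
searched for the nearest annotated relative, preferring descendants (children
direction) over ancestors.  The union of the pathway gene sets forms the seed
gene group, which is then expanded by one hop in the gene interaction
network, keeping only edges whose combined confidence score clears a
threshold.  The result is a functional group: the knowledge-driven dimension
reduction that restricts a large transcriptomic matrix to genes plausibly
linked to the measured metabolites.
"""

from __future__ import annotations

import enum
import os
import warnings
from collections import deque
from dataclasses import dataclass, field

from .io import KnowledgeBase, normalize_chebi

__all__ = [
    "ResolutionStatus",
    "Resolution",
    "GeneProvenance",
    "FunctionalGroup",
    "resolve_chebi",
    "expand_neighbors",
    "build_functional_group",
    "write_group_reports",
]

DEFAULT_SCORE_THRESHOLD = 400  # STRING "medium confidence"


class ResolutionStatus(str, enum.Enum):
    DIRECT = "DIRECT"
    VIA_CHILD = "VIA_CHILD"
    VIA_PARENT = "VIA_PARENT"
    UNMAPPED = "UNMAPPED"


class GeneProvenance(str, enum.Enum):
    PATHWAY = "PATHWAY"
    NEIGHBOR = "NEIGHBOR"


@dataclass(frozen=True)
class Resolution:
    """How one ChEBI query was matched to a pathway-annotated id.

    ``distance`` counts ontology edges walked (0 for a direct hit);
    ``representative_id`` is the annotated id standing in for the query,
    or ``None`` when the query is unmappable.
    """

    query_id: int
    status: ResolutionStatus
    representative_id: int | None
    distance: int

    def __post_init__(self) -> None:
        if self.status is ResolutionStatus.DIRECT:
            assert self.distance == 0 and self.representative_id == self.query_id
        if self.status is ResolutionStatus.UNMAPPED:
            assert self.representative_id is None


def _bfs_nearest_mapped(
    start: int, neighbors, mapped: set[int]
) -> tuple[int, int] | None:
    """Breadth-first search from ``start``; return (id, depth) of the nearest
    mapped node, ties at equal depth broken by smallest numeric id."""
    seen = {start}
    frontier = deque([start])
    depth = 0
    while frontier:
        depth += 1
        next_frontier: list[int] = []
        for node in frontier:
            for nxt in neighbors(node):
                if nxt not in seen:
                    seen.add(nxt)
                    next_frontier.append(nxt)
        hits = sorted(n for n in next_frontier if n in mapped)
        if hits:
            return hits[0], depth
        frontier = deque(next_frontier)
    return None


def resolve_chebi(query: int | str, kb: KnowledgeBase) -> Resolution:
    """Resolve a ChEBI id to its nearest pathway-annotated representative.

    Order of precedence: the query itself (DIRECT), then the nearest
    annotated descendant (VIA_CHILD, full subtree searched breadth-first),
    then the nearest annotated ancestor (VIA_PARENT).  "Nearest" means fewest
    ontology edges; ties at equal depth go to the smallest numeric id.
    Queries with no annotated relative are UNMAPPED and contribute nothing
    downstream.
    """
    qid = normalize_chebi(query)
    mapped = set(kb.met2pathway)
    if qid in mapped:
        return Resolution(qid, ResolutionStatus.DIRECT, qid, 0)
    if qid in kb.ontology:
        # ontology edges point child -> parent, so descendants are reached
        # against edge direction and ancestors along it
        hit = _bfs_nearest_mapped(qid, kb.ontology.predecessors, mapped)
        if hit is not None:
            return Resolution(qid, ResolutionStatus.VIA_CHILD, hit[0], hit[1])
        hit = _bfs_nearest_mapped(qid, kb.ontology.successors, mapped)
        if hit is not None:
            return Resolution(qid, ResolutionStatus.VIA_PARENT, hit[0], hit[1])
    return Resolution(qid, ResolutionStatus.UNMAPPED, None, 0)


def expand_neighbors(
    genes: set[str], kb: KnowledgeBase, score_threshold: int = DEFAULT_SCORE_THRESHOLD
) -> set[str]:
    """Add the one-hop interaction neighbors of ``genes``.

    Only edges with combined score ≥ ``score_threshold`` qualify.  Genes
    absent from the interaction network simply have no neighbors.  The
    operation is applied exactly once in the pipeline; it is not idempotent
    (a second application may grow the set further).
    """
    if not 0 <= score_threshold <= 1000:
        raise ValueError(f"score_threshold must be in [0, 1000], got {score_threshold}")
    out = {g.upper() for g in genes}
    for gene in list(out):
        if gene in kb.interactions:
            for nb, attrs in kb.interactions[gene].items():
                if attrs["score"] >= score_threshold:
                    out.add(nb)
    return out


@dataclass
class FunctionalGroup:
    """A metabolite set with its mapped pathways and expanded gene group."""

    metabolite_ids: list[int]
    resolutions: dict[int, Resolution]
    pathway_ids: set[str]
    seed_genes: set[str]
    expanded_genes: set[str]
    provenance: dict[str, GeneProvenance]
    gene_pathways: dict[str, set[str]] = field(default_factory=dict)
    score_threshold: int = DEFAULT_SCORE_THRESHOLD


def build_functional_group(
    metabolite_ids: list[int | str],
    kb: KnowledgeBase,
    score_threshold: int = DEFAULT_SCORE_THRESHOLD,
) -> FunctionalGroup:
    """Build a functional group for a list of metabolites.

    Resolves each metabolite, unions the gene sets of the reachable pathways
    into the seed set, and expands the seed by one interaction hop.  Per-gene
    provenance records whether a gene entered via a pathway or as an
    interaction neighbor; per-metabolite resolutions record how each ChEBI id
    was matched.  A group where every metabolite is unmappable is returned
    empty with a warning, not an error.
    """
    if not metabolite_ids:
        raise ValueError("metabolite_ids must be non-empty")
    ids = [normalize_chebi(m) for m in metabolite_ids]
    resolutions: dict[int, Resolution] = {}
    pathway_ids: set[str] = set()
    seed_genes: set[str] = set()
    gene_pathways: dict[str, set[str]] = {}
    for qid in ids:
        res = resolve_chebi(qid, kb)
        resolutions[qid] = res
        if res.status is ResolutionStatus.UNMAPPED:
            continue
        for pw in kb.met2pathway.get(res.representative_id, set()):
            pathway_ids.add(pw)
            for gene in kb.pathway2gene.get(pw, set()):
                seed_genes.add(gene)
                gene_pathways.setdefault(gene, set()).add(pw)
    if all(r.status is ResolutionStatus.UNMAPPED for r in resolutions.values()):
        warnings.warn(
            "no metabolite could be mapped to any pathway; gene group is empty",
            stacklevel=2,
        )
    expanded = expand_neighbors(seed_genes, kb, score_threshold)
    provenance = {
        g: (GeneProvenance.PATHWAY if g in seed_genes else GeneProvenance.NEIGHBOR)
        for g in expanded
    }
    return FunctionalGroup(
        metabolite_ids=ids,
        resolutions=resolutions,
        pathway_ids=pathway_ids,
        seed_genes=seed_genes,
        expanded_genes=expanded,
        provenance=provenance,
        gene_pathways=gene_pathways,
        score_threshold=score_threshold,
    )


def write_group_reports(
    group: FunctionalGroup,
    mapping_path: str | os.PathLike,
    genes_path: str | os.PathLike,
) -> None:
    """Write the metabolite-resolution and gene-membership TSV reports."""
    with open(mapping_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("metabolite_id\tresolution_status\trepresentative_id\tdistance\n")
        for qid in group.metabolite_ids:
            res = group.resolutions[qid]
            rep = "" if res.representative_id is None else f"CHEBI:{res.representative_id}"
            fh.write(f"CHEBI:{qid}\t{res.status.value}\t{rep}\t{res.distance}\n")
    with open(genes_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_symbol\tprovenance\tpathway_ids\n")
        for gene in sorted(group.expanded_genes):
            pws = ",".join(sorted(group.gene_pathways.get(gene, set())))
            fh.write(f"{gene}\t{group.provenance[gene].value}\t{pws}\n")
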