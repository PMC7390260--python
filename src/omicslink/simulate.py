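"""Synthetic paired omics matrices and miniature knowledge-base snapshots.

Two generators let the entire pipeline run with zero downloads:

* :func:`generate_paired_omics` draws sample-aligned X/Y matrices with
  *planted canonical structure*: for each requested canonical correlation
  ρ_i a shared standard-normal latent z_i is drawn, the X-side latent is z_i
  itself and the Y-side latent is ρ_i·z_i + √(1 − ρ_i²)·ε_i; the latents are
  embedded into feature space through random orthonormal loading matrices
  and isotropic Gaussian noise is added.  The noiseless construction has
  population canonical correlations exactly equal to the planted values
  (isotropic noise attenuates them by 1/(1 + noise_sd²)).  The latent-factor
  construction also fixes a ground-truth latent count for PLS
  cross-validation tests.

* :func:`generate_fixture_knowledgebase` writes a complete four-file
  snapshot (metabolite→pathway, pathway→gene, ontology edges, scored
  interactions) guaranteed to exercise every metabolite-resolution branch:
  at least one DIRECT, one VIA_CHILD, one VIA_PARENT and one UNMAPPED query
  exist by construction.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical spec + seed yields bitwise-identical
output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .io import Namespace, OmicsMatrix

__all__ = [
    "SyntheticSpec",
    "FixtureKnowledgeBase",
    "generate_paired_omics",
    "generate_fixture_knowledgebase",
]

CHEBI_BASE = 10000  # synthetic ChEBI ids start here


@dataclass
class SyntheticSpec:
    """Parameters of a paired-matrix generation.

    ``planted_rho`` must be non-increasing with entries in [0, 1) and no
    longer than min(p, q).  ``noise_sd`` is the standard deviation of the
    isotropic feature-space noise (default 0.1 — weak relative to the
    unit-variance latents, so estimated canonical correlations stay close
    to the planted ones).
    """

    n_samples: int
    p: int
    q: int
    planted_rho: list[float]
    noise_sd: float = 0.1
    seed: int = 0
    x_namespace: Namespace = Namespace.HGNC
    y_namespace: Namespace = Namespace.CHEBI
    x_feature_ids: list[str] | None = None
    y_feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        rho = np.asarray(self.planted_rho, dtype=float)
        if rho.size > min(self.p, self.q):
            raise ValueError(
                f"len(planted_rho) = {rho.size} exceeds min(p, q) = {min(self.p, self.q)}"
            )
        if np.any((rho < 0) | (rho >= 1)):
            raise ValueError(f"planted_rho entries must lie in [0, 1): {rho}")
        if np.any(np.diff(rho) > 0):
            raise ValueError(f"planted_rho must be non-increasing: {rho}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.x_feature_ids is not None and len(self.x_feature_ids) != self.p:
            raise ValueError("x_feature_ids length must equal p")
        if self.y_feature_ids is not None and len(self.y_feature_ids) != self.q:
            raise ValueError("y_feature_ids length must equal q")


def _orthonormal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    A = rng.standard_normal((rows, cols))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))  # deterministic sign fix


def generate_paired_omics(spec: SyntheticSpec) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Draw a sample-aligned (X, Y) pair with planted canonical correlations."""
    rng = np.random.default_rng(spec.seed)
    n, p, q = spec.n_samples, spec.p, spec.q
    rho = np.asarray(spec.planted_rho, dtype=float)
    k = rho.size
    Z = rng.standard_normal((n, k))
    Eps = rng.standard_normal((n, k))
    Zy = rho * Z + np.sqrt(1.0 - rho**2) * Eps
    Ax = _orthonormal(rng, p, k)
    Ay = _orthonormal(rng, q, k)
    Xv = Z @ Ax.T + spec.noise_sd * rng.standard_normal((n, p))
    Yv = Zy @ Ay.T + spec.noise_sd * rng.standard_normal((n, q))
    samples = [f"S{i + 1:04d}" for i in range(n)]
    x_ids = spec.x_feature_ids or [f"GENE{j + 1:04d}" for j in range(p)]
    y_ids = spec.y_feature_ids or [str(CHEBI_BASE + j + 1) for j in range(q)]
    X = OmicsMatrix(samples, list(x_ids), Xv, spec.x_namespace)
    Y = OmicsMatrix(samples, list(y_ids), Yv, spec.y_namespace)
    return X, Y


@dataclass
class FixtureKnowledgeBase:
    """Paths and content summary of a generated snapshot set."""

    paths: dict[str, str]
    metabolite_ids: list[int]  # query ids covering all resolution branches
    gene_symbols: list[str]
    pathway_ids: list[str]
    direct_ids: list[int] = field(default_factory=list)
    via_child_ids: list[int] = field(default_factory=list)
    via_parent_ids: list[int] = field(default_factory=list)
    unmapped_ids: list[int] = field(default_factory=list)


def generate_fixture_knowledgebase(
    n_metabolites: int,
    n_pathways: int,
    n_genes: int,
    ontology_depth: int,
    seed: int,
    out_dir: str | os.PathLike,
) -> FixtureKnowledgeBase:
    """Write a miniature four-file knowledge-base snapshot.

    The first four metabolite queries are constructed to resolve as DIRECT,
    VIA_CHILD, VIA_PARENT and UNMAPPED respectively (hence
    ``n_metabolites >= 4`` is required); the remainder map directly.  The
    VIA_CHILD query also carries a mapped parent at distance 1, so the
    child-over-parent precedence rule is genuinely exercised.  Ontology
    chain lengths never exceed ``ontology_depth``.
    """
    if n_metabolites < 4:
        raise ValueError("n_metabolites must be >= 4 to cover all resolution branches")
    if n_pathways < 1 or n_genes < 1 or ontology_depth < 1:
        raise ValueError("n_pathways, n_genes and ontology_depth must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{j + 1:04d}" for j in range(n_genes)]
    pathways = [f"PW{i + 1:03d}" for i in range(n_pathways)]

    # pathway membership: every gene belongs somewhere, plus random extras
    pathway2gene: dict[str, set[str]] = {pw: set() for pw in pathways}
    for g in genes:
        pathway2gene[pathways[int(rng.integers(n_pathways))]].add(g)
    for _ in range(n_genes):
        pw = pathways[int(rng.integers(n_pathways))]
        pathway2gene[pw].add(genes[int(rng.integers(n_genes))])

    next_id = CHEBI_BASE + 1

    def take() -> int:
        nonlocal next_id
        v = next_id
        next_id += 1
        return v

    queries: list[int] = [take() for _ in range(n_metabolites)]
    met2pathway: dict[int, set[str]] = {}
    ontology_edges: list[tuple[int, int]] = []  # child -> parent

    def map_met(chebi: int) -> None:
        n_pw = 1 + int(rng.integers(min(2, n_pathways)))
        chosen = rng.choice(n_pathways, size=n_pw, replace=False)
        met2pathway[chebi] = {pathways[i] for i in chosen}

    q_direct, q_child, q_parent, q_unmapped = queries[:4]
    map_met(q_direct)

    # VIA_CHILD: descendant chain below q_child; deepest node mapped;
    # plus a mapped parent at distance 1 so child precedence is tested
    depth = 1 + int(rng.integers(ontology_depth))
    node = q_child
    for _ in range(depth):
        child = take()
        ontology_edges.append((child, node))
        node = child
    map_met(node)
    parent = take()
    ontology_edges.append((q_child, parent))
    map_met(parent)
    via_child_distance = depth

    # VIA_PARENT: ancestor chain above q_parent; only the top is mapped
    depth = 1 + int(rng.integers(ontology_depth))
    node = q_parent
    for _ in range(depth):
        anc = take()
        ontology_edges.append((node, anc))
        node = anc
    map_met(node)

    # q_unmapped: absent from both the mapping table and the ontology
    for extra in queries[4:]:
        map_met(extra)

    # interactions: random gene pairs with uniform scores in [0, 1000]
    interactions: dict[frozenset, int] = {}
    n_edges = 2 * n_genes
    while len(interactions) < n_edges and n_genes > 1:
        i, j = rng.integers(n_genes, size=2)
        if i == j:
            continue
        key = frozenset((genes[i], genes[j]))
        if key not in interactions:
            interactions[key] = int(rng.integers(0, 1001))
        if len(interactions) >= n_genes * (n_genes - 1) // 2:
            break

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "met2pathway": os.path.join(out_dir, "chebi2reactome.tsv"),
        "pathway2gene": os.path.join(out_dir, "pathway2gene.tsv"),
        "ontology": os.path.join(out_dir, "ontology.tsv"),
        "interactions": os.path.join(out_dir, "interactions.tsv"),
    }
    with open(paths["met2pathway"], "w", encoding="utf-8", newline="\n") as fh:
        for chebi in sorted(met2pathway):
            for pw in sorted(met2pathway[chebi]):
                fh.write(f"CHEBI:{chebi}\t{pw}\tSynthetic pathway {pw}\tsynthetic\n")
    with open(paths["pathway2gene"], "w", encoding="utf-8", newline="\n") as fh:
        for pw in pathways:
            for g in sorted(pathway2gene[pw]):
                fh.write(f"{pw}\t{g}\n")
    with open(paths["ontology"], "w", encoding="utf-8", newline="\n") as fh:
        for child, par in ontology_edges:
            fh.write(f"CHEBI:{child}\tCHEBI:{par}\n")
    with open(paths["interactions"], "w", encoding="utf-8", newline="\n") as fh:
        for key in sorted(interactions, key=sorted):
            a, b = sorted(key)
            fh.write(f"{a}\t{b}\t{interactions[key]}\n")

    fixture = FixtureKnowledgeBase(
        paths=paths,
        metabolite_ids=queries,
        gene_symbols=genes,
        pathway_ids=pathways,
        direct_ids=[q_direct] + list(queries[4:]),
        via_child_ids=[q_child],
        via_parent_ids=[q_parent],
        unmapped_ids=[q_unmapped],
    )
    fixture.via_child_distance = via_child_distance  # type: ignore[attr-defined]
    return fixture
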