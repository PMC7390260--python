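"""Reading, validation and writing of omics matrices and knowledge-base snapshots.

Two kinds of inputs exist in the pipeline:

* **Omics matrices** — tab-delimited, samples in rows, features in columns.
  The transcriptomic matrix carries HGNC gene symbols as column headers; the
  metabolomic matrix carries ChEBI identifiers.  All values are assumed to be
  pre-normalized upstream; this module only validates structure.

* **Knowledge-base snapshots** — four tab-delimited files capturing the
  offline content needed for functional grouping: a metabolite→pathway table
  (ChEBI2Reactome dialect), a pathway→gene table, a ChEBI ontology edge table
  (child→parent), and a scored gene–gene interaction table (STRING dialect,
  combined score 0–1000).
"""

from __future__ import annotations

import enum
import os
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Namespace",
    "OmicsMatrix",
    "KnowledgeBase",
    "OmicsValidationError",
    "KnowledgeBaseError",
    "read_omics_matrix",
    "write_omics_matrix",
    "parse_knowledgebase",
    "normalize_chebi",
]

MIN_SAMPLES = 3  # below this no correlation has positive degrees of freedom


class OmicsValidationError(ValueError):
    """Raised when an omics matrix violates a structural invariant."""


class KnowledgeBaseError(ValueError):
    """Raised when a knowledge-base snapshot is malformed."""


class Namespace(str, enum.Enum):
    """Feature identifier namespace of an omics matrix."""

    HGNC = "HGNC"
    CHEBI = "CHEBI"
    ENSEMBL = "ENSEMBL"
    UNIPROT = "UNIPROT"


@dataclass
class OmicsMatrix:
    """A samples × features numeric table with a feature namespace.

    Parameters
    ----------
    sample_ids
        Row labels, unique, order preserved.
    feature_ids
        Column labels, unique, order preserved (column order matters for the
        greedy decorrelation step downstream).
    values
        Numeric array of shape ``(n_samples, n_features)`` with no missing
        entries.
    namespace
        Identifier namespace of the features.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    namespace: Namespace

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.namespace = Namespace(self.namespace)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise OmicsValidationError("values must be a 2-D array")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise OmicsValidationError(
                f"shape mismatch: values {self.values.shape}, "
                f"{len(self.sample_ids)} sample ids, {len(self.feature_ids)} feature ids"
            )
        if n == 0 or p == 0:
            raise OmicsValidationError("empty matrix")
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise OmicsValidationError(f"duplicate {name} id: {dup!r}")
        if n < MIN_SAMPLES:
            raise OmicsValidationError(
                f"at least {MIN_SAMPLES} samples required, got {n}"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise OmicsValidationError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    def select_features(self, feature_ids: list[str]) -> "OmicsMatrix":
        """Return a copy restricted to ``feature_ids`` (given order)."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise OmicsValidationError(f"unknown feature ids: {missing}")
        cols = [index[f] for f in feature_ids]
        return OmicsMatrix(
            sample_ids=list(self.sample_ids),
            feature_ids=list(feature_ids),
            values=self.values[:, cols].copy(),
            namespace=self.namespace,
        )


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_omics_matrix(path: str | os.PathLike, namespace: Namespace | str) -> OmicsMatrix:
    """Read a tab-delimited samples × features matrix.

    The first row holds feature identifiers, the first column sample
    identifiers, and every remaining cell must be numeric (missing values are
    rejected — downstream statistics assume complete data).  Column order is
    preserved exactly as in the file.
    """
    with open(path, "r", encoding="utf-8-sig", newline="") as fh:
        header = fh.readline().rstrip("\r\n")
    if not header:
        raise OmicsValidationError(f"{path}: empty file")
    feature_ids = header.split("\t")[1:]
    dup = _first_duplicate(feature_ids)
    if dup is not None:
        raise OmicsValidationError(f"{path}: duplicate feature id: {dup!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, encoding="utf-8-sig")
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise OmicsValidationError(f"{path}: empty matrix")
    sample_ids = [str(s) for s in raw.index]

    def _bad_cell(i: int, j: int, cell) -> OmicsValidationError:
        what = "missing value" if pd.isna(cell) else f"non-numeric cell {cell!r}"
        return OmicsValidationError(
            f"{path}: {what} at row {sample_ids[i]!r} (line {i + 2}), "
            f"column {feature_ids[j]!r}"
        )

    cells = raw.to_numpy(dtype=object)
    try:
        # float() per cell is round-trip exact, unlike pandas' fast parser
        values = cells.astype(np.float64)
    except (ValueError, TypeError):
        for (i, j), cell in np.ndenumerate(cells):
            try:
                float(cell)
            except (ValueError, TypeError):
                raise _bad_cell(i, j, cell) from None
        raise  # pragma: no cover - unreachable
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise _bad_cell(i, j, raw.iat[i, j])
    return OmicsMatrix(
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        values=values,
        namespace=Namespace(namespace),
    )


def write_omics_matrix(m: OmicsMatrix, path: str | os.PathLike) -> None:
    """Write a matrix as TSV using repr-roundtrip float formatting.

    The decimal text uses :func:`repr`-style shortest representation so a
    write/read cycle reproduces the values bit-for-bit.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\t" + "\t".join(m.feature_ids) + "\n")
        for sid, row in zip(m.sample_ids, m.values):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Knowledge-base snapshots
# ---------------------------------------------------------------------------

_CHEBI_RE = re.compile(r"^(?:CHEBI:)?(\d+)$", re.IGNORECASE)


def normalize_chebi(value: str | int) -> int:
    """Normalize a ChEBI identifier to a bare integer.

    Accepts ``28125``, ``"28125"`` or ``"CHEBI:28125"`` (case-insensitive
    prefix).  Anything else is a hard error.
    """
    if isinstance(value, (int, np.integer)):
        return int(value)
    m = _CHEBI_RE.match(str(value).strip())
    if m is None:
        raise KnowledgeBaseError(f"not a ChEBI identifier: {value!r}")
    return int(m.group(1))


@dataclass
class KnowledgeBase:
    """Parsed offline knowledge snapshot used for functional grouping.

    Attributes
    ----------
    met2pathway
        ChEBI id (bare integer) → set of pathway ids.
    pathway2gene
        Pathway id → set of gene symbols (uppercased).
    ontology
        Directed acyclic graph over ChEBI ids; each edge points child→parent.
    interactions
        Undirected gene–gene graph; each edge carries an integer
        ``score`` ∈ [0, 1000] (STRING combined score).
    species
        Free-text species label, logged but never enforced.
    """

    met2pathway: dict[int, set[str]] = field(default_factory=dict)
    pathway2gene: dict[str, set[str]] = field(default_factory=dict)
    ontology: nx.DiGraph = field(default_factory=nx.DiGraph)
    interactions: nx.Graph = field(default_factory=nx.Graph)
    species: str = "unspecified"

    def __eq__(self, other: object) -> bool:  # order-insensitive equality
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (
            self.met2pathway == other.met2pathway
            and self.pathway2gene == other.pathway2gene
            and set(self.ontology.edges) == set(other.ontology.edges)
            and set(self.ontology.nodes) == set(other.ontology.nodes)
            and {frozenset(e) for e in self.interactions.edges}
            == {frozenset(e) for e in other.interactions.edges}
            and all(
                self.interactions.edges[e]["score"] == other.interactions.edges[e]["score"]
                for e in self.interactions.edges
            )
            and self.species == other.species
        )


def _read_tsv_rows(path: str | os.PathLike, min_cols: int) -> list[list[str]]:
    rows = []
    with open(path, "r", encoding="utf-8-sig", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise KnowledgeBaseError(
                    f"{path}: line {lineno}: expected at least {min_cols} "
                    f"tab-separated columns, got {len(parts)}"
                )
            rows.append(parts)
    return rows


def parse_knowledgebase(
    met2pathway_path: str | os.PathLike,
    pathway2gene_path: str | os.PathLike,
    ontology_path: str | os.PathLike,
    interactions_path: str | os.PathLike,
    species: str = "unspecified",
) -> KnowledgeBase:
    """Parse the four snapshot files into a :class:`KnowledgeBase`.

    ChEBI ids are normalized to bare integers and gene symbols uppercased.
    The ontology is checked for cycles (a cyclic "ontology" would make the
    nearest-representative search ill-defined) and interaction scores must
    lie in [0, 1000].
    """
    kb = KnowledgeBase(species=species)

    for parts in _read_tsv_rows(met2pathway_path, 2):
        chebi = normalize_chebi(parts[0])
        kb.met2pathway.setdefault(chebi, set()).add(parts[1])

    for parts in _read_tsv_rows(pathway2gene_path, 2):
        kb.pathway2gene.setdefault(parts[0], set()).add(parts[1].upper())

    for parts in _read_tsv_rows(ontology_path, 2):
        child, parent = normalize_chebi(parts[0]), normalize_chebi(parts[1])
        kb.ontology.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(kb.ontology):
        cycle = nx.find_cycle(kb.ontology)
        pretty = " -> ".join(str(a) for a, _ in cycle) + f" -> {cycle[0][0]}"
        raise KnowledgeBaseError(f"{ontology_path}: ontology contains a cycle: {pretty}")

    for parts in _read_tsv_rows(interactions_path, 3):
        a, b = parts[0].upper(), parts[1].upper()
        try:
            score = int(parts[2])
        except ValueError as exc:
            raise KnowledgeBaseError(
                f"{interactions_path}: non-integer score {parts[2]!r} for edge {a}-{b}"
            ) from exc
        if not 0 <= score <= 1000:
            raise KnowledgeBaseError(
                f"{interactions_path}: score {score} outside [0, 1000] for edge {a}-{b}"
            )
        kb.interactions.add_edge(a, b, score=score)

    return kb
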