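"""On-disk formats and validated in-memory containers.

Three inputs drive the pipeline: a binary miRNA-disease association
matrix ``A`` (edge list or dense TSV), a precomputed miRNA functional
similarity matrix (dense TSV, MISIM-style), and a disease ontology given
as a child->parent edge list whose per-disease sub-DAGs define semantic
similarity.  All identifiers are matched case-sensitively; no
normalisation across miRBase versions is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseOntology",
    "read_associations",
    "write_associations",
    "read_similarity",
    "write_similarity",
    "read_ontology",
    "write_ontology",
    "write_scores",
]

#: asymmetry larger than this in a similarity table is an error;
#: smaller asymmetries (float-formatting noise) are repaired by averaging
ASYMMETRY_TOL = 1e-8


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValueError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class AssociationMatrix:
    """Binary ``nm x nd`` matrix of known miRNA-disease associations."""

    mirna_ids: list[str]
    disease_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        nm, nd = len(self.mirna_ids), len(self.disease_ids)
        if nm < 1 or nd < 1:
            raise ValueError("need at least one miRNA and one disease")
        if self.A.shape != (nm, nd):
            raise ValueError(f"A has shape {self.A.shape}, expected ({nm}, {nd})")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.A = self.A.astype(np.int8)
        _check_unique(self.mirna_ids, "miRNA")
        _check_unique(self.disease_ids, "disease")

    @property
    def nm(self) -> int:
        return len(self.mirna_ids)

    @property
    def nd(self) -> int:
        return len(self.disease_ids)

    @property
    def n_known(self) -> int:
        return int(self.A.sum())

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(list(self.mirna_ids), list(self.disease_ids), self.A.copy())


@dataclass
class SimilarityMatrix:
    """Square symmetric matrix of pairwise similarities in [0, 1]."""

    ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.ids)
        if self.S.shape != (n, n):
            raise ValueError(f"similarity matrix has shape {self.S.shape}, expected ({n}, {n})")
        if np.isnan(self.S).any():
            raise ValueError("similarity matrix contains NaN")
        if (self.S < 0).any() or (self.S > 1 + ASYMMETRY_TOL).any():
            raise ValueError("similarity values must lie in [0, 1]")
        asym = np.abs(self.S - self.S.T).max() if n else 0.0
        if asym > ASYMMETRY_TOL:
            raise ValueError(f"similarity matrix asymmetric (max |S - S^T| = {asym:g})")
        # repair float-formatting noise
        self.S = np.clip((self.S + self.S.T) / 2.0, 0.0, 1.0)
        _check_unique(self.ids, "similarity")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class DiseaseOntology:
    """Forest of disease DAGs given as a child->parent edge relation.

    ``graph`` stores edges child -> parent, so the ancestors of a term
    are the nodes reachable from it.  ``disease_ids`` are the diseases
    of interest: the universe over which per-term DAG-membership counts
    (hence semantic values) are computed.
    """

    terms: set[str]
    edges: set[tuple[str, str]]
    disease_ids: list[str]
    graph: nx.DiGraph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parent in self.edges:
            if child == parent:
                raise ValueError(f"self-loop at ontology term {child!r}")
            g.add_edge(child, parent)
        self.terms = set(g.nodes)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle through {cycle[0][0]!r}")
        missing = [d for d in self.disease_ids if d not in self.terms]
        if missing:
            raise ValueError(f"disease ids not in ontology terms: {missing[:5]}")
        _check_unique(self.disease_ids, "disease")
        self.graph = g

    def dag_terms(self, disease: str) -> set[str]:
        """Ancestor terms of *disease* plus the disease itself (the set D(d))."""
        if disease not in self.terms:
            raise KeyError(f"unknown ontology term {disease!r}")
        return nx.descendants(self.graph, disease) | {disease}


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv_rows(path: str | Path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    return rows


def read_associations(
    path: str | Path,
    format: str = "edge-list",
    mirna_ids: Sequence[str] | None = None,
    disease_ids: Sequence[str] | None = None,
) -> AssociationMatrix:
    """Read an association matrix from an edge list or a dense TSV.

    Edge-list rows are ``miRNA_id<TAB>disease_id``; identifier order is
    first-appearance order unless an explicit universe is supplied.
    Dense format carries identifiers in the header row and first column.
    Duplicate edges warn and are idempotent.
    """
    if format == "edge-list":
        m_order = list(mirna_ids) if mirna_ids is not None else []
        d_order = list(disease_ids) if disease_ids is not None else []
        m_fixed, d_fixed = mirna_ids is not None, disease_ids is not None
        edges: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        for row in _read_tsv_rows(path):
            if len(row) < 2:
                raise ValueError(f"edge-list row needs 2 columns, got {row!r}")
            m, d = row[0], row[1]
            if (m, d) in seen:
                warnings.warn(f"duplicate association edge ({m!r}, {d!r})", stacklevel=2)
                continue
            seen.add((m, d))
            edges.append((m, d))
            if m not in m_order:
                if m_fixed:
                    raise ValueError(f"miRNA {m!r} not in declared universe")
                m_order.append(m)
            if d not in d_order:
                if d_fixed:
                    raise ValueError(f"disease {d!r} not in declared universe")
                d_order.append(d)
        mi = {m: i for i, m in enumerate(m_order)}
        di = {d: j for j, d in enumerate(d_order)}
        A = np.zeros((len(m_order), len(d_order)), dtype=np.int8)
        for m, d in edges:
            A[mi[m], di[d]] = 1
        return AssociationMatrix(m_order, d_order, A)
    if format == "dense":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        A = df.to_numpy()
        if not np.isin(A, (0, 1)).all():
            raise ValueError("dense association matrix must be binary")
        return AssociationMatrix([str(i) for i in df.index], [str(c) for c in df.columns], A)
    raise ValueError(f"unknown association format {format!r} (use 'edge-list' or 'dense')")


def write_associations(am: AssociationMatrix, path: str | Path, format: str = "edge-list") -> None:
    if format == "edge-list":
        with open(path, "w") as fh:
            for i, j in np.argwhere(am.A == 1):
                fh.write(f"{am.mirna_ids[i]}\t{am.disease_ids[j]}\n")
    elif format == "dense":
        pd.DataFrame(am.A, index=am.mirna_ids, columns=am.disease_ids).to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown association format {format!r}")


def read_similarity(path: str | Path) -> SimilarityMatrix:
    """Read a dense similarity TSV with matching row/column identifiers."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"similarity table is not square: {df.shape}")
    rows = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise ValueError("row and column identifiers differ")
    return SimilarityMatrix(rows, df.to_numpy(dtype=float))


def write_similarity(sm: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sm.S, index=sm.ids, columns=sm.ids).to_csv(path, sep="\t")


def read_ontology(path: str | Path, diseases: Iterable[str] | str | Path | None = None) -> DiseaseOntology:
    """Read a child<TAB>parent edge list; optionally restrict the diseases of interest.

    *diseases* may be an iterable of term ids or a path to a one-id-per-line
    file.  Without it, every term is a disease of interest.
    """
    edges: set[tuple[str, str]] = set()
    terms: set[str] = set()
    for row in _read_tsv_rows(path):
        if len(row) < 2:
            raise ValueError(f"ontology row needs 2 columns, got {row!r}")
        child, parent = row[0], row[1]
        edges.add((child, parent))
        terms.update((child, parent))
    if diseases is None:
        disease_ids = sorted(terms)
    elif isinstance(diseases, (str, Path)):
        disease_ids = [r[0] for r in _read_tsv_rows(diseases)]
    else:
        disease_ids = list(diseases)
    return DiseaseOntology(terms, edges, disease_ids)


def write_ontology(onto: DiseaseOntology, path: str | Path) -> None:
    with open(path, "w") as fh:
        for child, parent in sorted(onto.edges):
            fh.write(f"{child}\t{parent}\n")


def write_scores(
    pairs: Sequence[tuple[str, str]],
    scores: Sequence[float],
    path: str | Path,
) -> pd.DataFrame:
    """Write a ranked score table (rank 1 = highest; ties keep input order)."""
    if len(pairs) != len(scores):
        raise ValueError(f"{len(pairs)} pairs but {len(scores)} scores")
    df = pd.DataFrame(
        {
            "miRNA_id": [p[0] for p in pairs],
            "disease_id": [p[1] for p in pairs],
            "score": np.asarray(scores, dtype=float),
        }
    )
    order = np.argsort(-df["score"].to_numpy(), kind="stable")
    rank = np.empty(len(df), dtype=int)
    rank[order] = np.arange(1, len(df) + 1)
    df["rank"] = rank
    df.to_csv(path, sep="\t", index=False)
    return df
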