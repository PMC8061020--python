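"""Self-contained synthetic benchmark generator.

Emulates the three real inputs without downloads: a sparse binary
association matrix with planted block (co-cluster) structure, a noisy
block-structured base similarity matrix with structural zeros (mirroring
the sparsity of precomputed functional-similarity tables), and a forest
of layered disease DAGs whose subtree membership follows the disease
blocks, so DAG semantic similarity carries real within-block signal.

The planted-truth set — within-block pairs that happen to be zero in A —
serves as held-out ground truth for end-to-end recovery tests: a good
model should rank them above out-of-block unknown pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import (
    AssociationMatrix,
    DiseaseOntology,
    SimilarityMatrix,
    write_associations,
    write_ontology,
    write_similarity,
)

__all__ = ["SyntheticSpec", "generate", "planted_truth", "write_dataset"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted block model.

    Within a co-cluster an association occurs with probability
    ``density_in``, outside with ``density_out``; ``sim_noise`` is the SD
    of Gaussian noise on the block-indicator base similarity and
    ``sim_sparsity`` the fraction of off-diagonal entries forced to zero.
    """

    nm: int = 30
    nd: int = 20
    n_blocks: int = 3
    density_in: float = 0.5
    density_out: float = 0.02
    sim_noise: float = 0.1
    sim_sparsity: float = 0.3
    dag_depth: int = 3
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.density_in <= 1 or not 0 <= self.density_out < 1:
            raise ValueError("densities out of range")
        if self.density_in <= self.density_out:
            raise ValueError("density_in must exceed density_out")
        if self.n_blocks < 1 or self.nm < self.n_blocks or self.nd < self.n_blocks:
            raise ValueError("need nm, nd >= n_blocks >= 1")
        if self.sim_noise < 0 or not 0 <= self.sim_sparsity < 1:
            raise ValueError("sim_noise/sim_sparsity out of range")
        if self.dag_depth < 1:
            raise ValueError("dag_depth must be >= 1")


def _blocks(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous block assignment for n entities."""
    return np.repeat(np.arange(n_blocks), np.diff(np.linspace(0, n, n_blocks + 1).astype(int)))


def generate(spec: SyntheticSpec) -> tuple[AssociationMatrix, SimilarityMatrix, DiseaseOntology]:
    rng = np.random.default_rng(spec.seed)
    mb = _blocks(spec.nm, spec.n_blocks)
    db = _blocks(spec.nd, spec.n_blocks)
    mirna_ids = [f"miR-{i:03d}" for i in range(spec.nm)]
    disease_ids = [f"D{j:03d}" for j in range(spec.nd)]

    same = mb[:, None] == db[None, :]
    prob = np.where(same, spec.density_in, spec.density_out)
    A = (rng.random((spec.nm, spec.nd)) < prob).astype(np.int8)
    am = AssociationMatrix(mirna_ids, disease_ids, A)

    S = (mb[:, None] == mb[None, :]).astype(float)
    noise = rng.normal(0.0, spec.sim_noise, size=S.shape)
    S = np.clip(S + (noise + noise.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    iu, ju = np.triu_indices(spec.nm, k=1)
    zero_mask = rng.random(iu.size) < spec.sim_sparsity
    S[iu[zero_mask], ju[zero_mask]] = 0.0
    S[ju[zero_mask], iu[zero_mask]] = 0.0
    base_sm = SimilarityMatrix(mirna_ids, S)

    # one layered DAG chain per block; diseases attach below their block's chain
    edges: set[tuple[str, str]] = set()
    for b in range(spec.n_blocks):
        chain = [f"T{b}L{lvl}" for lvl in range(spec.dag_depth)]
        for child, parent in zip(chain[1:], chain[:-1]):
            edges.add((child, parent))
        for j in np.flatnonzero(db == b):
            edges.add((disease_ids[j], chain[-1]))
    terms = {t for e in edges for t in e}
    onto = DiseaseOntology(terms, edges, disease_ids)
    return am, base_sm, onto


def planted_truth(spec: SyntheticSpec, am: AssociationMatrix) -> set[tuple[int, int]]:
    """Within-block pairs that are zero in A: unknown but structurally likely."""
    mb = _blocks(am.nm, spec.n_blocks)
    db = _blocks(am.nd, spec.n_blocks)
    same = mb[:, None] == db[None, :]
    return {tuple(p) for p in np.argwhere(same & (am.A == 0))}


def write_dataset(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Materialize the synthetic dataset in the on-disk interchange formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    am, base_sm, onto = generate(spec)
    paths = {
        "associations": out / "associations.tsv",
        "similarity": out / "mirna_similarity.tsv",
        "ontology": out / "ontology.tsv",
        "diseases": out / "diseases.tsv",
    }
    write_associations(am, paths["associations"])
    write_similarity(base_sm, paths["similarity"])
    write_ontology(onto, paths["ontology"])
    with open(paths["diseases"], "w") as fh:
        fh.write("\n".join(onto.disease_ids) + "\n")
    return paths
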