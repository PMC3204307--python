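"""Mitotype dissimilarity and UPGMA clustering.

The dissimilarity between two circular genomes G1, G2 is

    d = (2*N_SNP + L_Indel1 + L_Indel2) / (L_G1 + L_G2)

where N_SNP counts single-nucleotide substitutions inside syntenic blocks
and L_Indel1/L_Indel2 are the summed lengths of the > 400 bp insertion
sequences carried by each genome.  The matrix of pairwise d values feeds
classic UPGMA (average linkage), merging at height d/2 so that the
leaf-to-leaf path length equals d; ties break on the lexicographically
smallest label pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compare import count_snps, extract_indels, find_synteny_blocks

__all__ = [
    "DissimilarityResult",
    "UpgmaNode",
    "dissimilarity",
    "dissimilarity_matrix",
    "upgma",
]


@dataclass(frozen=True)
class DissimilarityResult:
    pair: tuple[str, str]
    n_snp: int
    l_indel1: int
    l_indel2: int
    l_g1: int
    l_g2: int

    @property
    def d(self) -> float:
        return (2 * self.n_snp + self.l_indel1 + self.l_indel2) / (
            self.l_g1 + self.l_g2
        )


def dissimilarity(n_snp, l_indel1, l_indel2, l_g1, l_g2, pair=("G1", "G2")):
    """Apply the dissimilarity formula; no rounding is stored."""
    if min(n_snp, l_indel1, l_indel2) < 0:
        raise ValueError("divergence terms must be >= 0")
    if l_g1 <= 0 or l_g2 <= 0:
        raise ValueError("genome lengths must be positive")
    return DissimilarityResult(tuple(pair), n_snp, l_indel1, l_indel2, l_g1, l_g2)


def pairwise_dissimilarity(a, b, min_block: int = 400, min_indel: int = 400):
    """Full compare pipeline (blocks -> SNPs -> indels) for one pair."""
    blocks = find_synteny_blocks(a, b, min_block=min_block)
    snp = count_snps(a, b, blocks) if blocks else None
    n_snp = snp.n_snp if snp else 0
    indels = extract_indels(a, b, blocks, min_indel=min_indel)
    l1 = sum(r.length for r in indels if r.carrier_genome == a.id)
    l2 = sum(r.length for r in indels if r.carrier_genome == b.id)
    if not blocks:
        # no homology at all: the genomes differ over their entire lengths
        l1, l2 = a.length, b.length
    return dissimilarity(n_snp, l1, l2, a.length, b.length, pair=(a.id, b.id))


def dissimilarity_matrix(genomes, min_block: int = 400, min_indel: int = 400):
    """Symmetric matrix of pairwise d over a genome panel.

    Returns ``(matrix as DataFrame, dict of DissimilarityResult by pair)``.
    """
    if len(genomes) < 2:
        raise ValueError("need >= 2 genomes")
    labels = [g.id for g in genomes]
    n = len(labels)
    mat = np.zeros((n, n))
    results = {}
    for i in range(n):
        for j in range(i + 1, n):
            try:
                res = pairwise_dissimilarity(
                    genomes[i], genomes[j], min_block, min_indel
                )
            except Exception as exc:  # pragma: no cover - context propagation
                raise RuntimeError(
                    f"pair ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
            mat[i, j] = mat[j, i] = res.d
            results[(labels[i], labels[j])] = res
    return pd.DataFrame(mat, index=labels, columns=labels), results


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class UpgmaNode:
    """A rooted ultrametric tree node; leaves have height 0."""

    label: str | None
    height: float
    children: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf:
            return self.label
        parts = [
            f"{c._nwk()}:{self.height - c.height:.10g}" for c in self.children
        ]
        return "(" + ",".join(parts) + ")"


def upgma(matrix, labels=None, atol: float = 1e-9) -> UpgmaNode:
    """Classic average-linkage agglomeration on a dissimilarity matrix.

    Merge height is d/2.  Among equal minimal distances the pair whose
    sorted label tuple is lexicographically smallest merges first (labels
    of internal clusters are the sorted concatenation of their leaves).
    """
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index) if labels is None else list(labels)
        mat = matrix.values.astype(float)
    else:
        mat = np.asarray(matrix, dtype=float)
        labels = list(labels)
    n = len(labels)
    if mat.shape != (n, n):
        raise ValueError("matrix/labels size mismatch")
    if not np.allclose(mat, mat.T, atol=atol):
        raise ValueError("matrix is not symmetric")
    if n < 2:
        raise ValueError("need >= 2 labels")

    clusters = {
        i: (UpgmaNode(labels[i], 0.0), 1, tuple([labels[i]])) for i in range(n)
    }
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = mat[i, j]
    next_id = n
    while len(clusters) > 1:
        best = None
        for (i, j), dv in dist.items():
            key = (
                dv,
                tuple(sorted(min(clusters[i][2], clusters[j][2]))),
                tuple(sorted(max(clusters[i][2], clusters[j][2]))),
            )
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        d_ij = dist.pop((i, j))
        node_i, size_i, leaves_i = clusters.pop(i)
        node_j, size_j, leaves_j = clusters.pop(j)
        merged = UpgmaNode(
            None,
            d_ij / 2.0,
            children=tuple(
                sorted((node_i, node_j), key=lambda nd: sorted(nd.leaves()))
            ),
        )
        for k in list(clusters):
            d_ik = dist.pop(tuple(sorted((i, k))))
            d_jk = dist.pop(tuple(sorted((j, k))))
            dist[tuple(sorted((next_id, k)))] = (
                size_i * d_ik + size_j * d_jk
            ) / (size_i + size_j)
        clusters[next_id] = (
            merged,
            size_i + size_j,
            tuple(sorted(leaves_i + leaves_j)),
        )
        next_id += 1
    return next(iter(clusters.values()))[0]
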