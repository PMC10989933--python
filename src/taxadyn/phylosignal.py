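"""Phylogenetic signal in estimated competition strengths.

If resource competition is trait-driven, closely related taxa (similar
16S sequences) should have similar competition strengths: across taxon
pairs, |k1_i - k1_j| should correlate negatively with sequence
similarity, at least above some similarity threshold.  This module
computes pairwise global-alignment identities and the Spearman rank
correlation between similarity and competition-strength difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .data_io import SequenceSet

__all__ = [
    "SimilarityMatrix",
    "pairwise_identity",
    "competition_similarity_correlation",
]


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise sequence-similarity matrix in [0, 1]."""

    taxon_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxon_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match taxon ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("similarity matrix diagonal must be 1")

    def get(self, a: str, b: str) -> float:
        i, j = self.taxon_ids.index(a), self.taxon_ids.index(b)
        return float(self.values[i, j])


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


def _identity(aligner: Align.PairwiseAligner, a: str, b: str) -> float:
    aln = aligner.align(a, b)[0]
    sa, sb = aln[0], aln[1]
    matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
    return matches / len(sa)


def pairwise_identity(seqs: SequenceSet) -> SimilarityMatrix:
    """Global-alignment identity for every sequence pair.

    Scoring: match +1, mismatch -1, gap -2; similarity is the fraction
    of matching columns over the alignment length.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    for tid, s in seqs.items():
        if not s:
            raise ValueError(f"empty sequence for {tid!r}")
    ids = list(seqs)
    n = len(ids)
    aligner = _make_aligner()
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = _identity(aligner, seqs[ids[i]], seqs[ids[j]])
    return SimilarityMatrix(taxon_ids=ids, values=values)


def competition_similarity_correlation(
    params: pd.DataFrame,
    sim: SimilarityMatrix,
    min_similarity: float = 0.70,
) -> dict:
    """Spearman correlation of similarity vs competition-strength difference.

    ``params`` is the competition-parameter table (columns ``taxon_id``,
    ``resource_name``, ``k1_j``).  Over all unordered taxon pairs with
    similarity >= ``min_similarity``, correlates similarity with
    |k1_i - k1_j| (Euclidean distance between k1 vectors when several
    resources are present).  A trait-driven community yields a negative
    rho.
    """
    wide = params.pivot(index="taxon_id", columns="resource_name", values="k1_j")
    taxa = [t for t in sim.taxon_ids if t in wide.index]
    if len(taxa) < 2:
        raise ValueError("fewer than two taxa shared between params and similarity")
    k1 = wide.loc[taxa].to_numpy(dtype=float)
    idx = [sim.taxon_ids.index(t) for t in taxa]
    S = sim.values[np.ix_(idx, idx)]

    sims, diffs = [], []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            if S[i, j] >= min_similarity:
                sims.append(S[i, j])
                diffs.append(float(np.linalg.norm(k1[i] - k1[j])))
    n_pairs = len(sims)
    if n_pairs < 10:
        raise ValueError(
            f"only {n_pairs} pairs above similarity {min_similarity}; need >= 10"
        )
    diffs_arr = np.asarray(diffs)
    if np.ptp(diffs_arr) == 0 or np.ptp(sims) == 0:
        return {
            "rho": np.nan,
            "p_value": np.nan,
            "n_pairs": n_pairs,
            "degenerate": True,
        }
    rho, p = stats.spearmanr(sims, diffs)
    return {
        "rho": float(rho),
        "p_value": float(p),
        "n_pairs": n_pairs,
        "degenerate": False,
    }
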