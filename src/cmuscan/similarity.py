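"""Asymmetric (Tversky alpha=1, beta=0) similarity between CMU sets.

``Asy(S1, S2)`` is the fraction of S1's CMU regions that share at least
one basepair with some CMU region of S2.  It is deliberately asymmetric:
``Asy(S1, S2) = 1`` says S1's units are fully represented within S2 even
when S2 carries many regions S1 lacks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import intervals as iv
from .icm import CMUSet

RegionSet = "CMUSet | Sequence[tuple[str, int, int]]"


def _as_regions(s) -> list[tuple[str, int, int]]:
    if isinstance(s, CMUSet):
        return s.regions()
    return [(str(c), int(a), int(b)) for c, a, b in s]


@dataclass
class AsymmetricSimilarityMatrix:
    """All-pairs Asy scores across datasets, with row/column medians.

    ``distance`` is 1 - Pearson correlation of score columns, suitable for
    complete-linkage hierarchical clustering of datasets.
    """

    labels: list[str]
    scores: np.ndarray
    row_medians: np.ndarray
    col_medians: np.ndarray
    distance: np.ndarray


def asymmetric_similarity(s1, s2) -> float:
    """Fraction of S1 CMU regions overlapping (>=1 bp) any S2 CMU region."""
    r1 = _as_regions(s1)
    r2 = _as_regions(s2)
    if not r1:
        raise ValueError("Asy(S1, S2) undefined for empty S1")
    if not r2:
        return 0.0
    targets = iv.by_chrom(r2)
    queries = iv.by_chrom(r1)
    n_hit = 0
    for chrom, (qs, qe) in queries.items():
        if chrom not in targets:
            continue
        ts, te = targets[chrom]
        n_hit += int(iv.overlaps_any(qs, qe, ts, te).sum())
    return n_hit / len(r1)


def similarity_matrix(sets: Sequence, labels: Sequence[str] | None = None) -> AsymmetricSimilarityMatrix:
    """Asy(S_i, S_j) for every ordered pair of >= 2 non-empty CMU sets."""
    if len(sets) < 2:
        raise ValueError("need at least 2 CMU sets")
    if labels is None:
        labels = [
            s.dataset if isinstance(s, CMUSet) else f"set{i}" for i, s in enumerate(sets)
        ]
    for lbl, s in zip(labels, sets):
        if not _as_regions(s):
            raise ValueError(f"CMU set '{lbl}' is empty")
    n = len(sets)
    scores = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                scores[i, j] = asymmetric_similarity(sets[i], sets[j])
    off = ~np.eye(n, dtype=bool)
    row_med = np.array([np.median(scores[i, off[i]]) for i in range(n)])
    col_med = np.array([np.median(scores[off[:, j], j]) for j in range(n)])
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(scores, rowvar=False)
    cor = np.nan_to_num(cor, nan=0.0)  # constant columns: no correlation signal
    np.fill_diagonal(cor, 1.0)
    distance = 1.0 - cor
    return AsymmetricSimilarityMatrix(
        labels=list(labels),
        scores=scores,
        row_medians=row_med,
        col_medians=col_med,
        distance=distance,
    )
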