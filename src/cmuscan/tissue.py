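"""Tissue-independent (TI) CMU region calling across many datasets.

A genomic region is tissue independent when it lies inside a CMU in
strictly more than 80% of unique tissues.  The implementation stacks each
tissue's (merged) CMU intervals and takes maximal basepair runs whose
coverage depth exceeds the threshold — the "largest region of overlap"
across tissues.  Non-contiguous units are compared by their spans (first
member start to last member end), which tolerates boundary variation of
the member CMUs between tissues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import intervals as iv
from .icm import CMUSet

DEFAULT_TI_THRESHOLD = 0.8


@dataclass
class TIRegion:
    """A region supported by strictly more than the threshold fraction of tissues."""

    chrom: str
    start: int
    end: int
    support_count: int
    support_fraction: float
    kind: str  # "contiguous" | "noncontiguous"

    @property
    def length(self) -> int:
        return self.end - self.start


def dedupe_by_tissue(sets: Sequence[CMUSet]) -> list[CMUSet]:
    """One dataset per unique tissue: largest n_samples, then label order."""
    best: dict[str, CMUSet] = {}
    for s in sets:
        key = s.tissue or s.dataset
        cur = best.get(key)
        if (
            cur is None
            or s.n_samples > cur.n_samples
            or (s.n_samples == cur.n_samples and s.dataset < cur.dataset)
        ):
            best[key] = s
    return [best[k] for k in sorted(best)]


def _min_depth(ti_threshold: float, n_tissues: int) -> int:
    # strictly more than threshold * n tissues
    return int(np.floor(ti_threshold * n_tissues + 1e-9)) + 1


def _stack_regions(
    per_tissue_regions: list[list[tuple[str, int, int]]],
    ti_threshold: float,
    kind: str,
    exclude: Sequence[tuple[str, int, int]] | None = None,
) -> list[TIRegion]:
    n = len(per_tissue_regions)
    if n < 2:
        raise ValueError("TI calling needs >= 2 tissues")
    excl = iv.by_chrom(exclude) if exclude else {}
    min_depth = _min_depth(ti_threshold, n)
    stacked: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for regions in per_tissue_regions:
        # merge within tissue so depth counts tissues, not intervals
        for chrom, (s, e) in iv.by_chrom(regions).items():
            if chrom in excl:
                s, e = iv.subtract(*iv.merge(s, e), *excl[chrom])
            else:
                s, e = iv.merge(s, e)
            if s.size:
                stacked.setdefault(chrom, []).append((s, e))
    out: list[TIRegion] = []
    for chrom in sorted(stacked):
        starts = np.concatenate([s for s, _ in stacked[chrom]])
        ends = np.concatenate([e for _, e in stacked[chrom]])
        for s, e, depth in iv.coverage_runs(starts, ends, min_depth):
            out.append(
                TIRegion(
                    chrom=chrom,
                    start=s,
                    end=e,
                    support_count=depth,
                    support_fraction=depth / n,
                    kind=kind,
                )
            )
    return out


def ti_contiguous_regions(
    sets: Sequence[CMUSet],
    ti_threshold: float = DEFAULT_TI_THRESHOLD,
    min_cpgs: int = 10,
    exclude: Sequence[tuple[str, int, int]] | None = None,
    dedupe: bool = True,
) -> list[TIRegion]:
    """TI contiguous CMU regions from one CMU set per unique tissue.

    Only CMUs with strictly more than ``min_cpgs`` probes participate
    (higher-confidence units); ``exclude`` intervals (e.g. the HLA region)
    are removed before stacking.
    """
    use = dedupe_by_tissue(sets) if dedupe else list(sets)
    per_tissue = [
        [(c.chrom, c.start, c.end) for c in s.contiguous if c.n_probes > min_cpgs]
        for s in use
    ]
    return _stack_regions(per_tissue, ti_threshold, "contiguous", exclude)


def ti_noncontiguous_regions(
    sets: Sequence[CMUSet],
    ti_threshold: float = DEFAULT_TI_THRESHOLD,
    min_members: int = 3,
    exclude: Sequence[tuple[str, int, int]] | None = None,
    dedupe: bool = True,
) -> list[TIRegion]:
    """TI non-contiguous CMU regions: span intersection across tissues.

    Per tissue, only non-contiguous CMUs with >= ``min_members`` member
    CMUs are considered; each contributes its span (first member start to
    last member end), so member boundary variation between tissues does
    not break the intersection.
    """
    use = dedupe_by_tissue(sets) if dedupe else list(sets)
    per_tissue = [
        [nc.span for nc in s.noncontiguous if nc.n_members >= min_members]
        for s in use
    ]
    return _stack_regions(per_tissue, ti_threshold, "noncontiguous", exclude)
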