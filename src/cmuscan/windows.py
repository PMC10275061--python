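"""Fixed non-overlapping genomic windows and per-window correlation images.

Chromosomes are tiled into 250 kb windows anchored at coordinate 0 (strong
inter-CpG correlation extends ~10 kb on average, so a 250 kb window holds
several candidate units while keeping each correlation matrix small).  The
Pearson correlation matrix of all probe pairs within a window is the
"image" that the ICM stage segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BetaMatrix, ProbeManifest

DEFAULT_WINDOW_SIZE = 250_000


@dataclass
class Window:
    """One genomic tile: [start, end) with the manifest indices it contains."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    probe_indices: np.ndarray  # ordered indices into the manifest

    @property
    def n_probes(self) -> int:
        return self.probe_indices.size


@dataclass
class CorrelationImage:
    """Symmetric Pearson matrix for one window, treated as an image.

    ``n_pairs_used`` counts the complete sample pairs behind each entry;
    entries with overlap below the floor, or involving a zero-variance
    probe, are set to 0 and recorded in ``flagged``.
    """

    window: Window
    R: np.ndarray
    n_pairs_used: np.ndarray
    flagged: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=bool))


def tile_windows(
    manifest: ProbeManifest, window_size: int = DEFAULT_WINDOW_SIZE
) -> list[Window]:
    """Tile each chromosome into [k*W, (k+1)*W) windows holding >=1 probe.

    A probe at 1-based position p occupies 0-based coordinate p-1, so the
    probe at position W exactly still belongs to window 0.
    """
    windows: list[Window] = []
    for chrom in manifest.chroms:
        idx = np.flatnonzero(manifest.chrom == chrom)
        coords = manifest.pos[idx] - 1  # 0-based
        k = coords // window_size
        for kk in np.unique(k):
            sel = idx[k == kk]
            windows.append(
                Window(
                    chrom=chrom,
                    start=int(kk) * window_size,
                    end=(int(kk) + 1) * window_size,
                    probe_indices=sel,
                )
            )
    return windows


def correlation_image(
    beta: BetaMatrix, window: Window, min_overlap: int = 30
) -> CorrelationImage:
    """Pairwise-complete Pearson correlation matrix over the window's probes.

    Pairs with fewer than ``min_overlap`` complete samples and zero-variance
    probes contribute 0 (not missing), so downstream image stages are total.
    """
    sub = beta.values[:, window.probe_indices]
    finite = np.isfinite(sub)
    n_pairs = (finite.astype(np.int64).T @ finite.astype(np.int64))
    if finite.all():
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.atleast_2d(np.corrcoef(sub, rowvar=False))
    else:
        R = pd.DataFrame(sub).corr(min_periods=1).to_numpy()
    if R.shape != n_pairs.shape:  # single-probe window
        R = np.ones_like(n_pairs, dtype=float)
    flagged = ~np.isfinite(R) | (n_pairs < min_overlap)
    R = np.where(flagged, 0.0, R)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    np.fill_diagonal(flagged, False)
    return CorrelationImage(window=window, R=R, n_pairs_used=n_pairs, flagged=flagged)
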