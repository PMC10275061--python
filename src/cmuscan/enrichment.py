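"""Feature-enrichment tests and chromatin-context overlap statistics.

Two complementary enrichment routes are provided.  The probe-based route
tests a 2x2 contingency of CpG probes (in CMU x in feature) with Fisher's
exact test, plus an upper-tail hypergeometric variant; it ignores spatial
clustering of probes.  The region-based route scores the observed CMU set
by the number of distinct feature intervals it hits and compares against
random background CMU sets matched for genomic size and drawn from windows
with enough probes — compensating for the non-uniform placement of array
probes.  The background score distribution is modeled as normal to give an
upper-tail enrichment p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from . import intervals as iv
from .icm import CMU, NonContiguousCMU
from .io import FeatureAnnotation, ProbeManifest
from .windows import DEFAULT_WINDOW_SIZE, tile_windows

Region = tuple[str, int, int]


@dataclass
class EnrichmentResult:
    feature_class: str
    test: str  # probe_fisher | hypergeometric | region_background
    observed: float
    p_value: float
    odds_ratio: float | None = None
    background_mean: float | None = None
    background_sd: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class OverlapStats:
    feature_class: str
    pct_cpg_overlap: float
    pct_cmu_overlap: float
    pct_unique_overlap: float | None  # None when no CMU overlaps the feature
    n_features_hit: dict[int, int]  # hits-per-CMU histogram
    flags: list[str] = field(default_factory=list)


def _as_regions(cmus) -> list[Region]:
    out: list[Region] = []
    for c in cmus:
        if isinstance(c, NonContiguousCMU):
            out.append(c.span)
        elif isinstance(c, CMU):
            out.append((c.chrom, c.start, c.end))
        else:
            chrom, s, e = c
            out.append((str(chrom), int(s), int(e)))
    return out


def probes_in_feature(manifest: ProbeManifest, feature: FeatureAnnotation) -> np.ndarray:
    """Boolean mask over manifest probes lying inside any feature interval."""
    mask = np.zeros(len(manifest), dtype=bool)
    per = feature.per_chrom()
    for chrom, (fs, fe) in per.items():
        sel = np.flatnonzero(manifest.chrom == chrom)
        if sel.size == 0:
            continue
        coords = manifest.pos[sel] - 1  # probe occupies [pos-1, pos)
        mask[sel] = iv.overlaps_any(coords, coords + 1, fs, fe)
    return mask


def probe_feature_test(
    cmu_probes: set[str],
    all_probes: set[str],
    feature: FeatureAnnotation,
    manifest: ProbeManifest,
) -> EnrichmentResult:
    """Two-sided Fisher exact test on the (in-CMU x in-feature) probe table."""
    if not cmu_probes <= all_probes:
        raise ValueError("cmu_probes must be a subset of all_probes")
    in_feat = probes_in_feature(manifest, feature)
    feat_ids = set(manifest.probe_ids[in_feat])
    a = len(cmu_probes & feat_ids)
    b = len(cmu_probes - feat_ids)
    c = len((all_probes - cmu_probes) & feat_ids)
    d = len(all_probes - cmu_probes - feat_ids)
    flags: list[str] = []
    if min(a + b, c + d, a + c, b + d) == 0:
        flags.append("degenerate_margin")
        return EnrichmentResult(
            feature_class=feature.feature_class,
            test="probe_fisher",
            observed=float(a),
            p_value=1.0,
            odds_ratio=None,
            flags=flags,
        )
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(
        feature_class=feature.feature_class,
        test="probe_fisher",
        observed=float(a),
        p_value=float(p),
        odds_ratio=float(odds),
        flags=flags,
    )


def hypergeometric_test(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k), X ~ Hypergeom(N population, K marked, n drawn)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"impossible hypergeometric parameters k={k} n={n} K={K} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


# ---------------------------------------------------------------------------
# region-based matched background
# ---------------------------------------------------------------------------

def eligible_windows(
    manifest: ProbeManifest,
    mode: str = "lenient",
    window_size: int = DEFAULT_WINDOW_SIZE,
):
    """Windows with enough probes to have been scanned (>=4 lenient, >=10 stringent)."""
    floor = {"lenient": 4, "stringent": 10}[mode]
    return [w for w in tile_windows(manifest, window_size) if w.n_probes >= floor]


def sample_background_cmus(
    observed: Sequence,
    manifest: ProbeManifest,
    mode: str = "lenient",
    rng_seed: int | np.random.Generator = 0,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> list[Region]:
    """One background set: per observed CMU, a random size-matched region.

    Each region is placed in a uniformly chosen eligible window at a
    uniform offset; same seed gives identical samples.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    wins = eligible_windows(manifest, mode, window_size)
    if not wins:
        raise ValueError("no eligible windows for background sampling")
    regions = _as_regions(observed)
    out: list[Region] = []
    for chrom, s, e in regions:
        length = e - s
        ok = [w for w in wins if (w.end - w.start) >= length]
        if not ok:
            import warnings

            warnings.warn(f"no window long enough for a {length} bp CMU; skipped")
            continue
        w = ok[rng.integers(len(ok))]
        start = int(rng.integers(w.start, w.end - length + 1))
        out.append((w.chrom, start, start + length))
    return out


def count_features_hit(regions: Sequence[Region], feature: FeatureAnnotation) -> int:
    """Number of distinct feature intervals overlapped by >=1 region."""
    per = feature.per_chrom()
    offsets: dict[str, int] = {}
    off = 0
    for chrom, (fs, _) in per.items():
        offsets[chrom] = off
        off += fs.size
    hit = np.zeros(off, dtype=bool)
    for chrom, s, e in regions:
        if chrom not in per:
            continue
        fs, fe = per[chrom]
        idx = iv.hit_indices(s, e, fs, fe)
        hit[offsets[chrom] + idx] = True
    return int(hit.sum())


def _background_scores(
    regions: Sequence[Region],
    feature: FeatureAnnotation,
    wins,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Scores of ``n_reps`` size-matched random CMU sets.

    Fast path: when every chromosome's feature ends are non-decreasing
    (equal-length or disjoint intervals), the features hit by a region form
    a contiguous index range, so distinct-hit counts per replicate reduce
    to a union of ranges computed with difference arrays.  Otherwise falls
    back to per-replicate exact counting.
    """
    lengths = np.array([e - s for _, s, e in regions], dtype=np.int64)
    m = lengths.size
    w_start = np.array([w.start for w in wins], dtype=np.int64)
    w_end = np.array([w.end for w in wins], dtype=np.int64)
    w_chrom = np.array([w.chrom for w in wins], dtype=object)
    fits = (w_end - w_start)[None, :] >= lengths[:, None]  # (m, n_wins)
    eligible_per_cmu = [np.flatnonzero(fits[i]) for i in range(m)]

    per = feature.per_chrom()
    fast = all(np.all(np.diff(fe) >= 0) for _, fe in per.values())
    # draw all placements at once (same stream order in both paths)
    widx = np.empty((m, n_reps), dtype=np.int64)
    starts = np.empty((m, n_reps), dtype=np.int64)
    for i in range(m):
        cand = eligible_per_cmu[i]
        if cand.size == 0:
            import warnings

            warnings.warn(
                f"no window long enough for a {int(lengths[i])} bp CMU; skipped"
            )
            widx[i] = -1
            starts[i] = 0
            continue
        wi = cand[rng.integers(cand.size, size=n_reps)]
        widx[i] = wi
        starts[i] = w_start[wi] + rng.integers(
            0, w_end[wi] - w_start[wi] - lengths[i] + 1, size=n_reps
        )
    if not fast:
        scores = np.empty(n_reps, dtype=np.int64)
        for rep in range(n_reps):
            regs = [
                (str(w_chrom[widx[i, rep]]), int(starts[i, rep]), int(starts[i, rep] + lengths[i]))
                for i in range(m)
                if widx[i, rep] >= 0
            ]
            scores[rep] = count_features_hit(regs, feature)
        return scores
    # fast path: per chromosome, [lo, hi) feature ranges per placement
    nfeat = sum(fs.size for fs, _ in per.values())
    offsets: dict[str, int] = {}
    off = 0
    for chrom, (fs, _) in per.items():
        offsets[chrom] = off
        off += fs.size
    diff = np.zeros((n_reps, nfeat + 1), dtype=np.int32)
    rep_ids = np.broadcast_to(np.arange(n_reps), (m, n_reps))
    for chrom, (fs, fe) in per.items():
        sel = np.zeros((m, n_reps), dtype=bool)
        for i in range(m):
            sel[i] = (widx[i] >= 0) & (w_chrom[widx[i]] == chrom)
        if not sel.any():
            continue
        qs = starts[sel]
        qe = qs + np.broadcast_to(lengths[:, None], (m, n_reps))[sel]
        reps = rep_ids[sel]
        lo = np.searchsorted(fe, qs, side="right") + offsets[chrom]
        hi = np.searchsorted(fs, qe, side="left") + offsets[chrom]
        keep = hi > lo
        np.add.at(diff, (reps[keep], lo[keep]), 1)
        np.add.at(diff, (reps[keep], hi[keep]), -1)
    covered = np.cumsum(diff[:, :-1], axis=1) > 0
    return covered.sum(axis=1).astype(np.int64)


def region_enrichment(
    observed: Sequence,
    feature: FeatureAnnotation,
    manifest: ProbeManifest,
    n_reps: int = 10_000,
    rng_seed: int = 0,
    mode: str = "lenient",
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> EnrichmentResult:
    """Matched-random-background enrichment of a CMU set for one feature.

    The observed score (distinct feature intervals hit) is compared to the
    score distribution of ``n_reps`` size-matched random CMU sets, modeled
    as a normal distribution; p is the upper-tail probability.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 to estimate a background distribution")
    regions = _as_regions(observed)
    obs = count_features_hit(regions, feature)
    rng = np.random.default_rng(rng_seed)
    wins = eligible_windows(manifest, mode, window_size)
    if not wins:
        raise ValueError("no eligible windows for background sampling")
    scores = _background_scores(regions, feature, wins, n_reps, rng)
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    flags: list[str] = []
    if sd == 0.0:
        flags.append("zero_background_sd")
        p = 1.0 if obs <= mean else 0.0
    else:
        p = float(stats.norm.sf(obs, loc=mean, scale=sd))
    return EnrichmentResult(
        feature_class=feature.feature_class,
        test="region_background",
        observed=float(obs),
        p_value=p,
        background_mean=mean,
        background_sd=sd,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# chromatin-context overlap statistics
# ---------------------------------------------------------------------------

def chromatin_overlap_stats(
    cmus: Sequence,
    feature: FeatureAnnotation,
    manifest: ProbeManifest,
) -> OverlapStats:
    """CpG-, CMU- and unique-overlap fractions for one chromatin feature.

    pct_cpg_overlap  = probes inside any feature interval / all probes
    pct_cmu_overlap  = CMUs hitting >=1 interval / all CMUs
    pct_unique_overlap = CMUs hitting exactly 1 interval / CMUs hitting >=1
    """
    regions = _as_regions(cmus)
    if not regions or len(manifest) == 0:
        raise ValueError("need non-empty CMUs and manifest")
    pct_cpg = float(probes_in_feature(manifest, feature).mean())
    per = feature.per_chrom()
    hits_per_cmu: list[int] = []
    for chrom, s, e in regions:
        if chrom not in per:
            hits_per_cmu.append(0)
            continue
        fs, fe = per[chrom]
        hits_per_cmu.append(int(iv.hit_indices(s, e, fs, fe).size))
    hits = np.asarray(hits_per_cmu)
    n_hit = int((hits >= 1).sum())
    flags: list[str] = []
    if n_hit == 0:
        flags.append("no_cmu_feature_overlap")
        unique = None
    else:
        unique = float((hits == 1).sum() / n_hit)
    vals, counts = np.unique(hits, return_counts=True)
    return OverlapStats(
        feature_class=feature.feature_class,
        pct_cpg_overlap=pct_cpg,
        pct_cmu_overlap=float(n_hit / hits.size),
        pct_unique_overlap=unique,
        n_features_hit={int(v): int(c) for v, c in zip(vals, counts)},
        flags=flags,
    )


def compartment_pair_score(stats_: OverlapStats) -> float:
    """log(%CMU overlap / %CpG overlap) for one compartment (A or B).

    Near 0 when CMUs fall into the compartment no more often than the
    array's probes do; positive when CMUs are over-represented.
    """
    if stats_.pct_cmu_overlap <= 0 or stats_.pct_cpg_overlap <= 0:
        raise ValueError("pair score undefined with zero overlap fraction")
    return float(np.log(stats_.pct_cmu_overlap / stats_.pct_cpg_overlap))


def tad_containment_fraction(
    spans: Sequence, tads: FeatureAnnotation
) -> float:
    """Fraction of spans fully contained within a single TAD interval.

    A span "does not cross a TAD boundary" when one TAD interval covers it
    entirely.
    """
    regions = _as_regions(spans)
    if not regions:
        raise ValueError("no spans given")
    per = tads.per_chrom()
    n_contained = 0
    for chrom, s, e in regions:
        if chrom not in per:
            continue
        fs, fe = per[chrom]
        idx = iv.hit_indices(s, e, fs, fe)
        if any(fs[i] <= s and fe[i] >= e for i in idx):
            n_contained += 1
    return n_contained / len(regions)
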