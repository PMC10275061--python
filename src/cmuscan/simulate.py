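"""Synthetic array-like methylation data with planted correlation structure.

The generator emulates the features the detection pipeline relies on: an
ordered probe manifest with roughly uniform spacing, a latent multivariate
normal per sample with block covariance (``within_r`` inside planted
blocks, signed ``inter_r`` between linked blocks, zero elsewhere) squashed
through the logistic function into (0,1) beta-like values.  The logistic
map is monotone, so the latent correlation survives the pipeline's rank
normalization essentially intact.  Truth tables describe every planted
unit so that recovery can be scored against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import BetaMatrix, FeatureAnnotation, ProbeManifest
from .preprocess import CovariateTable
from .windows import DEFAULT_WINDOW_SIZE, Window, tile_windows


@dataclass(frozen=True)
class PlantedBlock:
    """A contiguous probe run with uniform within-block latent correlation."""

    window: int  # global window index (tiling order)
    offset: int  # probe offset within the window
    size: int
    within_r: float = 0.8

    def __post_init__(self) -> None:
        if not abs(self.within_r) < 1:
            raise ValueError("|within_r| must be < 1")


@dataclass(frozen=True)
class BlockLink:
    """Requested signed correlation between two planted blocks."""

    a: int  # indices into SyntheticSpec.blocks
    b: int
    inter_r: float = 0.8

    def __post_init__(self) -> None:
        if not abs(self.inter_r) < 1:
            raise ValueError("|inter_r| must be < 1")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_samples: int = 200
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 2_500_000})
    mean_gap: int = 1250
    jitter: int = 400
    blocks: tuple = ()
    links: tuple = ()
    attenuation: dict = field(default_factory=dict)  # block idx -> case within_r
    covariate_effect_sd: float = 0.0
    noise_sd: float = 0.0
    window_size: int = DEFAULT_WINDOW_SIZE
    rng_seed: int = 0


def build_manifest(spec: SyntheticSpec, rng: np.random.Generator) -> ProbeManifest:
    """Probe positions via jittered uniform gaps along each chromosome."""
    ids: list[str] = []
    chroms: list[str] = []
    pos: list[int] = []
    counter = 0
    for chrom, length in spec.chrom_lengths.items():
        p = int(rng.integers(1, spec.mean_gap + 1))
        while p <= length:
            ids.append(f"cg{counter:08d}")
            chroms.append(chrom)
            pos.append(p)
            counter += 1
            lo = max(1, spec.mean_gap - spec.jitter)
            hi = spec.mean_gap + spec.jitter
            p += int(rng.integers(lo, hi + 1))
    return ProbeManifest(
        probe_ids=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        build="synthetic",
    )


def _block_runs(
    spec: SyntheticSpec, windows: list[Window]
) -> list[np.ndarray]:
    """Absolute manifest index runs for each planted block."""
    runs = []
    for blk in spec.blocks:
        if blk.window >= len(windows):
            raise ValueError(f"block window {blk.window} beyond tiling ({len(windows)})")
        w = windows[blk.window]
        if blk.offset + blk.size > w.n_probes:
            raise ValueError(
                f"block (window {blk.window}, offset {blk.offset}, size {blk.size}) "
                f"does not fit in a {w.n_probes}-probe window"
            )
        runs.append(w.probe_indices[blk.offset : blk.offset + blk.size])
    flat = np.concatenate(runs) if runs else np.zeros(0, dtype=np.int64)
    if np.unique(flat).size != flat.size:
        raise ValueError("planted block runs overlap")
    return runs


def _nearest_pd_correlation(C: np.ndarray) -> np.ndarray:
    """Clip eigenvalues and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(C)
    vals = np.clip(vals, 1e-8, None)
    C2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(C2))
    return C2 / np.outer(d, d)


def _group_covariances(
    spec: SyntheticSpec, runs: list[np.ndarray]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(probe indices, Cholesky factor) per connected group of linked blocks."""
    nb = len(spec.blocks)
    parent = list(range(nb))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for lk in spec.links:
        ra, rb = find(lk.a), find(lk.b)
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for i in range(nb):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        local = {b: i for i, b in enumerate(members)}
        sizes = [spec.blocks[b].size for b in members]
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        m = int(bounds[-1])
        C = np.eye(m)
        for b in members:
            i0, i1 = bounds[local[b]], bounds[local[b] + 1]
            r = spec.blocks[b].within_r
            C[i0:i1, i0:i1] = r
            np.fill_diagonal(C[i0:i1, i0:i1], 1.0)
        for lk in spec.links:
            if lk.a in local and lk.b in local:
                a0, a1 = bounds[local[lk.a]], bounds[local[lk.a] + 1]
                b0, b1 = bounds[local[lk.b]], bounds[local[lk.b] + 1]
                C[a0:a1, b0:b1] = lk.inter_r
                C[b0:b1, a0:a1] = lk.inter_r
        if np.linalg.eigvalsh(C).min() < 1e-10:
            warnings.warn(
                "requested block covariance not positive definite; repaired",
                stacklevel=2,
            )
            C = _nearest_pd_correlation(C)
        probes = np.concatenate([runs[b] for b in members])
        out.append((probes, np.linalg.cholesky(C)))
    return out


def _latent_matrix(
    spec: SyntheticSpec,
    n_probes: int,
    groups: list[tuple[np.ndarray, np.ndarray]],
    rng: np.random.Generator,
) -> np.ndarray:
    X = rng.standard_normal((spec.n_samples, n_probes))
    for probes, L in groups:
        Z = rng.standard_normal((spec.n_samples, probes.size))
        X[:, probes] = Z @ L.T
    if spec.noise_sd > 0:
        X = X + rng.standard_normal(X.shape) * spec.noise_sd
    return X


def _to_beta(
    X: np.ndarray, baselines: np.ndarray, sample_prefix: str = "s"
) -> BetaMatrix:
    vals = 1.0 / (1.0 + np.exp(-(baselines[None, :] + X)))
    return BetaMatrix(
        sample_ids=[f"{sample_prefix}{i:04d}" for i in range(X.shape[0])], values=vals
    )


def _truth_tables(
    spec: SyntheticSpec, manifest: ProbeManifest, runs: list[np.ndarray]
) -> dict:
    rows = []
    for i, (blk, run) in enumerate(zip(spec.blocks, runs)):
        rows.append(
            {
                "block_id": i,
                "chrom": manifest.chrom[run[0]],
                "first_probe": int(run[0]),
                "last_probe": int(run[-1]),
                "start_bp": int(manifest.pos[run[0]]) - 1,
                "end_bp": int(manifest.pos[run[-1]]),
                "size": blk.size,
                "within_r": blk.within_r,
            }
        )
    links = pd.DataFrame(
        [{"a": lk.a, "b": lk.b, "inter_r": lk.inter_r} for lk in spec.links],
        columns=["a", "b", "inter_r"],
    )
    return {"blocks": pd.DataFrame(rows), "links": links}


def generate_block_beta(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[ProbeManifest, BetaMatrix, dict]:
    """One dataset: manifest, beta matrix, and the planted-structure truth."""
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    manifest = build_manifest(spec, rng)
    windows = tile_windows(manifest, spec.window_size)
    runs = _block_runs(spec, windows)
    groups = _group_covariances(spec, runs)
    X = _latent_matrix(spec, len(manifest), groups, rng)
    baselines = rng.standard_normal(len(manifest))
    beta = _to_beta(X, baselines)
    truth = _truth_tables(spec, manifest, runs)
    return manifest, beta, truth


def generate_multi_tissue(
    spec: SyntheticSpec,
    n_tissues: int,
    share_map: dict,
    seed: int | None = None,
) -> tuple[ProbeManifest, list[tuple[str, BetaMatrix]], dict]:
    """Independent per-tissue datasets over one manifest.

    ``share_map`` maps block index -> collection of tissue indices carrying
    that block; tissues outside the set see independent noise there.
    """
    base_seed = spec.rng_seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    manifest = build_manifest(spec, rng)
    windows = tile_windows(manifest, spec.window_size)
    runs = _block_runs(spec, windows)
    baselines = rng.standard_normal(len(manifest))
    tissues: list[tuple[str, BetaMatrix]] = []
    for t in range(n_tissues):
        keep = [i for i in range(len(spec.blocks)) if t in share_map.get(i, ())]
        sub = replace(
            spec,
            blocks=tuple(spec.blocks[i] for i in keep),
            links=tuple(
                lk for lk in spec.links if lk.a in keep and lk.b in keep
            ),
        )
        # links/blocks reindexed to the kept subset
        remap = {b: i for i, b in enumerate(keep)}
        sub = replace(
            sub,
            links=tuple(
                BlockLink(remap[lk.a], remap[lk.b], lk.inter_r) for lk in sub.links
            ),
        )
        t_rng = np.random.default_rng((base_seed, t))
        t_runs = [runs[i] for i in keep]
        groups = _group_covariances(sub, t_runs)
        X = _latent_matrix(sub, len(manifest), groups, t_rng)
        tissues.append((f"tissue{t:02d}", _to_beta(X, baselines, f"t{t}_s")))
    truth = _truth_tables(spec, manifest, runs)
    truth["share_map"] = {int(k): sorted(v) for k, v in share_map.items()}
    return manifest, tissues, truth


def generate_case_control(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[ProbeManifest, BetaMatrix, BetaMatrix, dict, CovariateTable | None]:
    """Controls at planted within_r; cases at the attenuated within_r.

    When ``covariate_effect_sd`` > 0, the same per-probe linear covariate
    effect is injected into both groups (for residualization testing) and
    the covariate table is returned.
    """
    base_seed = spec.rng_seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    manifest = build_manifest(spec, rng)
    windows = tile_windows(manifest, spec.window_size)
    runs = _block_runs(spec, windows)
    baselines = rng.standard_normal(len(manifest))
    coefs = (
        rng.standard_normal(len(manifest)) * spec.covariate_effect_sd
        if spec.covariate_effect_sd > 0
        else None
    )
    case_spec = replace(
        spec,
        blocks=tuple(
            replace(b, within_r=spec.attenuation.get(i, b.within_r))
            for i, b in enumerate(spec.blocks)
        ),
    )
    betas = []
    cov_frames = []
    for role, s, sub_seed in (("control", spec, (base_seed, 1)), ("case", case_spec, (base_seed, 2))):
        g_rng = np.random.default_rng(sub_seed)
        groups = _group_covariances(s, runs)
        X = _latent_matrix(s, len(manifest), groups, g_rng)
        if coefs is not None:
            cov = g_rng.standard_normal(spec.n_samples)
            X = X + np.outer(cov, coefs)
            cov_frames.append((role, cov))
        betas.append(_to_beta(X, baselines, f"{role}_s"))
    truth = _truth_tables(spec, manifest, runs)
    truth["attenuation"] = dict(spec.attenuation)
    covariates = None
    if coefs is not None:
        frames = []
        for (role, cov), beta in zip(cov_frames, betas):
            frames.append(pd.DataFrame({"age": cov}, index=beta.sample_ids))
        covariates = CovariateTable(pd.concat(frames))
    return manifest, betas[0], betas[1], truth, covariates


def plant_features(
    manifest: ProbeManifest,
    layout: str = "uniform_random",
    n_features: int = 300,
    feature_length: int = 500,
    rng_seed: int | np.random.Generator = 0,
    truth: dict | None = None,
    feature_class: str = "feature",
) -> FeatureAnnotation:
    """Feature intervals either uniform over the genome or clustered on blocks."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    chroms: list[str] = []
    starts: list[int] = []
    if layout == "uniform_random":
        names = list({c: None for c in manifest.chrom})
        lengths = {
            c: int(manifest.pos[manifest.chrom == c].max()) + 1000 for c in names
        }
        total = sum(lengths.values())
        for _ in range(n_features):
            u = int(rng.integers(total - feature_length))
            for c in names:
                if u < lengths[c]:
                    chroms.append(c)
                    starts.append(u)
                    break
                u -= lengths[c]
    elif layout == "clustered_on_blocks":
        if truth is None or "blocks" not in truth:
            raise ValueError("clustered layout needs a truth table")
        blocks = truth["blocks"]
        if len(blocks) == 0:
            raise ValueError("no planted blocks to cluster on")
        for _ in range(n_features):
            row = blocks.iloc[int(rng.integers(len(blocks)))]
            lo = int(row.start_bp)
            hi = max(lo + 1, int(row.end_bp) - feature_length)
            chroms.append(str(row.chrom))
            starts.append(int(rng.integers(lo, hi)))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    starts_arr = np.asarray(starts, dtype=np.int64)
    return FeatureAnnotation(
        feature_class=feature_class,
        chrom=np.asarray(chroms, dtype=object),
        start=starts_arr,
        end=starts_arr + feature_length,
    )


# ---------------------------------------------------------------------------
# presets: the study conditions exercised by tests and the acceptance script
# ---------------------------------------------------------------------------

_BASIC_SIZES = [6, 8, 10, 12, 7, 9, 11, 6, 8, 10, 12, 7, 9, 11, 6, 8, 10, 12, 7, 9]


def basic_spec(n_samples: int = 200, seed: int = 0) -> SyntheticSpec:
    """20 planted blocks (6-12 probes, within-r 0.8) across 10 windows of a
    2.5 Mb chromosome carrying ~2000 probes."""
    blocks = []
    for w in range(10):
        blocks.append(PlantedBlock(window=w, offset=40, size=_BASIC_SIZES[2 * w]))
        blocks.append(PlantedBlock(window=w, offset=120, size=_BASIC_SIZES[2 * w + 1]))
    return SyntheticSpec(
        n_samples=n_samples,
        chrom_lengths={"chr1": 2_500_000},
        mean_gap=1250,
        jitter=300,
        blocks=tuple(blocks),
        rng_seed=seed,
    )


def multitissue_spec(n_samples: int = 100, seed: int = 0) -> SyntheticSpec:
    """Three 12-16 probe blocks in separate windows of a 1 Mb chromosome,
    for cross-tissue sharing scenarios (TI calling uses >10-probe CMUs)."""
    blocks = (
        PlantedBlock(window=0, offset=30, size=14),
        PlantedBlock(window=1, offset=50, size=12),
        PlantedBlock(window=2, offset=40, size=16),
    )
    return SyntheticSpec(
        n_samples=n_samples,
        chrom_lengths={"chr1": 1_000_000},
        mean_gap=1000,
        jitter=250,
        blocks=blocks,
        rng_seed=seed,
    )


def casecontrol_spec(
    n_samples: int = 150, attenuated_r: float = 0.4, seed: int = 0
) -> SyntheticSpec:
    """Two blocks on a 500 kb chromosome; block 0 attenuated in cases."""
    blocks = (
        PlantedBlock(window=0, offset=30, size=8),
        PlantedBlock(window=1, offset=60, size=10),
    )
    return SyntheticSpec(
        n_samples=n_samples,
        chrom_lengths={"chr1": 500_000},
        mean_gap=1000,
        jitter=250,
        blocks=blocks,
        attenuation={0: attenuated_r},
        rng_seed=seed,
    )


def noncontiguous_spec(n_samples: int = 200, seed: int = 0) -> SyntheticSpec:
    """Three blocks in one window; the middle one anti-correlated with both
    flanks, the flanks positively correlated (a 3-member non-contiguous unit)."""
    blocks = (
        PlantedBlock(window=0, offset=30, size=8),
        PlantedBlock(window=0, offset=60, size=8),
        PlantedBlock(window=0, offset=90, size=8),
    )
    links = (
        BlockLink(0, 1, -0.8),
        BlockLink(1, 2, -0.8),
        BlockLink(0, 2, 0.8),
    )
    return SyntheticSpec(
        n_samples=n_samples,
        chrom_lengths={"chr1": 250_000},
        mean_gap=800,
        jitter=200,
        blocks=blocks,
        links=links,
        rng_seed=seed,
    )
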