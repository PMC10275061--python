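"""Readers and writers for probe manifests, beta matrices, CMU sets and
feature annotations.

Conventions
-----------
* Manifest positions are 1-based points (Illumina manifest style).
* Every emitted interval is BED 0-based half-open; a CMU spanning probes at
  1-based positions ``a..b`` becomes ``[a-1, b)`` so a single-probe unit has
  length 1 bp.
* An overlap anywhere in the package means >=1 shared basepair.
* Missing beta values are represented as NaN, never as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv

AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


@dataclass
class ProbeManifest:
    """Ordered CpG probes with genomic coordinates (1-based positions)."""

    probe_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    build: str = "unknown"
    sorted: bool = True

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        ids, counts = np.unique(self.probe_ids, return_counts=True)
        if (counts > 1).any():
            dup = ids[counts > 1][:5]
            raise ValueError(f"duplicate probe ids in manifest: {list(dup)}")

    def __len__(self) -> int:
        return self.probe_ids.size

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    def index_of(self, probe_ids: Sequence[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.probe_ids)}
        return np.asarray([lookup[p] for p in probe_ids], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"probe_id": self.probe_ids, "chrom": self.chrom, "pos": self.pos}
        )


@dataclass
class BetaMatrix:
    """Samples x probes methylation values aligned to a ProbeManifest.

    ``transformed`` marks post-normalization values (e.g. inverse-normal or
    regression residuals) that are no longer constrained to [0, 1].
    """

    sample_ids: list[str]
    values: np.ndarray  # (n_samples, n_probes), NaN = missing
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("beta values must be a 2-D samples x probes matrix")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match value rows")
        if not self.transformed:
            bad = np.isfinite(self.values) & ((self.values < 0) | (self.values > 1))
            if bad.any():
                r, c = np.nonzero(bad)
                cells = [(self.sample_ids[i], int(j)) for i, j in zip(r[:5], c[:5])]
                raise ValueError(
                    f"beta values outside [0,1] at (sample, probe column) {cells}"
                    + ("..." if r.size > 5 else "")
                )
        if self.values.shape[0] < 30:
            warnings.warn(
                f"only {self.values.shape[0]} samples; correlation estimates "
                "are unstable below 30",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureAnnotation:
    """A named class of genomic intervals (0-based half-open), e.g. CTCF, TAD."""

    feature_class: str
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if (self.end < self.start).any():
            raise ValueError("feature interval with negative length")
        # sort per chromosome, stable across chromosomes
        order = np.lexsort((self.start, self.chrom.astype(str)))
        self.chrom = self.chrom[order]
        self.start = self.start[order]
        self.end = self.end[order]

    def __len__(self) -> int:
        return self.start.size

    def per_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in pd.unique(self.chrom):
            m = self.chrom == c
            out[str(c)] = (self.start[m], self.end[m])
        return out


def read_manifest(path: str | Path, autosomes_only: bool = True) -> ProbeManifest:
    """Read a delimited probe manifest with columns probe_id, chrom, pos.

    Probes are sorted by (chrom, pos); sex chromosomes and unplaced contigs
    are dropped when ``autosomes_only``.  Duplicate probe ids are a hard
    error.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={"chrom": str})
    required = {"probe_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if autosomes_only:
        keep = df["chrom"].isin(AUTOSOMES)
        n_drop = int((~keep).sum())
        if n_drop:
            warnings.warn(f"dropped {n_drop} non-autosomal probes", stacklevel=2)
        df = df[keep]
    if not df[["chrom", "pos"]].equals(df[["chrom", "pos"]].sort_values(["chrom", "pos"])):
        warnings.warn("manifest was not sorted; sorting by (chrom, pos)", stacklevel=2)
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return ProbeManifest(
        probe_ids=df["probe_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
    )


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, sep="\t", index=False)


def read_beta_matrix(path: str | Path, manifest: ProbeManifest) -> BetaMatrix:
    """Read a samples x probes beta matrix and align columns to the manifest.

    The file has a header row of probe ids and a first column of sample ids.
    Probes present in the file but absent from the manifest are dropped (a
    warning reports the count); probes in the manifest but absent from the
    file raise.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    extra = df.columns.difference(manifest.probe_ids)
    if len(extra):
        warnings.warn(
            f"dropped {len(extra)} probes absent from the manifest", stacklevel=2
        )
        df = df.drop(columns=extra)
    missing = set(manifest.probe_ids) - set(df.columns)
    if missing:
        raise ValueError(
            f"{len(missing)} manifest probes missing from beta matrix, "
            f"e.g. {sorted(missing)[:5]}"
        )
    df = df.loc[:, list(manifest.probe_ids)]
    return BetaMatrix(
        sample_ids=[str(s) for s in df.index], values=df.to_numpy(dtype=np.float64)
    )


def write_beta_matrix(beta: BetaMatrix, manifest: ProbeManifest, path: str | Path) -> None:
    pd.DataFrame(
        beta.values, index=beta.sample_ids, columns=manifest.probe_ids
    ).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# CMU BED output (the structures themselves live in cmuscan.icm)
# ---------------------------------------------------------------------------

def _bed_score(mean_abs_r: float) -> int:
    return int(min(round(abs(mean_abs_r) * 1000), 1000))


def write_cmu_bed(cmu_set, path: str | Path, noncontiguous_path: str | Path | None = None) -> None:
    """Write contiguous CMUs as BED6+1 (extra column: probe count).

    Non-contiguous CMUs go to a companion BED where each member interval
    carries its parent group id in a 7th column.
    """
    rows = [
        (c.chrom, c.start, c.end, c.id, _bed_score(c.mean_abs_r), ".", c.n_probes)
        for c in cmu_set.contiguous
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand", "n_probes"]
    ).to_csv(path, sep="\t", index=False, header=False)
    if noncontiguous_path is not None:
        nrows = []
        for nc in cmu_set.noncontiguous:
            for m in nc.members:
                nrows.append(
                    (m.chrom, m.start, m.end, m.id, _bed_score(m.mean_abs_r), ".", nc.id)
                )
        pd.DataFrame(
            nrows, columns=["chrom", "start", "end", "name", "score", "strand", "group"]
        ).to_csv(noncontiguous_path, sep="\t", index=False, header=False)


def read_cmu_bed(path: str | Path) -> pd.DataFrame:
    """Read a CMU BED written by :func:`write_cmu_bed` into a DataFrame."""
    names = ["chrom", "start", "end", "name", "score", "strand", "extra"]
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df.columns = names[: df.shape[1]]
    return df


def read_features_bed(path: str | Path, feature_class: str | None = None) -> list[FeatureAnnotation]:
    """Read a BED file of feature intervals.

    A 4th column, when present, carries the feature class; otherwise all
    intervals are assigned ``feature_class`` (required in that case).
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    if df.shape[1] >= 4:
        classes = df[3].astype(str)
    else:
        if feature_class is None:
            raise ValueError("3-column BED needs an explicit feature_class")
        classes = pd.Series([feature_class] * len(df))
    out = []
    for cls in pd.unique(classes):
        m = (classes == cls).to_numpy()
        out.append(
            FeatureAnnotation(
                feature_class=str(cls),
                chrom=df[0].to_numpy(dtype=object)[m],
                start=df[1].to_numpy(dtype=np.int64)[m],
                end=df[2].to_numpy(dtype=np.int64)[m],
            )
        )
    return out


def write_features_bed(features: Iterable[FeatureAnnotation], path: str | Path) -> None:
    rows = []
    for f in features:
        for c, s, e in zip(f.chrom, f.start, f.end):
            rows.append((c, s, e, f.feature_class))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
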