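"""Probe-wise rank-based inverse-normal transformation and covariate
residualization.

Correlation estimates on methylation beta values are sensitive to outliers
and to the bounded, often bimodal shape of the beta distribution; mapping
each probe's sample distribution onto a standard normal via average ranks
removes both problems while preserving the rank structure that carries the
co-methylation signal.  Residualizing transformed values on covariates
turns subsequent Pearson correlations into partial correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix

# Blom offset: quantile (r - 3/8) / (n + 1/4) for average rank r
_BLOM_C = 3.0 / 8.0


@dataclass
class CovariateTable:
    """Named covariates per sample; categoricals become indicator columns."""

    table: pd.DataFrame  # index = sample ids

    def design_matrix(self, sample_ids: list[str]) -> tuple[np.ndarray, list[str]]:
        """Intercept + expanded covariates, rows aligned to ``sample_ids``."""
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValueError(f"covariates missing for samples {missing[:5]}")
        df = self.table.loc[sample_ids]
        if df.shape[1]:
            expanded = pd.get_dummies(df, drop_first=True, dtype=float)
            X = np.column_stack(
                [np.ones(len(sample_ids)), expanded.to_numpy(dtype=float)]
            )
            names = ["intercept"] + list(expanded.columns)
        else:  # intercept-only design
            X = np.ones((len(sample_ids), 1))
            names = ["intercept"]
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # locate collinear columns via QR: small diagonal of R
            _, R = np.linalg.qr(X)
            d = np.abs(np.diag(R))
            bad = [names[i] for i in np.flatnonzero(d < 1e-8 * max(d.max(), 1.0))]
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")
        return X, names

    @classmethod
    def read(cls, path, index_col: int = 0) -> "CovariateTable":
        df = pd.read_csv(path, sep=None, engine="python", index_col=index_col)
        df.index = df.index.astype(str)
        return cls(df)


def inverse_normal_transform(beta: BetaMatrix, min_obs: int = 3) -> BetaMatrix:
    """Probe-wise rank-based inverse-normal transform (Blom offset).

    Per probe, non-missing values are replaced by
    ``Phi^-1((r - 3/8) / (n + 1/4))`` where ``r`` is the average rank (ties
    averaged) and ``n`` the non-missing count.  Missing entries stay missing.
    Probes with fewer than ``min_obs`` observations are set entirely missing
    and reported with a warning, which excludes them from correlation.
    """
    vals = beta.values
    df = pd.DataFrame(vals)
    ranks = df.rank(axis=0, method="average", na_option="keep").to_numpy()
    n = np.isfinite(vals).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        q = (ranks - _BLOM_C) / (n[None, :] + 0.25)
    out = stats.norm.ppf(q)
    low = n < min_obs
    if low.any():
        warnings.warn(
            f"{int(low.sum())} probes with <{min_obs} observations set to missing",
            stacklevel=2,
        )
        out[:, low] = np.nan
    return BetaMatrix(sample_ids=list(beta.sample_ids), values=out, transformed=True)


def residualize(beta: BetaMatrix, covariates: CovariateTable) -> BetaMatrix:
    """Per-probe OLS residuals of (transformed) values on the covariates.

    Fitted on complete cases per probe; residuals are orthogonal to every
    design column over those cases.  Probes keep their missing pattern.
    """
    X, _ = covariates.design_matrix(list(beta.sample_ids))
    Y = beta.values
    out = np.full_like(Y, np.nan)
    finite = np.isfinite(Y)
    if finite.all():
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        out = Y - X @ coef
    else:
        complete_cols = np.flatnonzero(finite.all(axis=0))
        if complete_cols.size:
            coef, *_ = np.linalg.lstsq(X, Y[:, complete_cols], rcond=None)
            out[:, complete_cols] = Y[:, complete_cols] - X @ coef
        for j in np.flatnonzero(~finite.all(axis=0)):
            m = finite[:, j]
            if m.sum() <= X.shape[1]:
                continue  # too few cases: left missing
            coef, *_ = np.linalg.lstsq(X[m], Y[m, j], rcond=None)
            out[m, j] = Y[m, j] - X[m] @ coef
    return BetaMatrix(sample_ids=list(beta.sample_ids), values=out, transformed=True)
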