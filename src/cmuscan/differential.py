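"""Case-control differential correlation of CMUs.

Each group's residualized data defines its own CMUs; for every CMU a
paired correlation matrix is computed on the same probes in the other
group, and two tests compare the pair:

* a Steiger-type chi-square on Fisher-transformed off-diagonals,
  ``chi2 = sum (z1_ij - z2_ij)^2 / (1/(n1-3) + 1/(n2-3))`` with
  ``df = p(p-1)/2`` — the null is that the off-diagonal difference
  R1 - R2 is zero;
* a one-sided Mann-Whitney rank-sum test of the defining group's
  off-diagonal correlations against the other group's shifted up by
  ``mu`` (default 0.1) — requiring the defining group to be more
  correlated by at least mu.

Both p-value families are Bonferroni-corrected per defining group; a CMU
is significantly differentially correlated only when both corrected
p-values clear the significance level.  The reported effect size is the
Hodges-Lehmann location shift of (other - defining), so a negative effect
means the defining group is more correlated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .icm import CMU, CMUSet, ICMParams, NonContiguousCMU, scan_dataset
from .io import BetaMatrix, ProbeManifest


@dataclass
class PairedMatrices:
    """Correlation matrices for one CMU's probes in both groups."""

    cmu: object  # CMU or NonContiguousCMU
    R1: np.ndarray  # defining group
    R2: np.ndarray  # other group
    n1: int
    n2: int

    @property
    def p(self) -> int:
        return self.R1.shape[0]


@dataclass
class DifferentialResult:
    cmu: object
    defining_group: str
    chi2: float
    df: int
    p_steiger: float
    p_steiger_bonf: float
    effect_size: float
    p_wilcox: float
    p_wilcox_bonf: float
    significant: bool
    flags: list[str] = field(default_factory=list)


def _unit_probes(cmu) -> np.ndarray:
    if isinstance(cmu, NonContiguousCMU):
        return cmu.probe_indices
    return cmu.probe_indices


def _corr(values: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(values, rowvar=False)
    R = np.atleast_2d(np.nan_to_num(R, nan=0.0))
    np.fill_diagonal(R, 1.0)
    return R


def paired_correlation_matrices(
    residuals_g1: BetaMatrix,
    residuals_g2: BetaMatrix,
    cmu,
) -> PairedMatrices:
    """Pearson matrices over one CMU's probes in both groups."""
    probes = _unit_probes(cmu)
    for g, name in ((residuals_g1, "group1"), (residuals_g2, "group2")):
        if probes.max() >= g.n_probes:
            raise ValueError(f"{name} does not cover probes {probes.tolist()}")
        if g.n_samples < 4:
            raise ValueError(f"{name} has fewer than 4 samples")
        if g.n_samples < 10:
            warnings.warn(f"{name} has <10 samples; tests will be weak", stacklevel=2)
    R1 = _corr(residuals_g1.values[:, probes])
    R2 = _corr(residuals_g2.values[:, probes])
    return PairedMatrices(
        cmu=cmu, R1=R1, R2=R2, n1=residuals_g1.n_samples, n2=residuals_g2.n_samples
    )


def steiger_matrix_test(
    pm: PairedMatrices, n1: int | None = None, n2: int | None = None, clip: float = 0.9999
) -> tuple[float, int, float]:
    """Chi-square comparison of two correlation matrices via Fisher z.

    Returns (chi2, df, p) with df = p(p-1)/2.  Off-diagonals are clipped
    to +/- ``clip`` before atanh.
    """
    n1 = pm.n1 if n1 is None else n1
    n2 = pm.n2 if n2 is None else n2
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need more than 3 samples per group for Fisher z")
    p = pm.p
    iu = np.triu_indices(p, 1)
    z1 = np.arctanh(np.clip(pm.R1[iu], -clip, clip))
    z2 = np.arctanh(np.clip(pm.R2[iu], -clip, clip))
    var = 1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    chi2 = float(((z1 - z2) ** 2).sum() / var)
    df = p * (p - 1) // 2
    return chi2, df, float(stats.chi2.sf(chi2, df))


def wilcoxon_shift_test(
    pm: PairedMatrices, mu: float = 0.1
) -> tuple[float, float, list[str]]:
    """One-sided shifted rank-sum test on off-diagonal correlations.

    Tests whether the defining group's off-diagonals are shifted right of
    the other group's by at least ``mu``.  Returns (effect_size, p, flags);
    effect_size is the Hodges-Lehmann estimate of (other - defining).
    """
    p = pm.p
    if p < 4:
        raise ValueError("need >= 4 probes (>= 6 off-diagonal entries)")
    iu = np.triu_indices(p, 1)
    x = pm.R1[iu]  # defining group
    y = pm.R2[iu]  # other group
    effect = float(np.median((y[None, :] - x[:, None]).ravel()))
    flags: list[str] = []
    if np.all(x == x[0]) and np.all(y + mu == x[0]):
        return 0.0, 1.0, ["all_tied"]
    try:
        res = stats.mannwhitneyu(x, y + mu, alternative="greater")
        pval = float(res.pvalue)
    except ValueError:
        flags.append("all_tied")
        return 0.0, 1.0, flags
    return effect, pval, flags


def collapse_cmu_lists(
    contiguous: list[CMU], noncontiguous: list[NonContiguousCMU]
) -> list:
    """Unified unit list: non-contiguous CMUs plus unabsorbed contiguous CMUs."""
    member_ids = {m.id for nc in noncontiguous for m in nc.members}
    return list(noncontiguous) + [c for c in contiguous if c.id not in member_ids]


def _test_units(
    units: list,
    defining: BetaMatrix,
    other: BetaMatrix,
    label: str,
    mu: float,
    alpha_sig: float,
) -> list[DifferentialResult]:
    if not units:
        return []
    raw: list[tuple] = []
    for u in units:
        pm = paired_correlation_matrices(defining, other, u)
        if pm.p < 4:
            continue
        chi2, df, p_st = steiger_matrix_test(pm)
        effect, p_wx, flags = wilcoxon_shift_test(pm, mu=mu)
        raw.append((u, chi2, df, p_st, effect, p_wx, flags))
    if not raw:
        return []
    p_st_bonf = multipletests([r[3] for r in raw], method="bonferroni")[1]
    p_wx_bonf = multipletests([r[5] for r in raw], method="bonferroni")[1]
    out = []
    for (u, chi2, df, p_st, effect, p_wx, flags), pb_st, pb_wx in zip(
        raw, p_st_bonf, p_wx_bonf
    ):
        out.append(
            DifferentialResult(
                cmu=u,
                defining_group=label,
                chi2=chi2,
                df=df,
                p_steiger=p_st,
                p_steiger_bonf=float(pb_st),
                effect_size=effect,
                p_wilcox=p_wx,
                p_wilcox_bonf=float(pb_wx),
                significant=bool(pb_st < alpha_sig and pb_wx < alpha_sig),
                flags=flags,
            )
        )
    return out


def differential_cmus(
    g1_beta: BetaMatrix,
    g2_beta: BetaMatrix,
    manifest: ProbeManifest,
    params: ICMParams = ICMParams(),
    mu: float = 0.1,
    alpha_sig: float = 0.05,
    labels: tuple[str, str] = ("group1", "group2"),
    include_noncontiguous: bool = True,
) -> list[DifferentialResult]:
    """End-to-end differential correlation on residualized group matrices.

    CMUs are called per group with ICM; each group is the defining group
    for its own units.  Non-contiguous units replace their member CMUs in
    the tested list (collapsed list).  Bonferroni families are one per
    defining group per test.
    """
    results: list[DifferentialResult] = []
    for defining, other, label in (
        (g1_beta, g2_beta, labels[0]),
        (g2_beta, g1_beta, labels[1]),
    ):
        cmu_set = scan_dataset(defining, manifest, params, dataset=label)
        units = (
            collapse_cmu_lists(cmu_set.contiguous, cmu_set.noncontiguous)
            if include_noncontiguous
            else list(cmu_set.contiguous)
        )
        results.extend(_test_units(units, defining, other, label, mu, alpha_sig))
    return results
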