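"""Mendelian-randomization estimators and instrument filters.

Implements the inverse-variance-weighted (IVW) estimator and its exact
variance, Cochran's Q heterogeneity statistic, summary-statistic effect
standardization, the Steiger directionality filter, fixed-effect
meta-analysis across sexes, multivariable MR (MVMR) as a weighted
no-intercept regression, greedy LD pruning of instruments, and the
between-sex heterogeneity filter.  All estimators consume plain arrays
(or :class:`SummaryStats`) so they work identically on emulated and real
GWAS summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    CollinearityError,
    InvalidArgumentError,
    NoInstrumentStrengthError,
)

__all__ = [
    "SummaryStats",
    "InstrumentSet",
    "MrEstimate",
    "MvmrEstimate",
    "ivw_estimate",
    "cochran_q",
    "standardize_effects",
    "steiger_filter",
    "meta_fixed",
    "mvmr_estimate",
    "select_instruments",
    "sex_heterogeneity_filter",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    """Per-SNP association statistics for one trait.

    ``beta`` is the per-allele effect, ``se`` its standard error, ``n``
    the per-SNP sample size and ``pval`` the association p-value.
    """

    snp: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    n: np.ndarray
    pval: np.ndarray
    effect_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp = np.asarray(self.snp, dtype=object)
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.pval = np.asarray(self.pval, dtype=float)
        lengths = {arr.size for arr in (self.snp, self.beta, self.se, self.n, self.pval)}
        if len(lengths) != 1:
            raise InvalidArgumentError("all SummaryStats columns must share a length")
        if self.size and (np.any(self.se <= 0) or np.any(self.n < 1)):
            raise InvalidArgumentError("se must be positive and n >= 1")
        if self.size and (np.any(self.pval < 0) or np.any(self.pval > 1)):
            raise InvalidArgumentError("p-values must lie in [0, 1]")

    @property
    def size(self) -> int:
        return self.beta.size

    def subset(self, mask: np.ndarray) -> "SummaryStats":
        allele = self.effect_allele[mask] if self.effect_allele is not None else None
        return SummaryStats(
            snp=self.snp[mask],
            beta=self.beta[mask],
            se=self.se[mask],
            n=self.n[mask],
            pval=self.pval[mask],
            effect_allele=allele,
        )

    def align_to(self, snp_order: Sequence[str]) -> "SummaryStats":
        """Reorder records to match ``snp_order`` (all ids must be present)."""
        pos = {s: i for i, s in enumerate(self.snp)}
        try:
            idx = np.array([pos[s] for s in snp_order], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - defensive
            raise InvalidArgumentError(f"SNP {exc} missing from summary stats")
        return self.subset(idx)


@dataclass
class InstrumentSet:
    """A pruned, filtered instrument panel for one exposure-outcome pair."""

    snp: np.ndarray
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    steiger_removed: int = 0
    sex_het_removed: int = 0
    ld_pruned: int = 0
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = (
            self.snp,
            self.beta_exposure,
            self.se_exposure,
            self.beta_outcome,
            self.se_outcome,
        )
        if len({np.asarray(a).size for a in arrays}) != 1:
            raise InvalidArgumentError("instrument arrays must share a length")

    @property
    def size(self) -> int:
        return np.asarray(self.snp).size


@dataclass
class MrEstimate:
    """Causal-effect estimate with uncertainty and heterogeneity summary."""

    alpha: float
    se: float
    pval: float
    k: int
    q: float = 0.0
    q_df: int = 0
    q_pval: float = float("nan")

    def z(self) -> float:
        return self.alpha / self.se


@dataclass
class MvmrEstimate:
    """Per-exposure direct effects from a multivariable MR fit."""

    exposures: tuple
    alpha: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    k: int

    def coefficient(self, name) -> tuple[float, float]:
        i = self.exposures.index(name)
        return float(self.alpha[i]), float(self.se[i])


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def ivw_estimate(
    beta_x: Sequence[float],
    beta_y: Sequence[float],
    se_y: Sequence[float],
    *,
    with_q: bool = True,
) -> MrEstimate:
    """Inverse-variance-weighted causal effect of X on Y.

    alpha = sum(bx * by / sy^2) / sum(bx^2 / sy^2), with
    Var(alpha) = 1 / sum(bx^2 / sy^2); for a single instrument this is
    the Wald ratio by/bx.  Equivalent to weighted least squares of the
    outcome effects on the exposure effects through the origin with
    weights 1/sy^2.
    """
    bx = np.asarray(beta_x, dtype=float)
    by = np.asarray(beta_y, dtype=float)
    sy = np.asarray(se_y, dtype=float)
    if not (bx.size == by.size == sy.size) or bx.size < 1:
        raise InvalidArgumentError("beta_x, beta_y, se_y must share length >= 1")
    if np.any(sy <= 0):
        raise InvalidArgumentError("se_y must be positive")
    w = sy**-2
    denom = float(np.sum(bx**2 * w))
    if denom == 0.0:
        raise NoInstrumentStrengthError("all exposure effects are zero")
    alpha = float(np.sum(bx * by * w)) / denom
    se = denom**-0.5
    pval = 2.0 * stats.norm.sf(abs(alpha / se))
    est = MrEstimate(alpha=alpha, se=se, pval=pval, k=bx.size)
    if with_q:
        est.q, est.q_df, est.q_pval = cochran_q(bx, by, sy, alpha)
    return est


def cochran_q(
    beta_x: Sequence[float],
    beta_y: Sequence[float],
    se_y: Sequence[float],
    alpha: float,
) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q of per-instrument Wald ratios around a
    pooled estimate.

    Q = sum_k w_k (by_k/bx_k - alpha)^2 with w_k = bx_k^2 / sy_k^2
    (first-order delta-method weights); the p-value uses chi-square with
    k - 1 degrees of freedom and is NaN for a single instrument.
    """
    bx = np.asarray(beta_x, dtype=float)
    by = np.asarray(beta_y, dtype=float)
    sy = np.asarray(se_y, dtype=float)
    nz = bx != 0.0
    wald = np.where(nz, by / np.where(nz, bx, 1.0), 0.0)
    w = bx**2 / sy**2
    q = float(np.sum(w[nz] * (wald[nz] - alpha) ** 2))
    df = int(nz.sum()) - 1
    if df < 1:
        return q, max(df, 0), float("nan")
    return q, df, float(stats.chi2.sf(q, df))


def standardize_effects(
    beta: Sequence[float] | float,
    se: Sequence[float] | float,
    n: Sequence[int] | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert per-SNP effects to the standardized (correlation) scale.

    Uses the z-statistic conversion b* = z / sqrt(n - 2 + z^2), exact for
    simple regression on standardized variables, so b*^2 is the variance
    explained by the SNP.  The standard error follows as b*/z (and
    1/sqrt(n-2) at b = 0).
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    se = np.atleast_1d(np.asarray(se, dtype=float))
    n = np.atleast_1d(np.asarray(n, dtype=float))
    if np.any(se <= 0):
        raise InvalidArgumentError("se must be positive")
    if np.any(n < 3):
        raise InvalidArgumentError("n must be >= 3")
    z = beta / se
    beta_std = z / np.sqrt(n - 2.0 + z**2)
    se_std = np.where(z != 0.0, beta_std / np.where(z != 0.0, z, 1.0), 1.0 / np.sqrt(n - 2.0))
    return beta_std, se_std


def steiger_filter(
    exp_std: Sequence[float],
    exp_std_se: Sequence[float],
    out_std: Sequence[float],
    out_std_se: Sequence[float],
    p_threshold: float = 0.001,
) -> np.ndarray:
    """Directionality filter against reverse causation.

    A SNP is removed when its standardized effect on the outcome exceeds
    the effect on the exposure in absolute value AND the one-tailed test
    of the difference (normal approximation, independent samples) is
    significant at ``p_threshold``.  Returns the retained mask.
    """
    ex = np.asarray(exp_std, dtype=float)
    ex_se = np.asarray(exp_std_se, dtype=float)
    ou = np.asarray(out_std, dtype=float)
    ou_se = np.asarray(out_std_se, dtype=float)
    if not (ex.size == ex_se.size == ou.size == ou_se.size):
        raise InvalidArgumentError("all arrays must share a length")
    z = (np.abs(ou) - np.abs(ex)) / np.sqrt(ex_se**2 + ou_se**2)
    p_one_sided = stats.norm.sf(z)
    removed = (np.abs(ou) > np.abs(ex)) & (p_one_sided < p_threshold)
    return ~removed


def meta_fixed(
    beta_a: Sequence[float] | float,
    se_a: Sequence[float] | float,
    beta_b: Sequence[float] | float,
    se_b: Sequence[float] | float,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effect inverse-variance meta-analysis of two effect series.

    Pooling happens at the SNP level (before MR) to limit weak-instrument
    bias.  Infinite standard errors receive zero weight.
    """
    ba = np.atleast_1d(np.asarray(beta_a, dtype=float))
    sa = np.atleast_1d(np.asarray(se_a, dtype=float))
    bb = np.atleast_1d(np.asarray(beta_b, dtype=float))
    sb = np.atleast_1d(np.asarray(se_b, dtype=float))
    if np.any(sa <= 0) or np.any(sb <= 0):
        raise InvalidArgumentError("standard errors must be positive")
    wa = np.where(np.isfinite(sa), sa**-2.0, 0.0)
    wb = np.where(np.isfinite(sb), sb**-2.0, 0.0)
    pooled = (ba * wa + bb * wb) / (wa + wb)
    return pooled, (wa + wb) ** -0.5


def mvmr_estimate(
    beta_out: Sequence[float],
    se_out: Sequence[float],
    beta_exposures: np.ndarray,
    exposures: Sequence | None = None,
) -> MvmrEstimate:
    """Multivariable MR: weighted no-intercept regression of outcome
    effects on several exposures' effect columns (weights 1/se_out^2).

    Returns the direct effect of each exposure conditional on the others.
    """
    by = np.asarray(beta_out, dtype=float)
    sy = np.asarray(se_out, dtype=float)
    bx = np.asarray(beta_exposures, dtype=float)
    if bx.ndim != 2 or bx.shape[0] != by.size or sy.size != by.size:
        raise InvalidArgumentError("beta_exposures must be (k, p) matching beta_out")
    k, p = bx.shape
    if k < p + 1:
        raise InvalidArgumentError("need at least one more instrument than exposures")
    # exposures with no instrument strength at all are dropped from the fit
    # (nested model) and reported with a zero effect and infinite se
    nonzero = ~np.all(bx == 0.0, axis=0)
    fit_cols = np.flatnonzero(nonzero)
    bx_fit = bx[:, fit_cols]
    if np.linalg.matrix_rank(bx_fit) < fit_cols.size:
        raise CollinearityError("exposure effect matrix is rank deficient")
    w = sy**-2
    xtwx = bx_fit.T @ (bx_fit * w[:, None])
    cond = np.linalg.cond(xtwx)
    if not np.isfinite(cond) or cond > 1e12:
        raise CollinearityError("exposure effect matrix is numerically collinear")
    xtwy = bx_fit.T @ (by * w)
    cov = np.linalg.inv(xtwx)
    alpha = np.zeros(p)
    se = np.full(p, np.inf)
    alpha[fit_cols] = cov @ xtwy
    se[fit_cols] = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore"):
        pval = np.where(
            np.isfinite(se), 2.0 * stats.norm.sf(np.abs(alpha / se)), 1.0
        )
    names = tuple(exposures) if exposures is not None else tuple(range(p))
    return MvmrEstimate(exposures=names, alpha=alpha, se=se, pval=pval, k=k)


def select_instruments(
    stats_table: SummaryStats,
    ld: np.ndarray | None = None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
) -> SummaryStats:
    """Genome-wide-significant, LD-independent instrument selection.

    Greedy pruning: candidates are ordered by ascending p-value; a SNP is
    accepted iff its squared LD correlation with every previously
    accepted SNP stays below ``r2_threshold``.  ``ld`` is a symmetric
    correlation matrix over the rows of ``stats_table`` (identity when
    omitted, i.e. independent loci).
    """
    sig = stats_table.pval < p_threshold
    table = stats_table.subset(sig)
    if table.size == 0:
        return table
    if ld is None:
        return table
    ld = np.asarray(ld, dtype=float)
    if ld.shape != (stats_table.size, stats_table.size):
        raise InvalidArgumentError("LD matrix must be square over all input SNPs")
    if not np.allclose(ld, ld.T, atol=1e-8) or not np.allclose(np.diag(ld), 1.0):
        raise InvalidArgumentError("LD matrix must be symmetric with unit diagonal")
    ld = ld[np.ix_(sig, sig)]
    order = np.argsort(table.pval, kind="stable")
    accepted: list[int] = []
    for i in order:
        if all(ld[i, j] ** 2 < r2_threshold for j in accepted):
            accepted.append(i)
    accepted_arr = np.sort(np.asarray(accepted, dtype=np.int64))
    return table.subset(accepted_arr)


def sex_heterogeneity_filter(
    beta_m: Sequence[float],
    se_m: Sequence[float],
    beta_f: Sequence[float],
    se_f: Sequence[float],
    n_ivs: int | None = None,
) -> np.ndarray:
    """Remove instruments whose effects differ between sexes.

    Per-SNP two-sample Z test of male vs female effects; a SNP is removed
    when its p-value beats the Bonferroni threshold 0.05 / n_ivs
    (``n_ivs`` defaults to the number of SNPs tested).  Returns the
    retained mask.
    """
    bm = np.asarray(beta_m, dtype=float)
    sm = np.asarray(se_m, dtype=float)
    bf = np.asarray(beta_f, dtype=float)
    sf = np.asarray(se_f, dtype=float)
    if not (bm.size == sm.size == bf.size == sf.size):
        raise InvalidArgumentError("all arrays must share a length")
    if n_ivs is None:
        n_ivs = bm.size
    if n_ivs < 1:
        raise InvalidArgumentError("n_ivs must be positive")
    z = (bm - bf) / np.sqrt(sm**2 + sf**2)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    return pval >= 0.05 / n_ivs
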