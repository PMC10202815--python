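"""Single-trait couple analysis: screening, cross-partner MR, comparison
of causal estimates to raw couple correlations, and convergence trends.

The analysis flow mirrors a phenome-wide couple study: identify couples
from household records, inverse-normal transform phenotypes, keep traits
with couple correlation above 0.1 and at least five valid instruments,
estimate the cross-partner causal effect per trait by IVW (sexes
meta-analysed at the SNP level), compare it to the observational
correlation with a Z test corrected for the effective number of tests,
and look for convergence by binning couples on age or time together.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    DegenerateInputError,
    InvalidArgumentError,
    ScreenFailureError,
)
from .mr_core import (
    MrEstimate,
    SummaryStats,
    ivw_estimate,
    meta_fixed,
    select_instruments,
    sex_heterogeneity_filter,
    standardize_effects,
    steiger_filter,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MrFilters",
    "TrendResult",
    "identify_couples",
    "inverse_normal_transform",
    "couple_correlation",
    "screen_traits",
    "effective_tests",
    "single_trait_couple_mr",
    "couple_mr_from_cohort",
    "compare_corr_vs_mr",
    "bin_couples",
    "trend_test",
]


@dataclass(frozen=True)
class MrFilters:
    """Thresholds applied along the instrument-selection chain."""

    p_instrument: float = 5e-8
    r2_prune: float = 0.001
    min_ivs: int = 5
    steiger: bool = False
    steiger_p: float = 0.001
    sex_het: bool = True


@dataclass
class TrendResult:
    """Weighted linear trend of per-bin estimates against bin centres."""

    bin_centres: np.ndarray
    estimates: np.ndarray
    se: np.ndarray
    slope: float
    slope_se: float
    slope_pval: float
    intercept: float


# ---------------------------------------------------------------------------
# couple identification and phenotype processing
# ---------------------------------------------------------------------------


def identify_couples(
    households: pd.DataFrame,
    partner_code: str = "partner",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Select couples from per-person household records.

    ``households`` needs columns ``person_id``, ``household_id``, ``sex``,
    ``related`` (boolean: related to the other household member) and
    ``relationship`` (self-reported code).  A household becomes a couple
    iff it holds exactly two unrelated, opposite-sex individuals who both
    report the partner relationship code.  Returns one row per retained
    couple plus per-rule exclusion counts.
    """
    required = {"person_id", "household_id", "sex", "related", "relationship"}
    missing = required - set(households.columns)
    if missing:
        raise InvalidArgumentError(f"missing columns: {sorted(missing)}")
    if households["person_id"].duplicated().any():
        raise InvalidArgumentError("duplicated person_id in household table")

    exclusions = {"household_size": 0, "same_sex": 0, "related": 0, "not_partner_coded": 0}
    couples = []
    for hid, group in households.groupby("household_id", sort=True):
        if len(group) != 2:
            exclusions["household_size"] += 1
            continue
        a, b = group.iloc[0], group.iloc[1]
        if a["sex"] == b["sex"]:
            exclusions["same_sex"] += 1
            continue
        if bool(a["related"]) or bool(b["related"]):
            exclusions["related"] += 1
            continue
        if a["relationship"] != partner_code or b["relationship"] != partner_code:
            exclusions["not_partner_coded"] += 1
            continue
        couples.append(
            {
                "household_id": hid,
                "index_id": a["person_id"],
                "partner_id": b["person_id"],
                "index_sex": a["sex"],
                "partner_sex": b["sex"],
            }
        )
    for rule, count in exclusions.items():
        if count:
            logger.info("identify_couples: excluded %d households (%s)", count, rule)
    return pd.DataFrame(
        couples,
        columns=["household_id", "index_id", "partner_id", "index_sex", "partner_sex"],
    ), exclusions


def inverse_normal_transform(values: Sequence[float]) -> np.ndarray:
    """Rank-preserving inverse normal quantile transformation.

    Blom offset: Phi^{-1}((rank - 0.375) / (n + 0.25)), average ranks for
    ties, missing values passed through as NaN.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 3:
        raise InvalidArgumentError("need at least 3 non-missing values")
    if np.nanstd(x) == 0.0:
        raise DegenerateInputError("all values identical")
    out = np.full(x.shape, np.nan)
    ranks = stats.rankdata(x[obs], method="average")
    out[obs] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def couple_correlation(
    x_i: Sequence[float], x_p: Sequence[float]
) -> tuple[float, float, float]:
    """Pearson couple correlation, its standard error and the Spearman
    correlation, over pairwise-complete couples.

    se(r) = sqrt((1 - r^2) / (n - 2)).
    """
    xi = np.asarray(x_i, dtype=float)
    xp = np.asarray(x_p, dtype=float)
    if xi.size != xp.size:
        raise InvalidArgumentError("x_i and x_p must share a length")
    ok = ~(np.isnan(xi) | np.isnan(xp))
    xi, xp = xi[ok], xp[ok]
    if xi.size < 4:
        raise InvalidArgumentError("need at least 4 complete pairs")
    if xi.std() == 0.0 or xp.std() == 0.0:
        raise DegenerateInputError("zero variance in one member's trait")
    r = float(np.corrcoef(xi, xp)[0, 1])
    se = float(np.sqrt((1.0 - r**2) / (xi.size - 2)))
    rho = float(stats.spearmanr(xi, xp).statistic)
    return r, se, rho


def screen_traits(
    trait_table: pd.DataFrame,
    corr_threshold: float = 0.1,
    min_ivs: int = 5,
) -> pd.DataFrame:
    """Apply the couple-correlation and instrument-count screens.

    ``trait_table`` needs columns ``trait``, ``pearson_r`` and
    ``n_valid_ivs``; other columns pass through.  Adds ``retained`` and a
    ``reason`` code (``ok`` / ``low_correlation`` / ``too_few_ivs``,
    correlation checked first).
    """
    required = {"trait", "pearson_r", "n_valid_ivs"}
    missing = required - set(trait_table.columns)
    if missing:
        raise InvalidArgumentError(f"missing columns: {sorted(missing)}")
    out = trait_table.copy()
    low_r = ~(out["pearson_r"] > corr_threshold)
    few_iv = out["n_valid_ivs"] < min_ivs
    out["retained"] = ~(low_r | few_iv)
    out["reason"] = np.select(
        [low_r, few_iv], ["low_correlation", "too_few_ivs"], default="ok"
    )
    for _, row in out.loc[~out["retained"]].iterrows():
        logger.info("screen_traits: %s excluded (%s)", row["trait"], row["reason"])
    return out


def effective_tests(corr: np.ndarray) -> float:
    """Effective number of independent tests among correlated traits.

    Li-Ji eigenvalue method on the absolute correlation matrix:
    Meff = sum_i [ I(|l_i| >= 1) + (|l_i| - floor(|l_i|)) ].  Negative
    eigenvalues (non-PSD input) are clipped at zero with a warning.
    """
    corr = np.abs(np.asarray(corr, dtype=float))
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise InvalidArgumentError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8) or not np.allclose(np.diag(corr), 1.0):
        raise InvalidArgumentError("matrix must be symmetric with unit diagonal")
    eigvals = np.linalg.eigvalsh(corr)
    if np.any(eigvals < -1e-8):
        warnings.warn("correlation matrix not PSD; clipping eigenvalues at 0")
    eigvals = np.clip(eigvals, 0.0, None)
    # round before floor: eigenvalues that are integers up to numerical
    # noise (e.g. 2 - 1e-15) must not contribute a spurious fraction of ~1
    eigvals = np.round(eigvals, 10)
    return float(np.sum((eigvals >= 1.0) + (eigvals - np.floor(eigvals))))


# ---------------------------------------------------------------------------
# cross-partner MR
# ---------------------------------------------------------------------------


def single_trait_couple_mr(
    exposure: SummaryStats | Mapping[str, SummaryStats],
    outcome: SummaryStats | Mapping[str, SummaryStats],
    filters: MrFilters = MrFilters(),
    ld: np.ndarray | None = None,
) -> MrEstimate:
    """Standardized cross-partner IVW estimate for one trait (pair).

    ``exposure`` holds same-person SNP effects, ``outcome`` the effects of
    the index genotype on the partner phenotype.  When per-sex mappings
    (keys ``"M"``/``"F"``) are given, the sex-heterogeneity filter runs on
    the exposure effects and both sides are pooled per SNP by fixed-effect
    meta-analysis before MR.  Instruments are selected on the exposure
    (p < ``p_instrument``, LD-pruned), optionally Steiger-filtered, and
    must number at least ``min_ivs``.
    """
    sex_split = isinstance(exposure, Mapping)
    if sex_split != isinstance(outcome, Mapping):
        raise InvalidArgumentError("exposure and outcome must both be per-sex or both pooled")

    if sex_split:
        exp_m, exp_f = exposure["M"], exposure["F"]
        out_m, out_f = outcome["M"], outcome["F"]
        exp_f = exp_f.align_to(exp_m.snp)
        out_m = out_m.align_to(exp_m.snp)
        out_f = out_f.align_to(exp_m.snp)
        keep = np.ones(exp_m.size, dtype=bool)
        if filters.sex_het:
            keep = sex_heterogeneity_filter(
                exp_m.beta, exp_m.se, exp_f.beta, exp_f.se
            )
        beta_exp, se_exp = meta_fixed(
            exp_m.beta[keep], exp_m.se[keep], exp_f.beta[keep], exp_f.se[keep]
        )
        beta_out, se_out = meta_fixed(
            out_m.beta[keep], out_m.se[keep], out_f.beta[keep], out_f.se[keep]
        )
        n_exp = exp_m.n[keep] + exp_f.n[keep]
        n_out = out_m.n[keep] + out_f.n[keep]
        pval = 2.0 * stats.norm.sf(np.abs(beta_exp / se_exp))
        exp_pooled = SummaryStats(
            snp=exp_m.snp[keep], beta=beta_exp, se=se_exp, n=n_exp, pval=pval
        )
        out_pooled = SummaryStats(
            snp=exp_m.snp[keep],
            beta=beta_out,
            se=se_out,
            n=n_out,
            pval=np.ones_like(beta_out),
        )
        if ld is not None:
            ld = ld[np.ix_(keep, keep)]
    else:
        exp_pooled, out_pooled = exposure, outcome.align_to(exposure.snp)

    selected = select_instruments(
        exp_pooled, ld, p_threshold=filters.p_instrument, r2_threshold=filters.r2_prune
    )
    if selected.size < filters.min_ivs:
        raise ScreenFailureError(
            f"only {selected.size} instruments survive selection (< {filters.min_ivs})"
        )
    out_sel = out_pooled.align_to(selected.snp)

    exp_std, exp_std_se = standardize_effects(selected.beta, selected.se, selected.n)
    out_std, out_std_se = standardize_effects(out_sel.beta, out_sel.se, out_sel.n)
    if filters.steiger:
        keep = steiger_filter(
            exp_std, exp_std_se, out_std, out_std_se, p_threshold=filters.steiger_p
        )
        if keep.sum() < filters.min_ivs:
            raise ScreenFailureError(
                f"only {int(keep.sum())} instruments survive the Steiger filter"
            )
        exp_std, exp_std_se = exp_std[keep], exp_std_se[keep]
        out_std, out_std_se = out_std[keep], out_std_se[keep]
    return ivw_estimate(exp_std, out_std, out_std_se)


def couple_mr_from_cohort(
    cohort,
    exposure_trait: str = "X",
    outcome_trait: str | None = None,
    filters: MrFilters = MrFilters(),
    exposure_cohort=None,
    couple_mask: np.ndarray | None = None,
) -> MrEstimate:
    """Run the full sex-stratified cross-partner MR chain on a simulated
    cohort.

    Exposure statistics are same-person associations of the exposure
    trait (from ``exposure_cohort`` when an independent exposure sample is
    desired, else from the couple cohort itself); outcome statistics
    regress the partner phenotype of ``outcome_trait`` (default: the
    exposure trait) on the index genotype, per sex, meta-analysed at the
    SNP level.  ``couple_mask`` restricts the outcome sample (e.g. one
    age/time bin).
    """
    from .sim_cohort import emulate_gwas_summary, CoupleCohort  # local: avoid cycle

    outcome_trait = outcome_trait or exposure_trait
    exp_src = exposure_cohort if exposure_cohort is not None else cohort
    out_src = cohort
    if couple_mask is not None:
        out_src = _subset_cohort(cohort, couple_mask)
    exposure = {
        s: emulate_gwas_summary(
            exp_src, exposure_trait, "index", sex=s, instrument_trait=exposure_trait
        )
        for s in ("M", "F")
    }
    outcome = {
        s: emulate_gwas_summary(
            out_src,
            outcome_trait,
            "partner",
            genotype_of="index",
            sex=s,
            instrument_trait=exposure_trait,
        )
        for s in ("M", "F")
    }
    return single_trait_couple_mr(exposure, outcome, filters=filters)


def _subset_cohort(cohort, mask: np.ndarray):
    """Restrict every per-couple array of a cohort to ``mask``."""
    from .sim_cohort import CoupleCohort, ROLES

    pick = lambda d: {t: {r: d[t][r][mask] for r in ROLES} for t in d}
    return CoupleCohort(
        n_couples=int(np.sum(mask)),
        traits=pick(cohort.traits),
        scores=pick(cohort.scores),
        envs=pick(cohort.envs),
        genotypes=pick(cohort.genotypes),
        snp_ids=cohort.snp_ids,
        sex={r: cohort.sex[r][mask] for r in ROLES},
        age={r: cohort.age[r][mask] for r in ROLES},
        time_together=cohort.time_together[mask],
        household_id=cohort.household_id[mask],
        parental=cohort.parental,
        params=cohort.params,
    )


def compare_corr_vs_mr(
    r: float, se_r: float, alpha: float, se_alpha: float
) -> tuple[float, float]:
    """Two-tailed Z test of the couple correlation against the MR estimate.

    z = (r - alpha) / sqrt(se_r^2 + se_alpha^2); the two estimates are
    treated as independent.
    """
    if se_r <= 0 or se_alpha <= 0:
        raise InvalidArgumentError("standard errors must be positive")
    z = (r - alpha) / np.hypot(se_r, se_alpha)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# convergence over age / time together
# ---------------------------------------------------------------------------


def bin_couples(
    values: Sequence[float], n_bins: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Split couples into roughly equal-sized quantile bins.

    Ties are kept within one bin (so heavy ties yield unequal sizes,
    logged); returns integer bin assignments and per-bin medians used as
    bin centres.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < n_bins:
        raise InvalidArgumentError(
            f"need at least {n_bins} distinct values for {n_bins} bins"
        )
    codes = pd.qcut(x, n_bins, labels=False, duplicates="drop")
    codes = np.asarray(codes, dtype=np.int64)
    sizes = np.bincount(codes)
    if sizes.max() - sizes.min() > 1:
        logger.info("bin_couples: unequal bin sizes %s due to ties", sizes.tolist())
    medians = np.array([np.median(x[codes == b]) for b in range(codes.max() + 1)])
    return codes, medians


def trend_test(
    estimates: Sequence[float],
    se: Sequence[float],
    bin_centres: Sequence[float],
) -> TrendResult:
    """Slope of per-bin estimates against bin centres, weighted by 1/SE.

    Weighted least squares with weights 1/se (inverse standard error, not
    inverse variance); two-sided p-value for the slope.
    """
    y = np.asarray(estimates, dtype=float)
    s = np.asarray(se, dtype=float)
    x = np.asarray(bin_centres, dtype=float)
    if not (y.size == s.size == x.size) or y.size < 3:
        raise InvalidArgumentError("need >= 3 bins with matching arrays")
    if np.any(s <= 0):
        raise InvalidArgumentError("standard errors must be positive")
    if np.allclose(x, x[0]):
        raise DegenerateInputError("bin centres have zero variance")
    design = sm.add_constant(x)
    fit = sm.WLS(y, design, weights=1.0 / s).fit()
    return TrendResult(
        bin_centres=x,
        estimates=y,
        se=s,
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        slope_pval=float(fit.pvalues[1]),
        intercept=float(fit.params[0]),
    )
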