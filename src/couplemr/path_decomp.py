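"""Decomposition of cross-trait cross-partner causal effects.

The total causal effect of trait X in the index person on trait Y in
the partner (omega) can travel two measurable paths:

* ``gamma`` -- assortment/influence on the exposure first:
  X_i -> X_p (single-trait couple effect) times the within-person effect
  X -> Y, and
* ``rho`` -- the within-person effect first: X_i -> Y_i times the direct
  couple effect Y_i -> Y_p, the latter estimated by multivariable MR
  (Y_p ~ Y_i + X_i) to strip residual X effects.

Because gamma and rho share signal, rho is residualized on gamma before
comparing their sum to omega; the through-origin regression of omega on
gamma + rho_resid and its (uncentered) R-squared quantify how much of
the total effect the two paths explain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, ScreenFailureError
from .couple_pipeline import MrFilters, couple_mr_from_cohort
from .mr_core import MrEstimate, MvmrEstimate, mvmr_estimate, standardize_effects

logger = logging.getLogger(__name__)

__all__ = [
    "PathEstimates",
    "product_effect",
    "estimate_omega",
    "estimate_gamma",
    "estimate_rho",
    "mvmr_couple_direct_effect",
    "residualize_rho",
    "compare_paths",
    "prune_trait_pairs",
]


@dataclass
class PathEstimates:
    """All estimated paths from X_i to Y_p for one trait pair."""

    pair: tuple[str, str]
    omega: float
    se_omega: float
    gamma: float
    se_gamma: float
    rho: float
    se_rho: float
    rho_resid: float = float("nan")


def product_effect(
    a: float, se_a: float, b: float, se_b: float
) -> tuple[float, float]:
    """Product of two independent estimates with propagated uncertainty.

    Var(AB) = Var(A)Var(B) + Var(A)E(B)^2 + Var(B)E(A)^2.
    """
    var = se_a**2 * se_b**2 + se_a**2 * b**2 + se_b**2 * a**2
    return float(a * b), float(np.sqrt(var))


def estimate_omega(
    cohort,
    exposure_trait: str,
    outcome_trait: str,
    filters: MrFilters | None = None,
    max_pair_corr: float = 0.8,
    exposure_cohort=None,
) -> MrEstimate:
    """Total cross-trait cross-partner effect X_i -> Y_p by couple MR.

    Instruments are the exposure trait's SNPs, Steiger-filtered against
    reverse causation; pairs whose same-person phenotypic correlation
    reaches ``max_pair_corr`` are refused as meaninglessly similar.
    """
    if filters is None:
        filters = MrFilters(steiger=True)
    x = cohort.trait(exposure_trait, "index")
    y = cohort.trait(outcome_trait, "index")
    pair_corr = float(np.corrcoef(x, y)[0, 1])
    if abs(pair_corr) >= max_pair_corr:
        raise ScreenFailureError(
            f"pair correlation {pair_corr:.2f} >= {max_pair_corr}; pair skipped"
        )
    return couple_mr_from_cohort(
        cohort,
        exposure_trait=exposure_trait,
        outcome_trait=outcome_trait,
        filters=filters,
        exposure_cohort=exposure_cohort,
    )


def estimate_gamma(
    alpha_xi_xp: float,
    se_xi_xp: float,
    alpha_x_y: float,
    se_x_y: float,
) -> tuple[float, float]:
    """Exposure-assortment path: gamma = alpha_{x_i->x_p} * alpha_{x->y}."""
    return product_effect(alpha_xi_xp, se_xi_xp, alpha_x_y, se_x_y)


def estimate_rho(
    mvmr: MvmrEstimate,
    outcome_exposure_name,
    alpha_x_y: float,
    se_x_y: float,
) -> tuple[float, float]:
    """Outcome-assortment path: rho = (direct Y_i -> Y_p effect from the
    MVMR fit) * alpha_{x->y}."""
    direct, direct_se = mvmr.coefficient(outcome_exposure_name)
    return product_effect(direct, direct_se, alpha_x_y, se_x_y)


def mvmr_couple_direct_effect(
    cohort,
    outcome_trait: str,
    covariate_trait: str,
    filters: MrFilters = MrFilters(),
) -> MvmrEstimate:
    """Direct couple effect Y_i -> Y_p adjusted for X_i via MVMR.

    Pools genome-wide-significant instruments of both traits, regresses
    the standardized index-genotype -> partner-Y effects jointly on the
    standardized same-person effects on Y and on X (weighted, no
    intercept).  The coefficient named ``outcome_trait`` is the direct
    cross-partner effect of Y free of residual X paths.
    """
    from .sim_cohort import emulate_gwas_summary  # local import: avoid cycle

    panels = []
    for inst_trait in (outcome_trait, covariate_trait):
        exp = emulate_gwas_summary(cohort, inst_trait, "index", instrument_trait=inst_trait)
        sig = exp.pval < filters.p_instrument
        panels.append((inst_trait, exp.subset(sig)))
    snp_ids = np.concatenate([p.snp for _, p in panels])
    if np.unique(snp_ids).size != snp_ids.size:
        raise InvalidArgumentError("overlapping SNP ids between instrument panels")
    if snp_ids.size < 3:
        raise ScreenFailureError("fewer than 3 pooled instruments for MVMR")

    def _stack(trait: str, person: str, genotype_of: str | None = None) -> tuple:
        betas, ses, ns = [], [], []
        for inst_trait, panel in panels:
            s = emulate_gwas_summary(
                cohort,
                trait,
                person,
                genotype_of=genotype_of,
                instrument_trait=inst_trait,
            ).align_to(panel.snp)
            betas.append(s.beta)
            ses.append(s.se)
            ns.append(s.n)
        return np.concatenate(betas), np.concatenate(ses), np.concatenate(ns)

    b_y, se_y, n_y = _stack(outcome_trait, "index")
    b_x, se_x, n_x = _stack(covariate_trait, "index")
    b_out, se_out, n_out = _stack(outcome_trait, "partner", genotype_of="index")

    by_std, _ = standardize_effects(b_y, se_y, n_y)
    bx_std, _ = standardize_effects(b_x, se_x, n_x)
    bout_std, bout_std_se = standardize_effects(b_out, se_out, n_out)
    return mvmr_estimate(
        bout_std,
        bout_std_se,
        np.column_stack([by_std, bx_std]),
        exposures=(outcome_trait, covariate_trait),
    )


def residualize_rho(
    rho: np.ndarray, gamma: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Residuals of the OLS regression rho ~ gamma (with intercept).

    Returns (rho_resid, intercept, slope); the residuals are uncorrelated
    with gamma by construction.
    """
    rho = np.asarray(rho, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if rho.size != gamma.size or rho.size < 3:
        raise InvalidArgumentError("need >= 3 matching (rho, gamma) pairs")
    if np.allclose(gamma, gamma[0]):
        raise InvalidArgumentError("gamma is constant; regression degenerate")
    design = np.column_stack([np.ones(gamma.size), gamma])
    coef, *_ = np.linalg.lstsq(design, rho, rcond=None)
    return rho - design @ coef, float(coef[0]), float(coef[1])


def prune_trait_pairs(
    pairs: pd.DataFrame,
    trait_corr: dict[tuple[str, str], float],
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Drop near-duplicate trait pairs before cross-pair comparisons.

    For pairs (A, B) and (C, D): when
    max(|corr(A,C)*corr(B,D)|, |corr(A,D)*corr(B,C)|) > threshold the
    pair with the larger omega p-value is dropped (ties broken by trait
    id order).  Requires columns ``exposure``, ``outcome``, ``p_omega``.
    """
    lookup = {tuple(k): float(v) for k, v in trait_corr.items()}
    lookup.update({(b, a): v for (a, b), v in list(lookup.items())})

    def corr(a: str, b: str) -> float:
        return 1.0 if a == b else lookup.get((a, b), 0.0)

    ranked = pairs.sort_values(
        ["p_omega", "exposure", "outcome"], kind="stable"
    ).reset_index(drop=True)
    kept_rows = []
    for _, row in ranked.iterrows():
        a, b = row["exposure"], row["outcome"]
        clash = any(
            max(
                abs(corr(a, k["exposure"]) * corr(b, k["outcome"])),
                abs(corr(a, k["outcome"]) * corr(b, k["exposure"])),
            )
            > threshold
            for k in kept_rows
        )
        if clash:
            logger.info("prune_trait_pairs: dropping (%s, %s)", a, b)
        else:
            kept_rows.append(row)
    return pd.DataFrame(kept_rows).reset_index(drop=True)


def compare_paths(estimates: pd.DataFrame) -> dict:
    """Contrast the estimated paths across trait pairs.

    ``estimates`` needs columns omega, se_omega, gamma, se_gamma, rho,
    se_rho (one row per trait pair).  Computes per-pair Z contrasts
    (rho vs gamma, omega vs each, omega vs gamma + rho_resid), category
    labels, the across-pair paired t test of gamma vs rho (after
    removing sign-mismatched pairs), and the through-origin regression of
    omega on gamma + rho_resid with its uncentered R-squared.
    """
    required = {"omega", "se_omega", "gamma", "se_gamma", "rho", "se_rho"}
    missing = required - set(estimates.columns)
    if missing:
        raise InvalidArgumentError(f"missing columns: {sorted(missing)}")
    df = estimates.copy().reset_index(drop=True)
    if len(df) < 3:
        raise InvalidArgumentError("need >= 3 trait pairs")

    rho_resid, intercept, slope_rg = residualize_rho(
        df["rho"].to_numpy(), df["gamma"].to_numpy()
    )
    df["rho_resid"] = rho_resid
    df["gamma_plus_rho_resid"] = df["gamma"] + df["rho_resid"]

    def zcontrast(a, se_a, b, se_b):
        z = (a - b) / np.sqrt(se_a**2 + se_b**2)
        return z, 2.0 * stats.norm.sf(np.abs(z))

    df["z_rho_vs_gamma"], df["p_rho_vs_gamma"] = zcontrast(
        df["rho"], df["se_rho"], df["gamma"], df["se_gamma"]
    )
    df["z_omega_vs_gamma"], df["p_omega_vs_gamma"] = zcontrast(
        df["omega"], df["se_omega"], df["gamma"], df["se_gamma"]
    )
    df["z_omega_vs_rho"], df["p_omega_vs_rho"] = zcontrast(
        df["omega"], df["se_omega"], df["rho"], df["se_rho"]
    )
    se_sum = np.sqrt(df["se_gamma"] ** 2 + df["se_rho"] ** 2)  # resid se approx.
    df["z_omega_vs_sum"], df["p_omega_vs_sum"] = zcontrast(
        df["omega"], df["se_omega"], df["gamma_plus_rho_resid"], se_sum
    )

    bonf = 0.05 / len(df)
    categories = []
    for _, row in df.iterrows():
        exceeds_both = (
            row["p_omega_vs_gamma"] < bonf
            and row["p_omega_vs_rho"] < bonf
            and abs(row["omega"]) > abs(row["gamma"])
            and abs(row["omega"]) > abs(row["rho"])
        )
        if exceeds_both:
            categories.append("unexplained")
        elif row["p_rho_vs_gamma"] < bonf:
            categories.append(
                "gamma_dominated" if abs(row["gamma"]) > abs(row["rho"]) else "rho_dominated"
            )
        else:
            categories.append("undetermined")
    df["category"] = categories

    signs = np.sign(df[["omega", "gamma", "rho", "gamma_plus_rho_resid"]].to_numpy())
    nz = signs != 0
    consistent = np.array(
        [np.unique(s[m]).size <= 1 for s, m in zip(signs, nz)]
    )
    n_sign_mismatch = int((~consistent).sum())
    sub = df.loc[consistent]
    if len(sub) >= 3:
        diffs = (sub["gamma"] - sub["rho"]).to_numpy()
        if np.allclose(diffs, diffs.mean()) and abs(diffs.mean()) < 1e-12:
            t_stat, t_pval = 0.0, 1.0  # identical paths: no difference
        else:
            t_stat, t_pval = stats.ttest_rel(sub["gamma"], sub["rho"])
    else:
        t_stat, t_pval = float("nan"), float("nan")

    x = df["gamma_plus_rho_resid"].to_numpy()
    y = df["omega"].to_numpy()
    sxx = float(x @ x)
    if sxx == 0.0:
        raise InvalidArgumentError("gamma + rho_resid identically zero")
    slope = float(x @ y) / sxx
    rss = float(np.sum((y - slope * x) ** 2))
    tss = float(y @ y)  # uncentered: through-origin convention
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")

    return {
        "table": df,
        "paired_t": float(t_stat),
        "paired_t_pval": float(t_pval),
        "n_sign_mismatch_removed": n_sign_mismatch,
        "origin_slope": slope,
        "origin_r2": r2,
        "rho_on_gamma_intercept": intercept,
        "rho_on_gamma_slope": slope_rg,
    }
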