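"""Couple correlation induced by confounder traits.

A trait Y confounds the couple correlation of a focal trait X when Y
causally affects X within a person and Y itself is assorted on (or
causally transmitted) between partners.  The induced couple correlation
is

    C = alpha_{y->x}^2 * alpha_{y_i->y_p},

the square of the within-person effect times the cross-partner effect of
the confounder.  This module scans candidate confounders with sequential
significance filters, propagates uncertainty into Var(C) via normal
approximations, prunes correlated confounders greedily by |C|, and forms
the total C_sum and the global confounding ratio C / cor(X_i, X_p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError

logger = logging.getLogger(__name__)

__all__ = [
    "ConfounderEffect",
    "ConfoundingResult",
    "confounder_scan",
    "confounding_correlation",
    "confounding_variance",
    "prune_confounders",
    "confounding_ratio",
]


@dataclass
class ConfounderEffect:
    """Estimated effects of one candidate confounder Y on a focal trait X."""

    confounder: str
    alpha_y_to_x: float
    se_y_to_x: float
    alpha_yi_to_yp: float
    se_yi_to_yp: float
    corr_with_x: float
    p_y_to_x: float = float("nan")
    p_yi_to_yp: float = float("nan")
    passed_filters: tuple = ()

    @property
    def c(self) -> float:
        return confounding_correlation(self.alpha_y_to_x, self.alpha_yi_to_yp)

    @property
    def var_c(self) -> float:
        return confounding_variance(
            self.alpha_y_to_x, self.se_y_to_x, self.alpha_yi_to_yp, self.se_yi_to_yp
        )


@dataclass
class ConfoundingResult:
    """Pruned confounder set with total induced correlation."""

    retained: list
    c_values: np.ndarray
    var_c_values: np.ndarray
    c_sum: float
    var_c_sum: float
    dropped: list = field(default_factory=list)

    @property
    def se_c_sum(self) -> float:
        return float(np.sqrt(self.var_c_sum))


def confounding_correlation(alpha_y_to_x: float, alpha_yi_to_yp: float) -> float:
    """Couple correlation induced by a confounder:
    C = alpha_{y->x}^2 * alpha_{y_i->y_p} (sign follows the couple effect)."""
    return float(alpha_y_to_x**2 * alpha_yi_to_yp)


def confounding_variance(
    alpha_y_to_x: float, se1: float, alpha_yi_to_yp: float, se2: float
) -> float:
    """Variance of the C estimator under normal approximations.

    With A = alpha_{y->x}^2: Var(A) = 4 mu^2 sigma^2 + 2 sigma^4 and
    E(A) = mu^2 + sigma^2 (mu, sigma the estimate and its se).  C = A * B
    with independent B = alpha_{y_i->y_p} uses the product formula
    Var(AB) = Var(A)Var(B) + Var(A)E(B)^2 + Var(B)E(A)^2.
    """
    if se1 < 0 or se2 < 0:
        raise InvalidArgumentError("standard errors must be non-negative")
    mu, sigma = alpha_y_to_x, se1
    var_a = 4.0 * mu**2 * sigma**2 + 2.0 * sigma**4
    e_a = mu**2 + sigma**2
    var_b = se2**2
    e_b = alpha_yi_to_yp
    return float(var_a * var_b + var_a * e_b**2 + var_b * e_a**2)


def confounder_scan(
    candidates: Sequence[ConfounderEffect],
    meff: float,
    corr_cap: float = 0.8,
) -> list[ConfounderEffect]:
    """Sequential significance filters for candidate confounders of X.

    Filter 1: same-person MR effect Y -> X significant at 0.05 / meff
    (candidate estimates are expected to be Steiger-prefiltered).
    Filter 2: within-couple MR effect Y_i -> Y_p significant at
    0.05 / (number remaining after filter 1).
    Filter 3: |phenotypic correlation with X| < ``corr_cap`` (near-
    duplicate traits excluded).  Each candidate records which filters it
    passed.
    """
    if meff < 1:
        raise InvalidArgumentError("meff must be >= 1")
    stage1 = []
    for cand in candidates:
        passed = []
        if cand.p_y_to_x < 0.05 / meff:
            passed.append("same_person_mr")
            stage1.append(cand)
        cand.passed_filters = tuple(passed)
    if not stage1:
        return []
    threshold2 = 0.05 / len(stage1)
    retained = []
    for cand in stage1:
        if cand.p_yi_to_yp < threshold2:
            cand.passed_filters += ("couple_mr",)
        else:
            logger.info(
                "confounder_scan: %s dropped (couple effect p=%.3g >= %.3g)",
                cand.confounder,
                cand.p_yi_to_yp,
                threshold2,
            )
            continue
        if abs(cand.corr_with_x) < corr_cap:
            cand.passed_filters += ("corr_cap",)
            retained.append(cand)
        else:
            logger.info(
                "confounder_scan: %s dropped (|corr with X| = %.2f >= %.2f)",
                cand.confounder,
                abs(cand.corr_with_x),
                corr_cap,
            )
    return retained


def prune_confounders(
    confounders: Sequence[ConfounderEffect],
    corr: np.ndarray | Mapping[tuple[str, str], float],
    r2_threshold: float = 0.1,
) -> ConfoundingResult:
    """Greedy pruning of correlated confounders, prioritising larger |C|.

    Candidates are visited by descending |C| (ties broken by confounder
    id); one is accepted iff its squared correlation with every accepted
    confounder stays below ``r2_threshold``.  C_sum is the sum of C over
    the accepted set and, the accepted estimates being (near) independent
    by construction, Var(C_sum) is the sum of the individual variances.
    """
    names = [c.confounder for c in confounders]
    if isinstance(corr, np.ndarray):
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (len(names), len(names)):
            raise InvalidArgumentError("correlation matrix must cover all candidates")
        lookup = {
            (names[i], names[j]): float(corr[i, j])
            for i in range(len(names))
            for j in range(len(names))
        }
    else:
        lookup = {tuple(k): float(v) for k, v in corr.items()}
        lookup.update({(b, a): v for (a, b), v in list(lookup.items())})

    order = sorted(confounders, key=lambda c: (-abs(c.c), c.confounder))
    accepted: list[ConfounderEffect] = []
    dropped: list[str] = []
    for cand in order:
        ok = True
        for acc in accepted:
            key = (cand.confounder, acc.confounder)
            if key not in lookup:
                raise InvalidArgumentError(f"missing correlation for pair {key}")
            if lookup[key] ** 2 >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(cand)
        else:
            dropped.append(cand.confounder)
            logger.info("prune_confounders: %s dropped (correlated)", cand.confounder)
    c_vals = np.array([c.c for c in accepted])
    var_vals = np.array([c.var_c for c in accepted])
    return ConfoundingResult(
        retained=accepted,
        c_values=c_vals,
        var_c_values=var_vals,
        c_sum=float(c_vals.sum()),
        var_c_sum=float(var_vals.sum()),
        dropped=dropped,
    )


def confounding_ratio(
    c: float | Sequence[float], couple_r: float
) -> float:
    """Share of the raw couple correlation attributable to confounding.

    ratio = C / cor(X_i, X_p); a sequence of C values (e.g. orthogonal
    birthplace coordinates) is summed before dividing.
    """
    total = float(np.sum(np.asarray(c, dtype=float)))
    if couple_r == 0.0:
        raise DegenerateInputError("couple correlation is zero; ratio undefined")
    return total / couple_r
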