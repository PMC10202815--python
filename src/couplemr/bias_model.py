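"""Closed-form expectations and bias of the cross-partner MR estimator.

Under the joint structural model (direct assortment on genetic score,
environment and trait; parental effects on the offspring environment)
the per-variant effect of the index genotype on the index trait, on the
partner trait, and hence the expectation of the cross-partner MR
estimate, admit closed forms.  The key derived quantity is the
genotype-environment correlation induced by parental effects,

    c = (1/sqrt(2)) * (s_G + g * s_X),

which opens a path from the index genotype to the partner trait through
environmental assortment.  The MR expectation is the ratio of the two
regression expectations; its deviation from the direct trait-assortment
parameter ``r_X`` is the bias studied on the parameter grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "BiasParams",
    "gene_environment_correlation",
    "expected_beta_index",
    "expected_beta_partner",
    "expected_mr",
    "expected_couple_correlations",
    "derived_violation_params",
    "bias_grid",
]


@dataclass(frozen=True)
class BiasParams:
    """Structural parameters entering the analytic bias formulas.

    Identical in meaning to the simulation parameters; optional secondary
    -trait inputs (``r_GXY``: genetic correlation with a secondary trait
    Y, ``r_Y``: assortment on Y, ``s_Y``: parental effect of Y) feed
    :func:`derived_violation_params`.
    """

    g: float = math.sqrt(0.2)
    e: float = math.sqrt(0.8)
    r_G: float = 0.0
    r_E: float = 0.0
    r_X: float = 0.2
    s_G: float = 0.0
    s_E: float = 0.0
    s_X: float = 0.0
    r_GXY: float | None = None
    r_Y: float | None = None
    s_Y: float | None = None

    def __post_init__(self) -> None:
        if self.g**2 > 1.0 + 1e-12:
            raise InvalidArgumentError("g^2 must not exceed 1")

    @classmethod
    def from_heritability(cls, h2: float, **kwargs) -> "BiasParams":
        return cls(g=math.sqrt(h2), e=math.sqrt(1.0 - h2), **kwargs)


def gene_environment_correlation(p: BiasParams) -> float:
    """Correlation between offspring genotype and offspring environment
    induced by parental effects: (1/sqrt(2)) * (s_G + s_X * g)."""
    return (p.s_G + p.s_X * p.g) / math.sqrt(2.0)


def expected_beta_index(p: BiasParams) -> float:
    """Expected per-unit-score effect of the index genotype on the index
    trait: g + c * e."""
    return p.g + gene_environment_correlation(p) * p.e


def expected_beta_partner(p: BiasParams) -> float:
    """Expected effect of the index genotype on the partner trait.

    Three additive paths: through direct trait assortment
    ((g + c*e) * r_X), direct genetic assortment (r_G * g) and direct
    environmental assortment (c * r_E * e).
    """
    c = gene_environment_correlation(p)
    return (p.g + c * p.e) * p.r_X + p.r_G * p.g + c * (p.r_E * p.e)


def expected_mr(p: BiasParams) -> tuple[float, float]:
    """Expectation of the cross-partner MR estimate and its bias.

    E[alpha] ~= E[beta_partner] / E[beta_index]
             = r_X + (r_G*g + c*(r_E*e)) / (g + c*e),
    bias = E[alpha] - r_X.  The ratio-of-expectations form is treated as
    the definition; the gap to the exact estimator expectation is
    quantified empirically against simulation.
    """
    denom = expected_beta_index(p)
    if abs(denom) < 1e-12:
        raise InvalidArgumentError(
            "expected index effect is zero; MR expectation undefined"
        )
    expectation = expected_beta_partner(p) / denom
    return expectation, expectation - p.r_X


def expected_couple_correlations(p: BiasParams) -> tuple[float, float, float]:
    """Expected cross-partner correlations of trait, environment and
    genetic score.

    corr_X = r_X + r_E e^2 + r_G g^2
    corr_E = r_E + r_X e^2 + r_G c^2
    corr_G = r_G + r_X g^2 + r_E c^2
    """
    c = gene_environment_correlation(p)
    corr_x = p.r_X + p.r_E * p.e**2 + p.r_G * p.g**2
    corr_e = p.r_E + p.r_X * p.e**2 + p.r_G * c**2
    corr_g = p.r_G + p.r_X * p.g**2 + p.r_E * c**2
    return corr_x, corr_e, corr_g


def derived_violation_params(
    g: float, r_GXY: float, r_Y: float, s_Y: float
) -> tuple[float, float]:
    """Typical magnitudes of genetic assortment and parental genetic
    effects induced by a genetically correlated secondary trait Y.

    r_G = (g * r_G(X,Y))^2 * r_Y  and  s_G = g * r_G(X,Y) * s_Y.
    """
    if abs(r_GXY) > 1.0:
        raise InvalidArgumentError("|r_GXY| must be <= 1")
    return (g * r_GXY) ** 2 * r_Y, g * r_GXY * s_Y


_GRID_PARAMS = ("r_G", "r_E", "s_G", "s_X", "r_X", "s_E")


def bias_grid(
    base: BiasParams,
    varied: tuple[str, str],
    ranges: tuple[Sequence[float], Sequence[float]],
    resolution: int = 41,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bias of the MR expectation over a dense 2-D parameter grid.

    ``varied`` names the two parameters scanned over ``ranges`` (each a
    (lo, hi) pair or an explicit value sequence); returns the two axes
    and the bias matrix (axis 0 = first parameter).
    """
    for name in varied:
        if name not in _GRID_PARAMS:
            raise InvalidArgumentError(f"unknown grid parameter {name!r}")
    axes = []
    for rng in ranges:
        vals = np.asarray(rng, dtype=float)
        if vals.size == 2:
            vals = np.linspace(vals[0], vals[1], resolution)
        axes.append(vals)
    bias = np.empty((axes[0].size, axes[1].size))
    for i, v1 in enumerate(axes[0]):
        for j, v2 in enumerate(axes[1]):
            p = replace(base, **{varied[0]: float(v1), varied[1]: float(v2)})
            bias[i, j] = expected_mr(p)[1]
    return axes[0], axes[1], bias
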