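"""Synthetic couple cohorts with assortative mating and parental effects.

The generative model describes a polygenic focal trait ``X = g*G + e*E``
where ``G`` is a standardized additive genetic score over independent
biallelic SNPs and ``E`` a unit-variance environment.  Three mechanisms
shape the data:

* **Direct assortment** -- couples are paired so that genetic scores,
  environments and traits of the two partners reach target correlations
  ``r_G``, ``r_E`` and ``r_X``.  Pairing uses a Gaussian-copula matching
  scheme (see :func:`assort_pairs` and the multi-channel generalisation
  used internally), which achieves arbitrary feasible targets without
  distorting the marginal distributions.
* **Parental (dynastic) effects** -- the offspring environment receives
  contributions ``s_G``, ``s_E`` and ``s_X`` from the scaled mean parental
  genetic score, environment and trait.  Parents are themselves simulated
  individuals (one generation) and transmit alleles Mendelianly, one per
  parent per locus.
* **Within-person causal networks** -- a second trait can depend causally
  on the first (or vice versa), enabling cross-trait couple analyses and
  confounder scenarios (:func:`simulate_trait_network`).

GWAS summary statistics are emulated by per-SNP linear regression
(:func:`emulate_gwas_summary`), optionally with the genotype taken from
one member of a couple and the phenotype from the other -- the
cross-partner design at the heart of couple MR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InfeasibleModelError, InvalidArgumentError
from .mr_core import SummaryStats

__all__ = [
    "CoupleModelParams",
    "TraitParams",
    "CausalEdge",
    "CoupleEffect",
    "TraitNetworkParams",
    "CoupleCohort",
    "simulate_genotypes",
    "assort_pairs",
    "simulate_couple_cohort",
    "simulate_trait_network",
    "emulate_gwas_summary",
]

ROLES = ("index", "partner")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoupleModelParams:
    """Structural parameters of the single-trait couple model.

    ``g`` and ``e`` are path coefficients of the genetic score and the
    environment on the trait; with no parental effects ``g**2 + e**2 = 1``
    so the trait has unit variance (heritability ``g**2``).  ``r_G``,
    ``r_E``, ``r_X`` are the direct-assortment correlation targets and
    ``s_G``, ``s_E``, ``s_X`` the parental effects on the offspring
    environment.
    """

    n_couples: int = 50_000
    n_snps: int = 100
    maf: float | Sequence[float] = 0.3
    g: float = math.sqrt(0.2)
    e: float = math.sqrt(0.8)
    r_G: float = 0.0
    r_E: float = 0.0
    r_X: float = 0.2
    s_G: float = 0.0
    s_E: float = 0.0
    s_X: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_couples < 1 or self.n_snps < 1:
            raise InvalidArgumentError("n_couples and n_snps must be positive")
        if abs(self.g**2 + self.e**2 - 1.0) > 1e-6:
            raise InvalidArgumentError(
                f"g^2 + e^2 must equal 1 (got {self.g ** 2 + self.e ** 2:.6f})"
            )
        for name in ("r_G", "r_E", "r_X"):
            if abs(getattr(self, name)) > 1.0:
                raise InvalidArgumentError(f"{name} must lie in [-1, 1]")
        total = self.r_G * self.g**2 + self.r_E * self.e**2 + self.r_X
        if abs(total) > 1.0:
            raise InvalidArgumentError(
                f"implied couple correlation {total:.3f} is not a valid correlation"
            )

    @classmethod
    def from_heritability(cls, h2: float, **kwargs) -> "CoupleModelParams":
        if not 0.0 <= h2 <= 1.0:
            raise InvalidArgumentError("heritability must lie in [0, 1]")
        return cls(g=math.sqrt(h2), e=math.sqrt(1.0 - h2), **kwargs)

    @property
    def heritability(self) -> float:
        return self.g**2

    def maf_array(self) -> np.ndarray:
        maf = np.broadcast_to(np.asarray(self.maf, dtype=float), (self.n_snps,))
        return np.array(maf)


@dataclass(frozen=True)
class TraitParams:
    """Architecture of one trait in a multi-trait network.

    ``r_assort`` is the direct couple assortment acting on this trait.
    Parental effects are not modelled in the network simulator; use
    :func:`simulate_couple_cohort` for dynastic scenarios.
    """

    n_snps: int = 100
    maf: float | Sequence[float] = 0.3
    h2: float = 0.2
    r_assort: float = 0.0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise InvalidArgumentError("n_snps must be positive")
        if not 0.0 < self.h2 <= 1.0:
            raise InvalidArgumentError("h2 must lie in (0, 1]")
        if abs(self.r_assort) > 1.0:
            raise InvalidArgumentError("r_assort must lie in [-1, 1]")


@dataclass(frozen=True)
class CausalEdge:
    """Within-person causal effect ``source -> target`` of size ``alpha``."""

    source: str
    target: str
    alpha: float

    def __post_init__(self) -> None:
        if abs(self.alpha) >= 1.0:
            raise InvalidArgumentError("|alpha| must be < 1 for unit-variance traits")


@dataclass(frozen=True)
class CoupleEffect:
    """Direct cross-partner injection: each person's ``target`` trait gains
    ``delta`` times their partner's ``source`` trait (e.g. secondhand
    smoke)."""

    source: str
    target: str
    delta: float


@dataclass(frozen=True)
class TraitNetworkParams:
    """A set of traits, within-person causal edges and couple effects."""

    n_couples: int = 50_000
    traits: Mapping[str, TraitParams] = field(
        default_factory=lambda: {"X": TraitParams(r_assort=0.2), "Y": TraitParams()}
    )
    edges: Sequence[CausalEdge] = ()
    couple_effects: Sequence[CoupleEffect] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_couples < 1:
            raise InvalidArgumentError("n_couples must be positive")
        names = set(self.traits)
        for edge in self.edges:
            if edge.source not in names or edge.target not in names:
                raise InvalidArgumentError(f"edge {edge} refers to unknown trait")
        for ce in self.couple_effects:
            if ce.source not in names or ce.target not in names:
                raise InvalidArgumentError(f"couple effect {ce} refers to unknown trait")

    def topological_order(self) -> list[str]:
        """Trait order in which within-person effects can be applied."""
        order: list[str] = []
        pending = dict.fromkeys(self.traits)
        deps = {t: {e.source for e in self.edges if e.target == t} for t in self.traits}
        while pending:
            ready = [t for t in pending if deps[t] <= set(order)]
            if not ready:
                raise InvalidArgumentError("causal edges form a cycle")
            for t in sorted(ready):
                order.append(t)
                del pending[t]
        return order


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------


@dataclass
class CoupleCohort:
    """Simulated couples: one row per couple, arrays per person role.

    All per-trait mappings are keyed first by trait name, then by role
    (``"index"`` / ``"partner"``).  ``parental`` holds the rescaled
    mean-parental aggregates (``G_P``, ``E_P``, ``X_P``) when a parental
    generation was simulated.
    """

    n_couples: int
    traits: dict
    scores: dict
    envs: dict
    genotypes: dict
    snp_ids: dict
    sex: dict
    age: dict
    time_together: np.ndarray
    household_id: np.ndarray
    parental: dict = field(default_factory=dict)
    params: object = None

    def trait(self, name: str, role: str = "index") -> np.ndarray:
        return self.traits[name][role]

    def score(self, name: str, role: str = "index") -> np.ndarray:
        return self.scores[name][role]

    def env(self, name: str, role: str = "index") -> np.ndarray:
        return self.envs[name][role]

    def genotype_matrix(self, name: str, role: str = "index") -> np.ndarray:
        return self.genotypes[name][role]

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n: int,
    k: int,
    maf: float | Sequence[float],
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    ld_rho: float = 0.0,
) -> np.ndarray:
    """Draw an ``n x k`` matrix of biallelic genotypes in {0, 1, 2}.

    Columns are independent Hardy-Weinberg draws at the given minor-allele
    frequencies unless ``ld_rho`` is nonzero, in which case adjacent loci
    share an AR(1) latent correlation of ``ld_rho`` per haplotype.
    """
    if n < 1 or k < 1:
        raise InvalidArgumentError("n and k must be positive")
    maf_arr = np.array(np.broadcast_to(np.asarray(maf, dtype=float), (k,)))
    if np.any(maf_arr <= 0.0) or np.any(maf_arr >= 1.0):
        raise InvalidArgumentError("allele frequencies must lie strictly in (0, 1)")
    if not 0.0 <= abs(ld_rho) < 1.0:
        raise InvalidArgumentError("|ld_rho| must be < 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if ld_rho == 0.0:
        return rng.binomial(2, maf_arr, size=(n, k)).astype(np.int8)
    # latent AR(1) Gaussian per haplotype, thresholded at the MAF quantile
    thresh = stats.norm.ppf(maf_arr)
    geno = np.zeros((n, k), dtype=np.int8)
    for _ in range(2):
        z = np.empty((n, k))
        z[:, 0] = rng.standard_normal(n)
        innov = rng.standard_normal((n, k - 1)) * math.sqrt(1.0 - ld_rho**2)
        for j in range(1, k):
            z[:, j] = ld_rho * z[:, j - 1] + innov[:, j - 1]
        geno += (z < thresh).astype(np.int8)
    return geno


def _standardized_score(geno: np.ndarray, maf: np.ndarray) -> np.ndarray:
    """Additive genetic score, standardized to zero mean and unit variance."""
    scale = np.sqrt(2.0 * maf * (1.0 - maf))
    score = ((geno - 2.0 * maf) / scale).sum(axis=1)
    sd = score.std()
    if sd == 0.0:
        raise DegenerateInputError("genetic score has zero variance")
    return (score - score.mean()) / sd


def _mendelian_child(
    mother: np.ndarray, father: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One offspring genotype per couple: one transmitted allele per parent."""
    return (
        rng.binomial(1, mother / 2.0) + rng.binomial(1, father / 2.0)
    ).astype(np.int8)


# ---------------------------------------------------------------------------
# assortment (Gaussian-copula matching)
# ---------------------------------------------------------------------------


def assort_pairs(
    a: Sequence[float],
    b: Sequence[float],
    target_r: float,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pair two equally sized pools to a target Pearson correlation.

    Returns a permutation ``perm`` such that ``(a, b[perm])`` realises
    approximately ``target_r``.  A latent bivariate normal at the target
    correlation is rank-matched against both pools, so arbitrary feasible
    targets are reached without changing either marginal.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidArgumentError("a and b must be 1-D sequences of equal length")
    if abs(target_r) > 1.0:
        raise InvalidArgumentError("|target_r| must be <= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = a.size
    u = rng.standard_normal(n)
    v = target_r * u + math.sqrt(max(0.0, 1.0 - target_r**2)) * rng.standard_normal(n)
    order_a = np.argsort(a, kind="stable")
    order_u = np.argsort(u, kind="stable")
    order_b = np.argsort(b, kind="stable")
    rank_v = np.argsort(np.argsort(v, kind="stable"), kind="stable")
    perm = np.empty(n, dtype=np.int64)
    perm[order_a] = order_b[rank_v[order_u]]
    return perm


def _stratified_match(targets: np.ndarray, pool: np.ndarray) -> np.ndarray:
    """Approximate multivariate rank matching of two equal-size point clouds.

    Returns indices ``idx`` into ``pool`` aligning ``pool[idx]`` with
    ``targets`` row-by-row.  One dimension is exact rank matching; higher
    dimensions use nested quantile strata (a cheap optimal-transport
    surrogate whose correlation error vanishes with the stratum count).
    """
    n, d = targets.shape
    if d == 1:
        out = np.empty(n, dtype=np.int64)
        out[np.argsort(targets[:, 0], kind="stable")] = np.argsort(
            pool[:, 0], kind="stable"
        )
        return out
    n_strata = max(1, int(round(n ** (1.0 / d))))
    t_strata = np.array_split(np.argsort(targets[:, 0], kind="stable"), n_strata)
    p_strata = np.array_split(np.argsort(pool[:, 0], kind="stable"), n_strata)
    out = np.empty(n, dtype=np.int64)
    for t_idx, p_idx in zip(t_strata, p_strata):
        sub = _stratified_match(targets[t_idx, 1:], pool[p_idx, 1:])
        out[t_idx] = p_idx[sub]
    return out


def _inv_sqrt(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    if np.any(vals <= 1e-10):
        raise DegenerateInputError("feature covariance is singular")
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def _assort_joint(
    feats_i: np.ndarray,
    feats_p: np.ndarray,
    channels: Sequence[tuple[np.ndarray, np.ndarray, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Pair two pools under several simultaneous direct assortments.

    Each channel ``(v_i, v_p, r)`` demands correlation ``r`` between the
    matched variables, with all other cross-partner correlations arising
    only through the matched ones (conditional-independence copula).  The
    implied cross-covariance is ``K = sum_c r_c u_i u_p^T / Var(v)`` with
    ``u = Cov(features, v)``; matching happens on the singular directions
    of the whitened ``K``.  Raises :class:`InfeasibleModelError` when the
    targets do not define a valid joint covariance.
    """
    n, d = feats_i.shape
    active = [(vi, vp, r) for vi, vp, r in channels if r != 0.0]
    if not active:
        return rng.permutation(n)
    ci = feats_i - feats_i.mean(axis=0)
    cp = feats_p - feats_p.mean(axis=0)
    sigma_i = ci.T @ ci / n
    sigma_p = cp.T @ cp / n
    K = np.zeros((d, d))
    for v_i, v_p, r in active:
        v_i = np.asarray(v_i, dtype=float)
        v_p = np.asarray(v_p, dtype=float)
        u_i = ci.T @ (v_i - v_i.mean()) / n / v_i.std()
        u_p = cp.T @ (v_p - v_p.mean()) / n / v_p.std()
        K += r * np.outer(u_i, u_p)
    w_i = _inv_sqrt(sigma_i)
    w_p = _inv_sqrt(sigma_p)
    m = w_i @ K @ w_p
    uu, sv, vt = np.linalg.svd(m)
    if sv.max() > 1.0 + 1e-6:
        raise InfeasibleModelError(
            f"assortment targets imply correlation {sv.max():.3f} > 1"
        )
    sv = np.clip(sv, 0.0, 1.0 - 1e-9)
    rank = int(np.sum(sv > 1e-8))
    if rank == 0:
        return rng.permutation(n)
    y_i = ci @ w_i @ uu[:, :rank]
    y_p = cp @ w_p @ vt[:rank].T
    lam = sv[:rank]
    noise = rng.standard_normal((n, rank))
    targets = y_i * lam + noise * np.sqrt(1.0 - lam**2)
    return _stratified_match(targets, y_p)


# ---------------------------------------------------------------------------
# single-trait couple cohort
# ---------------------------------------------------------------------------


def _simulate_person_pool(
    n: int,
    maf: np.ndarray,
    g: float,
    e: float,
    rng: np.random.Generator,
) -> dict:
    """A pool of unrelated individuals: genotypes, score, environment, trait."""
    geno = simulate_genotypes(n, maf.size, maf, rng=rng)
    score = _standardized_score(geno, maf)
    env = rng.standard_normal(n)
    return {"geno": geno, "G": score, "E": env, "X": g * score + e * env}


def _parental_aggregate(mother: np.ndarray, father: np.ndarray) -> np.ndarray:
    """Rescaled mean parental value (X_M + X_F)/sqrt(2(1 + cor)) with unit
    variance."""
    corr = float(np.corrcoef(mother, father)[0, 1])
    return (mother + father) / math.sqrt(2.0 * (1.0 + corr))


def _make_offspring(
    params: CoupleModelParams,
    maf: np.ndarray,
    rng: np.random.Generator,
) -> dict:
    """Simulate one parental couple pool plus one offspring per couple."""
    n = params.n_couples
    mothers = _simulate_person_pool(n, maf, params.g, params.e, rng)
    fathers = _simulate_person_pool(n, maf, params.g, params.e, rng)
    perm = _assort_joint(
        np.column_stack([mothers["G"], mothers["E"]]),
        np.column_stack([fathers["G"], fathers["E"]]),
        [
            (mothers["G"], fathers["G"], params.r_G),
            (mothers["E"], fathers["E"], params.r_E),
            (mothers["X"], fathers["X"], params.r_X),
        ],
        rng,
    )
    for key in ("geno", "G", "E", "X"):
        fathers[key] = fathers[key][perm]

    geno = _mendelian_child(mothers["geno"], fathers["geno"], rng)
    score = _standardized_score(geno, maf)
    g_par = _parental_aggregate(mothers["G"], fathers["G"])
    e_par = _parental_aggregate(mothers["E"], fathers["E"])
    x_par = _parental_aggregate(mothers["X"], fathers["X"])

    systematic = params.s_G * g_par + params.s_E * e_par + params.s_X * x_par
    var_sys = float(systematic.var())
    if var_sys > 1.0:
        raise InfeasibleModelError(
            f"parental effects explain {var_sys:.2f} > 1 of environment variance"
        )
    env = systematic + math.sqrt(1.0 - var_sys) * rng.standard_normal(n)
    trait = params.g * score + params.e * env
    return {
        "geno": geno,
        "G": score,
        "E": env,
        "X": trait,
        "G_P": g_par,
        "E_P": e_par,
        "X_P": x_par,
    }


def simulate_couple_cohort(params: CoupleModelParams) -> CoupleCohort:
    """Simulate a full couple cohort under the joint structural model.

    Each side of every couple is an offspring of a simulated (assorted)
    parental couple; offspring are then paired under simultaneous direct
    assortment on genetic score, environment and trait.  The realised
    cross-partner correlations follow the closed-form expectations of
    :mod:`couplemr.bias_model` up to Monte-Carlo error.
    """
    rng = np.random.default_rng(params.seed)
    maf = params.maf_array()
    n = params.n_couples

    index = _make_offspring(params, maf, rng)
    partner = _make_offspring(params, maf, rng)
    perm = _assort_joint(
        np.column_stack([index["G"], index["E"]]),
        np.column_stack([partner["G"], partner["E"]]),
        [
            (index["G"], partner["G"], params.r_G),
            (index["E"], partner["E"], params.r_E),
            (index["X"], partner["X"], params.r_X),
        ],
        rng,
    )
    for key in partner:
        partner[key] = partner[key][perm]

    sex_index = rng.integers(0, 2, size=n)
    age_index = np.clip(rng.normal(55.0, 8.0, size=n), 30.0, 75.0)
    age_partner = np.clip(age_index + rng.normal(0.0, 3.0, size=n), 30.0, 78.0)
    age_median = (age_index + age_partner) / 2.0
    time_together = np.clip(
        rng.normal(0.5 * age_median - 12.0, 6.0, size=n), 0.0, None
    )

    sides = {"index": index, "partner": partner}
    return CoupleCohort(
        n_couples=n,
        traits={"X": {r: sides[r]["X"] for r in ROLES}},
        scores={"X": {r: sides[r]["G"] for r in ROLES}},
        envs={"X": {r: sides[r]["E"] for r in ROLES}},
        genotypes={"X": {r: sides[r]["geno"] for r in ROLES}},
        snp_ids={"X": [f"rsX{j}" for j in range(params.n_snps)]},
        sex={
            "index": np.where(sex_index == 0, "F", "M"),
            "partner": np.where(sex_index == 0, "M", "F"),
        },
        age={"index": age_index, "partner": age_partner},
        time_together=time_together,
        household_id=np.arange(n),
        parental={
            "X": {
                r: {k: sides[r][k] for k in ("G_P", "E_P", "X_P")} for r in ROLES
            }
        },
        params=params,
    )


# ---------------------------------------------------------------------------
# multi-trait networks
# ---------------------------------------------------------------------------


def _network_pool(
    params: TraitNetworkParams, rng: np.random.Generator
) -> tuple[dict, dict, dict, dict]:
    n = params.n_couples
    genos, scores, envs, base = {}, {}, {}, {}
    for name, tp in params.traits.items():
        maf = np.array(np.broadcast_to(np.asarray(tp.maf, dtype=float), (tp.n_snps,)))
        geno = simulate_genotypes(n, tp.n_snps, maf, rng=rng)
        score = _standardized_score(geno, maf)
        env = rng.standard_normal(n)
        genos[name] = geno
        scores[name] = score
        envs[name] = env
        base[name] = math.sqrt(tp.h2) * score + math.sqrt(1.0 - tp.h2) * env
    traits: dict[str, np.ndarray] = {}
    for name in params.topological_order():
        incoming = [e for e in params.edges if e.target == name]
        systematic = sum(
            (e.alpha * traits[e.source] for e in incoming), np.zeros(n)
        )
        var_sys = float(np.var(systematic)) if incoming else 0.0
        if var_sys > 1.0:
            raise InfeasibleModelError(
                f"causal parents of {name} explain {var_sys:.2f} > 1 of its variance"
            )
        traits[name] = systematic + math.sqrt(1.0 - var_sys) * base[name]
    return genos, scores, envs, traits


def simulate_trait_network(params: TraitNetworkParams) -> CoupleCohort:
    """Simulate couples carrying several causally linked traits.

    Traits have independent SNP sets and environments; within-person
    causal edges are applied in topological order with residual rescaling
    so every trait keeps unit variance.  Couples assort directly on each
    trait with nonzero ``r_assort`` (simultaneously), and optional
    :class:`CoupleEffect` terms inject direct partner-to-partner
    influence after pairing.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_couples

    sides = {}
    for role in ROLES:
        genos, scores, envs, traits = _network_pool(params, rng)
        sides[role] = {"geno": genos, "G": scores, "E": envs, "X": traits}

    feats_i = np.column_stack(
        [sides["index"]["G"][t] for t in params.traits]
        + [sides["index"]["E"][t] for t in params.traits]
    )
    feats_p = np.column_stack(
        [sides["partner"]["G"][t] for t in params.traits]
        + [sides["partner"]["E"][t] for t in params.traits]
    )
    channels = [
        (sides["index"]["X"][t], sides["partner"]["X"][t], tp.r_assort)
        for t, tp in params.traits.items()
    ]
    perm = _assort_joint(feats_i, feats_p, channels, rng)
    for group in ("geno", "G", "E", "X"):
        for t in params.traits:
            sides["partner"][group][t] = sides["partner"][group][t][perm]

    for ce in params.couple_effects:
        # symmetric direct influence between partners
        src_i = sides["index"]["X"][ce.source].copy()
        src_p = sides["partner"]["X"][ce.source].copy()
        sides["partner"]["X"][ce.target] = (
            sides["partner"]["X"][ce.target] + ce.delta * src_i
        )
        sides["index"]["X"][ce.target] = (
            sides["index"]["X"][ce.target] + ce.delta * src_p
        )

    sex_index = rng.integers(0, 2, size=n)
    age_index = np.clip(rng.normal(55.0, 8.0, size=n), 30.0, 75.0)
    age_partner = np.clip(age_index + rng.normal(0.0, 3.0, size=n), 30.0, 78.0)
    time_together = np.clip(
        rng.normal(0.25 * (age_index + age_partner) - 12.0, 6.0, size=n), 0.0, None
    )
    return CoupleCohort(
        n_couples=n,
        traits={t: {r: sides[r]["X"][t] for r in ROLES} for t in params.traits},
        scores={t: {r: sides[r]["G"][t] for r in ROLES} for t in params.traits},
        envs={t: {r: sides[r]["E"][t] for r in ROLES} for t in params.traits},
        genotypes={t: {r: sides[r]["geno"][t] for r in ROLES} for t in params.traits},
        snp_ids={
            t: [f"rs{t}{j}" for j in range(tp.n_snps)]
            for t, tp in params.traits.items()
        },
        sex={
            "index": np.where(sex_index == 0, "F", "M"),
            "partner": np.where(sex_index == 0, "M", "F"),
        },
        age={"index": age_index, "partner": age_partner},
        time_together=time_together,
        household_id=np.arange(n),
        params=params,
    )


# ---------------------------------------------------------------------------
# emulated GWAS
# ---------------------------------------------------------------------------


def emulate_gwas_summary(
    cohort: CoupleCohort,
    trait: str,
    person: str = "index",
    *,
    genotype_of: str | None = None,
    instrument_trait: str | None = None,
    covariates: np.ndarray | None = None,
    sex: str | None = None,
) -> SummaryStats:
    """Per-SNP association summary statistics from a simulated cohort.

    ``person`` selects whose phenotype is the dependent variable;
    ``genotype_of`` (default: same person) selects whose genotype is the
    regressor -- the cross-partner design uses the index genotype with
    the partner phenotype.  ``instrument_trait`` picks which trait's SNP
    set to test (default: the phenotype trait's own SNPs).  Phenotype and
    genotype columns are standardized before regression (so betas live on
    the correlation scale and se ~ 1/sqrt(n)); optional covariate columns
    are projected out of both sides first.  Constant genotype columns are
    excluded from the output.
    """
    if person not in ROLES:
        raise InvalidArgumentError(f"person must be one of {ROLES}")
    genotype_of = genotype_of or person
    instrument_trait = instrument_trait or trait
    y = np.asarray(cohort.trait(trait, person), dtype=float)
    geno = np.asarray(
        cohort.genotype_matrix(instrument_trait, genotype_of), dtype=float
    )
    snp_ids = np.asarray(cohort.snp_ids[instrument_trait], dtype=object)
    mask = np.ones(y.size, dtype=bool)
    if sex is not None:
        mask = cohort.sex[genotype_of] == sex
    y = y[mask]
    geno = geno[mask]
    n = y.size
    if n < 30:
        raise InvalidArgumentError("at least 30 observations required")

    n_cov = 0
    if covariates is not None:
        cov = np.column_stack([np.ones(n), np.asarray(covariates, float)[mask]])
        n_cov = cov.shape[1] - 1
        beta_y, *_ = np.linalg.lstsq(cov, y, rcond=None)
        y = y - cov @ beta_y
        beta_g, *_ = np.linalg.lstsq(cov, geno, rcond=None)
        geno = geno - cov @ beta_g

    sd = y.std()
    if sd == 0.0:
        raise DegenerateInputError("phenotype has zero variance")
    y = (y - y.mean()) / sd

    gc = geno - geno.mean(axis=0)
    sd_g = gc.std(axis=0)
    keep = sd_g > 1e-9
    gc, snp_ids = gc[:, keep] / sd_g[keep], snp_ids[keep]
    sxx = (gc**2).sum(axis=0)
    sxy = gc.T @ y
    beta = sxy / sxx
    dof = n - 2 - n_cov
    rss = np.maximum(float(y @ y) - beta * sxy, 0.0)
    se = np.sqrt(rss / dof / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf)
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return SummaryStats(
        snp=snp_ids,
        beta=beta,
        se=se,
        n=np.full(beta.size, n, dtype=np.int64),
        pval=pval,
    )
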