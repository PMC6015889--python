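"""Posterior effect estimation and heritability partitioning.

A normal / inverse-gamma Gibbs cycle estimates fixed genetic effects,
random environment-interaction effect levels and their variance
components.  Phenotypic variance is then partitioned into per-kind
heritability components (percent of Var(y) explained by the fitted
contribution of each effect class), matching the additive, dominance,
epistasis and environment-interaction columns of the heritability
table plus the derived totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from qtsmap.datamodel import FIXED_KINDS, CoefficientDesign

_VARIANCE_GUARD = 1e12

#: kind -> heritability component name
KIND_TO_COMPONENT = {
    "a": "h2_A",
    "d": "h2_D",
    "aa": "h2_AA",
    "ad": "h2_AD",
    "da": "h2_DA",
    "dd": "h2_DD",
    "ae": "h2_AE",
    "de": "h2_DE",
    "aae": "h2_AAE",
    "ade": "h2_ADE",
    "dae": "h2_DAE",
    "dde": "h2_DDE",
}

DOMINANCE_COMPONENTS = ("h2_D", "h2_AD", "h2_DA", "h2_DD", "h2_DE", "h2_ADE", "h2_DAE", "h2_DDE")
ALL_COMPONENTS = tuple(KIND_TO_COMPONENT.values())


@dataclass
class HeritabilityPartition:
    """Percent-of-phenotypic-variance heritability components."""

    h2_A: float = 0.0
    h2_D: float = 0.0
    h2_AA: float = 0.0
    h2_AD: float = 0.0
    h2_DA: float = 0.0
    h2_DD: float = 0.0
    h2_AE: float = 0.0
    h2_DE: float = 0.0
    h2_AAE: float = 0.0
    h2_ADE: float = 0.0
    h2_DAE: float = 0.0
    h2_DDE: float = 0.0
    h2_A_plus: float | None = None  # signed additive split (optional)
    h2_A_minus: float | None = None

    def components(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self) if f.name in ALL_COMPONENTS}

    @property
    def h2_T(self) -> float:
        return float(sum(self.components().values()))

    @property
    def h2_Dplus(self) -> float:
        return float(sum(self.components()[c] for c in DOMINANCE_COMPONENTS))


def aggregate_heritability(p: HeritabilityPartition) -> tuple[float, float]:
    """Total heritability and the dominance-related aggregate.

    ``h2_T`` sums every component; ``h2_Dplus`` sums the components
    whose contribution involves a dominance coefficient (d, ad, da, dd,
    de and, when present, ade/dae/dde).
    """
    return p.h2_T, p.h2_Dplus


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


@dataclass
class GibbsResult:
    """Posterior draws from :func:`gibbs_fit` (post burn-in, thinned)."""

    fixed_names: list[str]
    beta: np.ndarray  # draws x p
    u: dict[str, np.ndarray]  # family -> draws x E
    sigma2: np.ndarray  # residual variance draws
    var_components: dict[str, np.ndarray]  # family -> variance draws
    converged: bool
    rhat: float

    def beta_mean(self) -> np.ndarray:
        return self.beta.mean(axis=0)

    def beta_sd(self) -> np.ndarray:
        return self.beta.std(axis=0, ddof=1)

    def u_means(self) -> dict[str, np.ndarray]:
        return {k: v.mean(axis=0) for k, v in self.u.items()}

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        j = self.fixed_names.index(name)
        lo = (1.0 - level) / 2.0
        return (
            float(np.quantile(self.beta[:, j], lo)),
            float(np.quantile(self.beta[:, j], 1.0 - lo)),
        )

    def posterior_tail_p(self, name: str) -> float:
        """Two-sided posterior tail probability that the effect crosses zero."""
        j = self.fixed_names.index(name)
        draws = self.beta[:, j]
        frac = min((draws > 0).mean(), (draws < 0).mean())
        return float(max(2.0 * frac, 1.0 / (len(draws) + 1.0)))


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction for one scalar chain."""
    n = len(x) // 2
    if n < 2:
        return 1.0
    halves = np.stack([x[:n], x[n : 2 * n]])
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within <= 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + between / (n * within)))


def gibbs_fit(
    design: CoefficientDesign,
    n_iter: int = 20000,
    burn_in: int = 2000,
    thin: int = 5,
    seed: int | np.random.Generator = 0,
    include=None,
    prior_shape: float = 1e-3,
    prior_scale: float = 1e-3,
) -> GibbsResult:
    """Normal / inverse-gamma Gibbs cycle over fixed effects, random
    environment-interaction levels and variance components.

    Fixed effects carry a flat prior; each random family ``f`` has
    levels ``u_f ~ N(0, sigma_f^2 I)`` with a weakly-informative
    inverse-gamma prior on ``sigma_f^2`` and on the residual variance.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = design.y
    n = len(y)

    keep = None if include is None else set(include)
    fixed_cols = [
        j
        for j, name in enumerate(design.fixed_names)
        if keep is None
        or name in keep
        or design.column_registry[name].kind not in FIXED_KINDS
    ]
    fixed_names = [design.fixed_names[j] for j in fixed_cols]
    X = design.X[:, fixed_cols]
    # guard against exactly collinear / all-zero candidate columns
    jitter = 1e-10 * np.trace(X.T @ X) / max(X.shape[1], 1)
    XtX = X.T @ X + jitter * np.eye(X.shape[1])
    chol = cho_factor(XtX)
    # Cholesky factor of (XtX)^-1 for drawing beta
    inv_chol = np.linalg.cholesky(np.linalg.inv(XtX))
    families = {
        name: Z
        for name, Z in design.random_blocks.items()
        if (keep is None or name in keep) and float((Z * Z).sum()) > 0.0
    }
    ztz = {name: Z.T @ Z for name, Z in families.items()}

    p = X.shape[1]
    beta = np.zeros(p)
    u = {name: np.zeros(Z.shape[1]) for name, Z in families.items()}
    var_f = {name: 1.0 for name in families}
    sigma2 = max(float(np.var(y)), 1e-6)

    n_keep = (n_iter - burn_in + thin - 1) // thin
    beta_draws = np.empty((n_keep, p))
    u_draws = {name: np.empty((n_keep, Z.shape[1])) for name, Z in families.items()}
    sigma2_draws = np.empty(n_keep)
    var_draws = {name: np.empty(n_keep) for name in families}

    r = y - X @ beta
    for name, Z in families.items():
        r -= Z @ u[name]

    k = 0
    for it in range(n_iter):
        # fixed effects | rest
        r += X @ beta
        mean = cho_solve(chol, X.T @ r)
        beta = mean + np.sqrt(sigma2) * (inv_chol @ rng.standard_normal(p))
        r -= X @ beta

        # random families | rest
        for name, Z in families.items():
            r += Z @ u[name]
            q = Z.shape[1]
            # posterior precision (scaled by sigma2): Z'Z + (sigma2/var_f) I
            A = ztz[name] + (sigma2 / var_f[name]) * np.eye(q)
            La = np.linalg.cholesky(A)
            mu_u = np.linalg.solve(A, Z.T @ r)
            z = rng.standard_normal(q)
            u[name] = mu_u + np.sqrt(sigma2) * np.linalg.solve(La.T, z)
            r -= Z @ u[name]
            # variance component | u
            shape = prior_shape + 0.5 * q
            scale = prior_scale + 0.5 * float(u[name] @ u[name])
            var_f[name] = scale / rng.gamma(shape)
            if var_f[name] > _VARIANCE_GUARD:
                raise RuntimeError(
                    f"variance draw diverged for family {name!r} at iteration {it}"
                )

        # residual variance | rest
        shape = prior_shape + 0.5 * n
        scale = prior_scale + 0.5 * float(r @ r)
        sigma2 = scale / rng.gamma(shape)
        if sigma2 > _VARIANCE_GUARD:
            raise RuntimeError(f"residual variance draw diverged at iteration {it}")

        if it >= burn_in and (it - burn_in) % thin == 0:
            beta_draws[k] = beta
            for name in families:
                u_draws[name][k] = u[name]
            sigma2_draws[k] = sigma2
            for name in families:
                var_draws[name][k] = var_f[name]
            k += 1

    beta_draws = beta_draws[:k]
    sigma2_draws = sigma2_draws[:k]
    u_draws = {name: v[:k] for name, v in u_draws.items()}
    var_draws = {name: v[:k] for name, v in var_draws.items()}

    rhat = max(
        [_split_rhat(sigma2_draws)]
        + [_split_rhat(beta_draws[:, j]) for j in range(min(p, 10))]
    )
    return GibbsResult(
        fixed_names=fixed_names,
        beta=beta_draws,
        u=u_draws,
        sigma2=sigma2_draws,
        var_components=var_draws,
        converged=rhat < 1.1,
        rhat=rhat,
    )


# ---------------------------------------------------------------------------
# heritability partitioning
# ---------------------------------------------------------------------------


def _contributions_by_kind(
    design: CoefficientDesign,
    beta: dict[str, float],
    u: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Fitted contribution vector (over observations) per effect kind."""
    out: dict[str, np.ndarray] = {}
    for name, value in beta.items():
        info = design.column_registry[name]
        if info.kind not in FIXED_KINDS:
            continue
        col = design.X[:, design.fixed_index(name)]
        out.setdefault(info.kind, np.zeros(design.n_obs))
        out[info.kind] += value * col
    for name, levels in u.items():
        info = design.column_registry[name]
        Z = design.random_blocks[name]
        out.setdefault(info.kind, np.zeros(design.n_obs))
        out[info.kind] += Z @ np.asarray(levels)
    return out


def partition_heritability(
    design: CoefficientDesign,
    fit: GibbsResult | None = None,
    beta: dict[str, float] | None = None,
    u: dict[str, np.ndarray] | None = None,
    signed_additive: bool = False,
) -> HeritabilityPartition:
    """Partition Var(y) into per-kind heritability components (percent).

    Each component is 100 x Var(fitted contribution of that kind's
    terms) / Var(y).  Pass either a :class:`GibbsResult` (posterior
    means are used) or explicit point estimates.
    """
    if fit is not None:
        bm = fit.beta_mean()
        beta = {name: float(bm[j]) for j, name in enumerate(fit.fixed_names)}
        u = fit.u_means()
    beta = beta or {}
    u = u or {}
    var_y = float(np.var(design.y))
    if var_y <= 0:
        raise ValueError("zero phenotypic variance")
    contrib = _contributions_by_kind(design, beta, u)
    part = HeritabilityPartition()
    for kind, vec in contrib.items():
        setattr(part, KIND_TO_COMPONENT[kind], 100.0 * float(np.var(vec)) / var_y)
    if signed_additive:
        pos = np.zeros(design.n_obs)
        neg = np.zeros(design.n_obs)
        for name, value in beta.items():
            info = design.column_registry[name]
            if info.kind != "a":
                continue
            col = design.X[:, design.fixed_index(name)]
            if value > 0:
                pos += value * col
            else:
                neg += value * col
        part.h2_A_plus = 100.0 * float(np.var(pos)) / var_y
        part.h2_A_minus = 100.0 * float(np.var(neg)) / var_y
    return part


def percent_variance_explained(
    design: CoefficientDesign, name: str, value: float | np.ndarray
) -> float:
    """Percent of Var(y) explained by a single term's fitted contribution."""
    var_y = float(np.var(design.y))
    if var_y <= 0:
        raise ValueError("zero phenotypic variance")
    if name in design.random_blocks:
        vec = design.random_blocks[name] @ np.asarray(value)
    else:
        vec = float(value) * design.X[:, design.fixed_index(name)]
    return 100.0 * float(np.var(vec)) / var_y


@dataclass
class EffectEstimate:
    """One estimated genetic effect with provenance-labeled significance."""

    name: str
    kind: str
    markers: tuple[str, ...]
    env: int | None
    estimate: float
    se: float
    neg_log10_p_ew: float | None  # from the mapping stage (permutation)
    p_posterior: float | None  # posterior tail probability, labeled distinctly
    pct_variance: float


def effect_estimates(
    design: CoefficientDesign,
    fit: GibbsResult,
    scan=None,
) -> list[EffectEstimate]:
    """Tabulate posterior effect estimates, attaching the mapping-stage
    experiment-wise significance when a scan result is supplied."""
    out: list[EffectEstimate] = []
    bm, bs = fit.beta_mean(), fit.beta_sd()
    scan_neg = {}
    if scan is not None:
        scan_neg = {t.name: t.neg_log10_p_ew for t in scan.terms}
    for j, name in enumerate(fit.fixed_names):
        info = design.column_registry[name]
        if info.kind not in FIXED_KINDS:
            continue
        out.append(
            EffectEstimate(
                name=name,
                kind=info.kind,
                markers=info.markers,
                env=None,
                estimate=float(bm[j]),
                se=float(bs[j]),
                neg_log10_p_ew=scan_neg.get(name),
                p_posterior=fit.posterior_tail_p(name),
                pct_variance=percent_variance_explained(design, name, float(bm[j])),
            )
        )
    for name, levels in fit.u_means().items():
        info = design.column_registry[name]
        sds = fit.u[name].std(axis=0, ddof=1)
        # deviation levels are identified only up to a shift under the
        # sum-to-zero block coding; report them centered
        levels = levels - levels.mean()
        for h in range(len(levels)):
            out.append(
                EffectEstimate(
                    name=f"{name}@{h + 1}",
                    kind=info.kind,
                    markers=info.markers,
                    env=h + 1,
                    estimate=float(levels[h]),
                    se=float(sds[h]),
                    neg_log10_p_ew=scan_neg.get(name),
                    p_posterior=None,
                    pct_variance=percent_variance_explained(design, name, levels),
                )
            )
    return out
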