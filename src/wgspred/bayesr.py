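"""Mixture-prior Gibbs sampler for genomic prediction (BayesR-style).

Model: y = 1 mu + X beta + e with per-variant effects drawn from a
four-component normal mixture with variances (0, 1e-4, 1e-3, 1e-2) x
sigma_g2, a Dirichlet prior on the class proportions, a flat
scaled-inverse-chi-square residual prior, and sigma_g2 re-estimated every
iteration from the current genetic values. An optional categorical line
effect (reference level absorbed by the intercept) supports multi-line
training sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from wgspred.errors import ConfigurationError, SchemaError

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


DEFAULT_FRACTIONS = (0.0, 1e-4, 1e-3, 1e-2)


@dataclass(frozen=True)
class BayesRConfig:
    n_iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 10
    mixture_variance_fractions: tuple = DEFAULT_FRACTIONS
    dirichlet_alpha: tuple = (1.0, 1.0, 1.0, 1.0)
    seed: int = 0
    #: sigma_g2 update: "var_g" = variance of current genetic values,
    #: "sum_var" = sum over variants of 2p(1-p) beta^2
    genetic_variance_update: str = "var_g"

    def validate(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ConfigurationError("burn_in must be < n_iterations")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        f = np.asarray(self.mixture_variance_fractions, dtype=float)
        if f[0] != 0.0 or (np.diff(f) <= 0).any() or (f < 0).any():
            raise ConfigurationError(
                "mixture fractions must start at 0 and strictly increase"
            )
        if len(self.dirichlet_alpha) != len(f):
            raise ConfigurationError("alpha length must match fractions")
        if self.genetic_variance_update not in ("var_g", "sum_var"):
            raise ConfigurationError("unknown genetic_variance_update")


@dataclass
class BayesRFit:
    """Posterior summaries of a fitted chain plus prediction metadata."""

    intercept: float
    line_effects: dict
    effect_means: np.ndarray
    component_probs: np.ndarray  # (m, n_components)
    sigma_g2: float
    sigma_e2: float
    mixture_proportions: np.ndarray
    samples_kept: int
    variant_ids: np.ndarray | None = None
    column_means: np.ndarray = field(default=None, repr=False)
    line_levels: tuple = ()
    config: BayesRConfig | None = None


@njit(cache=True, fastmath=True)
def _gibbs_kernel(
    Xt,  # (m, n) float32, C-contiguous, columns centered
    y,  # (n,) float64
    line_idx,  # (n,) int64, 0-based; all zeros when single line
    n_lines,
    fracs,  # (K,) float64, fracs[0] == 0
    alpha,  # (K,) float64
    n_iter,
    burn,
    thin,
    seed,
    sg_floor_frac,
    sg_update_mode,  # 0 = var(g), 1 = sum 2p(1-p) beta^2
):
    np.random.seed(seed)
    m, n = Xt.shape
    K = fracs.shape[0]

    xx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Xt[j, i] * Xt[j, i]
        xx[j] = s

    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - mu
    var_y = 0.0
    for i in range(n):
        var_y += e[i] * e[i]
    var_y /= n

    beta = np.zeros(m)
    g = np.zeros(n)
    line_eff = np.zeros(n_lines)
    sigma_g2 = 0.5 * var_y if var_y > 0 else 1.0
    sigma_e2 = 0.5 * var_y if var_y > 0 else 1.0
    sg_floor = sg_floor_frac * var_y if var_y > 0 else 1e-8
    pi = alpha / alpha.sum()

    beta_sum = np.zeros(m)
    comp_count = np.zeros((m, K))
    mu_sum = 0.0
    line_sum = np.zeros(n_lines)
    sg_sum = 0.0
    se_sum = 0.0
    pi_sum = np.zeros(K)
    n_kept = 0

    counts = np.empty(K)
    logp = np.empty(K)
    comp = np.zeros(m, dtype=np.int64)

    for it in range(n_iter):
        # intercept (flat prior)
        s = 0.0
        for i in range(n):
            s += e[i]
        new_mu = mu + s / n + np.random.normal() * np.sqrt(sigma_e2 / n)
        dmu = new_mu - mu
        for i in range(n):
            e[i] -= dmu
        mu = new_mu

        # line effects, reference line 0 absorbed in mu
        for l in range(1, n_lines):
            s = 0.0
            cnt = 0
            for i in range(n):
                if line_idx[i] == l:
                    s += e[i]
                    cnt += 1
            if cnt == 0:
                continue
            new_eff = (
                line_eff[l]
                + s / cnt
                + np.random.normal() * np.sqrt(sigma_e2 / cnt)
            )
            diff = new_eff - line_eff[l]
            for i in range(n):
                if line_idx[i] == l:
                    e[i] -= diff
            line_eff[l] = new_eff

        # variant effects, single-site
        for k in range(K):
            counts[k] = 0.0
        for j in range(m):
            rhs = 0.0
            for i in range(n):
                rhs += Xt[j, i] * e[i]
            rhs += xx[j] * beta[j]

            logp[0] = np.log(pi[0] + 1e-300)
            for k in range(1, K):
                v = fracs[k] * sigma_g2
                denom = xx[j] * v + sigma_e2
                logp[k] = (
                    np.log(pi[k] + 1e-300)
                    + 0.5 * np.log(sigma_e2 / denom)
                    + 0.5 * rhs * rhs * v / (sigma_e2 * denom)
                )
            mx = logp[0]
            for k in range(1, K):
                if logp[k] > mx:
                    mx = logp[k]
            tot = 0.0
            for k in range(K):
                logp[k] = np.exp(logp[k] - mx)
                tot += logp[k]
            u = np.random.random() * tot
            acc = 0.0
            kk = K - 1
            for k in range(K):
                acc += logp[k]
                if u <= acc:
                    kk = k
                    break
            comp[j] = kk
            counts[kk] += 1.0

            if kk == 0:
                new_beta = 0.0
            else:
                v = fracs[kk] * sigma_g2
                denom = xx[j] * v + sigma_e2
                mean_post = rhs * v / denom
                sd_post = np.sqrt(v * sigma_e2 / denom)
                new_beta = mean_post + np.random.normal() * sd_post
            diff = new_beta - beta[j]
            if diff != 0.0:
                for i in range(n):
                    e[i] -= Xt[j, i] * diff
                    g[i] += Xt[j, i] * diff
                beta[j] = new_beta

        # mixture proportions ~ Dirichlet(alpha + counts)
        tot = 0.0
        for k in range(K):
            pi[k] = np.random.standard_gamma(alpha[k] + counts[k])
            tot += pi[k]
        for k in range(K):
            pi[k] /= tot

        # residual variance, flat scaled-inv-chi-square (nu=-2, S=0)
        rss = 0.0
        for i in range(n):
            rss += e[i] * e[i]
        df = n - 2.0
        chi = 2.0 * np.random.standard_gamma(df / 2.0)
        sigma_e2 = rss / chi

        # total genetic variance re-estimated from current state
        if sg_update_mode == 0:
            gm = 0.0
            for i in range(n):
                gm += g[i]
            gm /= n
            sg = 0.0
            for i in range(n):
                sg += (g[i] - gm) ** 2
            sg /= n
        else:
            sg = 0.0
            for j in range(m):
                sg += (xx[j] / n) * beta[j] * beta[j]
        sigma_g2 = sg if sg > sg_floor else sg_floor

        if it >= burn and (it - burn) % thin == 0:
            n_kept += 1
            mu_sum += mu
            sg_sum += sigma_g2
            se_sum += sigma_e2
            for k in range(K):
                pi_sum[k] += pi[k]
            for l in range(n_lines):
                line_sum[l] += line_eff[l]
            for j in range(m):
                beta_sum[j] += beta[j]
                comp_count[j, comp[j]] += 1.0

    return (
        beta_sum / n_kept,
        comp_count / n_kept,
        mu_sum / n_kept,
        line_sum / n_kept,
        sg_sum / n_kept,
        se_sum / n_kept,
        pi_sum / n_kept,
        n_kept,
    )


def fit_bayesr(
    y: np.ndarray,
    X: np.ndarray,
    line_labels: np.ndarray | None = None,
    config: BayesRConfig | None = None,
    variant_ids: np.ndarray | None = None,
    sigma_g2_floor_fraction: float = 1e-4,
) -> BayesRFit:
    """Run the Gibbs sampler and return posterior summaries.

    ``X`` is the (n x m) dosage matrix restricted to the predictor variant
    set; it is column-centred internally by training means (kept for
    prediction). Deterministic given ``config.seed``.
    """
    config = config or BayesRConfig()
    config.validate()
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X)
    if not np.isfinite(y).all():
        raise ConfigurationError("y contains non-finite values")
    n, m = X.shape
    if len(y) != n:
        raise SchemaError("y length does not match X rows")
    if n < 50:
        warnings.warn("fewer than 50 training records: fit will be unstable")

    col_means = X.mean(axis=0, dtype=np.float64)
    Xt = np.ascontiguousarray(
        (X.astype(np.float64) - col_means).T, dtype=np.float32
    )

    levels: tuple = ()
    line_idx = np.zeros(n, dtype=np.int64)
    n_lines = 1
    if line_labels is not None:
        labels = np.asarray(line_labels, dtype=str)
        levels = tuple(sorted(set(labels)))
        if len(levels) > 1:
            lut = {lv: k for k, lv in enumerate(levels)}
            line_idx = np.array([lut[v] for v in labels], dtype=np.int64)
            n_lines = len(levels)

    if float(np.var(y)) == 0.0:
        warnings.warn("constant response: returning degenerate fit")
        K = len(config.mixture_variance_fractions)
        probs = np.zeros((m, K))
        probs[:, 0] = 1.0
        return BayesRFit(
            intercept=float(y[0]) if n else 0.0,
            line_effects={lv: 0.0 for lv in levels[1:]},
            effect_means=np.zeros(m),
            component_probs=probs,
            sigma_g2=0.0,
            sigma_e2=0.0,
            mixture_proportions=probs.mean(axis=0),
            samples_kept=0,
            variant_ids=variant_ids,
            column_means=col_means,
            line_levels=levels,
            config=config,
        )

    (
        beta_mean,
        comp_probs,
        mu_mean,
        line_means,
        sg_mean,
        se_mean,
        pi_mean,
        n_kept,
    ) = _gibbs_kernel(
        Xt,
        y,
        line_idx,
        n_lines,
        np.asarray(config.mixture_variance_fractions, dtype=np.float64),
        np.asarray(config.dirichlet_alpha, dtype=np.float64),
        config.n_iterations,
        config.burn_in,
        config.thin,
        config.seed,
        sigma_g2_floor_fraction,
        0 if config.genetic_variance_update == "var_g" else 1,
    )
    line_effects = (
        {lv: float(line_means[k]) for k, lv in enumerate(levels) if k > 0}
        if n_lines > 1
        else {}
    )
    return BayesRFit(
        intercept=float(mu_mean),
        line_effects=line_effects,
        effect_means=beta_mean,
        component_probs=comp_probs,
        sigma_g2=float(sg_mean),
        sigma_e2=float(se_mean),
        mixture_proportions=pi_mean,
        samples_kept=int(n_kept),
        variant_ids=variant_ids,
        column_means=col_means,
        line_levels=levels,
        config=config,
    )


def predict_gebv(
    fit: BayesRFit,
    X_new: np.ndarray,
    line_labels: np.ndarray | None = None,
    variant_ids: np.ndarray | None = None,
) -> np.ndarray:
    """GEBV = intercept + line effect + centered dosages @ effect means.

    Centering constants come from the training set.
    """
    X_new = np.asarray(X_new, dtype=np.float64)
    if X_new.shape[1] != len(fit.effect_means):
        raise SchemaError(
            f"{X_new.shape[1]} columns but fit has {len(fit.effect_means)}"
        )
    if (
        variant_ids is not None
        and fit.variant_ids is not None
        and not np.array_equal(
            np.asarray(variant_ids, dtype=object), fit.variant_ids
        )
    ):
        raise SchemaError("variant ids do not match the fitted set")
    gebv = fit.intercept + (X_new - fit.column_means) @ fit.effect_means
    if line_labels is not None and fit.line_effects:
        labels = np.asarray(line_labels, dtype=str)
        gebv = gebv + np.array(
            [fit.line_effects.get(v, 0.0) for v in labels]
        )
    return gebv
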