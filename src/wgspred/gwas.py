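"""Single-variant linear mixed-model association scan.

The null model y = C a + u + e with u ~ N(0, K sigma_u2) is fitted once by
REML over the variance ratio after a single eigendecomposition of K; every
variant is then tested by generalized least squares with the variance
components held fixed at their null estimates and a Wald test on the
allele-substitution effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from wgspred.errors import ConfigurationError, IntegrityError


@dataclass
class VarianceComponents:
    sigma_u2: float
    sigma_e2: float
    log_likelihood: float

    def __post_init__(self) -> None:
        if self.sigma_u2 < 0 or self.sigma_e2 <= 0:
            raise ConfigurationError("invalid variance components")

    @property
    def h2(self) -> float:
        return self.sigma_u2 / (self.sigma_u2 + self.sigma_e2)


@dataclass
class SpectralDecomposition:
    """Cached eigendecomposition of K, reusable across traits."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns are eigenvectors

    @classmethod
    def from_K(cls, K: np.ndarray, tol: float = 1e-6) -> "SpectralDecomposition":
        vals, vecs = np.linalg.eigh(np.asarray(K, dtype=np.float64))
        if vals.min() < -tol * max(1.0, vals.max()):
            raise IntegrityError("K is not positive semidefinite")
        return cls(np.maximum(vals, 0.0), vecs)

    def rotate(self, M: np.ndarray) -> np.ndarray:
        return self.eigenvectors.T @ M


def _reml_terms(
    delta: float,
    vals: np.ndarray,
    Uy: np.ndarray,
    UX: np.ndarray,
) -> tuple[float, float]:
    """Profiled REML pieces at variance ratio delta = sigma_e2/sigma_u2.

    Returns (log restricted likelihood, profiled sigma_u2).
    """
    n, p = UX.shape
    d = vals + delta
    w = 1.0 / d
    XtWX = UX.T @ (UX * w[:, None])
    XtWy = UX.T @ (Uy * w)
    beta = np.linalg.solve(XtWX, XtWy)
    r = Uy - UX @ beta
    rss = float(r @ (r * w))
    sigma_u2 = rss / (n - p)
    _, ld_xwx = np.linalg.slogdet(XtWX)
    _, ld_xx = np.linalg.slogdet(UX.T @ UX)
    ll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi * sigma_u2)
        + np.sum(np.log(d))
        + ld_xwx
        - ld_xx
        + (n - p)
    )
    return ll, sigma_u2


def estimate_null_vc(
    y: np.ndarray,
    spectral: SpectralDecomposition,
    covariates: np.ndarray | None = None,
    delta_bounds: tuple[float, float] = (1e-5, 1e5),
) -> VarianceComponents:
    """REML variance components via 1-D optimisation over sigma_e2/sigma_u2.

    ``covariates`` excludes the intercept, which is always included.
    """
    y = np.asarray(y, dtype=np.float64)
    if not np.isfinite(y).all():
        raise ConfigurationError("y contains non-finite values")
    n = len(y)
    if n < 30:
        warnings.warn("fewer than 30 records: variance components unstable")
    X = np.ones((n, 1))
    if covariates is not None:
        X = np.hstack([X, np.asarray(covariates, dtype=np.float64)])
    Uy = spectral.rotate(y)
    UX = spectral.rotate(X)
    vals = spectral.eigenvalues

    lo, hi = np.log(delta_bounds[0]), np.log(delta_bounds[1])
    grid = np.linspace(lo, hi, 25)
    lls = np.array([_reml_terms(np.exp(g), vals, Uy, UX)[0] for g in grid])
    k = int(np.argmax(lls))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda g: -_reml_terms(np.exp(g), vals, Uy, UX)[0],
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x)
    ll, sigma_u2 = _reml_terms(np.exp(log_delta), vals, Uy, UX)
    sigma_e2 = np.exp(log_delta) * sigma_u2
    return VarianceComponents(
        sigma_u2=sigma_u2, sigma_e2=sigma_e2, log_likelihood=ll
    )


def association_scan(
    y: np.ndarray,
    dosages: np.ndarray,
    variant_ids: np.ndarray,
    spectral: SpectralDecomposition,
    vc: VarianceComponents,
    covariates: np.ndarray | None = None,
    variant_meta: pd.DataFrame | None = None,
    rotated_dosages: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant GLS with Wald p-values, variance components held fixed.

    The covariance sigma_u2 K + sigma_e2 I is diagonalised by the cached
    eigendecomposition; covariates (plus intercept) are projected out under
    the induced weights and each variant is tested marginally.
    ``rotated_dosages`` (U' G) may be precomputed and shared across traits.

    Returns a frame: variant_id [, chrom, pos], beta, se, p, n, tested.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    X = np.ones((n, 1))
    if covariates is not None:
        X = np.hstack([X, np.asarray(covariates, dtype=np.float64)])
    Uy = spectral.rotate(y)
    UX = spectral.rotate(X)
    if rotated_dosages is None:
        rotated_dosages = spectral.rotate(np.asarray(dosages, dtype=np.float64))
    d = vc.sigma_u2 * spectral.eigenvalues + vc.sigma_e2
    sw = 1.0 / np.sqrt(d)

    yw = Uy * sw
    Xw = UX * sw[:, None]
    Gw = rotated_dosages * sw[:, None]
    Q, _ = np.linalg.qr(Xw)
    yr = yw - Q @ (Q.T @ yw)
    Gr = Gw - Q @ (Q.T @ Gw)

    xx = np.einsum("ij,ij->j", Gr, Gr)
    polymorphic = np.asarray(dosages).std(axis=0) > 0
    tested = polymorphic & (xx > 1e-10 * max(1.0, float(np.abs(xx).max())))
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (Gr.T @ yr) / xx
        se = 1.0 / np.sqrt(xx)
        z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    p = np.minimum(np.maximum(p, np.nextafter(0, 1)), 1.0)
    beta = np.where(tested, beta, np.nan)
    se = np.where(tested, se, np.nan)
    p = np.where(tested, p, np.nan)

    out = pd.DataFrame({"variant_id": np.asarray(variant_ids, dtype=object)})
    if variant_meta is not None:
        out["chrom"] = variant_meta["chrom"].to_numpy()
        out["pos"] = variant_meta["pos"].to_numpy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n
    out["tested"] = tested
    return out


def line_design_matrix(line_labels: np.ndarray) -> np.ndarray | None:
    """Dummy-code line labels (reference level absorbed by the intercept)."""
    levels = sorted(set(map(str, line_labels)))
    if len(levels) < 2:
        return None
    labels = np.asarray(line_labels, dtype=str)
    return np.column_stack(
        [(labels == lv).astype(float) for lv in levels[1:]]
    )
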