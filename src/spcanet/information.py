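"""Closed-form mutual information, conditional MI and part mutual information
under a joint-Gaussian model, plus empirical estimation from data.

All values are in nats. The three measures form a hierarchy:

* ``MI(X, Y)``          — dependence between a pair of variables,
* ``CMI(X, Y | Z)``     — dependence remaining after conditioning on Z,
* ``PMI(X, Y | Z)``     — like CMI, but with the conditional densities
  p(x|z), q(y|z) replaced by the partial-dependence functions
  p*(x|z) = ∫ p(x|y,z) p(y) dy and q*(y|z) = ∫ q(y|x,z) q(x) dx, which makes
  the measure less sensitive to near-degenerate conditioning.

For jointly Gaussian variables every quantity has a closed form in the
covariance matrix.  Because p(x|y,z) is Gaussian with mean linear in (y, z)
and p(y) is Gaussian, the compound p*(x|z) is itself Gaussian: its mean is
the (y, z)-regression of X with y frozen at E[Y], and its variance is the
residual variance inflated by b_y^2 Var(Y), where b_y is the regression
coefficient on Y.  PMI then reduces to expectations of log-Gaussian
quadratic forms, evaluated exactly here and cross-checked against the
definitional integrals in :func:`numeric_information_oracle`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from numpy.polynomial.hermite_e import hermegauss

__all__ = [
    "DataMatrix",
    "GaussianJointModel",
    "InformationValue",
    "DegenerateVariableError",
    "InsufficientSamplesError",
    "InfiniteInformationError",
    "UnsupportedDimensionError",
    "fit_gaussian",
    "mutual_information",
    "conditional_mutual_information",
    "part_mutual_information",
    "pmi_from_data",
    "pmi_from_covariance",
    "mi_from_covariance",
    "cmi_from_covariance",
    "numeric_information_oracle",
]

#: condition number above which a covariance is treated as singular
CONDITION_LIMIT = 1e12

Measure = Literal["MI", "CMI", "PMI"]


class DegenerateVariableError(ValueError):
    """A variable in the requested subset has (near-)zero variance."""


class InsufficientSamplesError(ValueError):
    """Too few observations to fit a covariance over the subset."""


class InfiniteInformationError(ValueError):
    """The covariance is singular: the information measure diverges."""


class UnsupportedDimensionError(ValueError):
    """The quadrature oracle only handles models of dimension <= 3."""


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DataMatrix:
    """An activity matrix: ``n`` variables (genes/proteins) x ``m`` samples.

    Rows are variables, columns observations, matching the conventional
    genes-in-rows layout of expression matrices.
    """

    values: np.ndarray
    variable_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "variable_ids", tuple(self.variable_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (variables x samples)")
        n, m = values.shape
        if n < 2:
            raise ValueError(f"need at least 2 variables, got {n}")
        if m < 3:
            raise ValueError(f"need at least 3 observations, got {m}")
        if not np.all(np.isfinite(values)):
            raise ValueError("data matrix contains non-finite entries")
        if len(self.variable_ids) != n:
            raise ValueError("variable_ids must align with rows")
        if len(set(self.variable_ids)) != n:
            dupes = sorted(
                {v for v in self.variable_ids if self.variable_ids.count(v) > 1}
            )
            raise ValueError(f"duplicate variable ids: {dupes}")

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GaussianJointModel:
    """Mean and covariance over an ordered subset of variables."""

    variable_subset: tuple[int, ...]
    mean: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "variable_subset", tuple(self.variable_subset))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sigma", sigma)
        k = len(self.variable_subset)
        if mean.shape != (k,) or sigma.shape != (k, k):
            raise ValueError("mean/sigma dimensions must match variable_subset")
        if not np.allclose(sigma, sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if np.min(np.linalg.eigvalsh(sigma)) < -1e-10:
            raise ValueError("sigma must be positive semi-definite")

    @property
    def dim(self) -> int:
        return len(self.variable_subset)


@dataclass(frozen=True)
class InformationValue:
    """A computed information measure with its conditioning context."""

    measure: Measure
    value: float
    conditioning_set: tuple[int, ...] = field(default_factory=tuple)

    @property
    def order(self) -> int:
        return len(self.conditioning_set)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_gaussian(D: DataMatrix, subset: Sequence[int]) -> GaussianJointModel:
    """Fit a Gaussian over ``subset`` by sample mean and covariance (ddof=1).

    Variables are standardized (zero mean, unit variance) first, so the
    returned ``sigma`` is the sample correlation matrix.  All three measures
    are invariant under per-variable affine rescaling, and standardizing
    improves conditioning of the determinant ratios.
    """
    subset = tuple(int(i) for i in subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    n, m = D.values.shape
    for i in subset:
        if not 0 <= i < n:
            raise IndexError(f"variable index {i} out of range for n={n}")
    if m < len(subset) + 1:
        raise InsufficientSamplesError(
            f"{m} samples cannot support a covariance over {len(subset)} variables"
        )
    sub = D.values[list(subset), :]
    sd = sub.std(axis=1, ddof=1)
    zero = np.nonzero(sd <= 0)[0]
    if zero.size:
        ids = [D.variable_ids[subset[k]] for k in zero]
        raise DegenerateVariableError(f"zero-variance variable(s): {ids}")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    sigma = (z @ z.T) / (m - 1)
    sigma = (sigma + sigma.T) / 2.0
    return GaussianJointModel(subset, np.zeros(len(subset)), sigma)


def _check_conditioning(sigma: np.ndarray) -> None:
    """Raise if a determinant ratio would be numerically meaningless."""
    if np.linalg.cond(sigma) > CONDITION_LIMIT:
        raise InfiniteInformationError(
            "covariance is singular (condition number exceeds 1e12)"
        )


def _logdet(sigma: np.ndarray) -> float:
    """log det via Cholesky; raises InfiniteInformationError if not SPD."""
    a = np.atleast_2d(sigma)
    if a.size == 0:
        return 0.0
    try:
        chol = np.linalg.cholesky(a)
    except np.linalg.LinAlgError as exc:
        raise InfiniteInformationError("covariance not positive definite") from exc
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


# ---------------------------------------------------------------------------
# Closed forms on a covariance matrix
# ---------------------------------------------------------------------------


def mi_from_covariance(sigma: np.ndarray) -> float:
    """MI of the first two variables: 0.5 ln(sigma_xx sigma_yy / det Sigma_xy)."""
    sigma = np.asarray(sigma, dtype=float)
    s = sigma[:2, :2]
    _check_conditioning(s)
    return 0.5 * (math.log(s[0, 0]) + math.log(s[1, 1]) - _logdet(s))


def cmi_from_covariance(sigma: np.ndarray) -> float:
    """CMI(X, Y | Z) with X, Y the first two variables and Z the rest.

    0.5 ln( det S_xz det S_yz / (det S_z det S_xyz) ); reduces to
    :func:`mi_from_covariance` when there is no Z.
    """
    sigma = np.asarray(sigma, dtype=float)
    d = sigma.shape[0]
    if d == 2:
        return mi_from_covariance(sigma)
    _check_conditioning(sigma)
    z = list(range(2, d))
    xz = [0] + z
    yz = [1] + z
    val = 0.5 * (
        _logdet(sigma[np.ix_(xz, xz)])
        + _logdet(sigma[np.ix_(yz, yz)])
        - _logdet(sigma[np.ix_(z, z)])
        - _logdet(sigma)
    )
    return max(val, 0.0)


def pmi_from_covariance(sigma: np.ndarray) -> float:
    """PMI(X, Y | Z) in closed form for a Gaussian joint.

    With zero means (WLOG — all terms are translation invariant):

    * p(x,y|z) is Gaussian with covariance S_xy|z, so
      E[ln p(x,y|z)] = -ln(2π) - 0.5 ln det S_xy|z - 1.
    * p*(x|z) = ∫ p(x|y,z) p(y) dy is Gaussian with mean c'z (the z-part of
      the (y,z)-regression of x) and variance v* = s²_{x|yz} + b_y² Var(Y);
      its expected log under the joint is
      -0.5 ln(2π v*) - E[(x - c'z)²] / (2 v*).

    PMI is the difference; it reduces to MI when Z is empty and is clamped
    at 0 from below (the population value is a KL divergence, so tiny
    negatives are numerical noise).
    """
    sigma = np.asarray(sigma, dtype=float)
    d = sigma.shape[0]
    if d == 2:
        return mi_from_covariance(sigma)
    _check_conditioning(sigma)

    z = list(range(2, d))
    szz = sigma[np.ix_(z, z)]
    # conditional covariance of (x, y) given z
    a = np.linalg.solve(szz, sigma[np.ix_(z, [0, 1])])
    s_xy_z = sigma[:2, :2] - sigma[np.ix_([0, 1], z)] @ a
    logdet_xy_z = _logdet(s_xy_z)

    def star_terms(target: int, other: int) -> tuple[float, float]:
        """(ln v*, E[(t - c'z)^2] / v*) for p*(target | z)."""
        idx = [other] + z
        s_ii = sigma[np.ix_(idx, idx)]
        beta = np.linalg.solve(s_ii, sigma[idx, target])
        resid = sigma[target, target] - sigma[target, idx] @ beta
        b_other, c = beta[0], beta[1:]
        v_star = resid + b_other**2 * sigma[other, other]
        if v_star <= 0:
            raise InfiniteInformationError("degenerate partial-dependence variance")
        e_sq = (
            sigma[target, target]
            - 2.0 * c @ sigma[z, target]
            + c @ szz @ c
        )
        return math.log(v_star), float(e_sq) / v_star

    log_vx, ex = star_terms(0, 1)
    log_vy, ey = star_terms(1, 0)
    val = 0.5 * (log_vx + log_vy - logdet_xy_z) + 0.5 * (ex + ey) - 1.0
    return max(val, 0.0)


# ---------------------------------------------------------------------------
# Model-level API
# ---------------------------------------------------------------------------


def _require_pair(model: GaussianJointModel) -> None:
    if model.dim != 2:
        raise ValueError(f"expected a 2-variable model, got {model.dim}")
    if model.sigma[0, 0] <= 0 or model.sigma[1, 1] <= 0:
        raise DegenerateVariableError("non-positive variance in model")


def mutual_information(model: GaussianJointModel) -> InformationValue:
    """MI of a two-variable Gaussian: -0.5 ln(1 - rho^2), in nats."""
    _require_pair(model)
    return InformationValue("MI", mi_from_covariance(model.sigma))


def conditional_mutual_information(model: GaussianJointModel) -> InformationValue:
    """CMI(X, Y | Z); X, Y are the model's first two variables."""
    if model.dim < 2:
        raise ValueError("model must contain at least X and Y")
    return InformationValue(
        "CMI", cmi_from_covariance(model.sigma), model.variable_subset[2:]
    )


def part_mutual_information(model: GaussianJointModel) -> InformationValue:
    """PMI(X, Y | Z); equals MI exactly when Z is empty."""
    if model.dim < 2:
        raise ValueError("model must contain at least X and Y")
    return InformationValue(
        "PMI", pmi_from_covariance(model.sigma), model.variable_subset[2:]
    )


def pmi_from_data(
    D: DataMatrix, i: int, j: int, K: Sequence[int] = ()
) -> InformationValue:
    """Empirical order-|K| PMI between variables i and j given K.

    With K empty this is the empirical MI (the zero-order PMI).
    """
    K = tuple(int(k) for k in K)
    if i == j:
        raise ValueError("i and j must differ")
    if i in K or j in K:
        raise ValueError("conditioning set may not contain i or j")
    model = fit_gaussian(D, (i, j) + K)
    return InformationValue("PMI", pmi_from_covariance(model.sigma), K)


# ---------------------------------------------------------------------------
# Definitional-integral oracle (verification only; dimension <= 3)
# ---------------------------------------------------------------------------


def _gauss_hermite_grid(sigma: np.ndarray, nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensorized probabilists' Gauss-Hermite grid for E_{N(0, sigma)}[f]."""
    d = sigma.shape[0]
    x1, w1 = hermegauss(nodes)
    w1 = w1 / math.sqrt(2.0 * math.pi)
    grids = np.meshgrid(*([x1] * d), indexing="ij")
    u = np.stack([g.ravel() for g in grids], axis=1)
    wgrids = np.meshgrid(*([w1] * d), indexing="ij")
    w = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)
    chol = np.linalg.cholesky(sigma)
    return u @ chol.T, w


def _normal_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    diff = x - mean
    sol = np.linalg.solve(cov, diff.T).T
    return -0.5 * (d * math.log(2 * math.pi) + _logdet(cov) + np.sum(diff * sol, axis=1))


def numeric_information_oracle(
    model: GaussianJointModel, measure: Measure, nodes: int = 48
) -> InformationValue:
    """Evaluate MI/CMI/PMI by quadrature of the definitional integral.

    Slow but independent of the closed forms: densities are evaluated
    pointwise on a tensorized Gauss-Hermite grid, and the PMI
    partial-dependence function p*(x|z) is itself computed by a one-
    dimensional quadrature over y of p(x|y,z) p(y) — the defining sum —
    rather than via its Gaussian reduction.  Accuracy is about 1e-6 for
    MI/CMI and 1e-5 for PMI on well-conditioned models.
    """
    if model.dim > 3:
        raise UnsupportedDimensionError("oracle supports at most 3 variables")
    if model.dim < 2:
        raise ValueError("need at least two variables")
    sigma = model.sigma
    _check_conditioning(sigma)
    if measure == "PMI" and model.dim == 3:
        nodes = min(nodes, 32)  # the inner integral dominates the cost
    pts, w = _gauss_hermite_grid(sigma, nodes)
    zero2 = np.zeros(2)

    log_joint = _normal_logpdf(pts, np.zeros(model.dim), sigma)

    if model.dim == 2 or measure == "MI":
        lxy = _normal_logpdf(pts[:, :2], zero2, sigma[:2, :2])
        lx = _normal_logpdf(pts[:, :1], zero2[:1], sigma[:1, :1])
        ly = _normal_logpdf(pts[:, 1:2], zero2[:1], sigma[1:2, 1:2])
        val = float(np.sum(w * (lxy - lx - ly)))
        return InformationValue(measure, val)

    z = [2]
    szz = sigma[np.ix_(z, z)]
    zc = pts[:, 2:3]

    def cond_logpdf(targets: list[int], given_z: np.ndarray) -> np.ndarray:
        """log p(x_targets | z) for each grid point, by Gaussian conditioning."""
        stz = sigma[np.ix_(targets, z)]
        gain = np.linalg.solve(szz, stz.T).T
        mean = given_z @ gain.T
        cov = sigma[np.ix_(targets, targets)] - stz @ gain.T
        return _normal_logpdf(pts[:, targets] - mean, np.zeros(len(targets)), cov)

    if measure == "CMI":
        lxy = cond_logpdf([0, 1], zc)
        lx = cond_logpdf([0], zc)
        ly = cond_logpdf([1], zc)
        val = float(np.sum(w * (lxy - lx - ly)))
        return InformationValue("CMI", val, model.variable_subset[2:])

    # PMI: p*(x|z) = ∫ p(x|y,z) p(y) dy.  The integrand in y is a product
    # of two Gaussians and can be a narrow spike when x is nearly determined
    # by (y, z), so the inner integral uses the trapezoid rule on a fine
    # fixed grid (spectrally accurate for Gaussians) rather than a
    # p(y)-weighted Gauss-Hermite rule.
    inner = 501

    def log_pstar(target: int, other: int) -> np.ndarray:
        cond = [other] + z
        scz = sigma[np.ix_(cond, cond)]
        stc = sigma[np.ix_([target], cond)]
        gain = np.linalg.solve(scz, stc.T).T  # 1 x 2
        resid = float(
            sigma[target, target] - (stc @ np.linalg.solve(scz, stc.T)).item()
        )
        sd_o = math.sqrt(sigma[other, other])
        grid = np.linspace(-8.0 * sd_o, 8.0 * sd_o, inner)
        dy = grid[1] - grid[0]
        log_py = (
            -0.5 * math.log(2 * math.pi * sigma[other, other])
            - 0.5 * grid**2 / sigma[other, other]
        )
        t = pts[:, target]
        out = np.empty(len(pts))
        log_norm = -0.5 * math.log(2 * math.pi * resid)
        for lo in range(0, len(pts), 4096):
            hi = min(lo + 4096, len(pts))
            means = gain[0, 0] * grid[None, :] + gain[0, 1] * zc[lo:hi]
            log_comp = (
                log_norm
                - 0.5 * (t[lo:hi, None] - means) ** 2 / resid
                + log_py[None, :]
            )
            mmax = log_comp.max(axis=1, keepdims=True)
            out[lo:hi] = mmax[:, 0] + np.log(
                dy * np.sum(np.exp(log_comp - mmax), axis=1)
            )
        return out

    lxy = cond_logpdf([0, 1], zc)
    lpx = log_pstar(0, 1)
    lqy = log_pstar(1, 0)
    val = float(np.sum(w * (lxy - lpx - lqy)))
    return InformationValue("PMI", val, model.variable_subset[2:])
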