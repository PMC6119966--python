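"""Decentralized linear regression with pooled-equivalent inference.

Three federated estimators for the model y ~ w'x + b on data split across
sites, plus decentralized computation of R-squared and per-coefficient
t / p values:

* **single-shot** — every site solves its own least-squares problem once and
  the aggregator takes the sample-size-weighted average of the local weight
  vectors.  Cheap (one round) but only meta-analysis quality: the average of
  local optima is generally not the pooled optimum, and site indicator
  covariates cannot be used (they are constant within a site).
* **DRNE** (decentralized regression with normal equation) — sites upload
  their Gram matrix X_j'X_j and moment vector X_j'y_j; the aggregator sums
  them and solves the pooled normal equations.  Exactly equal to pooled
  ordinary least squares, for any partition of the rows.
* **multi-shot** — iterative distributed gradient descent.  Each round the
  aggregator broadcasts the current weights, sites return local gradients of
  the sum-of-squared-error objective, and the aggregator applies an Adam
  update to their plain sum (the global objective is a sum of the local
  ones, so the global gradient is the sum of local gradients).  Converges to
  the pooled solution without anyone forming a Gram matrix.

All estimators accept a stack of response columns sharing one design (one
column per voxel in the imaging use-case) and vectorize over targets.
Every cross-site payload is recorded in a :class:`~decentnet.core_network.MessageLog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core_network import (
    AGGREGATOR,
    CollinearityError,
    MessageLog,
    SiteDataset,
)

__all__ = [
    "OptimizerConfig",
    "RegressionResult",
    "local_objective",
    "local_gradient",
    "single_shot_fit",
    "drne_fit",
    "multi_shot_fit",
    "decentralized_r2",
    "decentralized_tvalues",
]


@dataclass
class OptimizerConfig:
    """Hyper-parameters for the multi-shot Adam loop.

    The loop stops when the infinity norm of the aggregated gradient (of the
    internally standardized problem, see :func:`multi_shot_fit`) drops below
    ``tolerance``, when the largest weight change falls below
    ``weight_tolerance``, or after ``max_iterations`` rounds (the result is
    then flagged non-converged).  The learning rate is halved whenever the
    gradient norm has not improved for ``patience`` consecutive iterations —
    with a full (deterministic) gradient Adam otherwise settles into a limit
    cycle whose amplitude is set by the learning rate.
    """

    scheme: str = "adam"
    learning_rate: float = 0.05
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    tolerance: float = 1e-6
    weight_tolerance: float = 1e-9
    max_iterations: int = 10000
    patience: int = 50
    lr_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.scheme != "adam":
            raise ValueError(f"unsupported scheme {self.scheme!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("beta1/beta2 must lie in (0, 1)")
        if self.epsilon <= 0 or self.tolerance <= 0:
            raise ValueError("epsilon and tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class RegressionResult:
    """Weights plus goodness-of-fit and significance statistics.

    For a multi-target fit (V response columns) ``weights``, ``t_values``
    and ``p_values`` have shape (d+1, V) and ``sse``/``sst``/``r_squared``
    shape (V,); for a single 1-D response everything is squeezed to the
    shapes a single regression would produce.
    """

    weights: np.ndarray
    sse: np.ndarray | float
    sst: np.ndarray | float
    r_squared: np.ndarray | float
    t_values: np.ndarray
    p_values: np.ndarray
    dof: int
    iterations: int = 0
    converged: bool = True
    method: str = ""


def _check_dims(site: SiteDataset, w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape[0] != site.n_params:
        raise ValueError(
            f"weight vector has {w.shape[0]} entries but design has "
            f"{site.n_params} columns"
        )
    return w


def local_objective(site: SiteDataset, w: np.ndarray):
    """Sum of squared residuals of ``w`` on this site's data.

    Returns a scalar for a 1-D response, a length-V vector for stacked
    targets.
    """
    w = _check_dims(site, w)
    resid = site.response_2d - site.design @ w.reshape(site.n_params, -1)
    out = np.einsum("ij,ij->j", resid, resid)
    return float(out[0]) if site.response.ndim == 1 and w.ndim == 1 else out


def local_gradient(site: SiteDataset, w: np.ndarray) -> np.ndarray:
    """Gradient of the local sum-of-squares objective at ``w``.

    Because the global objective is the plain sum of the local ones, the
    pooled gradient is recovered exactly by summing these across sites.
    """
    w = _check_dims(site, w)
    w2 = w.reshape(site.n_params, -1)
    grad = -2.0 * site.design.T @ (site.response_2d - site.design @ w2)
    return grad.ravel() if w.ndim == 1 else grad


def _as_weight_matrix(sites: Sequence[SiteDataset]) -> tuple[int, int, bool]:
    """(d+1, V, squeeze) across a consistent site list."""
    if not sites:
        raise ValueError("need at least one site")
    p = sites[0].n_params
    v = sites[0].response_2d.shape[1]
    for s in sites:
        if s.n_params != p:
            raise ValueError("sites disagree on design dimension")
        if s.response_2d.shape[1] != v:
            raise ValueError("sites disagree on number of response targets")
    return p, v, sites[0].response.ndim == 1


def _squeeze(res: RegressionResult, squeeze: bool) -> RegressionResult:
    if squeeze:
        res.weights = res.weights.ravel()
        res.t_values = res.t_values.ravel()
        res.p_values = res.p_values.ravel()
        res.sse = float(np.asarray(res.sse).ravel()[0])
        res.sst = float(np.asarray(res.sst).ravel()[0])
        res.r_squared = float(np.asarray(res.r_squared).ravel()[0])
    return res


def _finish(
    sites: Sequence[SiteDataset],
    weights: np.ndarray,
    log: MessageLog | None,
    method: str,
    iterations: int = 0,
    converged: bool = True,
) -> RegressionResult:
    sse, sst, r2 = decentralized_r2(sites, weights, log=log)
    try:
        t, p, dof = decentralized_tvalues(sites, weights, log=log)
    except ValueError:
        # saturated model (n <= d+1): weights exist but inference does not
        t = np.full_like(np.atleast_2d(weights.reshape(sites[0].n_params, -1)), np.nan)
        p = np.full_like(t, np.nan)
        dof = sum(s.n_j for s in sites) - sites[0].n_params
    _, _, squeeze = _as_weight_matrix(sites)
    res = RegressionResult(
        weights=np.atleast_2d(weights.reshape(sites[0].n_params, -1)),
        sse=np.atleast_1d(sse),
        sst=np.atleast_1d(sst),
        r_squared=np.atleast_1d(r2),
        t_values=t.reshape(sites[0].n_params, -1),
        p_values=p.reshape(sites[0].n_params, -1),
        dof=dof,
        iterations=iterations,
        converged=converged,
        method=method,
    )
    return _squeeze(res, squeeze)


def single_shot_fit(
    sites: Sequence[SiteDataset],
    log: MessageLog | None = None,
) -> RegressionResult:
    """One-round federated fit: average of local least-squares solutions.

    Each site solves its own problem and uploads its weight matrix plus its
    sample count; the aggregator forms the n_j-weighted average.  Local
    designs must be full rank — in particular they cannot contain site
    indicator columns, which are constant within a site.
    """
    p, v, _ = _as_weight_matrix(sites)
    round0 = log.next_round if log is not None else 0
    num = np.zeros((p, v))
    n_total = 0
    for site in sites:
        if site.n_j <= p:
            raise CollinearityError(
                f"site {site.site_id!r} has n_j={site.n_j} <= d+1={p}; local "
                "least squares is under-determined"
            )
        w_j, _, rank, _ = np.linalg.lstsq(site.design, site.response_2d, rcond=None)
        if rank < p:
            raise CollinearityError(
                f"site {site.site_id!r} has a rank-deficient local design "
                f"(rank {rank} < {p}); remove collinear columns (e.g. site "
                "indicators) before a single-shot fit"
            )
        num += site.n_j * w_j
        n_total += site.n_j
        if log is not None:
            log.send(round0, site.site_id, AGGREGATOR, p * v + 1)  # weights + n_j
    weights = num / n_total
    return _finish(sites, weights, log, "single_shot")


def _summed_normal_equations(
    sites: Sequence[SiteDataset],
    log: MessageLog | None,
) -> tuple[np.ndarray, np.ndarray]:
    p, v, _ = _as_weight_matrix(sites)
    round0 = log.next_round if log is not None else 0
    gram = np.zeros((p, p))
    moment = np.zeros((p, v))
    for site in sites:
        gram += site.design.T @ site.design
        moment += site.design.T @ site.response_2d
        if log is not None:
            log.send(round0, site.site_id, AGGREGATOR, p * p + p * v)
    return gram, moment


def drne_fit(
    sites: Sequence[SiteDataset],
    log: MessageLog | None = None,
) -> RegressionResult:
    """Decentralized regression with the normal equation.

    Sites upload X_j'X_j and X_j'y_j; the aggregator solves
    (sum_j X_j'X_j) w = sum_j X_j'y_j.  Because the sums equal the pooled
    cross-products, the result is *exactly* the pooled ordinary
    least-squares solution, independent of how rows are partitioned.
    """
    gram, moment = _summed_normal_equations(sites, log)
    try:
        if np.linalg.cond(gram) > 1e12:
            raise CollinearityError("aggregated Gram matrix is singular or near-singular")
        weights = np.linalg.solve(gram, moment)
    except np.linalg.LinAlgError as err:
        raise CollinearityError(f"aggregated Gram matrix not invertible: {err}") from err
    return _finish(sites, weights, log, "drne")


def _standardization_round(
    sites: Sequence[SiteDataset],
    log: MessageLog | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate global column means/scales without moving raw rows.

    Sites upload per-column sums and sums of squares of design and response
    (2(d+1) + 2V scalars each); the aggregator forms global means and
    standard deviations.  The intercept column keeps mean 0 / scale 1 so
    fitted weights can be mapped back exactly.
    """
    p, v, _ = _as_weight_matrix(sites)
    round0 = log.next_round if log is not None else 0
    n = 0
    xs = np.zeros(p)
    xss = np.zeros(p)
    ys = np.zeros(v)
    yss = np.zeros(v)
    for site in sites:
        n += site.n_j
        xs += site.design.sum(axis=0)
        xss += (site.design**2).sum(axis=0)
        y2 = site.response_2d
        ys += y2.sum(axis=0)
        yss += (y2**2).sum(axis=0)
        if log is not None:
            log.send(round0, site.site_id, AGGREGATOR, 2 * p + 2 * v + 1)
    x_mean = xs / n
    x_sd = np.sqrt(np.maximum(xss / n - x_mean**2, 0.0))
    y_sd = np.sqrt(np.maximum(yss / n - (ys / n) ** 2, 0.0))
    x_sd[x_sd == 0] = 1.0
    y_sd[y_sd == 0] = 1.0
    x_mean[-1], x_sd[-1] = 0.0, 1.0  # leave the intercept column alone
    return x_mean, x_sd, y_sd


def multi_shot_fit(
    sites: Sequence[SiteDataset],
    cfg: OptimizerConfig | None = None,
    log: MessageLog | None = None,
    initial_weights: np.ndarray | None = None,
) -> RegressionResult:
    """Iterative decentralized gradient descent with Adam at the aggregator.

    One preliminary round aggregates global column means and scales so the
    optimization runs on a standardized copy of each site's data (raw
    covariates such as age in years make the unstandardized problem too
    ill-conditioned for a first-order method).  Then, per iteration, the
    aggregator broadcasts the current weights, each site returns the
    gradient of its local sum-of-squares objective on its standardized
    slice, and the aggregator Adam-updates the summed gradient.  Final
    weights are mapped back to the raw scale, where they coincide with the
    pooled least-squares solution once converged.
    """
    cfg = cfg or OptimizerConfig()
    p, v, _ = _as_weight_matrix(sites)
    x_mean, x_sd, y_sd = _standardization_round(sites, log)

    std_designs = [(s.design - x_mean) / x_sd for s in sites]
    std_resps = [s.response_2d / y_sd for s in sites]

    if initial_weights is None:
        w = np.zeros((p, v))
    else:
        # map raw-scale weights into the standardized problem
        w_raw = np.asarray(initial_weights, dtype=float).reshape(p, v)
        w = w_raw * x_sd[:, None] / y_sd[None, :]
        w[-1] = (w_raw[-1] + x_mean @ w_raw) / y_sd
    m = np.zeros_like(w)
    vv = np.zeros_like(w)
    lr = cfg.learning_rate
    best_gn = np.inf
    stall = 0
    converged = False
    t = 0
    round0 = log.next_round if log is not None else 0
    for t in range(1, cfg.max_iterations + 1):
        grad = np.zeros_like(w)
        for X, Y in zip(std_designs, std_resps):
            grad += -2.0 * X.T @ (Y - X @ w)
        if log is not None:
            rnd = round0 + t - 1
            for site in sites:
                log.send(rnd, AGGREGATOR, site.site_id, p * v)  # broadcast w
                log.send(rnd, site.site_id, AGGREGATOR, p * v)  # local gradient
        gn = np.abs(grad).max()
        if gn <= cfg.tolerance:
            converged = True
            break
        if gn < 0.9 * best_gn:
            best_gn = gn
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                lr = max(lr * cfg.lr_factor, 1e-12)
                stall = 0
        m = cfg.beta1 * m + (1 - cfg.beta1) * grad
        vv = cfg.beta2 * vv + (1 - cfg.beta2) * grad**2
        m_hat = m / (1 - cfg.beta1**t)
        v_hat = vv / (1 - cfg.beta2**t)
        w_new = w - lr * m_hat / (np.sqrt(v_hat) + cfg.epsilon)
        if np.abs(w_new - w).max() <= cfg.weight_tolerance:
            w = w_new
            converged = True
            break
        w = w_new

    # undo the standardization: w_raw[j] = w[j] * y_sd / x_sd[j], intercept
    # absorbs the means that were subtracted from the covariate columns
    weights = w * y_sd[None, :] / x_sd[:, None]
    weights[-1] = w[-1] * y_sd - x_mean @ weights
    return _finish(sites, weights, log, "multi_shot", iterations=t, converged=converged)


def decentralized_r2(
    sites: Sequence[SiteDataset],
    w: np.ndarray,
    log: MessageLog | None = None,
):
    """Goodness of fit of ``w`` computed without pooling rows.

    Sites first report local response means and sample counts; the
    aggregator broadcasts the global mean (the n_j-weighted average).  Sites
    then report local SSE and local SST about that global mean, which sum to
    their pooled values, giving R^2 = 1 - SSE/SST exactly as a pooled
    evaluation would.
    """
    p, v, squeeze = _as_weight_matrix(sites)
    w2 = np.asarray(w, dtype=float).reshape(p, -1)
    round0 = log.next_round if log is not None else 0

    n = 0
    y_sum = np.zeros(v)
    for site in sites:
        n += site.n_j
        y_sum += site.response_2d.sum(axis=0)
        if log is not None:
            log.send(round0, site.site_id, AGGREGATOR, v + 1)  # local mean + n_j
    y_bar = y_sum / n

    sse = np.zeros(v)
    sst = np.zeros(v)
    for site in sites:
        resid = site.response_2d - site.design @ w2
        sse += np.einsum("ij,ij->j", resid, resid)
        dev = site.response_2d - y_bar
        sst += np.einsum("ij,ij->j", dev, dev)
        if log is not None:
            log.send(round0 + 1, AGGREGATOR, site.site_id, v)  # global mean
            log.send(round0 + 1, site.site_id, AGGREGATOR, 2 * v)  # SSE_j, SST_j
    if np.any(sst <= 0):
        raise ZeroDivisionError(
            "global response is constant (SST = 0); R^2 is undefined"
        )
    r2 = 1.0 - sse / sst
    if squeeze and np.asarray(w).ndim == 1:
        return float(sse[0]), float(sst[0]), float(r2[0])
    return sse, sst, r2


def decentralized_tvalues(
    sites: Sequence[SiteDataset],
    w: np.ndarray,
    log: MessageLog | None = None,
):
    """Per-coefficient t statistics and two-tailed p values at ``w``.

    Sites upload their Gram matrices and the SSE of ``w`` on their rows; the
    aggregator forms the residual variance sigma^2 = SSE / (n - d - 1) and
    the standard OLS sampling variance sigma^2 * [(sum_j X_j'X_j)^{-1}]_mm,
    then t_m = w_m / se_m with p from the Student-t survival function.
    """
    p, v, squeeze = _as_weight_matrix(sites)
    w2 = np.asarray(w, dtype=float).reshape(p, -1)
    round0 = log.next_round if log is not None else 0

    gram = np.zeros((p, p))
    sse = np.zeros(v)
    n = 0
    for site in sites:
        gram += site.design.T @ site.design
        resid = site.response_2d - site.design @ w2
        sse += np.einsum("ij,ij->j", resid, resid)
        n += site.n_j
        if log is not None:
            log.send(round0, site.site_id, AGGREGATOR, p * p + v + 1)
    dof = n - p
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom (n={n}, d+1={p})")
    try:
        gram_inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError as err:
        raise CollinearityError(f"aggregated Gram matrix not invertible: {err}") from err
    sigma2 = sse / dof  # (V,)
    se = np.sqrt(np.outer(np.diag(gram_inv), sigma2))  # (p, V)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, w2 / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    if squeeze and np.asarray(w).ndim == 1:
        return t.ravel(), pvals.ravel(), int(dof)
    return t, pvals, int(dof)
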