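"""Decentralized group spatial ICA.

Group spatial ICA models each subject's fMRI data X_i (voxels x time) as a
mixture of r statistically independent spatial maps shared across the group.
The decentralized variant reproduces the pooled estimate without moving raw
data:

1. **LocalPCA** — every subject is reduced and whitened to k1 principal
   components in the temporal dimension at its own site.
2. **GlobalPCA** — sites concatenate their reduced subjects column-wise and
   pass a running, variance-weighted rank-r reduction along a peer chain;
   each hop stacks the incoming d x r package with the local block and
   re-truncates.  The terminal site (the aggregator) holds r global spatial
   eigenvectors V (r x d, orthonormal rows).
3. **ICA** — the aggregator whitens V and runs infomax ICA to learn an r x r
   unmixing matrix W; the estimated group spatial maps are the rows of W
   applied to the whitened eigenvectors, stored column-wise as A_hat (d x r).
4. **Back-reconstruction** — A_hat is broadcast and each site recovers
   subject time-courses and subject-specific maps by two least-squares
   regressions (spatio-temporal regression).

Per non-aggregator site the traffic is exactly one d x r eigenvector
package sent plus one r x r unmixing matrix received.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core_network import AGGREGATOR, MessageLog

__all__ = [
    "SubjectData",
    "SpatialDecomposition",
    "ICAConfig",
    "GICAConfig",
    "ICADivergenceError",
    "local_pca",
    "global_pca",
    "whiten_rows",
    "infomax_ica",
    "back_reconstruct",
    "match_components",
    "run_dgica",
]


class ICADivergenceError(RuntimeError):
    """Infomax learning diverged (weight norm blow-up)."""


@dataclass
class SubjectData:
    """One subject's voxels x timepoints matrix, tagged with provenance."""

    data: np.ndarray
    subject_id: str
    site_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("subject data must be 2-D (voxels x timepoints)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id!r} contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class ICAConfig:
    max_steps: int = 512
    learning_rate: float = 0.015
    anneal_deg: float = 60.0
    anneal_factor: float = 0.9
    w_change_tol: float = 1e-7
    seed: int = 0


@dataclass
class GICAConfig:
    """Reduction sizes and ICA settings for a group run.

    ``subject_pcs`` is the per-subject temporal reduction (120 at full study
    scale) and ``global_components`` the number of group spatial components
    (100 at full scale); desk-scale fixtures use far smaller values.
    """

    subject_pcs: int = 120
    global_components: int = 100
    ica: ICAConfig = field(default_factory=ICAConfig)


@dataclass
class SpatialDecomposition:
    """Everything the group decomposition produces."""

    eigenvectors: np.ndarray  # V, r x d, orthonormal rows
    unmixing: np.ndarray  # W, r x r
    spatial_maps: np.ndarray  # A_hat, d x r
    subject_timecourses: dict  # subject_id -> (N_i_reduced x r)
    subject_maps: dict  # subject_id -> (d x r)


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Deterministic SVD sign convention: largest-|entry| positive per column."""
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


def local_pca(subject: SubjectData, k1: int) -> np.ndarray:
    """Reduce and whiten one subject to k1 temporal principal components.

    The voxels x N_i matrix is column-centered (per-timepoint voxel mean
    removed) and its top k1 left singular directions are returned scaled so
    that, across voxels, the output columns have zero mean, unit variance
    and zero pairwise covariance.
    """
    x = subject.data - subject.data.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(x.shape) * np.finfo(float).eps)) if s.size else 0
    if k1 > rank:
        raise ValueError(
            f"k1={k1} exceeds the rank ({rank}) of subject {subject.subject_id!r}"
        )
    return _fix_signs(u[:, :k1]) * np.sqrt(x.shape[0] - 1)


def retained_variance(subject: SubjectData, k1: int) -> float:
    """Share of (column-centered) variance captured by the top k1 components."""
    x = subject.data - subject.data.mean(axis=0, keepdims=True)
    s = np.linalg.svd(x, compute_uv=False)
    return float((s[:k1] ** 2).sum() / (s**2).sum())


def global_pca(
    site_blocks: Sequence[np.ndarray],
    r: int,
    log: MessageLog | None = None,
    site_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Peer-chain reduction to r global spatial eigenvectors V (r x d).

    The first site reduces its own d x m block to rank r and passes the
    d x r package (eigenvectors scaled by singular values, so variance
    weights survive the hop) to the next site, which stacks it column-wise
    with its local block and re-reduces; the chain ends at the aggregator.
    Each hop is logged as d*r scalars.
    """
    if not site_blocks:
        raise ValueError("need at least one site block")
    d = site_blocks[0].shape[0]
    ids = list(site_ids) if site_ids is not None else [f"site{i}" for i in range(len(site_blocks))]
    rnd = log.next_round if log is not None else 0
    carry: np.ndarray | None = None
    for i, block in enumerate(site_blocks):
        if block.shape[0] != d:
            raise ValueError("all site blocks must share the voxel dimension")
        stacked = block if carry is None else np.hstack([carry, block])
        u, s, _ = np.linalg.svd(stacked, full_matrices=False)
        if r > int(np.sum(s > s[0] * max(stacked.shape) * np.finfo(float).eps)):
            raise ValueError(f"r={r} exceeds the rank of the stacked data at hop {i}")
        carry = _fix_signs(u[:, :r]) * s[:r]
        if log is not None and i < len(site_blocks) - 1:
            log.send(rnd, ids[i], ids[i + 1], d * r)
    assert carry is not None
    v = carry / np.linalg.norm(carry, axis=0, keepdims=True)
    return v.T  # r x d, orthonormal rows


def whiten_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and sphere the rows of x; returns (whitened, sphering matrix)."""
    xc = x - x.mean(axis=1, keepdims=True)
    cov = xc @ xc.T / xc.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals <= 0):
        raise np.linalg.LinAlgError("row covariance not positive definite")
    sphere = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    return sphere @ xc, sphere


def infomax_ica(whitened: np.ndarray, cfg: ICAConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Infomax ICA with a logistic nonlinearity and natural-gradient updates.

    ``whitened`` is r x d (components x voxels), already sphered.  Training
    follows the classic recipe: random sample order each pass, block updates
    of size max(8, floor(sqrt(d))), and learning-rate annealing driven by
    the angle between successive weight changes.  Returns the r x r
    unmixing matrix W and the estimated source matrix transposed,
    A_hat = (W @ whitened)' of shape d x r.  The logistic score targets the
    super-Gaussian (sparse) sources typical of spatial brain maps.
    """
    cfg = cfg or ICAConfig()
    z = np.asarray(whitened, dtype=float)
    r, d = z.shape
    rng = np.random.default_rng(cfg.seed)
    w = np.eye(r)
    block = max(8, int(np.sqrt(d)))
    lr = cfg.learning_rate
    d_w_old: np.ndarray | None = None
    ident = np.eye(r)
    for step in range(1, cfg.max_steps + 1):
        w_before = w.copy()
        perm = rng.permutation(d)
        for start in range(0, d - block + 1, block):
            zb = z[:, perm[start : start + block]]
            u = w @ zb
            y = 1.0 / (1.0 + np.exp(-u))
            w = w + (lr / block) * ((block * ident + (1.0 - 2.0 * y) @ u.T) @ w)
            if not np.all(np.isfinite(w)) or np.abs(w).max() > 1e8:
                raise ICADivergenceError(f"infomax diverged at step {step}")
        d_w = w - w_before
        change = float(np.sum(d_w**2))
        if d_w_old is not None:
            denom = np.sqrt(np.sum(d_w**2) * np.sum(d_w_old**2))
            if denom > 0:
                angle = np.degrees(np.arccos(np.clip(np.sum(d_w * d_w_old) / denom, -1, 1)))
                if angle > cfg.anneal_deg:
                    lr *= cfg.anneal_factor
        d_w_old = d_w
        if change < cfg.w_change_tol:
            break
    a_hat = (w @ z).T  # d x r: transposed estimated independent spatial maps
    return w, a_hat


def back_reconstruct(subject: SubjectData, a_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spatio-temporal regression of one subject onto the group maps.

    First regression: time-courses T (N_i x r) solve A_hat @ T' ~ X_i in
    least squares.  Second regression: subject-specific maps (d x r) solve
    T @ M' ~ X_i'.
    """
    a_hat = np.asarray(a_hat, dtype=float)
    if np.linalg.matrix_rank(a_hat) < a_hat.shape[1]:
        raise np.linalg.LinAlgError("A_hat is rank deficient; cannot back-reconstruct")
    tc = np.linalg.lstsq(a_hat, subject.data, rcond=None)[0].T  # N_i x r
    maps = np.linalg.lstsq(tc, subject.data.T, rcond=None)[0].T  # d x r
    return tc, maps


def match_components(
    estimated: np.ndarray,
    reference: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hungarian matching of component rows under correlation distance.

    Solves the assignment maximizing total |Pearson correlation| between
    rows of ``estimated`` and rows of ``reference``; also returns the signs
    that flip estimated components into positive correlation and the
    matched absolute correlations.  Useful both for comparing two
    decompositions and for selecting a subset of components against a
    reference set (pass a reference with fewer rows).
    """
    est = np.atleast_2d(np.asarray(estimated, dtype=float))
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    if est.shape[1] != ref.shape[1]:
        raise ValueError("estimated and reference must share the feature dimension")
    if np.any(est.std(axis=1) == 0) or np.any(ref.std(axis=1) == 0):
        raise ValueError("zero-variance component encountered")
    ez = (est - est.mean(1, keepdims=True)) / est.std(1, keepdims=True)
    rz = (ref - ref.mean(1, keepdims=True)) / ref.std(1, keepdims=True)
    corr = ez @ rz.T / est.shape[1]  # est x ref
    rows, cols = linear_sum_assignment(-np.abs(corr))
    order = np.argsort(cols)
    rows, cols = rows[order], cols[order]
    matched = corr[rows, cols]
    signs = np.sign(matched)
    signs[signs == 0] = 1.0
    return rows, signs, np.abs(matched)


def run_dgica(
    sites: Sequence[Sequence[SubjectData]],
    cfg: GICAConfig,
    log: MessageLog | None = None,
    site_ids: Sequence[str] | None = None,
) -> SpatialDecomposition:
    """End-to-end decentralized group spatial ICA.

    ``sites`` is one list of subjects per site; the last site in the chain
    acts as aggregator.  Per-site subject reductions are concatenated
    temporally (column-wise), passed through the peer-chain global PCA, and
    the aggregator whitens and unmixes the global eigenvectors; the r x r
    unmixing matrix is then broadcast (logged once per non-aggregator site)
    and every subject is back-reconstructed.
    """
    if not sites or not any(len(s) for s in sites):
        raise ValueError("need at least one subject")
    ids = list(site_ids) if site_ids is not None else [f"site{i}" for i in range(len(sites))]
    ids[-1] = ids[-1] if site_ids is not None else AGGREGATOR

    blocks = []
    for subjects in sites:
        reduced = [local_pca(s, cfg.subject_pcs) for s in subjects]
        blocks.append(np.hstack(reduced))
    v = global_pca(blocks, cfg.global_components, log=log, site_ids=ids)

    z, sphere = whiten_rows(v)
    w, a_hat = infomax_ica(z, cfg.ica)
    if log is not None:
        rnd = log.next_round
        for sid in ids[:-1]:
            log.send(rnd, ids[-1], sid, cfg.global_components**2)

    tcs: dict = {}
    maps: dict = {}
    for subjects in sites:
        for s in subjects:
            tc, m = back_reconstruct(s, a_hat)
            tcs[s.subject_id] = tc
            maps[s.subject_id] = m
    return SpatialDecomposition(
        eigenvectors=v,
        unmixing=w,
        spatial_maps=a_hat,
        subject_timecourses=tcs,
        subject_maps=maps,
    )
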