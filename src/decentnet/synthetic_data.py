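"""Multi-site fixtures with known ground truth.

Two generators cover the package's study designs:

* :func:`gen_multisite_regression` — voxelwise linear-model data in the
  shape of a multi-site structural study: per-site covariate tables (age,
  diagnosis, gender), a shared set of planted per-voxel coefficients, additive
  site offsets and Gaussian noise.  Used to verify the decentralized
  regression estimators against their pooled counterparts.
* :func:`gen_fmri_subjects` — ICA-mixture functional data: sparse spatial
  blobs on a small 3-D grid mixed with per-subject component time-courses
  whose correlation structure switches among k planted covariance states.
  Motion-parameter tables and framewise-displacement series with planted
  spikes are emitted alongside, so the full dynamic-connectivity pipeline is
  exercisable end to end.

Every generator is a pure function of its seed: calling it twice with the
same truth object reproduces identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_network import SiteDataset
from .dgica import SubjectData

__all__ = [
    "RegressionTruth",
    "FMRITruth",
    "gen_multisite_regression",
    "gen_fmri_subjects",
    "site_design",
    "strip_site_columns",
]


@dataclass
class RegressionTruth:
    """Planted parameters for the voxelwise regression fixture.

    ``n_per_site`` defaults to three sites of 50 subjects and ``n_voxels``
    to 200 — large enough for stable per-voxel statistics, small enough to
    fit comfortably on one workstation.  ``true_weights`` has one row per
    covariate (age, diagnosis, gender) plus the intercept (last row) and one
    column per voxel; when omitted it is drawn N(0, 1) from ``seed``.
    """

    n_per_site: Sequence[int] = (50, 50, 50)
    n_voxels: int = 200
    d: int = 3  # age, diagnosis, gender
    noise_sd: float = 1.0
    site_offsets: Sequence[float] = (0.0, 1.0, -1.0)
    seed: int = 0
    true_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.site_offsets) != len(self.n_per_site):
            raise ValueError("site_offsets length must equal the site count")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


COVARIATE_COLUMNS = ["id", "age", "diagnosis", "gender", "site"]


def _covariate_tables(truth: RegressionTruth, rng: np.random.Generator) -> list[pd.DataFrame]:
    tables = []
    uid = 0
    for j, n_j in enumerate(truth.n_per_site):
        age = rng.uniform(18.0, 65.0, n_j)
        diagnosis = rng.integers(0, 2, n_j)
        gender = rng.integers(0, 2, n_j)
        tables.append(
            pd.DataFrame(
                {
                    "id": [f"sub{uid + i:04d}" for i in range(n_j)],
                    "age": age,
                    "diagnosis": diagnosis,
                    "gender": gender,
                    "site": f"site{j}",
                }
            )
        )
        uid += n_j
    return tables


def site_design(
    table: pd.DataFrame,
    site_labels: Sequence[str],
    include_site_dummies: bool = True,
) -> np.ndarray:
    """Augmented design matrix for one site's covariate table.

    Columns: age, diagnosis, gender, then one indicator per non-reference
    site (the first label in ``site_labels`` is the dropped reference), then
    the constant-1 intercept column last.  Site indicators are excluded for
    single-shot fits, where they would be locally constant.
    """
    cols = [table["age"].to_numpy(float), table["diagnosis"].to_numpy(float), table["gender"].to_numpy(float)]
    if include_site_dummies:
        for label in site_labels[1:]:
            cols.append((table["site"] == label).to_numpy(float))
    cols.append(np.ones(len(table)))
    return np.column_stack(cols)


def strip_site_columns(sites: Sequence[SiteDataset], n_site_dummies: int) -> list[SiteDataset]:
    """Drop the site-indicator columns (kept just before the intercept)."""
    out = []
    for s in sites:
        keep = list(range(s.n_params - 1 - n_site_dummies)) + [s.n_params - 1]
        out.append(SiteDataset(s.site_id, s.design[:, keep], s.response))
    return out


def gen_multisite_regression(
    truth: RegressionTruth,
) -> tuple[list[SiteDataset], list[pd.DataFrame], RegressionTruth]:
    """Simulate per-site design matrices and voxel responses.

    Responses are ``design_covariates @ true_weights`` plus the site's
    offset plus N(0, noise_sd) noise.  The returned site datasets carry
    S-1 site indicator columns (reference = first site) ahead of the
    intercept, ready for the normal-equation and multi-shot estimators;
    use :func:`strip_site_columns` for single-shot designs.
    """
    rng = np.random.default_rng(truth.seed)
    tables = _covariate_tables(truth, rng)
    site_labels = [f"site{j}" for j in range(len(truth.n_per_site))]

    if truth.true_weights is None:
        truth.true_weights = rng.normal(0.0, 1.0, (truth.d + 1, truth.n_voxels))
    w_true = np.asarray(truth.true_weights, dtype=float)
    if w_true.shape != (truth.d + 1, truth.n_voxels):
        raise ValueError(
            f"true_weights must have shape {(truth.d + 1, truth.n_voxels)}, got {w_true.shape}"
        )

    sites = []
    for j, table in enumerate(tables):
        bare = site_design(table, site_labels, include_site_dummies=False)
        clean = bare @ w_true  # (n_j, V); intercept row included via last column
        noise = rng.normal(0.0, truth.noise_sd, clean.shape)
        response = clean + truth.site_offsets[j] + noise
        design = site_design(table, site_labels, include_site_dummies=True)
        sites.append(SiteDataset(site_labels[j], design, response))
    return sites, tables, truth


# ---------------------------------------------------------------------------
# functional fixture


@dataclass
class FMRITruth:
    """Planted parameters for the ICA-mixture functional fixture.

    Desk-scale defaults: a 10 x 10 x 5 voxel grid (d = 500), r = 5 spatial
    sources, k = 3 connectivity states, T = 162 timepoints — the shape of a
    resting-state session, shrunk to seconds of compute.  ``dwell_range``
    keeps every state visit at least one window long so each state is
    represented by pure windows.  Filled-in fields (``spatial_maps``,
    ``templates`` and the per-subject records) are populated by
    :func:`gen_fmri_subjects`.
    """

    grid: tuple[int, int, int] = (10, 10, 5)
    r: int = 5
    k: int = 3
    T: int = 162
    noise_sd: float = 0.1
    tc_noise_sd: float = 0.2
    window: int = 22
    dwell_range: tuple[int, int] = (40, 70)
    spike_rate: float = 0.02
    spike_magnitude: float = 1.5
    fd_baseline: tuple[float, float] = (0.08, 0.02)
    min_template_separation: float = 0.5
    seed: int = 0

    spatial_maps: np.ndarray | None = None  # (d, r)
    templates: np.ndarray | None = None  # (k, r, r)
    subject_states: dict = field(default_factory=dict)  # id -> (T,) int labels
    subject_timecourses: dict = field(default_factory=dict)  # id -> (T, r)
    subject_fd: dict = field(default_factory=dict)  # id -> (T,)
    subject_motion: dict = field(default_factory=dict)  # id -> (T, 24)
    subject_spikes: dict = field(default_factory=dict)  # id -> index array

    @property
    def d(self) -> int:
        return int(np.prod(self.grid))


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _correlation_distance(a: np.ndarray, b: np.ndarray) -> float:
    return 1.0 - float(np.corrcoef(a, b)[0, 1])


def _make_templates(rng: np.random.Generator, truth: FMRITruth) -> np.ndarray:
    """k well-separated symmetric PSD covariance templates over r components."""
    r, k = truth.r, truth.k
    for _ in range(200):
        templates = []
        for _ in range(k):
            b = rng.normal(0.0, 1.0, (r, max(1, r // 2)))
            templates.append(b @ b.T / b.shape[1] + 0.5 * np.eye(r))
        ok = all(
            _correlation_distance(_upper(templates[i]), _upper(templates[j]))
            >= truth.min_template_separation
            for i in range(k)
            for j in range(i + 1, k)
        )
        if ok:
            return np.stack(templates)
    raise RuntimeError("could not draw sufficiently separated covariance templates")


def _make_spatial_maps(rng: np.random.Generator, truth: FMRITruth) -> np.ndarray:
    """Sparse Gaussian blobs at well-separated grid locations, one per source."""
    nx, ny, nz = truth.grid
    coords = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"), -1)
    centers = []
    attempts = 0
    while len(centers) < truth.r:
        c = rng.uniform([1, 1, 0.5], [nx - 1, ny - 1, nz - 0.5])
        if all(np.linalg.norm(c - np.asarray(prev)) >= 3.0 for prev in centers) or attempts > 500:
            centers.append(c)
        attempts += 1
    maps = []
    for c in centers:
        dist2 = ((coords - c) ** 2).sum(-1)
        blob = np.exp(-dist2 / (2 * 1.5**2))
        blob[blob < 0.05] = 0.0  # sparse, super-Gaussian across voxels
        maps.append(blob.ravel())
    return np.column_stack(maps)


def _state_sequence(rng: np.random.Generator, truth: FMRITruth) -> np.ndarray:
    labels = np.empty(truth.T, dtype=int)
    t = 0
    prev = -1
    lo, hi = truth.dwell_range
    while t < truth.T:
        state = int(rng.integers(truth.k))
        while state == prev and truth.k > 1:
            state = int(rng.integers(truth.k))
        dwell = int(rng.integers(lo, hi + 1))
        labels[t : t + dwell] = state
        t += dwell
        prev = state
    return labels


def _motion_table(rng: np.random.Generator, T: int) -> np.ndarray:
    """24 regressors: 6 smooth rigid-body series, derivatives, squares of both."""
    base = np.cumsum(rng.normal(0.0, 0.02, (T, 6)), axis=0)
    deriv = np.vstack([np.zeros((1, 6)), np.diff(base, axis=0)])
    return np.column_stack([base, deriv, base**2, deriv**2])


def gen_fmri_subjects(
    truth: FMRITruth,
    n_subjects: int = 20,
    n_sites: int = 2,
    T: int | None = None,
) -> tuple[list[list[SubjectData]], FMRITruth]:
    """Simulate per-site subject lists for the functional pipeline.

    Each subject's r component time-courses are drawn segment-wise from the
    k covariance templates (dwell >= one window), mixed through the shared
    sparse spatial maps and degraded with white noise.  A smooth 24-column
    motion table and a framewise-displacement series with planted spikes
    (spike positions also perturb the time-courses) accompany each subject.
    Subjects are dealt round-robin across sites.
    """
    if T is not None:
        truth.T = int(T)
    if truth.r > truth.d:
        raise ValueError("need r <= d")
    if truth.dwell_range[0] < truth.window:
        raise ValueError("minimum dwell must be at least one window")
    rng = np.random.default_rng(truth.seed)
    truth.templates = _make_templates(rng, truth)
    truth.spatial_maps = _make_spatial_maps(rng, truth)
    chol = [np.linalg.cholesky(c) for c in truth.templates]

    sites: list[list[SubjectData]] = [[] for _ in range(n_sites)]
    for i in range(n_subjects):
        sid = f"sub{i:03d}"
        states = _state_sequence(rng, truth)
        tc = np.empty((truth.T, truth.r))
        for state in range(truth.k):
            idx = np.flatnonzero(states == state)
            tc[idx] = rng.normal(0.0, 1.0, (len(idx), truth.r)) @ chol[state].T
        tc += rng.normal(0.0, truth.tc_noise_sd, tc.shape)

        motion = _motion_table(rng, truth.T)
        mu, sd = truth.fd_baseline
        fd = np.abs(rng.normal(mu, sd, truth.T))
        n_spikes = rng.binomial(truth.T, truth.spike_rate)
        spikes = np.sort(rng.choice(np.arange(3, truth.T - 3), size=n_spikes, replace=False))
        fd[spikes] += truth.spike_magnitude
        tc[spikes] += rng.normal(0.0, 3.0, (len(spikes), truth.r))

        data = truth.spatial_maps @ tc.T + rng.normal(0.0, truth.noise_sd, (truth.d, truth.T))
        site = i % n_sites
        sites[site].append(SubjectData(data=data, subject_id=sid, site_id=f"site{site}"))
        truth.subject_states[sid] = states
        truth.subject_timecourses[sid] = tc
        truth.subject_fd[sid] = fd
        truth.subject_motion[sid] = motion
        truth.subject_spikes[sid] = spikes
    return sites, truth
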