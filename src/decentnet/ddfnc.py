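"""Decentralized dynamic functional network connectivity (dFNC).

The pipeline turns per-subject component time-courses into recurring
connectivity "states" without pooling any subject's windows:

1. post-processing — drop the first scans, regress out 24 motion
   parameters, and replace motion spikes (framewise displacement above
   mean + 2.5 sd) by cubic-spline interpolants;
2. sliding-window covariance — stride-1 boxcar windows of length w, each
   summarized by the strict upper triangle of its r x r sample covariance;
3. exemplar selection — windows at local maxima of the across-pair
   connectivity-variance series seed the clustering;
4. two-stage decentralized K-Means — many random-start runs on the
   exemplars, the best by silhouette initializing a final run over all
   windows.  Each iteration sites upload local per-cluster means and
   counts; the aggregator merges them by count-weighted averaging and
   rebroadcasts, which reproduces pooled Lloyd updates exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from .core_network import AGGREGATOR, MessageLog

__all__ = [
    "CleanTimecourse",
    "WindowedFNC",
    "ClusterModel",
    "DFNCConfig",
    "DFNCResult",
    "detect_spikes",
    "despike",
    "clean_timecourse",
    "sliding_windows",
    "select_exemplars",
    "correlation_distance",
    "dkmeans",
    "run_ddfnc",
]


@dataclass
class CleanTimecourse:
    """Component time-courses with their motion bookkeeping.

    values: timepoints x r component time-courses
    fd:     framewise displacement, one non-negative value per timepoint
    motion: timepoints x 24 motion regressors (6 rigid-body estimates,
            their derivatives, and squares of both)
    """

    values: np.ndarray
    fd: np.ndarray | None = None
    motion: np.ndarray | None = None
    subject_id: str = ""
    site_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (timepoints x components)")
        if self.fd is not None:
            self.fd = np.asarray(self.fd, dtype=float)
            if self.fd.shape != (self.values.shape[0],):
                raise ValueError("fd length must match the number of timepoints")
            if np.any(self.fd < 0):
                raise ValueError("framewise displacement must be non-negative")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape[0] != self.values.shape[0]:
                raise ValueError("motion table length must match the timecourse")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


@dataclass
class WindowedFNC:
    """Sliding-window covariance stack for one subject."""

    windows: np.ndarray  # n_windows x r x r symmetric matrices
    vectorized: np.ndarray  # n_windows x r(r-1)/2 upper-triangle features
    window_length: int

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


@dataclass
class ClusterModel:
    centroids: np.ndarray  # k x features
    k: int
    assignments: np.ndarray  # labels for the rows the model was fit on
    distance: str = "correlation"
    counts: np.ndarray | None = None
    iterations: int = 0


@dataclass
class DFNCConfig:
    """Study parameters for the clustering pipeline.

    Defaults follow the full-scale protocol: window length 22 scans, k = 5
    states, 200 random initializations for the exemplar stage.  Desk-scale
    tests shrink ``n_init`` and ``k`` through this config, never by editing
    the pipeline.
    """

    window: int = 22
    k: int = 5
    n_init: int = 200
    seed: int = 0
    distance: str = "correlation"
    drop_initial: int = 2
    max_iterations: int = 1000


@dataclass
class DFNCResult:
    model: ClusterModel
    labels: dict  # subject_id -> per-window state labels
    exemplar_counts: list[int] = field(default_factory=list)
    stage1_iterations: int = 0
    best_init: int = -1
    silhouette: float = float("nan")


def detect_spikes(fd: np.ndarray) -> np.ndarray:
    """Indices where framewise displacement exceeds mean(FD) + 2.5 sd(FD).

    The threshold is strict, so a constant series (sd = 0) flags nothing.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.ndim != 1 or fd.size < 3:
        raise ValueError("fd must be a 1-D series of length >= 3")
    return np.flatnonzero(fd > fd.mean() + 2.5 * fd.std())


def despike(tc: CleanTimecourse, spikes: np.ndarray) -> CleanTimecourse:
    """Replace spiked timepoints by cubic-spline fits through good neighbors.

    Each component is interpolated independently with a natural cubic
    spline over the non-spike timepoints (exact on cubic polynomials);
    non-spike values are untouched.  Spikes at the series edges are
    extrapolated from the spline.
    """
    spikes = np.asarray(spikes, dtype=int)
    if spikes.size == 0:
        return tc
    t = np.arange(tc.n_timepoints)
    good = np.setdiff1d(t, spikes)
    if good.size < 4:
        raise ValueError("need at least 4 good timepoints per component to despike")
    values = tc.values.copy()
    spline = CubicSpline(good, values[good], axis=0)
    values[spikes] = spline(spikes)
    return CleanTimecourse(values, tc.fd, tc.motion, tc.subject_id, tc.site_id)


def clean_timecourse(tc: CleanTimecourse, drop_initial: int = 2) -> CleanTimecourse:
    """Full post-ICA cleaning: drop initial scans, remove motion, despike.

    The first ``drop_initial`` timepoints are discarded, the 24 motion
    regressors (plus an intercept) are projected out by least squares, and
    framewise-displacement spikes are spline-interpolated.
    """
    if tc.motion is None or tc.fd is None:
        raise ValueError("clean_timecourse needs both a motion table and an fd series")
    T = tc.n_timepoints
    if T <= drop_initial + 24:
        raise ValueError("timecourse too short to clean")
    values = tc.values[drop_initial:]
    motion = tc.motion[drop_initial:]
    fd = tc.fd[drop_initial:]
    design = np.column_stack([motion, np.ones(len(motion))])
    beta = np.linalg.lstsq(design, values, rcond=None)[0]
    resid = values - design @ beta
    cleaned = CleanTimecourse(resid, fd, motion, tc.subject_id, tc.site_id)
    return despike(cleaned, detect_spikes(fd))


def sliding_windows(tc: CleanTimecourse, w: int) -> WindowedFNC:
    """Stride-1 boxcar windows; T - w windows of length w per subject.

    Each window contributes the sample covariance of its w timepoints;
    features are the strict upper triangle (the constant diagonal carries
    no information under correlation distance).
    """
    T, r = tc.values.shape
    if T <= w:
        raise ValueError(f"need more than w={w} timepoints, got {T}")
    n_win = T - w
    iu = np.triu_indices(r, k=1)
    windows = np.empty((n_win, r, r))
    for i in range(n_win):
        windows[i] = np.cov(tc.values[i : i + w].T, ddof=1)
    vectorized = windows[:, iu[0], iu[1]]
    return WindowedFNC(windows=windows, vectorized=vectorized, window_length=w)


def select_exemplars(fnc: WindowedFNC) -> np.ndarray:
    """Window indices at local maxima of the connectivity-variance series.

    Per window the variance of the dynamic connectivity across all
    component pairs is computed; strict interior local maxima are the
    exemplars.  When no interior maximum exists (monotone or constant
    series) the single global-maximum window is returned.
    """
    if fnc.n_windows < 3:
        raise ValueError("need at least 3 windows to select exemplars")
    var_series = fnc.vectorized.var(axis=1)
    interior = np.flatnonzero(
        (var_series[1:-1] > var_series[:-2]) & (var_series[1:-1] > var_series[2:])
    )
    if interior.size == 0:
        return np.array([int(np.argmax(var_series))])
    return interior + 1


def correlation_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Pearson correlation between two feature vectors; range [0, 2]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation distance undefined for constant vectors")
    return 1.0 - float(np.corrcoef(a, b)[0, 1])


def _distances(x: np.ndarray, c: np.ndarray, metric: str) -> np.ndarray:
    return cdist(x, c, metric="correlation" if metric == "correlation" else "euclidean")


def dkmeans(
    sites: Sequence[np.ndarray],
    k: int,
    init_centroids: np.ndarray,
    distance: str = "correlation",
    log: MessageLog | None = None,
    max_iterations: int = 1000,
    site_ids: Sequence[str] | None = None,
) -> ClusterModel:
    """Decentralized K-Means by count-weighted centroid averaging.

    Per iteration every site assigns its rows to the nearest centroid,
    computes local per-cluster sums and counts, and uploads its k local
    centroids; the aggregator merges them weighted by counts (recovering
    the pooled mean exactly) and rebroadcasts.  Iteration stops when the
    global assignment is unchanged for a full round.  A cluster that ends
    a round empty is reseeded from the globally farthest point (one extra
    logged broadcast).
    """
    mats = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sites]
    if any(m.shape[0] < 1 for m in mats):
        raise ValueError("every site must hold at least one row")
    n_total = sum(m.shape[0] for m in mats)
    if k > n_total:
        raise ValueError(f"k={k} exceeds the total number of rows ({n_total})")
    f = mats[0].shape[1]
    centroids = np.array(init_centroids, dtype=float, copy=True)
    if centroids.shape != (k, f):
        raise ValueError(f"init_centroids must have shape {(k, f)}")
    ids = list(site_ids) if site_ids is not None else [f"site{i}" for i in range(len(mats))]

    prev_labels: list[np.ndarray] | None = None
    it = 0
    rnd0 = log.next_round if log is not None else 0
    for it in range(1, max_iterations + 1):
        labels = [np.argmin(_distances(m, centroids, distance), axis=1) for m in mats]
        sums = np.zeros((k, f))
        counts = np.zeros(k, dtype=int)
        for m, lab, sid in zip(mats, labels, ids):
            for c in range(k):
                mask = lab == c
                counts[c] += int(mask.sum())
                if mask.any():
                    sums[c] += m[mask].sum(axis=0)
            if log is not None:
                log.send(rnd0 + it - 1, sid, AGGREGATOR, k * f)
        empty = counts == 0
        new_centroids = np.where(
            empty[:, None], centroids, sums / np.maximum(counts, 1)[:, None]
        )
        for c in np.flatnonzero(empty):
            # reseed from the globally farthest point from its own centroid
            best_d, best_row = -np.inf, None
            for m, lab in zip(mats, labels):
                d = _distances(m, new_centroids, distance)[np.arange(len(lab)), lab]
                j = int(np.argmax(d))
                if d[j] > best_d:
                    best_d, best_row = d[j], m[j]
            new_centroids[c] = best_row
            if log is not None:
                log.send(rnd0 + it - 1, AGGREGATOR, "all", f)
        if log is not None:
            for sid in ids:
                log.send(rnd0 + it - 1, AGGREGATOR, sid, k * f)
        converged = prev_labels is not None and all(
            np.array_equal(a, b) for a, b in zip(labels, prev_labels)
        )
        centroids = new_centroids
        if converged:
            break
        prev_labels = labels

    all_labels = np.concatenate(
        [np.argmin(_distances(m, centroids, distance), axis=1) for m in mats]
    )
    counts = np.bincount(all_labels, minlength=k)
    return ClusterModel(
        centroids=centroids,
        k=k,
        assignments=all_labels,
        distance=distance,
        counts=counts,
        iterations=it,
    )


def _prepare_windows(
    sites: Sequence[Sequence[CleanTimecourse]],
    cfg: DFNCConfig,
    clean: bool,
) -> tuple[list[np.ndarray], list[np.ndarray], list[list[str]], list[list[int]]]:
    """Per-site window stacks, exemplar stacks, subject ids, window counts."""
    win_stacks, ex_stacks, sid_lists, win_counts = [], [], [], []
    for subjects in sites:
        wins, exs, sids, counts = [], [], [], []
        for tc in subjects:
            cleaned = clean_timecourse(tc, cfg.drop_initial) if clean else tc
            fnc = sliding_windows(cleaned, cfg.window)
            wins.append(fnc.vectorized)
            exs.append(fnc.vectorized[select_exemplars(fnc)])
            sids.append(tc.subject_id)
            counts.append(fnc.n_windows)
        win_stacks.append(np.vstack(wins))
        ex_stacks.append(np.vstack(exs))
        sid_lists.append(sids)
        win_counts.append(counts)
    return win_stacks, ex_stacks, sid_lists, win_counts


def run_ddfnc(
    sites: Sequence[Sequence[CleanTimecourse]],
    cfg: DFNCConfig | None = None,
    log: MessageLog | None = None,
    clean: bool = True,
) -> DFNCResult:
    """Two-stage decentralized clustering of all subjects' dFNC windows.

    Stage 1 runs ``cfg.n_init`` decentralized K-Means fits on the exemplar
    windows, each initialized with k windows drawn uniformly at random from
    the decentralized data (one child seed per run), and keeps the run with
    the highest silhouette score on the exemplars.  Stage 2 re-runs
    decentralized K-Means over *all* windows starting from those centroids.
    Returns the final model plus per-subject state labels.
    """
    cfg = cfg or DFNCConfig()
    win_stacks, ex_stacks, sid_lists, win_counts = _prepare_windows(sites, cfg, clean)
    ex_all = np.vstack(ex_stacks)
    n_ex = ex_all.shape[0]
    if cfg.k > n_ex:
        raise ValueError(f"k={cfg.k} exceeds the number of exemplar windows ({n_ex})")

    master = np.random.SeedSequence(cfg.seed)
    best: tuple[float, int, ClusterModel] | None = None
    for run, child in enumerate(master.spawn(cfg.n_init)):
        rng = np.random.default_rng(child)
        idx = rng.choice(n_ex, size=cfg.k, replace=False)
        model = dkmeans(
            ex_stacks,
            cfg.k,
            ex_all[idx],
            distance=cfg.distance,
            max_iterations=cfg.max_iterations,
        )
        if len(np.unique(model.assignments)) < 2:
            continue
        score = silhouette_score(ex_all, model.assignments, metric=cfg.distance)
        if best is None or score > best[0]:
            best = (score, run, model)
    if best is None:
        raise RuntimeError("no exemplar clustering produced more than one cluster")
    sil, best_run, stage1 = best

    model = dkmeans(
        win_stacks,
        cfg.k,
        stage1.centroids,
        distance=cfg.distance,
        log=log,
        max_iterations=cfg.max_iterations,
        site_ids=[f"site{i}" for i in range(len(sites))],
    )

    labels: dict = {}
    offset = 0
    for sids, counts in zip(sid_lists, win_counts):
        for sid, n_win in zip(sids, counts):
            labels[sid] = model.assignments[offset : offset + n_win]
            offset += n_win
    return DFNCResult(
        model=model,
        labels=labels,
        exemplar_counts=[e.shape[0] for e in ex_stacks],
        stage1_iterations=stage1.iterations,
        best_init=best_run,
        silhouette=float(sil),
    )
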