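"""Voxel-based morphometry over simulated multi-site data.

Mass-univariate analysis: at every voxel inside a brain mask, gray-matter
concentration is regressed on subject covariates (age, diagnosis, gender,
plus site indicators), using any of the decentralized estimators or the
pooled reference path.  Because all voxels of one site share a single design
matrix, the estimators vectorize over voxels — the Gram matrix is computed
once per site and reused for every voxel.

Outputs are :class:`StatMaps`: per-covariate t, p and signed -log10(p)
grids plus per-voxel SSE and R^2 grids, mappable back onto the 3-D volume
via the mask (unmasked or degenerate voxels carry NaN).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .core_network import MessageLog, SiteDataset
from .regression import (
    OptimizerConfig,
    RegressionResult,
    drne_fit,
    multi_shot_fit,
    single_shot_fit,
)
from .synthetic_data import site_design

__all__ = [
    "VoxelMatrix",
    "StatMaps",
    "load_volumes",
    "signed_log_p",
    "run_voxelwise",
    "method_comparison_table",
    "read_covariates",
]

METHODS = ("pooled", "single_shot", "drne", "multi_shot")


@dataclass
class VoxelMatrix:
    """Subjects x masked-voxels matrix tied back to its 3-D grid."""

    values: np.ndarray  # (subjects, n_masked)
    mask: np.ndarray  # 3-D boolean grid
    affine: np.ndarray  # 4 x 4

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x masked voxels)")
        if self.values.shape[1] != int(self.mask.sum()):
            raise ValueError(
                f"values has {self.values.shape[1]} columns but the mask has "
                f"{int(self.mask.sum())} true voxels"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def voxel_index(self) -> tuple[np.ndarray, ...]:
        """Grid coordinates of each masked column, in column order."""
        return np.nonzero(self.mask)

    def unflatten(self, row: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-voxel vector back onto the 3-D grid."""
        row = np.asarray(row, dtype=float)
        if row.shape != (self.n_voxels,):
            raise ValueError(f"expected a length-{self.n_voxels} vector")
        grid = np.full(self.mask.shape, fill)
        grid[self.mask] = row
        return grid


def load_volumes(paths: Sequence, mask_path) -> VoxelMatrix:
    """Read 3-D volumes and flatten them to the masked voxels.

    All volumes must share the mask's grid shape and affine; rows follow
    the input order.
    """
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    if not mask.any():
        raise ValueError("mask is empty")
    rows = []
    for p in paths:
        img = nib.load(str(p))
        if img.shape != mask.shape:
            raise ValueError(f"{p}: shape {img.shape} does not match mask {mask.shape}")
        if not np.allclose(img.affine, mask_img.affine, atol=1e-6):
            raise ValueError(f"{p}: affine does not match the mask's affine")
        rows.append(np.asarray(img.dataobj, dtype=float)[mask])
    return VoxelMatrix(np.vstack(rows), mask, mask_img.affine)


def signed_log_p(t, p):
    """-log10(p) carrying the sign of t; sign(0) = 0.  Requires p in (0, 1]."""
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    valid = np.isnan(p) | ((p > 0) & (p <= 1))
    if not np.all(valid):
        raise ValueError("p-values must lie in (0, 1]")
    with np.errstate(divide="ignore"):
        out = -np.log10(p) * np.sign(t)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class StatMaps:
    """Per-covariate significance grids plus per-voxel fit-quality grids."""

    covariates: list[str]
    t: dict  # name -> 3-D grid
    p: dict
    signed_log_p_maps: dict
    sse: np.ndarray  # 3-D grid
    r_squared: np.ndarray  # 3-D grid
    mask: np.ndarray
    affine: np.ndarray
    result: RegressionResult | None = None

    def masked(self, statistic: str, covariate: str | None = None) -> np.ndarray:
        """Per-voxel vector of a statistic over the masked voxels."""
        if statistic in ("sse", "r_squared"):
            grid = getattr(self, statistic)
        else:
            grid = {"t": self.t, "p": self.p, "signed_log_p": self.signed_log_p_maps}[
                statistic
            ][covariate]
        return grid[self.mask]

    def to_nifti(self, outdir) -> list[Path]:
        """Write every grid as a NIfTI-1 volume in the input affine."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        grids: list[tuple[str, np.ndarray]] = [("sse", self.sse), ("r_squared", self.r_squared)]
        for name in self.covariates:
            grids += [
                (f"t_{name}", self.t[name]),
                (f"p_{name}", self.p[name]),
                (f"signed_log_p_{name}", self.signed_log_p_maps[name]),
            ]
        for name, grid in grids:
            path = outdir / f"{name}.nii.gz"
            nib.save(nib.Nifti1Image(grid.astype(np.float32), self.affine), str(path))
            written.append(path)
        return written


def read_covariates(path) -> pd.DataFrame:
    """Read a covariate CSV with columns id, age, diagnosis, gender, site."""
    table = pd.read_csv(path)
    missing = {"id", "age", "diagnosis", "gender", "site"} - set(table.columns)
    if missing:
        raise ValueError(f"covariate file {path} lacks columns: {sorted(missing)}")
    return table


def _pooled_fit(sites: Sequence[SiteDataset]) -> RegressionResult:
    """Reference path: concatenate all rows and solve pooled least squares."""
    design = np.vstack([s.design for s in sites])
    response = np.vstack([s.response_2d for s in sites])
    pooled = SiteDataset("pooled", design, response)
    return drne_fit([pooled])  # one site == pooled normal equations


def run_voxelwise(
    site_volumes: Sequence[tuple[VoxelMatrix, pd.DataFrame]],
    method: str = "drne",
    cfg: OptimizerConfig | None = None,
    covariate_names: Sequence[str] = ("age", "diagnosis", "gender"),
    log: MessageLog | None = None,
) -> StatMaps:
    """Fit every masked voxel with the chosen estimator and build maps.

    ``site_volumes`` pairs each site's voxel matrix with its covariate
    table (rows aligned).  Site indicator columns (reference = first site)
    are appended for the pooled/DRNE/multi-shot designs and omitted for
    single-shot, where they would be locally constant.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    ref = site_volumes[0][0]
    for vm, table in site_volumes:
        if vm.mask.shape != ref.mask.shape or not np.array_equal(vm.mask, ref.mask):
            raise ValueError("all sites must share one mask")
        if len(table) != vm.n_subjects:
            raise ValueError("covariate rows must align with volume rows")

    site_labels = [str(table["site"].iloc[0]) for _, table in site_volumes]
    with_dummies = method != "single_shot"
    sites = [
        SiteDataset(
            label,
            site_design(table, site_labels, include_site_dummies=with_dummies),
            vm.values,
        )
        for label, (vm, table) in zip(site_labels, site_volumes)
    ]

    if method == "pooled":
        result = _pooled_fit(sites)
    elif method == "drne":
        result = drne_fit(sites, log=log)
    elif method == "multi_shot":
        result = multi_shot_fit(sites, cfg, log=log)
    else:
        result = single_shot_fit(sites, log=log)

    names = list(covariate_names)
    if with_dummies:
        names = names + [f"site_{lab}" for lab in site_labels[1:]]
    names = names + ["intercept"]

    t_maps, p_maps, slp_maps = {}, {}, {}
    for i, name in enumerate(names):
        t_i = result.t_values[i]
        p_i = result.p_values[i]
        t_maps[name] = ref.unflatten(t_i)
        p_maps[name] = ref.unflatten(p_i)
        slp_maps[name] = ref.unflatten(signed_log_p(t_i, p_i))
    return StatMaps(
        covariates=names,
        t=t_maps,
        p=p_maps,
        signed_log_p_maps=slp_maps,
        sse=ref.unflatten(np.asarray(result.sse)),
        r_squared=ref.unflatten(np.asarray(result.r_squared)),
        mask=ref.mask,
        affine=ref.affine,
        result=result,
    )


def method_comparison_table(
    maps: Mapping[str, StatMaps],
    statistic: str = "sse",
) -> pd.DataFrame:
    """Pearson correlations of a per-voxel statistic across methods.

    Mirrors the standard cross-method summary: a symmetric matrix with unit
    diagonal whose (i, j) entry correlates the statistic vectors of methods
    i and j over the masked voxels.
    """
    names = list(maps)
    if not names:
        raise ValueError("need at least one method")
    ref_mask = maps[names[0]].mask
    vectors = {}
    for name in names:
        if not np.array_equal(maps[name].mask, ref_mask):
            raise ValueError("all StatMaps must share a mask")
        vec = maps[name].masked(statistic)
        vec = vec[np.isfinite(vec)]
        if vec.size < 2:
            raise ValueError("need at least 2 finite voxels")
        if np.std(vec) == 0:
            raise ValueError(f"statistic {statistic!r} is constant for {name!r}")
        vectors[name] = vec
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in combinations(names, 2):
        rho = float(np.corrcoef(vectors[a], vectors[b])[0, 1])
        out.loc[a, b] = out.loc[b, a] = rho
    return out
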