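"""First-level OLS estimation and second-level inference.

First level: per-voxel ordinary least squares on the full design
(task + modulated + drift + nuisance), with t statistics for the
modulated columns.  Prewhitening is deliberately omitted; the
inferences of interest are spatial patterns, and recovery is assessed
against planted truth.

Second level: voxel-wise one-sample t tests on first-level contrast
maps across subjects, with Cohen's d (mean / between-subject SD) and a
natural-log Bayes factor from the BIC approximation
``logBF = (n/2) ln(1 + t^2 / (n-1)) - (1/2) ln n``.  Statistical maps
are thresholded jointly on d and logBF.  A one-way within-subject
ANOVA over per-condition maps and a minimum-statistic ("conjunction
null") AND-conjunction complete the group toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.linalg import solve_triangular

from .design import BoldDataset, DesignMatrix
from .stats import rm_anova_f_map

#: group-map joint thresholds: minimum effect size and minimum evidence
D_THRESHOLDS = (0.2, 0.5)
LOGBF_MIN = 3.0

_D_CAP = 1e6  # replaces an infinite d at zero between-subject variance


@dataclass(frozen=True)
class FirstLevelResult:
    """Per-voxel OLS fit of one design on one subject's BOLD data."""

    columns: tuple[str, ...]
    betas: np.ndarray        # (n_columns, n_voxels)
    sigma2: np.ndarray       # residual variance per voxel
    dof: int
    xtx_inv_diag: np.ndarray
    grid_shape: tuple
    modulated_columns: tuple[str, ...]

    def beta_map(self, column: str) -> np.ndarray:
        return self.betas[self.columns.index(column)].reshape(self.grid_shape)

    def contrast(self, column: str, sign: int = +1) -> np.ndarray:
        """Contrast map for [+1] or [-1] on the named column."""
        return sign * self.beta_map(column)

    def t_map(self, column: str) -> np.ndarray:
        i = self.columns.index(column)
        se = np.sqrt(self.sigma2 * self.xtx_inv_diag[i])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.betas[i] / se
        return t.reshape(self.grid_shape)


def fit_first_level(bold: BoldDataset, design: DesignMatrix) -> FirstLevelResult:
    """OLS fit of the design to every voxel's kept time series."""
    design.check_full_rank()
    zero_cols = [c for c in design.matrix.columns
                 if np.allclose(design.matrix[c], 0.0)]
    if zero_cols:
        raise ValueError(f"cannot fit a design with all-zero columns: {zero_cols}")
    X = design.values
    Y = bold.kept().reshape(-1, bold.n_volumes - bold.discard).T  # time x voxel
    if len(X) != len(Y):
        raise ValueError(f"design has {len(X)} frames but data has {len(Y)} kept volumes")
    n, p = X.shape
    # QR solve: better conditioned than inv(X'X) for mixed-scale columns
    q, r = np.linalg.qr(X)
    betas = solve_triangular(r, q.T @ Y)
    r_inv = solve_triangular(r, np.eye(p))
    xtx_inv = r_inv @ r_inv.T
    resid = Y - X @ betas
    dof = n - p
    sigma2 = np.sum(resid ** 2, axis=0) / dof
    return FirstLevelResult(
        columns=tuple(design.matrix.columns),
        betas=betas,
        sigma2=sigma2,
        dof=dof,
        xtx_inv_diag=np.diag(xtx_inv),
        grid_shape=bold.data.shape[:-1],
        modulated_columns=design.modulated_columns,
    )


def log_bf_onesample(t: np.ndarray, n: int) -> np.ndarray:
    """Natural-log BIC Bayes factor for a one-sample t statistic."""
    t = np.asarray(t, float)
    return 0.5 * (n * np.log1p(t ** 2 / (n - 1)) - np.log(n))


@dataclass(frozen=True)
class GroupResult:
    """Voxel-wise one-sample group statistics for one contrast."""

    mean: np.ndarray
    sd: np.ndarray
    t: np.ndarray
    d: np.ndarray
    logbf: np.ndarray
    n: int
    zero_variance: np.ndarray

    def threshold_mask(self, d_min: float, logbf_min: float = LOGBF_MIN) -> np.ndarray:
        """Joint effect-size / evidence mask for the positive direction."""
        return (self.d >= d_min) & (self.logbf >= logbf_min)


def second_level_onesample(maps: np.ndarray) -> GroupResult:
    """One-sample t, Cohen's d, and logBF maps across subjects.

    ``maps`` is (n_subjects, ...).  Voxels with zero between-subject
    variance get a capped d and are flagged.
    """
    maps = np.asarray(maps, float)
    n = maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} voxels have zero between-subject variance")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(zero_var, np.sign(mean) * _D_CAP, mean / sd)
        t = d * np.sqrt(n)
    t = np.clip(t, -_D_CAP, _D_CAP)
    logbf = log_bf_onesample(t, n)
    return GroupResult(mean=mean, sd=sd, t=t, d=d, logbf=logbf, n=n,
                       zero_variance=zero_var)


def condition_anova(maps: np.ndarray) -> np.ndarray:
    """Voxel-wise one-way within-subject ANOVA F map.

    ``maps`` is (n_subjects, k_conditions, ...); returns the F map over
    the trailing spatial axes.
    """
    maps = np.asarray(maps, float)
    n, k = maps.shape[:2]
    spatial = maps.shape[2:]
    F = rm_anova_f_map(maps.reshape(n, k, -1))
    return F.reshape(spatial)


def conjunction(t_maps: list[np.ndarray], threshold: float | None = None):
    """Minimum-statistic AND-conjunction over contrast t maps.

    Each voxel gets the minimum t across contrasts; with ``threshold``
    the supra-threshold mask (conjunction null: every contrast exceeds
    the single-map threshold) is returned as well.
    """
    if len(t_maps) < 1:
        raise ValueError("need at least one map")
    if len(t_maps) == 1:
        warnings.warn("conjunction of a single map is the map itself")
    stack = np.stack(t_maps)
    mn = stack.min(axis=0)
    if threshold is None:
        return mn
    return mn, mn > threshold


def mask_counts(mask: np.ndarray, labels: np.ndarray, label_names) -> dict:
    """Voxel counts of a threshold mask per label set (JSON-friendly)."""
    out = {"total": int(mask.sum())}
    for i, name in enumerate(label_names):
        sel = labels == i
        out[name] = {
            "n_voxels": int(sel.sum()),
            "n_detected": int((mask & sel).sum()),
        }
    return out
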