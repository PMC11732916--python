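"""Image-quality comparison layer: sumSUV, TBR/CNR, paired and rank tests.

The contrast metrics compare tumor-lesion VOIs against the liver
parenchyma background on each image type (late-frame sumSUV, the Patlak
influx maps, and VOI-level compartment parameters)::

    TBR_mean = mean(L) / mean(B)        TBR_max = max(L) / mean(B)
    CNR_mean = (mean(L) - mean(B)) / SD(B)
    CNR_max  = (max(L) - mean(B)) / SD(B)

All four are invariant under a positive rescaling of the whole image.
Paired image types are compared with the Wilcoxon matched-pairs
signed-rank test (zero differences dropped before ranking), influx
estimates across methods with Spearman rank correlation, and tumor
vs. normal-organ parameters with Welch's t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import DynamicImage, VoiSet
from .errors import ParameterError, WindowError

__all__ = [
    "sum_suv",
    "voi_values",
    "tbr_cnr",
    "LesionMetrics",
    "fold_change_summary",
    "wilcoxon_positive_ranks",
    "rank_correlation_matrix",
    "tumor_vs_normal_test",
]


def sum_suv(image: DynamicImage, window_minutes=(50.0, 60.0)) -> np.ndarray:
    """Mean SUV map over the frames fully inside ``window_minutes``.

    On the standard protocol with the default 50-60 min window this is
    the unweighted average of the last two 300-s frames — the static
    late-image surrogate.
    """
    lo, hi = (m * 60.0 for m in window_minutes)
    sched = image.schedule
    inside = (sched.starts >= lo - 1e-9) & (sched.ends <= hi + 1e-9)
    if not inside.any():
        raise WindowError(f"no frames fully inside {window_minutes} min")
    return image.voxels[..., inside].mean(axis=-1)


def voi_values(volume: np.ndarray, vois: VoiSet, label_or_name) -> np.ndarray:
    """Finite voxel values of one VOI in a 3-D map."""
    vals = volume[vois.mask(label_or_name)]
    return vals[np.isfinite(vals)]


@dataclass
class LesionMetrics:
    """Contrast metrics of one lesion on one image type.

    For VOI-level parameters (a single fitted value rather than a voxel
    distribution) only ``tbr_mean`` is defined; max- and SD-based
    entries are NaN.
    """

    tbr_mean: float
    tbr_max: float = np.nan
    cnr_mean: float = np.nan
    cnr_max: float = np.nan

    def as_dict(self) -> dict:
        return {
            "TBR_mean": self.tbr_mean, "TBR_max": self.tbr_max,
            "CNR_mean": self.cnr_mean, "CNR_max": self.cnr_max,
        }


def tbr_cnr(lesion_values, background_values) -> LesionMetrics:
    """Target-to-background and contrast-to-noise ratios for one lesion.

    ``lesion_values`` may be a scalar (VOI-level parameter): then only
    ``TBR_mean`` is defined.  The background SD is the voxel SD of the
    background VOI **in the same image type**.  Degenerate backgrounds
    (zero mean for TBR, zero SD for CNR) yield NaN with a warning.
    """
    lesion = np.atleast_1d(np.asarray(lesion_values, dtype=float))
    background = np.atleast_1d(np.asarray(background_values, dtype=float))
    if background.size == 0 or lesion.size == 0:
        raise ParameterError("lesion and background must be non-empty")
    b_mean = background.mean()
    scalar_lesion = lesion.size == 1
    if b_mean == 0:
        warnings.warn("background mean is 0: TBR undefined", stacklevel=2)
        return LesionMetrics(np.nan)
    tbr_mean = lesion.mean() / b_mean
    if scalar_lesion:
        return LesionMetrics(tbr_mean)
    b_sd = background.std(ddof=1)
    tbr_max = lesion.max() / b_mean
    if b_sd == 0:
        warnings.warn("background SD is 0: CNR undefined", stacklevel=2)
        return LesionMetrics(tbr_mean, tbr_max)
    cnr_mean = (lesion.mean() - b_mean) / b_sd
    cnr_max = (lesion.max() - b_mean) / b_sd
    return LesionMetrics(tbr_mean, tbr_max, cnr_mean, cnr_max)


def fold_change_summary(mean_tbr_by_method: dict, reference: str = "sumSUV") -> dict:
    """Ratio of each method's mean TBR_mean to the reference method's,
    rounded to one decimal for display."""
    if reference not in mean_tbr_by_method:
        raise ParameterError(f"reference method {reference!r} missing")
    ref = mean_tbr_by_method[reference]
    return {
        method: round(value / ref, 1)
        for method, value in mean_tbr_by_method.items()
        if method != reference
    }


def wilcoxon_positive_ranks(paired_a, paired_b):
    """Positive-difference count and signed-rank p-value for paired data.

    Returns ``(count of pairs with a > b, two-sided p)``.  Zero
    differences are dropped before ranking (the original signed-rank
    rule); the null is exact for n <= 25 without ties, otherwise the
    normal approximation with tie correction.  All-zero differences are
    degenerate: ``(0, 1.0)``.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 5:
        raise ParameterError("need equal-length paired samples with n >= 5")
    d = a - b
    n_pos = int((d > 0).sum())
    if np.all(d == 0):
        return 0, 1.0
    nz = d[d != 0]
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                         correction=False, method=method)
    return n_pos, float(res.pvalue)


def rank_correlation_matrix(values_by_method: pd.DataFrame, groups=None) -> dict:
    """Spearman rho matrices per tissue group.

    Parameters
    ----------
    values_by_method : DataFrame
        One row per region, one column per method (e.g. the influx
        estimate of each method).
    groups : Series or array, optional
        Group label per row (e.g. ``tissue_type``); the matrix is
        computed for ``"all"`` plus each distinct group with >= 3 rows.

    Returns
    -------
    dict of group name -> DataFrame (symmetric, unit diagonal).
    """
    frames = {"all": values_by_method}
    if groups is not None:
        groups = pd.Series(np.asarray(groups), index=values_by_method.index)
        for g in groups.unique():
            frames[str(g)] = values_by_method[groups == g]
    out = {}
    for name, frame in frames.items():
        if len(frame) < 3:
            continue
        cols = frame.columns
        mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
        for i, ci in enumerate(cols):
            for j in range(i + 1, len(cols)):
                cj = cols[j]
                xi, xj = frame[ci].to_numpy(), frame[cj].to_numpy()
                if np.unique(xi).size < 2 or np.unique(xj).size < 2:
                    warnings.warn(
                        f"constant vector in group {name!r}: rho undefined",
                        stacklevel=2,
                    )
                    rho = np.nan
                else:
                    rho = stats.spearmanr(xi, xj).statistic
                mat.loc[ci, cj] = mat.loc[cj, ci] = rho
        out[name] = mat
    return out


def tumor_vs_normal_test(tumor_values, normal_values, equal_var: bool = False):
    """Two-sample t-test of a kinetic parameter, tumor vs normal organs.

    Welch's unequal-variance form by default; set ``equal_var=True`` for
    the classic pooled-variance test.  Returns ``(t, p)``.
    """
    res = stats.ttest_ind(np.asarray(tumor_values, dtype=float),
                          np.asarray(normal_values, dtype=float),
                          equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
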