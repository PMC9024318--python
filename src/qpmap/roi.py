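"""Regional extraction, WMH mask logic, and cohort statistics.

ROI means are plain arithmetic means over labeled voxels (non-finite voxels
excluded with a logged count). WMH handling follows common volumetric
practice: binary masks are resampled with trilinear interpolation and
re-binarized at the 0.5 probability level, lesions below 100 mm^3 are
excluded, and normal-appearing white matter (NAWM) is white matter minus
WMH. Cohort statistics are the nonparametric two-group / paired / k-group
tests plus Pearson correlation and an ordinary least squares regression of a
regional outcome on age (per decade), sex and vascular-risk count, with
added-variable (partial-regression) data for plotting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

__all__ = [
    "resample_mask",
    "filter_wmh",
    "wmh_volume_mm3",
    "roi_mean",
    "roi_table",
    "nawm_mask",
    "group_compare",
    "correlate",
    "region_regression",
    "RegressionResult",
]


# ---------------------------------------------------------------------------
# masks and regions


def resample_mask(mask: np.ndarray, src_affine: np.ndarray,
                  dst_shape: tuple[int, ...], dst_affine: np.ndarray) -> np.ndarray:
    """Resample a binary mask onto a target grid.

    Trilinear interpolation of the 0/1 mask followed by thresholding at the
    0.5 probability level. On identical grids the input is returned
    unchanged; a non-overlapping field of view yields an empty mask with a
    warning.
    """
    mask = np.asarray(mask)
    src_affine = np.asarray(src_affine, dtype=float)
    dst_affine = np.asarray(dst_affine, dtype=float)
    if mask.shape == tuple(dst_shape) and np.allclose(src_affine, dst_affine):
        return mask.astype(bool)
    # voxel-to-voxel transform: src_vox = inv(src_affine) @ dst_affine @ dst_vox
    m = np.linalg.inv(src_affine) @ dst_affine
    out = ndimage.affine_transform(
        mask.astype(float), m[:3, :3], offset=m[:3, 3],
        output_shape=tuple(dst_shape), order=1, mode="constant", cval=0.0,
    )
    result = out > 0.5
    if not result.any() and mask.any():
        warnings.warn("resampled mask is empty: fields of view may not overlap",
                      stacklevel=2)
    return result


def wmh_volume_mm3(mask: np.ndarray, voxel_size) -> float:
    """Total mask volume in mm^3 (voxel count times voxel volume)."""
    vv = float(np.prod(np.asarray(voxel_size, dtype=float)))
    return float(np.count_nonzero(mask) * vv)


def filter_wmh(mask: np.ndarray, voxel_size, min_volume: float = 100.0) -> bool:
    """Inclusion flag: True when total WMH volume is >= ``min_volume`` mm^3."""
    return wmh_volume_mm3(mask, voxel_size) >= min_volume


def roi_mean(volume: np.ndarray, labels: np.ndarray, label_id: int) -> float:
    """Mean of ``volume`` over voxels carrying ``label_id``.

    Non-finite voxels are excluded (their count is logged); an absent or
    entirely non-finite label raises.
    """
    volume = np.asarray(volume, dtype=float)
    labels = np.asarray(labels)
    if volume.shape != labels.shape:
        raise ValueError(f"volume shape {volume.shape} != labels shape {labels.shape}")
    sel = labels == label_id
    if not sel.any():
        raise ValueError(f"label {label_id} absent from label volume")
    vals = volume[sel]
    finite = np.isfinite(vals)
    n_bad = int((~finite).sum())
    if n_bad:
        logger.info("roi_mean(label=%s): excluding %d non-finite voxels", label_id, n_bad)
    if not finite.any():
        raise ValueError(f"label {label_id} contains no finite voxels")
    return float(vals[finite].mean())


def roi_table(maps: dict[str, np.ndarray], labels: np.ndarray,
              names: dict[int, str], strict: bool = True) -> pd.DataFrame:
    """Tidy table of ROI means: one row per region, one column per map.

    With ``strict=False`` labels absent from the volume are skipped instead
    of raising (small grids can lose the smallest regions).
    """
    rows = []
    present = set(np.unique(labels).tolist())
    for label_id, name in sorted(names.items()):
        if not strict and label_id not in present:
            continue
        row = {"label": label_id, "region": name}
        for key, vol in maps.items():
            row[key] = roi_mean(vol, labels, label_id)
        rows.append(row)
    return pd.DataFrame(rows)


def nawm_mask(wm_mask: np.ndarray, wmh_mask: np.ndarray) -> np.ndarray:
    """Normal-appearing white matter: white matter excluding WMH."""
    wm = np.asarray(wm_mask, dtype=bool)
    wmh = np.asarray(wmh_mask, dtype=bool)
    if wm.shape != wmh.shape:
        raise ValueError("white-matter and WMH masks must share a grid")
    return wm & ~wmh


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class CompareResult:
    test: str
    statistic: float
    p: float
    posthoc: pd.DataFrame | None = None


def _dunn_posthoc(groups, alpha_adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-sum z tests after Kruskal-Wallis, Bonferroni-adjusted."""
    k = len(groups)
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array([ranks[offsets[i]:offsets[i + 1]].mean() for i in range(k)])
    n_comp = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1 / sizes[i] + 1 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            p_adj = min(1.0, p * n_comp)
            rows.append({"group_a": i, "group_b": j, "z": z, "p": p, "p_adj": p_adj})
    return pd.DataFrame(rows)


def group_compare(values_a, values_b=None, *, groups=None,
                  test: str = "mann_whitney",
                  zero_method: str = "wilcox") -> CompareResult:
    """Nonparametric group comparison, two-sided.

    ``wilcoxon_signed_rank`` compares paired samples (exact null enumeration
    for n <= 12 without ties, zero differences dropped by default);
    ``mann_whitney`` compares two independent samples; ``kruskal_wallis_dunn``
    takes ``groups`` (list of samples) and attaches a Bonferroni-adjusted
    Dunn post-hoc table.
    """
    if test == "kruskal_wallis_dunn":
        if groups is None or len(groups) < 2:
            raise ValueError("kruskal_wallis_dunn requires groups=[...] with >= 2 samples")
        stat, p = stats.kruskal(*groups)
        return CompareResult(test=test, statistic=float(stat), p=float(p),
                             posthoc=_dunn_posthoc(groups))
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "wilcoxon_signed_rank":
        if a.shape != b.shape:
            raise ValueError("paired test requires equal-length samples")
        diff = a - b
        if zero_method == "wilcox":
            diff = diff[diff != 0]
        if diff.size == 0:
            return CompareResult(test=test, statistic=0.0, p=1.0)
        method = "exact" if diff.size <= 12 else "auto"
        res = stats.wilcoxon(diff, method=method, zero_method=zero_method,
                             alternative="two-sided")
        return CompareResult(test=test, statistic=float(res.statistic), p=float(res.pvalue))
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact" if min(a.size, b.size) <= 12 else "auto")
        return CompareResult(test=test, statistic=float(res.statistic), p=float(res.pvalue))
    raise ValueError(f"unknown test {test!r}")


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("Pearson correlation needs paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# cohort regression


@dataclass
class RegressionResult:
    """OLS fit of outcome ~ age/decade + sex + risk count.

    ``table`` holds term, estimate, se, p and the 95% CI; ``added_variable``
    holds the partial-regression data for age (residualized outcome vs
    residualized age/decade), whose slope equals the multiple-regression age
    coefficient exactly.
    """

    outcome: str
    table: pd.DataFrame
    added_variable: pd.DataFrame
    model: object


def region_regression(cohort: pd.DataFrame, outcome: str) -> RegressionResult:
    """Multiple linear regression of a regional metric on age, sex and risk.

    Age enters per decade (age/10) so the age coefficient reads
    "units per decade". Requires complete predictors and n > 4.
    """
    needed = ["age", "sex", "risk_count", outcome]
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns: {missing}")
    df = cohort[needed]
    if df.isna().any().any():
        raise ValueError("missing values in predictors or outcome")
    if len(df) <= 4:
        raise ValueError("regression needs more than 4 subjects")
    X = pd.DataFrame({
        "age_decade": df["age"] / 10.0,
        "sex": df["sex"].astype(float),
        "risk_count": df["risk_count"].astype(float),
    })
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(df[outcome].to_numpy(), Xc).fit()
    ci = fit.conf_int()
    table = pd.DataFrame({
        "term": Xc.columns,
        "estimate": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "p": fit.pvalues.to_numpy(),
        "ci_low": ci[0].to_numpy(),
        "ci_high": ci[1].to_numpy(),
    })
    # Frisch-Waugh partialling for the added-variable plot
    Z = sm.add_constant(X[["sex", "risk_count"]])
    ry = sm.OLS(df[outcome].to_numpy(), Z).fit().resid
    rx = sm.OLS(X["age_decade"].to_numpy(), Z).fit().resid
    av = pd.DataFrame({"age_decade_resid": rx, "outcome_resid": ry})
    return RegressionResult(outcome=outcome, table=table, added_variable=av, model=fit)
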