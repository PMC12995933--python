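"""Frame-correlation decay analysis of cortical actin dynamics.

For each ROI, the Pearson correlation r between every pair of frames is
computed; the mean r per time lag (the mean of each superdiagonal of the
T x T correlation matrix) gives a correlation decay trace.  Faster decay
means a more dynamic cytoskeleton.  To compare ROIs with different baseline
correlations, each trace is Fisher z-transformed and normalized by its z
value at the smallest lag.  Two groups of ROIs are compared per lag with
two-tailed Welch t tests on the normalized z values, with Benjamini-Hochberg
correction across the lag family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ImageStack, RoiSet

logger = logging.getLogger(__name__)

#: correlations are clamped to +/- (1 - _R_CLAMP) before atanh
_R_CLAMP = 1e-7


@dataclass
class CorrelationTrace:
    """Mean Pearson r per time lag for one ROI.

    Lag 0 (trivially r = 1) is excluded; ``lags_s[k-1] = k * frame_interval_s``
    and ``n_pairs[k-1] = T - k`` frame pairs contribute to ``r_mean[k-1]``.
    """

    roi_id: int
    lags_s: np.ndarray
    r_mean: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.r_mean = np.asarray(self.r_mean, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (len(self.lags_s) == len(self.r_mean) == len(self.n_pairs)):
            raise ValueError("lags_s, r_mean and n_pairs must have equal length")


@dataclass
class NormalizedTrace:
    """Fisher-z trace normalized to its value at the smallest lag."""

    roi_id: int
    lags_s: np.ndarray
    z_norm: np.ndarray
    group_label: str = ""


def correlation_matrix(stack: ImageStack, roi: tuple[int, int, int]) -> np.ndarray:
    """T x T matrix of pairwise Pearson correlations within one ROI.

    Entry (i, j) is the Pearson r between the ROI's pixel vectors of frames
    i and j.  A frame whose ROI pixels have zero variance makes r undefined
    and raises, naming the offending frame.
    """
    r0, c0, side = roi
    t, h, w = stack.shape
    if r0 < 0 or c0 < 0 or r0 + side > h or c0 + side > w:
        raise ValueError(f"ROI {roi} does not lie inside the {h}x{w} image")
    pixels = stack.frames[:, r0 : r0 + side, c0 : c0 + side].reshape(t, -1)
    sd = pixels.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"zero pixel variance in ROI {roi} at frame {int(bad[0])}"
        )
    mat = np.corrcoef(pixels)
    np.fill_diagonal(mat, 1.0)
    return mat


def trace_from_matrix(
    matrix: np.ndarray, frame_interval_s: float, roi_id: int = 0
) -> CorrelationTrace:
    """Average each superdiagonal of a correlation matrix into a lag trace."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"correlation matrix must be square, got {matrix.shape}")
    t = matrix.shape[0]
    if t < 2:
        raise ValueError("need at least 2 frames for a lag trace")
    lags = np.arange(1, t)
    r_mean = np.array([np.diagonal(matrix, k).mean() for k in lags])
    return CorrelationTrace(
        roi_id=roi_id,
        lags_s=lags * frame_interval_s,
        r_mean=r_mean,
        n_pairs=t - lags,
    )


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z transform, atanh(r), clamping |r| to 1 - 1e-7 first."""
    r = np.asarray(r, dtype=float)
    n_clamped = int(np.sum(np.abs(r) > 1 - _R_CLAMP))
    if n_clamped:
        logger.warning("fisher_z: clamped %d correlation(s) to |r| = 1 - 1e-7", n_clamped)
    clamped = np.clip(r, -(1 - _R_CLAMP), 1 - _R_CLAMP)
    z = np.arctanh(clamped)
    return z if z.ndim else float(z)


def fisher_z_inverse(z: np.ndarray | float) -> np.ndarray | float:
    """Back-transform Fisher z to the r scale, tanh(z)."""
    r = np.tanh(np.asarray(z, dtype=float))
    return r if r.ndim else float(r)


def normalize_trace(
    trace: CorrelationTrace, group_label: str = ""
) -> NormalizedTrace:
    """Normalize a trace by its Fisher-z value at the smallest lag.

    ``z_norm(k) = atanh(r_mean(k)) / atanh(r_mean(1))``; the first element is
    exactly 1.  A zero z at the smallest lag leaves the normalization
    undefined and raises; pipeline callers exclude such ROIs with a logged
    reason (see :func:`stack_traces`).
    """
    z = np.atleast_1d(fisher_z(trace.r_mean))
    if z[0] == 0:
        raise ValueError(
            f"ROI {trace.roi_id}: Fisher z at the smallest lag is 0; "
            "normalization undefined"
        )
    z_norm = z / z[0]
    z_norm[0] = 1.0
    return NormalizedTrace(trace.roi_id, trace.lags_s.copy(), z_norm, group_label)


def stack_traces(
    stack: ImageStack, rois: RoiSet, group_label: str = ""
) -> list[NormalizedTrace]:
    """Correlation decay traces for every kept ROI of a stack.

    ROIs whose normalization is undefined (zero Fisher z at the smallest lag)
    or that contain a zero-variance frame are excluded with a logged reason.
    """
    out: list[NormalizedTrace] = []
    for roi_id, roi in rois.kept_rois():
        try:
            mat = correlation_matrix(stack, roi)
            trace = trace_from_matrix(mat, stack.frame_interval_s, roi_id)
            out.append(normalize_trace(trace, group_label))
        except ValueError as err:
            logger.warning("excluding ROI %d: %s", roi_id, err)
    return out


def traces_to_frame(traces: list[NormalizedTrace]) -> pd.DataFrame:
    """Tidy long-format table (roi_id, group, lag_s, z_norm) of traces."""
    rows = []
    for tr in traces:
        for lag, z in zip(tr.lags_s, tr.z_norm):
            rows.append(
                {"roi_id": tr.roi_id, "group": tr.group_label, "lag_s": lag, "z_norm": z}
            )
    return pd.DataFrame(rows)


def traces_from_frame(df: pd.DataFrame) -> list[NormalizedTrace]:
    """Inverse of :func:`traces_to_frame`."""
    out = []
    for (roi_id, group), sub in df.groupby(["roi_id", "group"], sort=True):
        sub = sub.sort_values("lag_s")
        out.append(
            NormalizedTrace(
                int(roi_id),
                sub["lag_s"].to_numpy(),
                sub["z_norm"].to_numpy(),
                str(group),
            )
        )
    return out


def _znorm_array(traces: list[NormalizedTrace]) -> tuple[np.ndarray, np.ndarray]:
    lags = traces[0].lags_s
    for tr in traces[1:]:
        if tr.lags_s.shape != lags.shape or not np.allclose(tr.lags_s, lags):
            raise ValueError("traces do not share a common lag grid")
    return lags, np.vstack([tr.z_norm for tr in traces])


def compare_groups(
    traces_a: list[NormalizedTrace],
    traces_b: list[NormalizedTrace],
    alpha_levels: tuple[float, ...] = (0.05, 0.01),
) -> pd.DataFrame:
    """Per-lag Welch t tests between two groups of normalized traces.

    At each lag a two-tailed two-sample Welch t test compares z_norm across
    ROIs of group A versus group B; p-values are Benjamini-Hochberg adjusted
    across all lags jointly, and significance flags are set at each level in
    ``alpha_levels``.  :func:`attach_r_scale` adds group means with pointwise
    95% confidence intervals back-transformed to the r scale for plotting.

    Returns a table with one row per lag: ``lag_s, mean_diff, p_raw, p_bh``,
    ``sig_<level>`` flags, and ``mean_r_a/r_lo_a/r_hi_a`` (same for b).
    """
    if len(traces_a) < 2 or len(traces_b) < 2:
        raise ValueError("need at least 2 ROIs per group")
    lags, za = _znorm_array(traces_a)
    lags_b, zb = _znorm_array(traces_b)
    if lags.shape != lags_b.shape or not np.allclose(lags, lags_b):
        raise ValueError("groups do not share a common lag grid")

    with warnings.catch_warnings():
        # lag 1 is identically 1 in every trace by construction; scipy warns
        # about the resulting catastrophic cancellation
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        t_stat, p_raw = stats.ttest_ind(za, zb, axis=0, equal_var=False)
    # lag 1 is identically 1 in both groups: no test is possible there
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    _, p_bh, _, _ = multipletests(p_raw, method="fdr_bh")

    def _group_ci(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        m = z.mean(axis=0)
        se = z.std(axis=0, ddof=1) / np.sqrt(z.shape[0])
        return m, m - 1.96 * se, m + 1.96 * se

    ma, lo_a, hi_a = _group_ci(za)
    mb, lo_b, hi_b = _group_ci(zb)
    out = pd.DataFrame(
        {
            "lag_s": lags,
            "mean_diff": ma - mb,
            "t_stat": t_stat,
            "p_raw": p_raw,
            "p_bh": p_bh,
        }
    )
    for alpha in alpha_levels:
        out[f"sig_{alpha:g}".replace("0.", "")] = out["p_bh"] < alpha
    return out


def attach_r_scale(
    comparison: pd.DataFrame,
    traces_a: list[NormalizedTrace],
    traces_b: list[NormalizedTrace],
) -> pd.DataFrame:
    """Add back-transformed (r-scale) group means and 95% CIs to a comparison.

    Group mean normalized-z curves and their pointwise 95% CIs are passed
    through tanh so the plotted curves read as "normalized correlation" over
    time rather than raw z units.
    """
    comparison = comparison.copy()
    raise_if_empty = not traces_a or not traces_b
    if raise_if_empty:
        raise ValueError("need traces for both groups")
    lags, za = _znorm_array(traces_a)
    _, zb = _znorm_array(traces_b)
    for tag, z in (("a", za), ("b", zb)):
        m = z.mean(axis=0)
        se = z.std(axis=0, ddof=1) / np.sqrt(z.shape[0])
        comparison[f"mean_r_{tag}"] = np.tanh(m)
        comparison[f"r_lo_{tag}"] = np.tanh(m - 1.96 * se)
        comparison[f"r_hi_{tag}"] = np.tanh(m + 1.96 * se)
    return comparison
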