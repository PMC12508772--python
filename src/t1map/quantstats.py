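"""Repeatability and reproducibility statistics for quantitative T1 maps.

Implements the study-level statistical surface on top of the fitted maps:
per-ROI summaries, the coefficient of variation CV = 100 * SD / mean, the
repeatability coefficient RC = 1.96 * sqrt(2) * temporal SD (the maximum
expected test–retest difference 95% of the time), Bland–Altman agreement
with limits at +/- 1.96 SD of the paired differences, the NiCl2
relaxivity fit R1 = r1 * C + R1_{C=0} restricted to the protocol's
optimised T1 range, one-way ANOVA with Tukey HSD post hoc comparisons,
paired hemispheric t-tests, and histogram shape metrics (FWHM and
skewness).  Classical tests are delegated to scipy.stats; sample standard
deviations use the n-1 denominator throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .t1fit import QuantMaps

__all__ = [
    "ROIStats",
    "RepeatabilityResult",
    "BlandAltmanResult",
    "RelaxivityFit",
    "AnovaTukeyResult",
    "roi_stats",
    "compute_cv",
    "compute_rc",
    "repeatability_summary",
    "bland_altman",
    "relaxivity_fit",
    "one_way_anova",
    "tukey_hsd",
    "paired_t_test",
    "histogram_shape",
    "roi_table",
]

RC_FACTOR = 1.96 * np.sqrt(2.0)
ALPHA = 0.05


@dataclass
class ROIStats:
    """Mean/SD of T1 over the valid voxels of one labelled region."""

    roi_label: int | str
    mean_t1: float
    sd_t1: float
    n_voxels: int
    session_id: str | None = None
    site_id: str | None = None
    run_id: str | None = None
    hemisphere: str | None = None

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if self.sd_t1 < 0:
            raise ValueError("sd_t1 must be >= 0")


@dataclass
class RepeatabilityResult:
    """Longitudinal summary for one structure across repeated sessions."""

    mean: float
    temporal_sd: float
    cv: float
    rc: float
    n_sessions: int


@dataclass
class BlandAltmanResult:
    """Paired-agreement summary: mean difference and limits of agreement."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int


@dataclass
class RelaxivityFit:
    """Linear fit of R1 (s^-1) versus dopant concentration (mM)."""

    r1_slope: float
    intercept_r1_c0: float
    fit_range_t1: tuple[float, float]
    n_points_used: int


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA with optional Tukey HSD pairwise table."""

    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    significant: bool
    degenerate: bool = False
    pairwise: list[dict] = field(default_factory=list)


def roi_stats(maps: QuantMaps, labels: np.ndarray, **ids) -> list[ROIStats]:
    """Per-label mean/SD of T1 over fit-valid voxels.

    Voxels outside ``fit_mask`` (failed or bound-limited fits) never
    contribute; labels with no valid voxel are omitted with a warning.
    Extra keyword arguments (``session_id``, ``site_id``, ...) are copied
    onto every result.
    """
    labels = np.asarray(labels)
    if labels.shape != maps.t1.shape:
        raise ValueError("label volume does not match the map grid")
    out = []
    for lab in sorted(set(np.unique(labels)) - {0}):
        valid = (labels == lab) & maps.fit_mask
        n = int(valid.sum())
        if n == 0:
            warnings.warn(f"label {lab} has no valid voxels; omitted")
            continue
        vals = maps.t1[valid]
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        out.append(ROIStats(roi_label=int(lab), mean_t1=float(vals.mean()),
                            sd_t1=sd, n_voxels=n, **ids))
    return out


def compute_cv(mean: float, temporal_sd: float) -> float:
    """Coefficient of variation in percent: 100 * SD / mean."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if temporal_sd < 0:
        raise ValueError("temporal_sd must be >= 0")
    return 100.0 * temporal_sd / mean


def compute_rc(temporal_sd: float) -> float:
    """Repeatability coefficient RC = 1.96 * sqrt(2) * temporal SD (ms)."""
    if temporal_sd < 0:
        raise ValueError("temporal_sd must be >= 0")
    return RC_FACTOR * temporal_sd


def repeatability_summary(session_means) -> RepeatabilityResult:
    """Longitudinal mean, temporal SD (n-1), CV and RC across sessions."""
    m = np.asarray(session_means, dtype=float)
    if m.size < 2:
        raise ValueError("repeatability needs at least 2 sessions")
    mean = float(m.mean())
    sd = float(np.std(m, ddof=1))
    return RepeatabilityResult(mean=mean, temporal_sd=sd,
                               cv=compute_cv(mean, sd), rc=compute_rc(sd),
                               n_sessions=int(m.size))


def bland_altman(values_a, values_b) -> BlandAltmanResult:
    """Mean difference (a - b), its SD and the +/- 1.96 SD limits of
    agreement for paired measurements."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(mean_diff=mean, sd_diff=sd,
                             loa_low=mean - 1.96 * sd,
                             loa_high=mean + 1.96 * sd, n_pairs=int(a.size))


def relaxivity_fit(concentrations, t1_values,
                   fit_range: tuple[float, float] = (100.0, 1000.0)
                   ) -> RelaxivityFit:
    """OLS fit of R1 = 1/T1 (s^-1) against concentration (mM).

    Only points whose T1 lies inside ``fit_range`` (ms, inclusive)
    contribute; the slope is the longitudinal relaxivity r1 in
    s^-1 mM^-1 and the intercept the undoped relaxation rate.
    """
    c = np.asarray(concentrations, dtype=float)
    t1 = np.asarray(t1_values, dtype=float)
    if c.shape != t1.shape:
        raise ValueError("concentrations and t1_values must match")
    lo, hi = fit_range
    sel = (t1 >= lo) & (t1 <= hi)
    if sel.sum() < 2:
        raise ValueError("need at least 2 points inside the fit range")
    r1 = 1000.0 / t1[sel]                 # ms -> s^-1
    res = stats.linregress(c[sel], r1)
    return RelaxivityFit(r1_slope=float(res.slope),
                         intercept_r1_c0=float(res.intercept),
                         fit_range_t1=(lo, hi), n_points_used=int(sel.sum()))


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    return gs


def one_way_anova(groups, alpha: float = ALPHA) -> AnovaTukeyResult:
    """Classical one-way ANOVA across groups of ROI means.

    Degenerate input (zero within-group variance everywhere) yields an
    undefined F; the result is flagged instead of raising.
    """
    gs = _check_groups(groups)
    k = len(gs)
    n = sum(g.size for g in gs)
    allv = np.concatenate(gs)
    if np.ptp(allv) == 0 or all(np.ptp(g) == 0 for g in gs):
        return AnovaTukeyResult(f_stat=float("nan"), p_value=float("nan"),
                                df_between=k - 1, df_within=n - k,
                                significant=False, degenerate=True)
    f, p = stats.f_oneway(*gs)
    return AnovaTukeyResult(f_stat=float(f), p_value=float(p),
                            df_between=k - 1, df_within=n - k,
                            significant=bool(p < alpha))


def tukey_hsd(groups, alpha: float = ALPHA,
              labels: list | None = None) -> list[dict]:
    """Tukey HSD pairwise comparisons (Tukey–Kramer for unequal n).

    Returns one row per unordered pair with the mean difference and the
    studentized-range adjusted p-value; symmetric in pair order.
    """
    gs = _check_groups(groups)
    if labels is None:
        labels = list(range(len(gs)))
    res = stats.tukey_hsd(*gs)
    rows = []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            p = float(res.pvalue[i, j])
            rows.append({
                "group_i": labels[i], "group_j": labels[j],
                "mean_diff": float(gs[i].mean() - gs[j].mean()),
                "adjusted_p": p, "significant": bool(p < alpha),
            })
    return rows


def paired_t_test(values_a, values_b) -> tuple[float, float, bool]:
    """Classical paired t-test; returns (t, p, degenerate).

    Zero-variance differences are flagged: identical inputs give
    (0, 1, True), a constant nonzero shift (+/- inf, 0, True).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired inputs must have equal length >= 2")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0, True
        return float(np.sign(d[0]) * np.inf), 0.0, True
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), False


def histogram_shape(values, n_bins: int = 200,
                    value_range: tuple[float, float] = (1.0, 500.0)
                    ) -> tuple[float, float, bool]:
    """Histogram FWHM (seconds) and skewness of a T1 sample (ms).

    The histogram uses ``n_bins`` equal bins over ``value_range`` (ms, the
    study default is 200 bins over 1–500 ms).  FWHM is measured between
    the outermost half-maximum crossings, located by linear interpolation
    between bin centres, and is returned in seconds; when noise creates
    multiple crossings the outermost are used and the result is flagged.
    Skewness is the Fisher–Pearson g1 of the raw values.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be nonempty")
    counts, edges = np.histogram(v, bins=n_bins, range=value_range)
    centres = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    half = counts.max() / 2.0
    above = counts >= half
    runs = int(np.sum(np.diff(above.astype(int)) == 1) + int(above[0]))
    multimodal = runs > 1
    i_first = int(np.argmax(above))
    i_last = int(len(above) - 1 - np.argmax(above[::-1]))
    if i_first == 0:
        left = edges[0]
    else:
        c0, c1 = counts[i_first - 1], counts[i_first]
        left = centres[i_first - 1] + width * (half - c0) / (c1 - c0)
    if i_last == len(counts) - 1:
        right = edges[-1]
    else:
        c0, c1 = counts[i_last], counts[i_last + 1]
        right = centres[i_last] + width * (half - c0) / (c1 - c0)
    fwhm_s = (right - left) / 1000.0
    skew = 0.0 if np.ptp(v) == 0 else float(stats.skew(v, bias=True))
    return float(fwhm_s), skew, multimodal


# ---------------------------------------------------------------------------
# tabular layer: the shared CSV layout
# ---------------------------------------------------------------------------

ROI_TABLE_COLUMNS = ["site", "subject", "session", "run", "roi",
                     "hemisphere", "mean_t1_ms", "sd_t1_ms", "n_voxels"]


def roi_table(rows: list[ROIStats]) -> pd.DataFrame:
    """Convert ROI summaries to the shared tabular layout."""
    return pd.DataFrame([{
        "site": r.site_id, "subject": None, "session": r.session_id,
        "run": r.run_id, "roi": r.roi_label, "hemisphere": r.hemisphere,
        "mean_t1_ms": r.mean_t1, "sd_t1_ms": r.sd_t1, "n_voxels": r.n_voxels,
    } for r in rows], columns=ROI_TABLE_COLUMNS)
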