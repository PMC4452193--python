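"""Cross-scanner agreement statistics.

Implements the statistical battery used to compare per-layer thicknesses
from two OCT devices:

* **Bland–Altman** on same-day pairs: mean difference d(bar) with its 95% CI
  (t-based), limits of agreement d(bar) +- 1.96 s, and 95% CIs of each LOA via
  the sqrt(3/n) variance approximation with t quantiles.
* **Interscanner agreement index** per eye:
  ``1 - |X_a - X_b| / ((X_a + X_b)/2)`` — 1 means identical readings;
  aggregated as unweighted mean +- SD over eyes.
* **Repeated-measures Bland–Altman** on between-visit changes: the
  difference SD is rebuilt from one-way (subject) ANOVA variance
  components so two eyes of one subject do not masquerade as independent;
  CIs use the subject count as the effective n (conservative).
* **Mixed-effects rate of change** and **group comparison**: linear mixed
  models with a per-subject random intercept shared by both eyes,
  adjusting for baseline age and sex; REML fit, Wald inference.

The difference convention is fixed globally as device B minus device A
(by default "spectralis" minus "cirrus"); swapping the roles negates the
mean difference and mirrors the LOA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "BlandAltmanResult",
    "AgreementIndexResult",
    "RateOfChangeResult",
    "GroupComparisonResult",
    "bland_altman",
    "upper_loa_from_symmetry",
    "agreement_index",
    "aggregate_agreement_index",
    "modified_bland_altman",
    "fit_rate_of_change",
    "compare_groups",
    "bland_altman_table",
]

Z_LOA = 1.96  # conventional 95% population band multiplier


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    mean_diff: float
    sd_diff: float
    ci_mean: tuple[float, float]
    loa_lower: float
    loa_upper: float
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    n_subjects: Optional[int] = None  # set by the repeated-measures variant

    def __post_init__(self) -> None:
        if abs((self.loa_upper - self.mean_diff) - (self.mean_diff - self.loa_lower)) > 1e-9:
            raise ValidationError("limits of agreement are not symmetric about the mean")


@dataclass(frozen=True)
class AgreementIndexResult:
    layer: str
    values: np.ndarray
    mean: float
    sd: float


@dataclass(frozen=True)
class RateOfChangeResult:
    device: str
    layer: str
    slope: float           # um / year
    ci: tuple[float, float]
    p_value: float
    n_eyes: int
    n_subjects: int

    def __post_init__(self) -> None:
        if not (self.ci[0] - 1e-12 <= self.slope <= self.ci[1] + 1e-12):
            raise ValidationError("CI does not contain the point estimate")


@dataclass(frozen=True)
class GroupComparisonResult:
    device: str
    layer: str
    difference: float      # um, MS minus HC
    ci: tuple[float, float]
    p_value: float
    n_ms: int
    n_hc: int


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

def _ba_from_diffs(d: np.ndarray, n_eff: int, n_obs: int,
                   n_subjects: Optional[int] = None,
                   sd_override: Optional[float] = None) -> BlandAltmanResult:
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if sd_override is None else float(sd_override)
    if sd == 0.0:
        warnings.warn("zero difference variance: limits of agreement collapse "
                      "onto the mean and CIs are degenerate", stacklevel=3)
        lo = hi = mean
        return BlandAltmanResult(n_obs, mean, 0.0, (mean, mean), lo, hi,
                                 (lo, lo), (hi, hi), n_subjects)
    t = stats.t.ppf(0.975, n_eff - 1)
    se_mean = sd / np.sqrt(n_eff)
    se_loa = sd * np.sqrt(3.0 / n_eff)
    lo = mean - Z_LOA * sd
    hi = mean + Z_LOA * sd
    return BlandAltmanResult(
        n=n_obs,
        mean_diff=mean,
        sd_diff=sd,
        ci_mean=(mean - t * se_mean, mean + t * se_mean),
        loa_lower=lo,
        loa_upper=hi,
        ci_loa_lower=(lo - t * se_loa, lo + t * se_loa),
        ci_loa_upper=(hi - t * se_loa, hi + t * se_loa),
        n_subjects=n_subjects,
    )


def bland_altman(x_a: Sequence[float], x_b: Sequence[float]) -> BlandAltmanResult:
    """Bland–Altman agreement of paired measurements (difference = b - a).

    Requires at least 3 pairs. Returns the mean difference with t-based 95%
    CI, the 1.96-SD limits of agreement, and 95% CIs of each limit.
    """
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("x_a and x_b must be 1-D arrays of equal length")
    if a.size < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {a.size}")
    return _ba_from_diffs(b - a, n_eff=a.size, n_obs=a.size)


def upper_loa_from_symmetry(mean_diff: float, loa_lower: float) -> float:
    """Upper limit of agreement implied by the mean and the lower limit.

    The limits sit symmetrically at mean +- 1.96 s, so
    ``upper = 2 * mean - lower``; useful for internal-consistency checks of
    reported tables.
    """
    return 2.0 * mean_diff - loa_lower


# ---------------------------------------------------------------------------
# interscanner agreement index
# ---------------------------------------------------------------------------

def agreement_index(x_a, x_b):
    """``1 - |X_a - X_b| / ((X_a + X_b)/2)`` (scalar or elementwise).

    Equals 1 iff the two devices read identically; 0 when the absolute
    difference equals the mean (e.g. readings 30 and 10); can go negative
    for grossly discordant pairs but never exceeds 1. Invariant under
    swapping the devices and under common positive scaling.
    """
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    denom = (a + b) / 2.0
    if np.any(denom <= 0):
        raise ValidationError("agreement index needs positive measurement sums")
    out = 1.0 - np.abs(a - b) / denom
    return float(out) if out.ndim == 0 else out


def aggregate_agreement_index(
    x_a: Sequence[float], x_b: Sequence[float], layer: str = ""
) -> AgreementIndexResult:
    """Per-eye indices aggregated as unweighted mean +- SD."""
    values = agreement_index(np.asarray(x_a, float), np.asarray(x_b, float))
    values = np.atleast_1d(values)
    return AgreementIndexResult(
        layer=layer, values=values,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# repeated-measures Bland–Altman on longitudinal change
# ---------------------------------------------------------------------------

def modified_bland_altman(
    delta_a: Sequence[float],
    delta_b: Sequence[float],
    subjects: Sequence,
) -> BlandAltmanResult:
    """Bland–Altman on between-visit changes with subject clustering.

    ``delta_a``/``delta_b`` are per-eye thickness changes between serial
    scans on each device; ``subjects`` labels which subject each eye belongs
    to. The difference SD is rebuilt as sqrt(between-subject + within-
    subject variance) from one-way ANOVA estimators, and CIs use the number
    of subjects as the effective sample size.
    """
    da = np.asarray(delta_a, dtype=float)
    db = np.asarray(delta_b, dtype=float)
    subj = np.asarray(subjects)
    if not (da.shape == db.shape == subj.shape) or da.ndim != 1:
        raise ValidationError("delta_a, delta_b, subjects must be equal-length 1-D")
    if da.size < 3:
        raise InsufficientDataError(f"need >= 3 eyes, got {da.size}")
    groups = pd.unique(subj)
    k = len(groups)
    if k < 2:
        raise InsufficientDataError("repeated-measures adjustment needs >= 2 subjects")
    d = db - da
    n_total = d.size
    grand = d.mean()
    ss_between = ss_within = 0.0
    sizes = []
    for g in groups:
        dg = d[subj == g]
        sizes.append(dg.size)
        ss_between += dg.size * (dg.mean() - grand) ** 2
        ss_within += ((dg - dg.mean()) ** 2).sum()
    sizes = np.asarray(sizes, dtype=float)
    msb = ss_between / (k - 1)
    if n_total == k:  # one eye per subject: plain independent differences
        total_var = float(np.var(d, ddof=1))
    else:
        msw = ss_within / (n_total - k)
        n0 = (n_total - (sizes**2).sum() / n_total) / (k - 1)
        var_between = max(0.0, (msb - msw) / n0)
        total_var = var_between + msw
    return _ba_from_diffs(d, n_eff=k, n_obs=n_total, n_subjects=k,
                          sd_override=np.sqrt(total_var))


# ---------------------------------------------------------------------------
# mixed-effects models
# ---------------------------------------------------------------------------

def _prepare_model_frame(records: pd.DataFrame, device: Optional[str],
                         layer: str) -> pd.DataFrame:
    df = records.copy()
    if device is not None and "device" in df.columns:
        df = df[df["device"] == device]
    if layer not in df.columns:
        raise ValidationError(f"no column for layer {layer!r}")
    df = df.dropna(subset=[layer])
    if df.empty:
        raise InsufficientDataError("no observations after filtering")
    df["_y"] = df[layer].astype(float)
    df["_sex_male"] = (df["sex"].astype(str).str.upper().str.startswith("M")).astype(float)
    df["_age"] = df["age"].astype(float)
    return df


def _fit_mixedlm(df: pd.DataFrame, fixed_cols: list[str], effect_col: str):
    import statsmodels.formula.api as smf

    formula = "_y ~ " + " + ".join(fixed_cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["subject"])
        fit = model.fit(reml=True, method=["lbfgs", "powell"])
    est = float(fit.params[effect_col])
    se = float(fit.bse[effect_col])
    z = stats.norm.ppf(0.975)
    ci = (est - z * se, est + z * se)
    p = float(fit.pvalues[effect_col])
    return est, ci, p


def fit_rate_of_change(
    records: pd.DataFrame, device: Optional[str], layer: str
) -> RateOfChangeResult:
    """Annual rate of layer-thickness change from a longitudinal table.

    Fits ``thickness ~ years + age + sex`` with a per-subject random
    intercept (shared by the subject's two eyes), REML; reports the Wald
    95% CI and p-value of the time slope in um/year. ``records`` needs
    columns subject, eye, years, age, sex and one column per layer.
    """
    df = _prepare_model_frame(records, device, layer)
    if "years" not in df.columns:
        raise ValidationError("longitudinal table needs a 'years' column")
    visit_counts = df.groupby("subject")["years"].nunique()
    if (visit_counts >= 2).sum() < 5:
        raise InsufficientDataError(
            "need >= 2 visits for >= 5 subjects to estimate a rate of change"
        )
    if df["years"].nunique() < 2:
        raise ValidationError("no time variation in the records")
    slope, ci, p = _fit_mixedlm(df, ["years", "_age", "_sex_male"], "years")
    return RateOfChangeResult(
        device=device or "all", layer=layer, slope=slope, ci=ci, p_value=p,
        n_eyes=int(df.groupby(["subject", "eye"]).ngroups),
        n_subjects=int(df["subject"].nunique()),
    )


def compare_groups(
    records: pd.DataFrame, device: Optional[str], layer: str,
    *, reference_group: str = "HC",
) -> GroupComparisonResult:
    """Cross-sectional MS-versus-control layer-thickness difference.

    Fits ``thickness ~ group + age + sex`` with a per-subject random
    intercept; reports the MS-minus-HC adjusted difference (um) with Wald
    95% CI and p-value.
    """
    df = _prepare_model_frame(records, device, layer)
    df["_ms"] = (df["group"].astype(str) != reference_group).astype(float)
    n_ms = int(df.loc[df["_ms"] == 1, "subject"].nunique())
    n_hc = int(df.loc[df["_ms"] == 0, "subject"].nunique())
    if n_ms == 0 or n_hc == 0:
        raise InsufficientDataError("both groups must be present")
    diff, ci, p = _fit_mixedlm(df, ["_ms", "_age", "_sex_male"], "_ms")
    return GroupComparisonResult(
        device=device or "all", layer=layer, difference=diff, ci=ci,
        p_value=p, n_ms=n_ms, n_hc=n_hc,
    )


# ---------------------------------------------------------------------------
# table drivers
# ---------------------------------------------------------------------------

def bland_altman_table(paired: pd.DataFrame) -> pd.DataFrame:
    """Agreement summary per layer from a paired table.

    ``paired`` is long format with columns subject, eye, layer, x_a, x_b
    (as produced by :func:`octlayers.cohort.simulate_paired_eyes`). One row
    per layer: average thickness (SD), mean difference (CI), upper and
    lower LOA (CI), mean agreement index (SD).
    """
    rows = []
    for layer, g in paired.groupby("layer", sort=False):
        ba = bland_altman(g["x_a"], g["x_b"])
        idx = aggregate_agreement_index(g["x_a"], g["x_b"], layer)
        avg = (g["x_a"] + g["x_b"]) / 2.0
        rows.append({
            "layer": layer,
            "n_eyes": ba.n,
            "avg_thickness": float(avg.mean()),
            "avg_thickness_sd": float(avg.std(ddof=1)),
            "mean_diff": ba.mean_diff,
            "mean_diff_ci_low": ba.ci_mean[0],
            "mean_diff_ci_high": ba.ci_mean[1],
            "upper_loa": ba.loa_upper,
            "upper_loa_ci_low": ba.ci_loa_upper[0],
            "upper_loa_ci_high": ba.ci_loa_upper[1],
            "lower_loa": ba.loa_lower,
            "lower_loa_ci_low": ba.ci_loa_lower[0],
            "lower_loa_ci_high": ba.ci_loa_lower[1],
            "agreement_index_mean": idx.mean,
            "agreement_index_sd": idx.sd,
        })
    return pd.DataFrame(rows)


def bland_altman_plot(x_a, x_b, ax=None, label: str = ""):
    """Difference-versus-mean scatter with the mean line and LOA lines."""
    import matplotlib.pyplot as plt

    a = np.asarray(x_a, float)
    b = np.asarray(x_b, float)
    res = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2.0, b - a, s=8, alpha=0.6)
    for v, style in ((res.mean_diff, "-"), (res.loa_lower, "--"), (res.loa_upper, "--")):
        ax.axhline(v, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of devices (um)")
    ax.set_ylabel("difference, b - a (um)")
    if label:
        ax.set_title(label)
    return ax, res
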