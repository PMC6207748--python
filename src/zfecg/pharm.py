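"""Drug-response analyses: pre/post comparison, dose-response, AV-block calls.

Mirrors the pharmacology workflow of an in vivo zebrafish ECG screen:
paired pre/post recordings per fish, per-subject metric means, fold and
percent change, a paired two-sided Student t-test, a dose-response
table, and a rule-based atrioventricular-block classifier.

The paired t statistic and its p-value are implemented from their
definitions (p via the regularized incomplete beta function) so the
analysis is self-contained and directly testable against an independent
statistics library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .core import RecordingSummary, ValidationError
from .metrics import summarize


def paired_t(pre: Sequence[float], post: Sequence[float]) -> tuple:
    """Two-sided paired Student t-test on per-subject values.

    Returns ``(t, p, df, no_variance)``.  ``t = d_bar / (s_d / sqrt(n))``
    with ``d = post - pre``; ``p = I_{df/(df+t^2)}(df/2, 1/2)``.  When
    the differences have zero variance the test is undefined and the
    ``no_variance`` flag is set (t and p are NaN).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValidationError("pre and post must be equal-length 1-D sequences")
    n = pre.size
    if n < 2:
        raise ValidationError("paired t-test needs at least 2 subjects")
    d = post - pre
    df = n - 1
    s_d = float(np.std(d, ddof=1))
    if s_d == 0.0:
        return (float("nan"), float("nan"), df, True)
    t = float(np.mean(d) / (s_d / np.sqrt(n)))
    p = float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))
    return (t, p, df, False)


@dataclass(frozen=True)
class ComparisonResult:
    """Pre/post drug comparison over paired subjects.

    ``fold_change`` is the mean over subjects of ``post_i / pre_i``;
    ``percent_change`` is the signed ``(fold - 1) * 100`` and
    ``percent_reduction`` its negation, so a 25% heart-rate drop reads
    ``percent_reduction = 25``.  Test fields are absent (NaN) when fewer
    than two subjects are available or the differences have no variance.
    """

    metric: str
    n_subjects: int
    pre_means: np.ndarray
    post_means: np.ndarray
    pre_summary: RecordingSummary
    post_summary: RecordingSummary
    delta_mean: float
    fold_change: float
    percent_change: float
    t_statistic: float = float("nan")
    p_value: float = float("nan")
    df: Optional[int] = None
    no_variance: bool = False

    @property
    def percent_reduction(self) -> float:
        return -self.percent_change

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "n_subjects": self.n_subjects,
            "pre_means": [float(x) for x in self.pre_means],
            "post_means": [float(x) for x in self.post_means],
            "delta_mean": self.delta_mean,
            "fold_change": self.fold_change,
            "percent_change": self.percent_change,
            "percent_reduction": self.percent_reduction,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "df": self.df,
            "no_variance": self.no_variance,
        }


def _subject_means(tables: Sequence[pd.DataFrame], metric: str) -> np.ndarray:
    means = []
    for i, tbl in enumerate(tables):
        if metric not in tbl.columns:
            raise ValidationError(f"table {i} has no column {metric!r}")
        vals = tbl[metric].dropna()
        if vals.empty:
            raise ValidationError(f"table {i} has no {metric!r} measurements")
        means.append(float(vals.mean()))
    return np.asarray(means)


def compare_pre_post(pre_tables: Sequence[pd.DataFrame],
                     post_tables: Sequence[pd.DataFrame],
                     metric: str = "hr_bpm") -> ComparisonResult:
    """Compare a metric between paired pre/post interval tables.

    ``pre_tables[i]`` and ``post_tables[i]`` must belong to the same
    subject.  Per-subject means are compared; fold and percent change
    are computed per subject and then averaged, and the paired t-test
    runs on the per-subject means (two-sided).
    """
    if len(pre_tables) != len(post_tables):
        raise ValidationError(
            f"mismatched pairing: {len(pre_tables)} pre vs "
            f"{len(post_tables)} post subjects")
    if len(pre_tables) == 0:
        raise ValidationError("no subjects")
    pre = _subject_means(pre_tables, metric)
    post = _subject_means(post_tables, metric)
    if np.any(pre == 0):
        raise ValidationError("zero pre-treatment mean; fold change undefined")
    n = pre.size
    fold = float(np.mean(post / pre))
    result = dict(
        metric=metric,
        n_subjects=n,
        pre_means=pre,
        post_means=post,
        pre_summary=_means_summary(pre),
        post_summary=_means_summary(post),
        delta_mean=float(np.mean(post - pre)),
        fold_change=fold,
        percent_change=(fold - 1.0) * 100.0,
    )
    if n >= 2:
        t, p, df, novar = paired_t(pre, post)
        result.update(t_statistic=t, p_value=p, df=df, no_variance=novar)
    return ComparisonResult(**result)


def _means_summary(vals: np.ndarray) -> RecordingSummary:
    mean = {"value": float(np.mean(vals))}
    sd = {"value": float(np.std(vals, ddof=1))} if vals.size >= 2 else {}
    return RecordingSummary(n_beats=int(vals.size), mean=mean, sd=sd)


def dose_response(folds: Mapping[float, Sequence[float]]) -> pd.DataFrame:
    """Tabulate per-dose fold changes: ``dose, log10_dose, mean_fold, sd_fold, n``.

    Rows are sorted by ascending dose.  No curve is fitted — the
    dose-response relationship is reported as points.
    """
    rows = []
    for dose, vals in folds.items():
        if dose <= 0:
            raise ValidationError(f"dose must be positive, got {dose}")
        vals = np.asarray(list(vals), dtype=float)
        if vals.size == 0:
            raise ValidationError(f"no fold changes for dose {dose}")
        rows.append({
            "dose": float(dose),
            "log10_dose": float(np.log10(dose)),
            "mean_fold": float(np.mean(vals)),
            "sd_fold": float(np.std(vals, ddof=1)) if vals.size >= 2 else np.nan,
            "n": int(vals.size),
        })
    df = pd.DataFrame(rows, columns=["dose", "log10_dose", "mean_fold",
                                     "sd_fold", "n"])
    return df.sort_values("dose", ignore_index=True)


@dataclass(frozen=True)
class AVBlockCall:
    """Atrioventricular-block classification with its evidence.

    ``grade`` is ``"none"``, ``"first_degree"`` (PR prolonged beyond the
    baseline reference but every P conducted) or ``"high_degree"``
    (P waves without a following QRS).
    """

    grade: str
    mean_pr_ms: Optional[float]
    baseline_pr_mean: float
    baseline_pr_sd: float
    pr_threshold_ms: float
    dropped_ratio: float
    evidence: str = ""


def classify_av_block(table: pd.DataFrame, p_events,
                      baseline_pr_mean: float, baseline_pr_sd: float,
                      pr_sd_mult: float = 3.0,
                      dropped_ratio_thresh: float = 0.05) -> AVBlockCall:
    """Classify AV conduction from an interval table and P-only events.

    * ``high_degree`` when the dropped-QRS ratio (P events without a
      QRS / total P events) exceeds ``dropped_ratio_thresh``;
    * ``first_degree`` when the mean PR exceeds
      ``baseline_pr_mean + pr_sd_mult * baseline_pr_sd`` with every P
      conducted;
    * ``none`` otherwise.  Missing PR data yields ``none`` with the
      evidence flag ``"insufficient"``.

    ``p_events`` may be a count or a sequence of P-only events.  The
    thresholds are screening defaults (the classical definitions give no
    quantitative cutoffs); both are configurable.
    """
    n_dropped = p_events if isinstance(p_events, (int, np.integer)) else len(p_events)
    if n_dropped < 0:
        raise ValidationError("p_events count must be >= 0")
    pr_vals = table["pr_ms"].dropna() if "pr_ms" in table.columns else pd.Series(dtype=float)
    n_conducted = int(pr_vals.size)
    total_p = n_conducted + n_dropped
    ratio = n_dropped / total_p if total_p > 0 else 0.0
    threshold = baseline_pr_mean + pr_sd_mult * baseline_pr_sd

    if ratio > dropped_ratio_thresh:
        return AVBlockCall("high_degree",
                           float(pr_vals.mean()) if n_conducted else None,
                           baseline_pr_mean, baseline_pr_sd, threshold, ratio,
                           evidence=f"{n_dropped}/{total_p} P waves not conducted")
    if n_conducted == 0:
        return AVBlockCall("none", None, baseline_pr_mean, baseline_pr_sd,
                           threshold, ratio, evidence="insufficient")
    mean_pr = float(pr_vals.mean())
    if mean_pr > threshold and n_dropped == 0:
        return AVBlockCall("first_degree", mean_pr, baseline_pr_mean,
                           baseline_pr_sd, threshold, ratio,
                           evidence=f"mean PR {mean_pr:.1f} ms > "
                                    f"{threshold:.1f} ms reference")
    return AVBlockCall("none", mean_pr, baseline_pr_mean, baseline_pr_sd,
                       threshold, ratio)
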