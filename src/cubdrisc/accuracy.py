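"""Diagnostic accuracy of an integer risk score against a binary gold standard.

Given per-participant questionnaire totals and the OGTT-derived dysglycemia
label, this module sweeps integer cutoffs (test-positive ⇔ score ≥ cutoff),
builds 2×2 tables, and computes sensitivity, specificity, predictive values
(Wilson score intervals), likelihood ratios (log-transform intervals), the
empirical ROC curve with trapezoidal AUC (Hanley–McNeil standard error), and
optimal operating points by the Youden index or by likelihood-ratio
usefulness constraints (LR+ > 2 and LR− < 0.5).

AUC is graded on the conventional scheme: 0.9–1.0 excellent, 0.8–0.9 very
good, 0.7–0.8 good, 0.6–0.7 sufficient, 0.5–0.6 poor, below 0.5 not useful
(bands closed on the left).
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionTable",
    "CiValue",
    "DiagnosticMetrics",
    "AccuracyReport",
    "RocCurve",
    "AucBand",
    "OptimalCutoff",
    "confusion_at_cutoff",
    "diagnostic_metrics",
    "likelihood_ratios",
    "roc_curve",
    "auc",
    "auc_band",
    "optimal_cutoff",
    "evaluate_cutoffs",
    "accuracy_table",
    "format_accuracy_tsv",
    "roc_points_tsv",
]


class AucBand(str, enum.Enum):
    EXCELLENT = "excellent"
    VERY_GOOD = "very_good"
    GOOD = "good"
    SUFFICIENT = "sufficient"
    POOR = "poor"
    NOT_USEFUL = "not_useful"


@dataclass(frozen=True)
class CiValue:
    """A point estimate with a two-sided confidence interval."""

    value: float
    lower: float
    upper: float

    def __iter__(self):
        return iter((self.value, self.lower, self.upper))


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        """Diseased (gold-standard positive) total."""
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D sequences of equal length")
    if len(scores) == 0:
        raise ValueError("empty input: no records to evaluate")
    if not labels.any():
        raise ValueError("degenerate labels: no gold-standard positive records")
    if labels.all():
        raise ValueError("degenerate labels: no gold-standard negative records")
    return scores, labels


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionTable:
    """2×2 table with test-positive ⇔ score ≥ cutoff."""
    scores, labels = _as_arrays(scores, labels)
    pos = scores >= cutoff
    return ConfusionTable(
        tp=int(np.sum(pos & labels)),
        fp=int(np.sum(pos & ~labels)),
        fn=int(np.sum(~pos & labels)),
        tn=int(np.sum(~pos & ~labels)),
    )


def _wilson(count: int, nobs: int, alpha: float) -> CiValue | None:
    """Proportion with a Wilson score interval; None when undefined."""
    if nobs == 0:
        return None
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    return CiValue(value=count / nobs, lower=float(lo), upper=float(hi))


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Se/Sp/PPV/NPV; a metric whose denominator is zero is None (undefined)."""

    se: CiValue | None
    sp: CiValue | None
    ppv: CiValue | None
    npv: CiValue | None


def diagnostic_metrics(table: ConfusionTable, alpha: float = 0.05) -> DiagnosticMetrics:
    """Sensitivity, specificity and predictive values with Wilson intervals."""
    return DiagnosticMetrics(
        se=_wilson(table.tp, table.tp + table.fn, alpha),
        sp=_wilson(table.tn, table.tn + table.fp, alpha),
        ppv=_wilson(table.tp, table.tp + table.fp, alpha),
        npv=_wilson(table.tn, table.tn + table.fn, alpha),
    )


def likelihood_ratios(table: ConfusionTable, alpha: float = 0.05) -> tuple[CiValue, CiValue]:
    """LR+ = Se/(1−Sp) and LR− = (1−Se)/Sp with log-transform intervals.

    With a perfect specificity (fp = 0) LR+ is infinite; a one-sided interval
    is reported whose finite lower bound uses a 0.5 continuity correction.
    Symmetrically for fn = 0 and LR−.
    """
    if table.n_pos == 0 or table.n_neg == 0:
        raise ValueError("likelihood ratios require both diseased and non-diseased records")
    z = norm.ppf(1 - alpha / 2)
    lr_pos = _one_lr(table.tp, table.fn, table.fp, table.tn, z)
    lr_neg = _one_lr(table.fn, table.tp, table.tn, table.fp, z)
    return lr_pos, lr_neg


def _one_lr(a: int, a_comp: int, b: int, b_comp: int, z: float) -> CiValue:
    """LR for rates a/(a+a_comp) over b/(b+b_comp), log-method interval."""
    n1 = a + a_comp
    n2 = b + b_comp
    if b == 0:
        # infinite ratio; continuity-corrected one-sided lower bound
        ac, bc = a + 0.5, 0.5
        lr_c = (ac / (n1 + 1)) / (bc / (n2 + 1))
        se_log = math.sqrt(1 / ac - 1 / (n1 + 1) + 1 / bc - 1 / (n2 + 1))
        return CiValue(value=math.inf, lower=lr_c * math.exp(-z * se_log), upper=math.inf)
    if a == 0:
        ac, bc = 0.5, b + 0.5
        lr_c = (ac / (n1 + 1)) / (bc / (n2 + 1))
        se_log = math.sqrt(1 / ac - 1 / (n1 + 1) + 1 / bc - 1 / (n2 + 1))
        return CiValue(value=0.0, lower=0.0, upper=lr_c * math.exp(z * se_log))
    lr = (a / n1) / (b / n2)
    se_log = math.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2)
    return CiValue(
        value=lr,
        lower=lr * math.exp(-z * se_log),
        upper=lr * math.exp(z * se_log),
    )


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: one point per candidate threshold, descending.

    The leading +inf sentinel yields the (fpr, tpr) = (0, 0) corner; the
    lowest observed score yields (1, 1) since test-positive is score ≥ cutoff.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    n_pos: int
    n_neg: int


def roc_curve(scores, labels) -> RocCurve:
    """ROC over all distinct observed scores plus a +inf sentinel."""
    scores, labels = _as_arrays(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    distinct = np.unique(scores)[::-1]  # descending
    thresholds = np.concatenate(([np.inf], distinct))
    # cumulative counts of cases/controls with score >= threshold
    order = np.argsort(scores, kind="stable")[::-1]
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    cum_pos = np.cumsum(sorted_labels)
    cum_neg = np.cumsum(~sorted_labels)
    # index of last element >= each distinct threshold
    idx = np.searchsorted(-sorted_scores, -distinct, side="right") - 1
    tpr = np.concatenate(([0.0], cum_pos[idx] / n_pos))
    fpr = np.concatenate(([0.0], cum_neg[idx] / n_neg))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, n_pos=n_pos, n_neg=n_neg)


def auc_band(value: float) -> AucBand:
    """Qualitative accuracy grade of an AUC; bands closed on the left."""
    if not 0 <= value <= 1:
        raise ValueError(f"AUC must lie in [0, 1], got {value}")
    if value >= 0.9:
        return AucBand.EXCELLENT
    if value >= 0.8:
        return AucBand.VERY_GOOD
    if value >= 0.7:
        return AucBand.GOOD
    if value >= 0.6:
        return AucBand.SUFFICIENT
    if value >= 0.5:
        return AucBand.POOR
    return AucBand.NOT_USEFUL


def auc(roc: RocCurve, alpha: float = 0.05) -> tuple[CiValue, AucBand]:
    """Trapezoidal AUC with the Hanley–McNeil standard error.

    The trapezoidal area over the empirical step curve equals the
    pairwise-comparison statistic P(case > control) + ½·P(tie).
    """
    area = float(np.trapezoid(roc.tpr, roc.fpr))
    q1 = area / (2 - area)
    q2 = 2 * area**2 / (1 + area)
    var = (
        area * (1 - area)
        + (roc.n_pos - 1) * (q1 - area**2)
        + (roc.n_neg - 1) * (q2 - area**2)
    ) / (roc.n_pos * roc.n_neg)
    se = math.sqrt(max(var, 0.0))
    z = norm.ppf(1 - alpha / 2)
    ci = CiValue(
        value=area,
        lower=max(0.0, area - z * se),
        upper=min(1.0, area + z * se),
    )
    return ci, auc_band(area)


@dataclass(frozen=True)
class AccuracyReport:
    """Full accuracy panel at one cutoff (AUC describes the whole curve)."""

    cutoff: int
    table: ConfusionTable
    se: CiValue | None
    sp: CiValue | None
    ppv: CiValue | None
    npv: CiValue | None
    lr_pos: CiValue
    lr_neg: CiValue
    auc: CiValue
    auc_band: AucBand
    scale: str | None = None


def _report_at(scores, labels, cutoff: int, alpha: float, roc_ci: CiValue, band: AucBand, scale=None) -> AccuracyReport:
    table = confusion_at_cutoff(scores, labels, cutoff)
    m = diagnostic_metrics(table, alpha)
    lr_pos, lr_neg = likelihood_ratios(table, alpha)
    return AccuracyReport(
        cutoff=int(cutoff),
        table=table,
        se=m.se,
        sp=m.sp,
        ppv=m.ppv,
        npv=m.npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        auc=roc_ci,
        auc_band=band,
        scale=scale,
    )


def evaluate_cutoffs(
    scores, labels, cutoffs: Sequence[int], alpha: float = 0.05, scale: str | None = None
) -> list[AccuracyReport]:
    """One :class:`AccuracyReport` per requested integer cutoff."""
    scores, labels = _as_arrays(scores, labels)
    roc = roc_curve(scores, labels)
    roc_ci, band = auc(roc, alpha)
    return [
        _report_at(scores, labels, int(c), alpha, roc_ci, band, scale) for c in cutoffs
    ]


@dataclass(frozen=True)
class OptimalCutoff:
    cutoff: int
    report: AccuracyReport
    method: str
    youden: float
    fell_back: bool = False  # lr_constrained had no feasible cutoff


def optimal_cutoff(scores, labels, method: str = "youden", alpha: float = 0.05) -> OptimalCutoff:
    """Best integer cutoff by Youden's J (Se + Sp − 1) or LR constraints.

    ``lr_constrained`` restricts candidates to cutoffs with LR+ > 2 and
    LR− < 0.5 (the conventional usefulness thresholds for a screening test)
    and maximises J within the feasible set; an empty feasible set falls back
    to plain Youden with ``fell_back=True``.  Ties break toward the lower
    cutoff, favouring sensitivity in a screening context.
    """
    if method not in ("youden", "lr_constrained"):
        raise ValueError(f"unknown method {method!r}; expected 'youden' or 'lr_constrained'")
    scores, labels = _as_arrays(scores, labels)
    if np.unique(scores).size < 2:
        raise ValueError("all scores are identical; no cutoff separates the classes")
    lo, hi = int(np.min(scores)), int(np.max(scores))
    candidates = range(lo, hi + 1)
    reports = evaluate_cutoffs(scores, labels, list(candidates), alpha=alpha)

    def j(r: AccuracyReport) -> float:
        return r.se.value + r.sp.value - 1

    pool = reports
    fell_back = False
    if method == "lr_constrained":
        feasible = [r for r in reports if r.lr_pos.value > 2 and r.lr_neg.value < 0.5]
        if feasible:
            pool = feasible
        else:
            fell_back = True
    # max J, ties toward the lower cutoff (pool is ordered by cutoff)
    best = max(pool, key=lambda r: (j(r), -r.cutoff))
    return OptimalCutoff(
        cutoff=best.cutoff,
        report=best,
        method=method,
        youden=j(best),
        fell_back=fell_back,
    )


# ---------------------------------------------------------------------------
# Report-shaped exports: one row per (scale, cutoff), percentages at one
# decimal, LR+ one decimal, LR− two decimals, AUC three decimals.
# ---------------------------------------------------------------------------


def accuracy_table(
    scores_by_scale: Mapping[str, Sequence[int]],
    labels,
    cutoffs: Sequence[int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Accuracy panel across scales and cutoffs as a tidy DataFrame."""
    rows = []
    for scale, scores in scores_by_scale.items():
        for r in evaluate_cutoffs(scores, labels, cutoffs, alpha=alpha, scale=scale):
            rows.append(
                {
                    "scale": scale,
                    "cutoff": r.cutoff,
                    "tp": r.table.tp,
                    "fp": r.table.fp,
                    "fn": r.table.fn,
                    "tn": r.table.tn,
                    "se": r.se.value,
                    "se_lo": r.se.lower,
                    "se_hi": r.se.upper,
                    "sp": r.sp.value,
                    "sp_lo": r.sp.lower,
                    "sp_hi": r.sp.upper,
                    "ppv": r.ppv.value if r.ppv else math.nan,
                    "ppv_lo": r.ppv.lower if r.ppv else math.nan,
                    "ppv_hi": r.ppv.upper if r.ppv else math.nan,
                    "npv": r.npv.value if r.npv else math.nan,
                    "npv_lo": r.npv.lower if r.npv else math.nan,
                    "npv_hi": r.npv.upper if r.npv else math.nan,
                    "lr_pos": r.lr_pos.value,
                    "lr_pos_lo": r.lr_pos.lower,
                    "lr_pos_hi": r.lr_pos.upper,
                    "lr_neg": r.lr_neg.value,
                    "lr_neg_lo": r.lr_neg.lower,
                    "lr_neg_hi": r.lr_neg.upper,
                    "auc": r.auc.value,
                    "auc_lo": r.auc.lower,
                    "auc_hi": r.auc.upper,
                    "auc_band": r.auc_band.value,
                }
            )
    return pd.DataFrame(rows)


def _pct(x: float) -> str:
    return "" if not math.isfinite(x) else f"{100 * x:.1f}"


def _f(x: float, nd: int) -> str:
    return "inf" if math.isinf(x) else f"{x:.{nd}f}"


def format_accuracy_tsv(table: pd.DataFrame) -> str:
    """Render the accuracy panel as a TSV mirroring the published precision."""
    header = [
        "scale",
        "cutoff",
        "se_pct",
        "se_95ci",
        "sp_pct",
        "sp_95ci",
        "ppv_pct",
        "ppv_95ci",
        "npv_pct",
        "npv_95ci",
        "lr_pos",
        "lr_pos_95ci",
        "lr_neg",
        "lr_neg_95ci",
        "auc",
        "auc_95ci",
        "auc_band",
    ]
    lines = ["\t".join(header)]
    for _, r in table.iterrows():
        lines.append(
            "\t".join(
                [
                    str(r["scale"]),
                    str(int(r["cutoff"])),
                    _pct(r["se"]),
                    f"{_pct(r['se_lo'])}-{_pct(r['se_hi'])}",
                    _pct(r["sp"]),
                    f"{_pct(r['sp_lo'])}-{_pct(r['sp_hi'])}",
                    _pct(r["ppv"]),
                    f"{_pct(r['ppv_lo'])}-{_pct(r['ppv_hi'])}",
                    _pct(r["npv"]),
                    f"{_pct(r['npv_lo'])}-{_pct(r['npv_hi'])}",
                    _f(r["lr_pos"], 1),
                    f"{_f(r['lr_pos_lo'], 1)}-{_f(r['lr_pos_hi'], 1)}",
                    _f(r["lr_neg"], 2),
                    f"{_f(r['lr_neg_lo'], 2)}-{_f(r['lr_neg_hi'], 2)}",
                    _f(r["auc"], 3),
                    f"{_f(r['auc_lo'], 3)}-{_f(r['auc_hi'], 3)}",
                    str(r["auc_band"]),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def roc_points_tsv(roc: RocCurve) -> str:
    """ROC points as TSV: threshold, tpr, fpr."""
    lines = ["threshold\ttpr\tfpr"]
    for t, tp, fp in zip(roc.thresholds, roc.tpr, roc.fpr):
        tstr = "inf" if math.isinf(t) else f"{t:g}"
        lines.append(f"{tstr}\t{tp:.6f}\t{fp:.6f}")
    return "\n".join(lines) + "\n"
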