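"""Criterion- and construct-validity statistics for phenotype validation.

Criterion validity: cross-tabulate algorithm output against the reference
standard (manual chart review) and report unweighted Cohen kappa, agreement,
sensitivity, specificity, PPV, NPV, and accuracy.  Construct validity: 2x2
odds ratios with Wald 95% confidence intervals against known risk factors.
The univariable cross-product OR is identical to the single-covariate
logistic estimate, so no iterative fitter is needed.

Display conventions: half-away-from-zero rounding; integer percentages,
1 decimal for odds ratios and CIs, 2 decimals for kappa and agreement.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

__all__ = [
    "ConfusionMatrix",
    "TwoByTwo",
    "MetricReport",
    "OddsRatioResult",
    "FunnelReport",
    "confusion",
    "cohen_kappa",
    "diagnostic_metrics",
    "odds_ratio_wald",
    "eligibility_funnel",
    "round_half_away",
    "render_validation_report",
]

Z_95 = 1.96  # fixed 95% confidence level


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the tabulation convention used here)."""
    factor = 10.0 ** ndigits
    # tiny epsilon so decimal halves stored just below .5 (e.g. 2.55) round up
    r = math.floor(abs(x) * factor + 0.5 + 1e-9) / factor
    return math.copysign(r, x)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Patient counts: reference standard in rows, algorithm in columns."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fn, self.fp, self.tn):
            if v < 0 or v != int(v):
                raise ValueError("confusion-matrix cells must be non-negative integers")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-outcome counts for a univariable odds ratio."""

    exposed_cases: int
    unexposed_cases: int
    exposed_controls: int
    unexposed_controls: int

    def cells(self) -> tuple[int, int, int, int]:
        return (
            self.exposed_cases,
            self.unexposed_cases,
            self.exposed_controls,
            self.unexposed_controls,
        )


def confusion(pred: Mapping[str, bool], ref: Mapping[str, bool]) -> ConfusionMatrix:
    """Exact cross-tabulation of two binary patient maps with identical keys."""
    if set(pred) != set(ref):
        diff = sorted(set(pred) ^ set(ref))
        raise ValueError(f"patient key mismatch between prediction and reference: {diff}")
    tp = fn = fp = tn = 0
    for pid, r in ref.items():
        p = pred[pid]
        if r and p:
            tp += 1
        elif r and not p:
            fn += 1
        elif p:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fn, fp, tn)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Unweighted Cohen kappa: (p_o - p_e) / (1 - p_e) from the 2x2 margins."""
    n = cm.total
    p_o = (cm.tp + cm.tn) / n
    ref_pos = (cm.tp + cm.fn) / n
    pred_pos = (cm.tp + cm.fp) / n
    p_e = ref_pos * pred_pos + (1 - ref_pos) * (1 - pred_pos)
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0  # degenerate single-category table with perfect agreement
        raise ValueError("kappa undefined: chance agreement is 1 but observed is not")
    return (p_o - p_e) / (1 - p_e)


@dataclass(frozen=True)
class MetricReport:
    """Diagnostic metrics, raw; ``None`` marks an undefined (0-denominator) metric."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: float
    agreement: float
    kappa: float

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(
            name
            for name in ("sensitivity", "specificity", "ppv", "npv")
            if getattr(self, name) is None
        )

    def display(self) -> dict[str, Optional[float]]:
        """Paper-style rounded values: integer %, kappa/agreement to 2 dp."""
        out: dict[str, Optional[float]] = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, name)
            out[name] = None if v is None else round_half_away(100 * v)
        out["agreement"] = round_half_away(self.agreement, 2)
        out["kappa"] = round_half_away(self.kappa, 2)
        return out


def diagnostic_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Sensitivity/specificity/PPV/NPV/accuracy plus kappa and agreement."""

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    accuracy = (cm.tp + cm.tn) / cm.total
    return MetricReport(
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        ppv=ratio(cm.tp, cm.tp + cm.fp),
        npv=ratio(cm.tn, cm.tn + cm.fn),
        accuracy=accuracy,
        agreement=accuracy,
        kappa=cohen_kappa(cm),
    )


@dataclass(frozen=True)
class OddsRatioResult:
    oddsratio: float
    ci_low: float
    ci_high: float

    def display(self) -> tuple[float, float, float]:
        return (
            round_half_away(self.oddsratio, 1),
            round_half_away(self.ci_low, 1),
            round_half_away(self.ci_high, 1),
        )


def odds_ratio_wald(t: TwoByTwo, haldane: bool = False) -> OddsRatioResult:
    """Cross-product odds ratio with a Wald 95% CI on the log scale.

    With ``haldane`` a zero cell triggers the Haldane-Anscombe +0.5 correction
    on all four cells; otherwise a zero cell is an error.
    """
    a, b, c, d = (float(v) for v in t.cells())
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 cells must be non-negative")
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError("zero cell in 2x2 table; pass haldane=True to correct")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oddsratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        oddsratio=oddsratio,
        ci_low=math.exp(math.log(oddsratio) - Z_95 * se),
        ci_high=math.exp(math.log(oddsratio) + Z_95 * se),
    )


@dataclass(frozen=True)
class FunnelReport:
    cohort_size: int
    stages: tuple[tuple[str, int], ...]
    eligible_n: int

    def lines(self) -> list[str]:
        out = [f"cohort: {self.cohort_size}"]
        out += [f"excluded ({label}): {count}" for label, count in self.stages]
        out.append(f"eligible: {self.eligible_n}")
        return out


def eligibility_funnel(
    cohort_size: int, exclusion_counts: Sequence[tuple[str, int]]
) -> FunnelReport:
    """Sequential, mutually exclusive exclusion accounting for a study cohort."""
    if cohort_size < 0:
        raise ValueError("cohort_size must be non-negative")
    total_excluded = 0
    for label, count in exclusion_counts:
        if count < 0:
            raise ValueError(f"negative exclusion count for {label!r}")
        total_excluded += count
    if total_excluded > cohort_size:
        raise ValueError(
            f"exclusions ({total_excluded}) exceed cohort size ({cohort_size})"
        )
    return FunnelReport(
        cohort_size=cohort_size,
        stages=tuple((str(l), int(c)) for l, c in exclusion_counts),
        eligible_n=cohort_size - total_excluded,
    )


def render_validation_report(
    cm: ConfusionMatrix,
    or_rows: Sequence[tuple[str, OddsRatioResult]] = (),
) -> str:
    """Human-readable concordance (and optional risk-factor) report."""
    rep = diagnostic_metrics(cm)
    disp = rep.display()

    def pct(name: str) -> str:
        v = disp[name]
        return "undefined" if v is None else f"{v:.0f}"

    lines = [
        "Concordance with reference standard",
        "-----------------------------------",
        f"                 algorithm+   algorithm-",
        f"reference+       {cm.tp:>10d}   {cm.fn:>10d}",
        f"reference-       {cm.fp:>10d}   {cm.tn:>10d}",
        "",
        f"kappa       = {disp['kappa']:.2f}",
        f"agreement   = {disp['agreement']:.2f}",
        f"sensitivity = {pct('sensitivity')}%",
        f"specificity = {pct('specificity')}%",
        f"PPV         = {pct('ppv')}%",
        f"NPV         = {pct('npv')}%",
        f"accuracy    = {pct('accuracy')}%",
    ]
    if or_rows:
        lines += ["", "Risk-factor associations (OR, Wald 95% CI)",
                  "------------------------------------------"]
        for label, res in or_rows:
            o, lo, hi = res.display()
            lines.append(f"{label:<24s} {o:.1f} ({lo:.1f}, {hi:.1f})")
    return "\n".join(lines) + "\n"
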