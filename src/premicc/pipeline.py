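"""End-to-end validation of the score on a cohort.

The analysis surface is exposed statsmodels-style: a
:class:`CohortValidation` model is built from a schema-valid
:class:`~premicc.cohort_io.CohortDataset`; :meth:`~CohortValidation.fit`
runs scoring -> event derivation -> survival -> diagnostics in that
order and returns a :class:`ValidationResults` object carrying the
stratum-wise Kaplan-Meier curves, the log-rank comparison, horizon
diagnostics with Wilson intervals, the ROC, the week-8 escalation
proportions, and the baseline-table comparisons, with a
``summary()`` table and JSON/CSV rendering.

Everything is deterministic given the dataset.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import diagnostics as diag
from . import survival as surv
from .cohort_io import CohortDataset
from .events import (
    DEFAULT_EVENT_CONFIG,
    EventConfig,
    TimeToEventRecord,
    assess_week8_escalation,
    build_tte_dataset,
)
from .scoring import BaselineRecord, PreMiCCResult, RiskClass, compute_score

__all__ = ["CohortValidation", "ValidationResults", "run_validation", "render_report"]

_STRATA = (RiskClass.MILD_PREDICTED, RiskClass.SEVERE_PREDICTED)


@dataclass
class HorizonDiagnostics:
    horizon_months: float
    confusion: diag.ConfusionMatrix
    metrics: diag.DiagnosticSummary
    wilson_cis: dict[str, Optional[tuple[float, float]]]
    roc: Optional[diag.RocResult]
    odds: Optional[diag.OddsRatioResult]


@dataclass
class ValidationResults:
    """Fitted validation analysis of one cohort."""

    n_total: int
    stratum_sizes: dict[str, int]
    score_distribution: dict[str, dict[int, int]]
    week8_overall: float
    week8_by_stratum: dict[str, Optional[float]]
    tte: list[TimeToEventRecord]
    km_curves: dict[str, Optional[surv.SurvivalCurve]]
    escalation_by_month: dict[str, dict[float, Optional[float]]]
    logrank: Optional[surv.LogRankResult]
    horizon_diagnostics: list[HorizonDiagnostics]
    baseline_comparisons: list[diag.ComparisonResult]
    horizons: tuple[float, ...]
    proportion_months: tuple[float, ...]

    def summary(self) -> str:
        """Human-readable report (percentages to one decimal)."""
        lines = []
        w = lines.append
        w("PreMiCC cohort validation")
        w("=" * 60)
        w(f"Patients: {self.n_total}  "
          f"(score <=2: {self.stratum_sizes['mild_predicted']}, "
          f"score >2: {self.stratum_sizes['severe_predicted']})")
        w(f"Week-8 escalation: {100 * self.week8_overall:.1f}% overall")
        for key, label in (("mild_predicted", "score <=2"), ("severe_predicted", "score >2")):
            v = self.week8_by_stratum.get(key)
            if v is not None:
                w(f"  {label}: {100 * v:.1f}%")
        w("")
        w("Escalation proportions (1 - KM survival):")
        header = "  month   " + "".join(f"{m:>10.0f}" for m in self.proportion_months)
        w(header)
        for key, label in (("mild_predicted", "score<=2"), ("severe_predicted", "score>2 ")):
            row = f"  {label}"
            for m in self.proportion_months:
                v = self.escalation_by_month[key].get(m)
                row += f"{100 * v:>9.1f}%" if v is not None else "        --"
            w(row)
        if self.logrank is not None:
            p = self.logrank.p_value
            w("")
            w(f"Log-rank: chi2 = {self.logrank.chi_square:.2f}, "
              f"p = {'<.001' if p < 0.001 else f'{p:.3f}'}")
        for hd in self.horizon_diagnostics:
            w("")
            w(f"Diagnostics at month {hd.horizon_months:.0f} "
              f"(complete-case n = {hd.confusion.total}):")
            m = hd.metrics
            for name, v in (
                ("sensitivity", m.sensitivity),
                ("specificity", m.specificity),
                ("PPV", m.ppv),
                ("NPV", m.npv),
            ):
                w(f"  {name:>12}: " + (f"{100 * v:.1f}%" if v is not None else "undefined"))
            if hd.roc is not None:
                w(f"  {'AUC':>12}: {hd.roc.auc:.3f}")
            if hd.odds is not None:
                w(f"  {'OR':>12}: {hd.odds.odds_ratio:.2f} "
                  f"({hd.odds.ci_lower:.2f}-{hd.odds.ci_upper:.2f})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """Full-precision machine-readable report."""
        def curve_dict(c: Optional[surv.SurvivalCurve]):
            if c is None:
                return None
            return {
                "time_months": c.event_times.tolist(),
                "at_risk": c.at_risk.tolist(),
                "events": c.events.tolist(),
                "survival": c.survival.tolist(),
                "se": c.greenwood_se.tolist(),
                "ci_lower": c.ci_lower.tolist(),
                "ci_upper": c.ci_upper.tolist(),
                "n_initial": c.n_initial,
            }

        return {
            "n_total": self.n_total,
            "stratum_sizes": self.stratum_sizes,
            "score_distribution": {
                k: {str(t): n for t, n in sorted(v.items())}
                for k, v in self.score_distribution.items()
            },
            "week8": {
                "overall": self.week8_overall,
                "by_stratum": self.week8_by_stratum,
            },
            "escalation_by_month": {
                k: {str(m): v for m, v in d.items()}
                for k, d in self.escalation_by_month.items()
            },
            "km_curves": {k: curve_dict(c) for k, c in self.km_curves.items()},
            "logrank": None
            if self.logrank is None
            else {
                "chi_square": self.logrank.chi_square,
                "p_value": self.logrank.p_value,
                "observed": list(self.logrank.observed),
                "expected": list(self.logrank.expected),
            },
            "diagnostics": [
                {
                    "horizon_months": hd.horizon_months,
                    "cells": {
                        "tp": hd.confusion.tp,
                        "fp": hd.confusion.fp,
                        "fn": hd.confusion.fn,
                        "tn": hd.confusion.tn,
                    },
                    "metrics": {
                        "sensitivity": hd.metrics.sensitivity,
                        "specificity": hd.metrics.specificity,
                        "ppv": hd.metrics.ppv,
                        "npv": hd.metrics.npv,
                    },
                    "wilson_95ci": {
                        k: (list(v) if v is not None else None)
                        for k, v in hd.wilson_cis.items()
                    },
                    "auc": None if hd.roc is None else hd.roc.auc,
                    "roc_points": None
                    if hd.roc is None
                    else [list(p) for p in hd.roc.points],
                    "odds_ratio": None
                    if hd.odds is None
                    else {
                        "or": hd.odds.odds_ratio,
                        "ci": [hd.odds.ci_lower, hd.odds.ci_upper],
                    },
                }
                for hd in self.horizon_diagnostics
            ],
            "baseline_comparisons": [
                {
                    "variable": c.variable,
                    "test": c.test_name,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "significant": c.significant,
                }
                for c in self.baseline_comparisons
            ],
        }


class CohortValidation:
    """Validation model for a scored inception cohort.

    Parameters
    ----------
    dataset : CohortDataset
        Schema-valid cohort (nonempty; every patient has a timeline).
    horizons : tuple of float
        Months at which horizon diagnostics (2x2, metrics, ROC, OR)
        are computed.
    proportion_months : tuple of float
        Months at which per-stratum KM escalation proportions are
        reported.
    event_config : EventConfig
        Escalation-definition parameters.
    """

    def __init__(
        self,
        dataset: CohortDataset,
        horizons: Sequence[float] = (36.0, 48.0),
        proportion_months: Sequence[float] = (12.0, 24.0, 36.0),
        event_config: EventConfig = DEFAULT_EVENT_CONFIG,
    ) -> None:
        if len(dataset) == 0:
            raise ValueError("cannot validate an empty cohort")
        missing = [pid for pid in dataset.patient_ids if pid not in dataset.timelines]
        if missing:
            raise ValueError(f"patients without timelines: {missing[:5]}")
        self.dataset = dataset
        self.horizons = tuple(float(h) for h in horizons)
        self.proportion_months = tuple(float(m) for m in proportion_months)
        self.event_config = event_config

    def fit(self) -> ValidationResults:
        ds = self.dataset
        scores: list[PreMiCCResult] = [compute_score(r) for r in ds.baseline]
        by_class: dict[RiskClass, list[PreMiCCResult]] = {s: [] for s in _STRATA}
        for s in scores:
            by_class[s.risk_class].append(s)
        stratum_sizes = {s.value: len(by_class[s]) for s in _STRATA}
        score_distribution = {
            s.value: dict(Counter(r.total for r in by_class[s])) for s in _STRATA
        }

        # week-8 escalation
        cls_by_id = {s.patient_id: s.risk_class for s in scores}
        flags = {
            pid: assess_week8_escalation(t, self.event_config)
            for pid, t in ds.timelines.items()
        }
        week8_overall = sum(flags.values()) / len(flags)
        week8_by_stratum: dict[str, Optional[float]] = {}
        for s in _STRATA:
            ids = [pid for pid in flags if cls_by_id[pid] is s]
            week8_by_stratum[s.value] = (
                sum(flags[pid] for pid in ids) / len(ids) if ids else None
            )

        # time-to-event analysis
        tte = build_tte_dataset(ds, scores, self.event_config)
        groups = {s: [r for r in tte if r.risk_class is s] for s in _STRATA}
        km_curves: dict[str, Optional[surv.SurvivalCurve]] = {}
        escalation: dict[str, dict[float, Optional[float]]] = {}
        for s in _STRATA:
            curve = surv.km_fit(groups[s]) if groups[s] else None
            km_curves[s.value] = curve
            escalation[s.value] = {
                m: (1.0 - surv.survival_at(curve, m)) if curve is not None else None
                for m in self.proportion_months
            }
        logrank = (
            surv.logrank_test(groups[RiskClass.SEVERE_PREDICTED],
                              groups[RiskClass.MILD_PREDICTED])
            if all(groups[s] for s in _STRATA)
            else None
        )

        # horizon diagnostics
        total_by_id = {s.patient_id: s.total for s in scores}
        horizon_diags = []
        for h in self.horizons:
            cm = diag.confusion_at_horizon(tte, h)
            metrics = diag.diagnostic_metrics(cm, h)
            wilson = {
                "sensitivity": self._wilson(cm.tp, cm.tp + cm.fn),
                "specificity": self._wilson(cm.tn, cm.tn + cm.fp),
                "ppv": self._wilson(cm.tp, cm.tp + cm.fp),
                "npv": self._wilson(cm.tn, cm.tn + cm.fn),
            }
            # complete-case score/outcome pairs for the ROC at this horizon
            pairs = []
            for r in tte:
                if r.event and r.time_months <= h:
                    pairs.append((total_by_id[r.patient_id], False))
                elif r.time_months >= h:
                    pairs.append((total_by_id[r.patient_id], True))
            classes = {m for _, m in pairs}
            roc = diag.roc_auc(pairs) if len(classes) == 2 else None
            odds = None
            n_hi = cm.tn + cm.fn  # severe-predicted, complete case
            n_lo = cm.tp + cm.fp
            if n_hi > 0 and n_lo > 0:
                odds = diag.odds_ratio(cm.tn, n_hi, cm.fp, n_lo)
            horizon_diags.append(
                HorizonDiagnostics(
                    horizon_months=h,
                    confusion=cm,
                    metrics=metrics,
                    wilson_cis=wilson,
                    roc=roc,
                    odds=odds,
                )
            )

        # baseline-table comparisons (high-score vs low-score stratum)
        base_by_class: dict[RiskClass, list[BaselineRecord]] = {s: [] for s in _STRATA}
        for rec in ds.baseline:
            base_by_class[cls_by_id[rec.patient_id]].append(rec)
        comparisons: list[diag.ComparisonResult] = []
        if all(base_by_class[s] for s in _STRATA):
            for var in diag.NUMERIC_VARIABLES + diag.CATEGORICAL_VARIABLES:
                comparisons.append(
                    diag.compare_baseline(
                        base_by_class[RiskClass.SEVERE_PREDICTED],
                        base_by_class[RiskClass.MILD_PREDICTED],
                        var,
                    )
                )

        return ValidationResults(
            n_total=len(ds),
            stratum_sizes=stratum_sizes,
            score_distribution=score_distribution,
            week8_overall=week8_overall,
            week8_by_stratum=week8_by_stratum,
            tte=tte,
            km_curves=km_curves,
            escalation_by_month=escalation,
            logrank=logrank,
            horizon_diagnostics=horizon_diags,
            baseline_comparisons=comparisons,
            horizons=self.horizons,
            proportion_months=self.proportion_months,
        )

    @staticmethod
    def _wilson(successes: int, n: int) -> Optional[tuple[float, float]]:
        return diag.wilson_interval(successes, n) if n > 0 else None


def run_validation(
    dataset: CohortDataset,
    horizons: Sequence[float] = (36.0, 48.0),
    proportion_months: Sequence[float] = (12.0, 24.0, 36.0),
    event_config: EventConfig = DEFAULT_EVENT_CONFIG,
) -> ValidationResults:
    """Convenience wrapper: build the model and fit it."""
    return CohortValidation(
        dataset, horizons=horizons, proportion_months=proportion_months,
        event_config=event_config,
    ).fit()


def render_report(
    results: ValidationResults,
    outdir: str | Path,
    plots: bool = False,
) -> list[Path]:
    """Write the report files; returns the paths written.

    Always writes ``report.json`` (full precision), per-stratum
    ``km_<stratum>.csv``, ``logrank.json``, ``diagnostics.json``,
    ``baseline_comparison.csv`` and ``summary.txt``; with
    ``plots=True`` also KM and ROC figures (fixed styling).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report = results.to_dict()

    p = outdir / "report.json"
    p.write_text(json.dumps(report, indent=2))
    written.append(p)

    for key, curve in results.km_curves.items():
        if curve is None:
            continue
        p = outdir / f"km_{key}.csv"
        pd.DataFrame(
            {
                "time_months": curve.event_times,
                "at_risk": curve.at_risk,
                "events": curve.events,
                "survival": curve.survival,
                "se": curve.greenwood_se,
                "ci_lower": curve.ci_lower,
                "ci_upper": curve.ci_upper,
            }
        ).to_csv(p, index=False)
        written.append(p)

    p = outdir / "logrank.json"
    p.write_text(json.dumps(report["logrank"], indent=2))
    written.append(p)

    p = outdir / "diagnostics.json"
    p.write_text(json.dumps(report["diagnostics"], indent=2))
    written.append(p)

    p = outdir / "baseline_comparison.csv"
    pd.DataFrame(report["baseline_comparisons"]).to_csv(p, index=False)
    written.append(p)

    p = outdir / "summary.txt"
    p.write_text(results.summary() + "\n")
    written.append(p)

    if plots:
        written.extend(_render_plots(results, outdir))
    return written


def _render_plots(results: ValidationResults, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    fig, ax = plt.subplots(figsize=(6, 4))
    labels = {"mild_predicted": "score ≤2", "severe_predicted": "score >2"}
    for key, curve in results.km_curves.items():
        if curve is None:
            continue
        t = np.concatenate([[0.0], np.repeat(curve.event_times, 2)])
        s = np.concatenate([[1.0, 1.0], np.repeat(curve.survival, 2)[:-1]])
        ax.plot(t, s, label=labels.get(key, key))
        ax.fill_between(
            np.concatenate([[0.0], curve.event_times]),
            np.concatenate([[1.0], curve.ci_lower]),
            np.concatenate([[1.0], curve.ci_upper]),
            step="post",
            alpha=0.15,
        )
    ax.set_xlabel("months since baseline")
    ax.set_ylabel("escalation-free proportion")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    p = outdir / "km.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    for hd in results.horizon_diagnostics:
        if hd.roc is None:
            continue
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        xs = [pt[0] for pt in hd.roc.points]
        ys = [pt[1] for pt in hd.roc.points]
        ax.plot(xs, ys, marker="o")
        ax.plot([0, 1], [0, 1], linestyle=":", color="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(
            f"ROC at month {hd.horizon_months:.0f} (AUC = {hd.roc.auc:.3f})"
        )
        fig.tight_layout()
        p = outdir / f"roc_{hd.horizon_months:.0f}.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    return written
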