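"""Descriptive group summaries, the two-sample t-test on suture durations,
and the human-readable run report.

The t-test is computed from summary statistics (means, sample SDs, counts) so
that printed group summaries can be fed straight in; the pooled variant is
the default and agrees to 1e-10 with the same test computed from raw values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import json
import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .classify import CVReport
from .simulate import SutureTimeline

__all__ = [
    "GroupSummary",
    "TTestResult",
    "summarize_groups",
    "two_sample_t",
    "duration_t_test",
    "render_report",
    "report_json",
]


@dataclass
class GroupSummary:
    group: str
    n_sutures: int
    duration_mean: float
    duration_sd: float
    blink_rate_mean: float
    blink_rate_sd: float


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    variant: str
    infinite: bool = False  # zero pooled variance with unequal means


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if len(values) == 0:
        return np.nan, np.nan
    if len(values) == 1:
        return float(values[0]), np.nan  # spread undefined from one suture
    return float(values.mean()), float(values.std(ddof=1))


def summarize_groups(
    suture_df: pd.DataFrame, timelines: Iterable[SutureTimeline]
) -> list[GroupSummary]:
    """Per-group duration and blink-rate means/SDs over successful sutures."""
    durs = {
        (tl.participant_id, tl.slot, tl.suture_index): tl.duration
        for tl in timelines
        if tl.success
    }
    out = []
    for group in ("expert", "novice"):
        sub = suture_df[suture_df["group"] == group]
        if sub.empty:
            out.append(GroupSummary(group, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        d = np.array(
            [
                durs[(r.participant_id, r.slot, r.suture_index)]
                for r in sub.itertuples()
                if (r.participant_id, r.slot, r.suture_index) in durs
            ]
        )
        dm, ds = _mean_sd(d)
        bm, bs = _mean_sd(sub["blink_rate"].to_numpy(dtype=float))
        out.append(GroupSummary(group, len(sub), dm, ds, bm, bs))
    return out


def two_sample_t(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> TTestResult:
    """Two-tailed two-sample t-test from summary statistics.

    ``pooled``: t = (mean2 - mean1) / (s_p * sqrt(1/n1 + 1/n2)) with s_p^2 the
    df-weighted pooled variance and df = n1 + n2 - 2.  ``welch``: unpooled
    variances with Welch-Satterthwaite df.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    diff = mean2 - mean1
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variant == "welch":
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        denom = np.sqrt(v1 + v2)
        if v1 + v2 > 0:
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        else:
            df = n1 + n2 - 2
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    if denom == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=float(df), p=1.0, variant=variant)
        return TTestResult(
            t=np.inf if diff > 0 else -np.inf, df=float(df), p=0.0,
            variant=variant, infinite=True,
        )
    t = diff / denom
    p = float(2.0 * t_dist.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=p, variant=variant)


def duration_t_test(
    summaries: list[GroupSummary], variant: str = "pooled"
) -> TTestResult:
    """Expert-vs-novice suture-duration t-test from group summaries."""
    by = {s.group: s for s in summaries}
    e, n = by["expert"], by["novice"]
    return two_sample_t(
        e.duration_mean, e.duration_sd, e.n_sutures,
        n.duration_mean, n.duration_sd, n.n_sutures,
        variant=variant,
    )


def _fmt(x: float, nd: int = 3) -> str:
    return "nan" if not np.isfinite(x) else f"{x:.{nd}f}"


def render_report(
    summaries: list[GroupSummary],
    cv_reports: list[CVReport],
    t_result: TTestResult | None = None,
    majority: float | None = None,
) -> str:
    """Deterministic Markdown report: group summaries, the duration t-test,
    and one metric table per classification scheme."""
    lines = ["# Expertise-classification run report", ""]
    lines += ["## Group summaries", ""]
    lines += ["| group | n sutures | duration mean (s) | duration SD | blink rate mean (/min) | blink rate SD |",
              "|---|---|---|---|---|---|"]
    for s in sorted(summaries, key=lambda s: s.group):
        lines.append(
            f"| {s.group} | {s.n_sutures} | {_fmt(s.duration_mean, 1)} | "
            f"{_fmt(s.duration_sd, 1)} | {_fmt(s.blink_rate_mean, 2)} | "
            f"{_fmt(s.blink_rate_sd, 2)} |"
        )
    lines.append("")
    if t_result is not None:
        lines += [
            "## Suture-duration t-test (novice - expert)",
            "",
            f"t({t_result.df:.0f}) = {t_result.t:.2f}, two-tailed p = {t_result.p:.2e}"
            f" ({t_result.variant})",
            "",
        ]
    if majority is not None:
        lines += [f"Majority-class baseline accuracy: {100 * majority:.1f}%", ""]
    if cv_reports:
        lines += ["## Classification results", ""]
        for rep in sorted(cv_reports, key=lambda r: (r.scheme, r.left_out or "")):
            lines.append(f"### {rep.scheme}" + (f" (left out {rep.left_out})" if rep.left_out else ""))
            lines.append("")
            lines.append("| metric | mean | 95% CI |")
            lines.append("|---|---|---|")
            for m in rep.means:
                lines.append(
                    f"| {m} | {_fmt(rep.means[m])} | "
                    f"[{_fmt(rep.ci_low[m])}, {_fmt(rep.ci_high[m])}] |"
                )
            lines.append(
                f"\n{rep.n_folds_scored} folds, {rep.n_rows} rows, seed {rep.seed}\n"
            )
    return "\n".join(lines) + "\n"


def report_json(
    summaries: list[GroupSummary],
    cv_reports: list[CVReport],
    t_result: TTestResult | None = None,
    majority: float | None = None,
) -> str:
    """Machine-readable companion to :func:`render_report`."""
    payload = {
        "group_summaries": [vars(s) for s in sorted(summaries, key=lambda s: s.group)],
        "duration_t_test": (vars(t_result) if t_result else None),
        "majority_baseline": majority,
        "cv_reports": [
            rec
            for rep in sorted(cv_reports, key=lambda r: (r.scheme, r.left_out or ""))
            for rec in rep.as_records()
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
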