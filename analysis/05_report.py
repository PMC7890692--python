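#!/usr/bin/env python
"""Summarize the run.

Computes per-group suture-duration and blink-rate summaries, the pooled
two-sample duration t-test, and renders the Markdown + JSON report combining
them with the classification tables.
"""

import argparse
from pathlib import Path

import pandas as pd

from gazemetrics import io as gio
from gazemetrics.classify import CVReport, majority_baseline
from gazemetrics.stats import duration_t_test, render_report, report_json, summarize_groups


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    suture_df = gio.read_features(args.out_dir / "features_suture.csv")
    timelines = gio.read_timelines(args.out_dir / "timelines.csv")
    summaries = summarize_groups(suture_df, timelines)
    t_res = duration_t_test(summaries)
    maj = majority_baseline(suture_df["group"].to_numpy())
    for s in summaries:
        print(f"{s.group}: {s.n_sutures} sutures, duration "
              f"{s.duration_mean:.1f} s (SD {s.duration_sd:.1f}), blink rate "
              f"{s.blink_rate_mean:.2f}/min (SD {s.blink_rate_sd:.2f})")
    print(f"duration t({t_res.df:.0f}) = {t_res.t:.2f}, p = {t_res.p:.2e}")

    cv = pd.read_csv(args.out_dir / "cv_reports.csv")
    reports = []
    for (scheme, left_out), sub in cv.groupby(
        ["scheme", cv["left_out"].fillna("")], sort=True
    ):
        reports.append(
            CVReport(
                scheme=scheme,
                means={r.metric: r.mean for r in sub.itertuples()},
                ci_low={r.metric: r.ci_low for r in sub.itertuples()},
                ci_high={r.metric: r.ci_high for r in sub.itertuples()},
                n_folds_scored=int(sub["n_folds"].iloc[0]),
                seed=int(sub["seed"].iloc[0]),
                n_rows=int(sub["n_rows"].iloc[0]),
                left_out=str(left_out) or None,
            )
        )
    (args.out_dir / "report.md").write_text(
        render_report(summaries, reports, t_res, maj)
    )
    (args.out_dir / "report.json").write_text(
        report_json(summaries, reports, t_res, maj)
    )
    print(f"wrote {args.out_dir / 'report.md'} and report.json")


if __name__ == "__main__":
    main()
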