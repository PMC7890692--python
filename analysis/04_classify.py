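#!/usr/bin/env python
"""Classify expertise from the feature tables.

Evaluates the SVM (C = 0.25, RBF) under every scheme: per-segment
(APCPS, SDPCPS) classifiers, the 21-feature suture scheme, the pupil-only
variant, block-wise PCA (4 + 4 components + blink rate), and
leave-one-participant-out.  Also reports the exponential C grid search.
Writes cv_reports.csv.
"""

import argparse
from pathlib import Path

from gazemetrics import io as gio
from gazemetrics.classify import (
    evaluate_lopo,
    evaluate_repeated_kfold,
    grid_search_C,
    majority_baseline,
    scheme_matrix,
)
from gazemetrics.config import ClassifierConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    cfg = ClassifierConfig(seed=args.seed)
    suture_df = gio.read_features(args.out_dir / "features_suture.csv")
    segment_df = gio.read_segment_features(args.out_dir / "features_segment.csv")
    maj = majority_baseline(suture_df["group"].to_numpy())
    print(f"majority baseline {100 * maj:.1f}% over {len(suture_df)} sutures")

    X, y, pids, _ = scheme_matrix(suture_df, "suture", segment_df)
    best_c, table = grid_search_C(X, y, cfg)
    print(f"grid search over {len(table)} C values -> best C = {best_c:g} "
          f"(pipeline uses C = {cfg.C:g} throughout)")

    reports = []
    schemes = ["suture", "suture_pca", "suture_pupil_only"] + [
        f"segment:{lb}" for lb in segment_df["segment_label"].unique()
    ]
    for scheme in schemes:
        X, y, pids, use_pca = scheme_matrix(suture_df, scheme, segment_df)
        rep = evaluate_repeated_kfold(X, y, cfg, scheme, use_pca)
        reports.append(rep)
        print(f"{scheme:28s} accuracy {rep.means['accuracy']:.3f} "
              f"[{rep.ci_low['accuracy']:.3f}, {rep.ci_high['accuracy']:.3f}]")

    X, y, pids, _ = scheme_matrix(suture_df, "suture", segment_df)
    lopo = evaluate_lopo(X, y, pids, cfg)
    reports.extend(lopo)
    accs = [r.means["accuracy"] for r in lopo]
    print(f"leave-one-participant-out: {len(lopo)} reports, accuracy "
          f"{min(accs):.3f}..{max(accs):.3f}")

    gio.write_cv_reports(args.out_dir / "cv_reports.csv", reports)


if __name__ == "__main__":
    main()
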