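#!/usr/bin/env python
"""Extract the PCPS and blink features.

Computes one baseline per task-board slot (200-frame pre-suture window),
normalizes the pupil signal to PCPS = (X - mu)/mu, reduces each of the 10
segments to (APCPS, SDPCPS), appends the per-suture blink rate, imputes
missing segments from same-label donors, and writes the suture-level
(21 features) and segment-level tables.
"""

import argparse
from pathlib import Path

from gazemetrics import io as gio
from gazemetrics.features import extract_features


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    utraces = gio.read_processed(args.out_dir / "samples_processed.csv")
    timelines = gio.read_timelines(args.out_dir / "timelines.csv")
    participants = gio.read_participants(args.out_dir / "participants.csv")
    groups = dict(zip(participants["participant_id"], participants["group"]))

    suture_df, segment_df, baselines = extract_features(utraces, timelines, groups)
    gio.write_features(args.out_dir / "features_suture.csv", suture_df)
    gio.write_segment_features(args.out_dir / "features_segment.csv", segment_df)

    n_imputed = int(segment_df["imputed"].sum())
    n_dropped = suture_df.attrs["n_dropped_unsuccessful"]
    print(f"{len(suture_df)} successful sutures x 21 features "
          f"({n_dropped} unsuccessful dropped), {len(segment_df)} segment rows "
          f"({n_imputed} imputed), {len(baselines)} slot baselines")


if __name__ == "__main__":
    main()
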