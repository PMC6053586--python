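"""Window the tracks and compute the six movement features per fix.

Applies the data-quality filters (sampling interval <= 6 s, 11:00-15:00
SAST midday window, segments with >= 5 fixes including 3-s data), then
extracts mean 3D speed, the altitude trend slopes and R^2 pair, and the
heading-periodogram dominant frequency for every 90-s track segment.

Reads results/data/tracks.csv; writes results/features.csv.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from soarscape import track_features as tf

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    track = pd.read_csv(ROOT / "data" / "tracks.csv", parse_dates=["timestamp_utc"])
    fixes = tf.prepare_fixes(track)
    fixes = tf.filter_fixes_for_analysis(fixes)
    print(f"{len(fixes)} fixes inside the midday window at <= 6-s sampling")

    segments = tf.segment_track(fixes)
    kept, removal_log = tf.flag_data_poor_segments(segments, fixes)
    if len(removal_log):
        print("removed data-poor segments:", removal_log["reason"].value_counts().to_dict())
    features = tf.extract_features(kept, fixes)
    features.to_csv(ROOT / "features.csv", index=False)
    print(f"features for {len(features)} segments "
          f"({int(features['missing_any'].sum())} with missing values)")
    print(features.groupby("true_label")[tf.FEATURE_COLUMNS].mean().round(3))


if __name__ == "__main__":
    main()
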