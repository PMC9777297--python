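"""Simulate the 14-participant synthetic EEG cohort and summarise it.

Writes results/cohort_summary.csv (one row per participant: duration, trial
and window counts, measured frontal-alpha-asymmetry contrast via the wavelet
feature path).
"""

import argparse
from pathlib import Path

import pandas as pd

from emodecode import (epoch_windows, extract_timefreq_features, faa_contrast,
                       generate_cohort, reduced_study_config)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--faa-effect", type=float, default=1.5)
    args = ap.parse_args()

    cfg = reduced_study_config(seed=args.seed, faa_effect=args.faa_effect)
    rows = []
    for rec in generate_cohort(cfg):
        ws = epoch_windows(rec)
        fa = extract_timefreq_features(ws, montage=rec.montage)
        rows.append({
            "participant": rec.participant_id,
            "duration_s": rec.n_samples / rec.sampling_rate,
            "n_trials": len({a.trial_id for a in rec.annotations
                             if a.condition != "neutral"}),
            "n_windows": ws.n_windows,
            "n_features": fa.n_features,
            "faa_contrast": round(faa_contrast(fa), 4),
        })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "cohort_summary.csv", index=False)
    print(df.to_string(index=False))
    print(f"\ninjected FAA contrast delta = {args.faa_effect}; cohort mean "
          f"recovered = {df['faa_contrast'].mean():.3f}")


if __name__ == "__main__":
    main()
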