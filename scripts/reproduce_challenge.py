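#!/usr/bin/env python
"""Optional driver for the public PhysioNet/CinC 2016 heart-sound database.

This script is NOT part of the automated checks: it requires the challenge
training set (3,153 WAV recordings plus reference labels), which must be
downloaded manually from https://physionet.org/content/challenge-2016/ and
unpacked so that a single directory contains the ``*.wav`` files and a
``REFERENCE.csv`` with ``record_id,diagnosis`` rows (plus, optionally, a
``REFERENCE_SQI.csv`` with ``record_id,quality``).

It then runs the full pipeline on the real data: preprocessing, built-in
segmentation, extraction of the 515 features, and the repeated
stratified-split evaluation at training fractions 0.1..0.9.

Usage:
    python scripts/reproduce_challenge.py --data /path/to/training --out results/
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pcgkit import (
    extract_table,
    preprocess,
    read_wav,
    run_split_experiment,
    segment,
    write_feature_table,
)


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, required=True)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--repeats", type=int, default=200)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    wavs = sorted(args.data.glob("*.wav"))
    ref_path = args.data / "REFERENCE.csv"
    if not wavs or not ref_path.exists():
        print(
            f"error: {args.data} does not look like an unpacked challenge set\n"
            "(expected *.wav files and REFERENCE.csv; see the module docstring "
            "for the manual download step)",
            file=sys.stderr,
        )
        return 2

    refs = pd.read_csv(ref_path, header=None, names=["record_id", "diagnosis"]).set_index(
        "record_id"
    )
    sqi_path = args.data / "REFERENCE_SQI.csv"
    if sqi_path.exists():
        refs["quality"] = pd.read_csv(
            sqi_path, header=None, names=["record_id", "quality"]
        ).set_index("record_id")["quality"]
    else:
        refs["quality"] = 1  # no quality annotations: treat all as clean

    recs, segs, kept = [], [], []
    for path in wavs:
        rec = preprocess(read_wav(path))
        try:
            seg = segment(rec)
        except Exception as exc:  # noqa: BLE001 - per-record failure flag
            print(f"skipping {path.stem}: segmentation failed ({exc})", file=sys.stderr)
            continue
        recs.append(rec)
        segs.append(seg)
        kept.append(path.stem)

    table = extract_table(recs, segs)
    args.out.mkdir(parents=True, exist_ok=True)
    write_feature_table(table, args.out / "challenge_features.csv")

    refs = refs.loc[kept]
    rows = []
    for tf in np.arange(0.1, 1.0, 0.1):
        summary = run_split_experiment(
            table, refs, float(tf), repeats=args.repeats, seed=args.seed
        )
        rows.append(
            {
                "train_fraction": round(float(tf), 1),
                "se": f"{summary.se_mean:.2f}±{summary.se_sd:.2f}",
                "sp": f"{summary.sp_mean:.2f}±{summary.sp_sd:.2f}",
                "overall": f"{summary.overall_mean:.2f}±{summary.overall_sd:.2f}",
            }
        )
        print(rows[-1])
    pd.DataFrame(rows).to_csv(args.out / "challenge_scores.csv", index=False)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
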