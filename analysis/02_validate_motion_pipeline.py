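#!/usr/bin/env python
"""Validate the video -> motion -> coordination path on rendered toy videos.

Two checks: (1) coordination traces recovered from rendered two-blob videos
against traces computed directly on the generating signals; (2) the paired
block-vs-constant coupling comparison showing that coupling volatility, not
mean coupling, drives IBC variability.
"""

import argparse
from pathlib import Path

from coordsam.validation import endtoend_video_recovery, volatility_sensitivity

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

e2e = endtoend_video_recovery(n_seeds=10, seed=args.seed, n_frames=900)
e2e.to_csv(args.out / "video_recovery.csv", index=False)
print("End-to-end recovery (10 rendered 64x128 videos, 900 frames):")
print(f"  median trace correlation = {e2e['trace_correlation'].median():.4f}")
print(f"  worst  trace correlation = {e2e['trace_correlation'].min():.4f}")

vol = volatility_sensitivity(n_reps=50, seed=args.seed + 1)
vol.to_csv(args.out / "volatility_sensitivity.csv", index=False)
wins = int(vol["block_wins"].sum())
print("\nPaired coupling-volatility comparison (50 replicates):")
print(f"  block-alternating coupling produced higher IBC variability in {wins}/50")
print(f"  mean variability: block {vol['block'].mean():.3f} vs constant {vol['const'].mean():.3f}")
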