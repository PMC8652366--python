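#!/usr/bin/env python
"""Fit the social accuracy model on one study-scale simulated dataset.

Draws a full rating study (105 targets, 94 perceivers in 8 viewing subsets,
24 items), fits the cross-classified model with IBC variability moderating
the distinctive and normative accuracy slopes, and reports the coefficient
table, simple slopes at the four +/-1 SD probe combinations, and the 2-SD
moderation effect size with its Wald interval.
"""

import argparse
from pathlib import Path

import pandas as pd

from coordsam.sam import effect_size_d, simple_slopes
from coordsam.simulate import StudyGenConfig
from coordsam.validation import fit_simulated_study

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

fit, truth, frame = fit_simulated_study(StudyGenConfig(seed=args.seed))
table = fit.fixed_effects.copy()
table["generating"] = pd.Series(truth["gamma"])
table.rename_axis("term").reset_index().to_csv(args.out / "sam_coefficients.csv", index=False)

print(f"rows: {fit.result.n_obs}, converged: {fit.converged}")
print(table.round(4).to_string())

rows = []
print("\nDistinctive-accuracy simple slopes:")
for o in (-1.0, 1.0):
    for m in (-1.0, 1.0):
        s = simple_slopes(
            fit, "distinctive", observability_level=o,
            moderator_levels={"ibc_variability": m},
        )
        rows.append({"observability_sd": o, "moderator_sd": m, **{k: s[k] for k in ("estimate", "se", "z", "p")}})
        print(
            f"  obs {o:+.0f} SD, IBC variability {m:+.0f} SD: "
            f"b = {s['estimate']:.3f}, z = {s['z']:.2f}, p = {s['p']:.2g}"
        )
pd.DataFrame(rows).to_csv(args.out / "sam_simple_slopes.csv", index=False)

d = effect_size_d(fit, "ibc_variability", observability_level=1.0)
print(
    f"\nModeration effect at high observability: b = {d['b']:.3f}, "
    f"d = {d['d']:.2f}, 95% CI [{d['ci_low']:.2f}, {d['ci_high']:.2f}]"
)
print("(d = 2-SD change in the distinctive slope / SD of target-level slopes)")
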