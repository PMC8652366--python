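"""End-to-end orchestration: video/motion -> coordination -> accuracy model.

A single YAML (or dict) run configuration selects exactly one input mode —

* ``simulate``    — draw a full synthetic study (optionally linking a
                    simulated motion arm to the rating arm by rank-matching
                    IBC variability to targets);
* ``motion_csv``  — precomputed per-target motion series plus rating CSVs;
* ``video``       — raw videos with per-target head/body ROIs plus rating
                    CSVs;

and runs whatever stages its inputs require, producing a reproducible
:class:`RunReport` (coefficients with z/p, simple slopes at the four
+/-1 SD observability x moderator probe combinations, the 2-SD effect size
with Wald CI, empirical-Bayes accuracy scores, per-target IBC summaries and
cohort descriptives).  Identical config + seed yields a byte-identical
numeric report payload.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coordination import (
    CMAConfig,
    IBCSummary,
    cohort_descriptives,
    instantaneous_correlation,
    summarize_ibc,
    write_ibc_csv,
)
from .criteria import assemble_long_data, build_accuracy_criterion, prepare_observability
from .motion import ROISpec, compute_motion_magnitude, extract_roi_motion, read_motion_csv, read_video
from .sam import SAMSpec, effect_size_d, empirical_bayes_accuracy, fit_sam, simple_slopes
from .simulate import StudyGenConfig, simulate_personality_study

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    mode: str  # simulate | motion_csv | video
    seed: int = 0
    out_dir: str | None = None
    simulation: dict = field(default_factory=dict)  # StudyGenConfig overrides
    link_motion: bool = False  # simulate mode: derive the moderator from signals
    ratings: dict = field(default_factory=dict)  # paths: self/other/perceptions/observability
    motion: dict = field(default_factory=dict)  # target_id -> motion CSV prefix
    videos: dict = field(default_factory=dict)  # target_id -> {path, roi_head, roi_body, frame_rate}
    cma: dict = field(default_factory=dict)  # CMAConfig overrides
    moderator_name: str = "ibc_variability"
    covariates: tuple[str, ...] = ()
    include_video_length: bool = False  # add video length (s) as a covariate
    reml: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "motion_csv", "video"):
            raise ValueError(f"unknown run mode {self.mode!r}")
        if self.mode != "simulate" and not self.ratings:
            raise ValueError(f"mode {self.mode!r} requires rating CSV paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        cfg = cls(**payload)
        for key in ("ratings",):
            for name, p in cfg.ratings.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} file not found: {p}")
        return cfg


@dataclass
class RunReport:
    coefficients: pd.DataFrame
    random_sds: dict
    simple_slopes: dict
    effect_size: dict
    ibc_summaries: list[IBCSummary] | None
    ibc_descriptives: dict | None
    eb_slopes: pd.DataFrame | None
    converged: bool
    provenance: dict

    def payload(self) -> dict:
        out = {
            "coefficients": {
                name: {
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "z": row["z"],
                    "p": row["p"],
                }
                for name, row in self.coefficients.iterrows()
            },
            "random_sds": self.random_sds,
            "simple_slopes": self.simple_slopes,
            "effect_size": self.effect_size,
            "converged": self.converged,
            "provenance": self.provenance,
        }
        if self.ibc_descriptives is not None:
            out["ibc_descriptives"] = self.ibc_descriptives
        return out

    def to_json(self) -> str:
        return json.dumps(self.payload(), sort_keys=True, indent=2, allow_nan=True)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage context."""
    class _Ctx:
        def __enter__(self):
            return self
        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r}: {exc}") from exc
            return False
    return _Ctx()


class _StageError(RuntimeError):
    pass


def _motion_to_ibc(config: RunConfig) -> tuple[list[IBCSummary], dict[str, float]]:
    cma = CMAConfig(**config.cma) if config.cma else CMAConfig()
    summaries, lengths = [], {}
    if config.mode == "video":
        for tid, spec in sorted(config.videos.items()):
            with _stage(f"motion[{tid}]"):
                stack = read_video(spec["path"], spec.get("frame_rate"))
                roi_h = ROISpec("head", *spec["roi_head"])
                roi_b = ROISpec("body", *spec["roi_body"])
                if roi_h.overlaps(roi_b):
                    raise ValueError(f"target {tid}: head and body ROIs overlap")
                grids = compute_motion_magnitude(stack, spec.get("method", "framediff"))
                head = extract_roi_motion(grids, roi_h, stack.frame_rate)
                body = extract_roi_motion(grids, roi_b, stack.frame_rate)
                lengths[tid] = stack.n_frames / stack.frame_rate
            with _stage(f"coordination[{tid}]"):
                series = instantaneous_correlation(head, body, cma)
                summaries.append(summarize_ibc(series, tid))
    else:  # motion_csv
        for tid, prefix in sorted(config.motion.items()):
            with _stage(f"coordination[{tid}]"):
                pair = read_motion_csv(prefix)
                series = instantaneous_correlation(pair["head"], pair["body"], cma)
                summaries.append(summarize_ibc(series, tid))
                lengths[tid] = (len(pair["head"]) + 1) / pair["head"].frame_rate
    return summaries, lengths


def _load_ratings(config: RunConfig) -> dict[str, pd.DataFrame]:
    paths = config.ratings
    out = {}
    for key in ("self_reports", "other_reports", "perceptions", "observability"):
        if key in paths:
            out[key] = pd.read_csv(paths[key])
    for required in ("self_reports", "perceptions", "observability"):
        if required not in out:
            raise ValueError(f"ratings config must provide {required!r}")
    out.setdefault("other_reports", None)
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages and assemble a reproducible report."""
    moderator = config.moderator_name
    ibc_summaries = ibc_desc = None
    video_lengths: dict[str, float] = {}

    if config.mode == "simulate":
        with _stage("simulate"):
            gen = StudyGenConfig(seed=config.seed, **config.simulation)
            study = simulate_personality_study(gen)
        tables = study
        moderators_df = study["moderators"]
        if config.link_motion:
            with _stage("link_motion"):
                moderators_df, ibc_summaries = _simulated_motion_arm(
                    gen, moderators_df, config
                )
        moderator = gen.moderator_name
    else:
        with _stage("ratings"):
            tables = _load_ratings(config)
        summaries, video_lengths = _motion_to_ibc(config)
        ibc_summaries = summaries
        moderators_df = pd.DataFrame(
            {
                "target_id": [s.target_id for s in summaries],
                "name": moderator,
                "value": [s.variability for s in summaries],
            }
        )

    if ibc_summaries is not None and len(ibc_summaries) >= 3:
        ibc_desc = cohort_descriptives(ibc_summaries)

    with _stage("criteria"):
        criteria = build_accuracy_criterion(
            tables["self_reports"], tables["other_reports"]
        )
        obs = prepare_observability(tables["observability"])

    covariate_df = None
    cov_names = list(config.covariates)
    if config.include_video_length and video_lengths:
        covariate_df = pd.DataFrame(
            {
                "target_id": list(video_lengths),
                "name": "video_length",
                "value": list(video_lengths.values()),
            }
        )
        cov_names.append("video_length")

    with _stage("assemble"):
        frame = assemble_long_data(
            tables["perceptions"], criteria, obs,
            moderators=moderators_df, covariates=covariate_df,
        )

    with _stage("fit"):
        spec = SAMSpec(
            moderators=(moderator,), covariates=tuple(cov_names), reml=config.reml
        )
        fit = fit_sam(frame, spec)

    slopes = {}
    for o_lv in (-1.0, 0.0, 1.0):
        for m_lv in (-1.0, 0.0, 1.0):
            key = f"distinctive@obs{o_lv:+.0f}sd_mod{m_lv:+.0f}sd"
            slopes[key] = simple_slopes(
                fit, "distinctive",
                observability_level=o_lv, moderator_levels={moderator: m_lv},
            )
    effect = {
        f"obs{o_lv:+.0f}sd": effect_size_d(fit, moderator, observability_level=o_lv)
        for o_lv in (-1.0, 0.0, 1.0)
    }

    eb = None
    try:
        eb = pd.concat(
            [
                empirical_bayes_accuracy(frame, spec, subset)
                for subset in ("low_obs", "high_obs")
            ],
            ignore_index=True,
        )
    except ValueError:
        pass  # too few items on one side of the observability split

    report = RunReport(
        coefficients=fit.fixed_effects,
        random_sds={
            f"{fac}_{term}_sd": fit.result.re_sd(fac, term)
            for fac in ("target", "perceiver")
            for term in ("intercept", "distinctive", "normative")
        }
        | {"residual_sd": float(np.sqrt(fit.result.sigma2))},
        simple_slopes=slopes,
        effect_size=effect,
        ibc_summaries=ibc_summaries,
        ibc_descriptives=ibc_desc,
        eb_slopes=eb,
        converged=fit.converged,
        provenance={
            "package": "coordsam",
            "version": __version__,
            "seed": config.seed,
            "mode": config.mode,
            "reml": config.reml,
            "used_diagonal_fallback": fit.used_diagonal,
        },
    )
    if config.out_dir:
        _write_outputs(report, frame, moderator, Path(config.out_dir))
    return report


def _simulated_motion_arm(gen: StudyGenConfig, moderators_df, config: RunConfig):
    """Replace drawn moderator values by IBC variability computed from
    simulated coupled signals, rank-matched to the drawn values."""
    from .simulate import CouplingProfile, simulate_coupled_signals

    cma = CMAConfig(**config.cma) if config.cma else CMAConfig()
    rng = np.random.default_rng(gen.seed + 1)
    summaries = []
    n_frames = 1800
    for tid in moderators_df["target_id"]:
        base = rng.uniform(0.55, 0.95)
        amp = rng.uniform(0.0, min(1.0 - base, base))
        period = rng.integers(4 * cma.window_frames, 12 * cma.window_frames)
        phase = rng.uniform(0, 2 * np.pi)
        rho = np.clip(
            base + amp * np.sin(2 * np.pi * np.arange(n_frames) / period + phase),
            -1.0, 1.0,
        )
        head, body = simulate_coupled_signals(
            n_frames, CouplingProfile(rho=rho), seed=int(rng.integers(2**31))
        )
        series = instantaneous_correlation(head, body, cma)
        summaries.append(summarize_ibc(series, tid))
    drawn = moderators_df.set_index("target_id")["value"]
    computed = pd.Series(
        {s.target_id: s.variability for s in summaries}, name="value"
    )
    # rank-preserving assignment: i-th largest drawn value -> i-th largest IBC
    order_drawn = drawn.sort_values().index
    assigned = pd.Series(
        np.sort(computed.to_numpy()), index=order_drawn, name="value"
    ).reindex(drawn.index)
    out = moderators_df.copy()
    out["value"] = assigned.to_numpy()
    return out, summaries


def _write_outputs(
    report: RunReport, frame: pd.DataFrame, moderator: str, out_dir: Path
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(report.to_json())
    report.coefficients.rename_axis("term").reset_index().to_csv(
        out_dir / "coefficients.csv", index=False
    )
    if report.ibc_summaries:
        write_ibc_csv(report.ibc_summaries, out_dir / "ibc_summaries.csv")
    if report.eb_slopes is not None:
        report.eb_slopes.to_csv(out_dir / "eb_slopes.csv", index=False)
        _scatter_figure(report.eb_slopes, frame, moderator, out_dir)


def _scatter_figure(eb, frame, moderator, out_dir: Path) -> None:
    """EB accuracy vs moderator, one panel per item subset, with linear fit."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mod = frame.drop_duplicates("target_id").set_index("target_id")[moderator]
    subsets = sorted(eb["item_subset"].unique())
    fig, axes = plt.subplots(1, len(subsets), figsize=(5 * len(subsets), 4), squeeze=False)
    for ax, subset in zip(axes[0], subsets):
        sub = eb[eb["item_subset"] == subset]
        x = mod.loc[sub["target_id"]].to_numpy()
        y = sub["eb_distinctive_slope"].to_numpy()
        ax.scatter(x, y, s=12, alpha=0.7)
        if len(x) > 2 and np.std(x) > 0:
            b, a = np.polyfit(x, y, 1)
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, a + b * xs, color="black")
        ax.set_xlabel(f"{moderator} (standardized)")
        ax.set_ylabel("EB distinctive slope")
        ax.set_title(subset)
    fig.tight_layout()
    fig.savefig(out_dir / "eb_slopes.png", dpi=120)
    plt.close(fig)
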