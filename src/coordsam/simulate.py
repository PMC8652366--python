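"""Synthetic inputs for every pipeline stage.

Three generators:

* :func:`simulate_coupled_signals` — paired head/body motion series whose
  instantaneous coupling follows a prescribed profile rho(t), the test
  harness for the correlation-map stage;
* :func:`render_synthetic_video` — a toy two-blob video whose per-frame
  blob displacements are driven by those signals, for end-to-end checks of
  the motion-extraction -> coordination path;
* :func:`simulate_personality_study` — full target/perceiver/item rating
  datasets drawn from the social accuracy model's own generating equation,
  with declared fixed effects, random-effect SDs, and residual noise.

The study generator inverts the fitted model exactly: the distinctive and
normative predictors entering the linear predictor are computed from the
*emitted* self/other/observability tables by the same criterion-building
code the analyst runs, so with all noise terms at zero the fitted
coefficients equal the generating ones to numerical precision.

Scale defaults mirror the study design this package targets: 105 targets in
8 viewing subsets, 94 perceivers (10-16 viewing each target), 24 items
(21 Big Five Inventory items plus 3 intelligence items) on a 1-7 scale, and
a log-normal IBC-variability moderator matched to cohort moments
M = 0.19, SD = 0.06.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .criteria import build_accuracy_criterion, prepare_observability
from .motion import FrameStack, MotionSeries, ROISpec

__all__ = [
    "CouplingProfile",
    "BlobGeometry",
    "StudyGenConfig",
    "simulate_coupled_signals",
    "render_synthetic_video",
    "simulate_personality_study",
]


@dataclass
class CouplingProfile:
    """Time-varying head-body coupling rho(t) plus noise/smoothness settings."""

    rho: np.ndarray
    noise_sd: float = 1.0
    smoothness: float = 0.9  # AR(1) coefficient of the base motion processes

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if np.any(np.abs(self.rho) > 1.0) or not np.all(np.isfinite(self.rho)):
            raise ValueError("coupling rho(t) must lie in [-1, 1] and be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.smoothness < 1.0):
            raise ValueError("smoothness must lie in [0, 1)")

    @classmethod
    def constant(cls, rho: float, n_frames: int, **kw) -> "CouplingProfile":
        return cls(rho=np.full(n_frames, rho), **kw)

    @classmethod
    def blocks(
        cls, rho_high: float, rho_low: float, n_frames: int, block_len: int, **kw
    ) -> "CouplingProfile":
        """Coupling alternating between high and low blocks of fixed length."""
        idx = (np.arange(n_frames) // block_len) % 2
        return cls(rho=np.where(idx == 0, rho_high, rho_low), **kw)


def _ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized AR(1) path: stationary variance 1."""
    innov_sd = np.sqrt(1.0 - phi * phi) if phi > 0 else 1.0
    x = np.empty(n)
    x[0] = rng.normal()
    eps = rng.normal(scale=innov_sd, size=n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def simulate_coupled_signals(
    n_frames: int,
    profile: CouplingProfile,
    seed: int,
    baseline: float = 3.0,
) -> tuple[MotionSeries, MotionSeries]:
    """Head/body motion series with instantaneous coupling rho(t).

    head is a smoothed, rectified positive process; body mixes the head
    signal with an independent smoothed noise process:
    ``body = rho * head + (1 - |rho|) * noise``, rectified at zero.
    Identical seeds give bit-identical output.
    """
    if len(profile.rho) != n_frames:
        raise ValueError(
            f"coupling profile length {len(profile.rho)} != n_frames {n_frames}"
        )
    rng = np.random.default_rng(seed)
    head = np.clip(baseline + _ar1(n_frames, profile.smoothness, rng), 0.0, None)
    noise = np.clip(
        baseline + profile.noise_sd * _ar1(n_frames, profile.smoothness, rng),
        0.0,
        None,
    )
    body = np.clip(profile.rho * head + (1.0 - np.abs(profile.rho)) * noise, 0.0, None)
    roi_h = ROISpec("head", 0, 0, 64, 64)
    roi_b = ROISpec("body", 0, 64, 64, 128)
    return (
        MotionSeries(values=head, roi=roi_h, frame_rate=30.0),
        MotionSeries(values=body, roi=roi_b, frame_rate=30.0),
    )


@dataclass(frozen=True)
class BlobGeometry:
    """Layout of the rendered toy video: head blob above, body blob below."""

    rows: int = 128
    cols: int = 64
    head_roi: tuple[int, int, int, int] = (0, 0, 64, 64)  # x0, y0, x1, y1
    body_roi: tuple[int, int, int, int] = (0, 64, 64, 128)
    blob_sigma: float = 4.0
    max_step: float = 1.2  # largest per-frame displacement, px
    travel: float = 16.0  # half-range of horizontal blob travel, px


def _render_blob_track(
    signal: np.ndarray, roi: ROISpec, geom: BlobGeometry
) -> np.ndarray:
    """Horizontal sub-pixel blob positions whose steps are ∝ the signal."""
    smax = float(np.max(signal))
    steps = signal * (geom.max_step / smax) if smax > 0 else np.zeros_like(signal)
    cx = (roi.x0 + roi.x1) / 2.0
    margin = 3.0 * geom.blob_sigma
    if cx - geom.travel - margin < roi.x0 or cx + geom.travel + margin > roi.x1:
        raise ValueError("blob travel range escapes its ROI; shrink travel or sigma")
    pos = np.empty(len(signal) + 1)
    pos[0], direction = cx, 1.0
    for t, s in enumerate(steps):
        nxt = pos[t] + direction * s
        if abs(nxt - cx) > geom.travel:
            direction = -direction
            nxt = pos[t] + direction * s
        pos[t + 1] = nxt
    return pos


def render_synthetic_video(
    head: MotionSeries,
    body: MotionSeries,
    geometry: BlobGeometry | None = None,
) -> tuple[FrameStack, ROISpec, ROISpec]:
    """Render two Gaussian blobs moving proportionally to the input signals.

    The series hold per-transition motion, so a length-L pair yields L+1
    frames.  Blob displacements bounce inside a fixed travel range so the
    blobs never leave their ROIs.
    """
    if len(head) != len(body):
        raise ValueError("head and body signals must have equal length")
    geom = geometry or BlobGeometry()
    roi_h = ROISpec("head", *geom.head_roi)
    roi_b = ROISpec("body", *geom.body_roi)
    if roi_h.overlaps(roi_b):
        raise ValueError("head and body ROIs overlap")
    px = _render_blob_track(head.values, roi_h, geom)
    pb = _render_blob_track(body.values, roi_b, geom)
    yy, xx = np.mgrid[0 : geom.rows, 0 : geom.cols]
    cy_h = (roi_h.y0 + roi_h.y1) / 2.0
    cy_b = (roi_b.y0 + roi_b.y1) / 2.0
    s2 = 2.0 * geom.blob_sigma**2
    frames = np.empty((len(px), geom.rows, geom.cols))
    for t in range(len(px)):
        f = 255.0 * np.exp(-((xx - px[t]) ** 2 + (yy - cy_h) ** 2) / s2)
        f += 255.0 * np.exp(-((xx - pb[t]) ** 2 + (yy - cy_b) ** 2) / s2)
        frames[t] = f
    stack = FrameStack(frames=frames, frame_rate=head.frame_rate)
    return stack, roi_h, roi_b


# ---------------------------------------------------------------------------
# rating-study generator


@dataclass
class StudyGenConfig:
    """Generating values for a full rating study.

    The gamma dictionary is keyed by the fitter's design-column names; the
    defaults form an internally coherent set that reproduces the magnitude
    and pattern of published social-accuracy moderation findings (base
    distinctive slope .12 rising to ~.16 on highly observable items, a
    normative slope ~.64 falling with observability, and a positive
    moderator x distinctive x observability term).
    """

    n_targets: int = 105
    n_perceivers: int = 94
    n_subsets: int = 8
    n_items: int = 24
    gamma: dict = field(
        default_factory=lambda: {
            "intercept": 4.0,
            "distinctive": 0.12,
            "normative": 0.64,
            "observability": 0.05,
            "distinctive:observability": 0.046,
            "normative:observability": -0.233,
            "ibc_variability": 0.0,
            "ibc_variability:distinctive": 0.025,
            "ibc_variability:normative": 0.0,
            "ibc_variability:observability": 0.0,
            "ibc_variability:distinctive:observability": 0.05,
            "ibc_variability:normative:observability": 0.0,
        }
    )
    moderator_name: str = "ibc_variability"
    target_sds: tuple[float, float, float] = (0.4, 0.23, 0.2)  # intercept, D, N
    perceiver_sds: tuple[float, float, float] = (0.5, 0.10, 0.25)
    residual_sd: float = 1.0
    normative_mean: float = 4.4
    normative_sd: float = 0.8
    distinctive_sd: float = 1.0  # per-item deviation of true profiles
    self_report_sd: float = 0.0
    other_report_sd: float = 0.5
    n_other_probs: tuple[float, ...] = (0.27, 0.30, 0.25, 0.18)  # P(0..3 reports)
    n_obs_raters: int = 106
    obs_profile_mean: float = 4.0
    obs_profile_sd: float = 0.9
    obs_rater_sd: float = 1.0
    # log-normal IBC variability matched to cohort moments M=.19, SD=.06
    moderator_lognorm_mu: float = -1.7083
    moderator_lognorm_sigma: float = 0.3084
    clip_ratings: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 4:
            raise ValueError("n_items must be >= 4")
        sds = self.target_sds + self.perceiver_sds + (self.residual_sd,)
        if any(s < 0 for s in sds):
            raise ValueError("all SDs must be >= 0")
        if abs(sum(self.n_other_probs) - 1.0) > 1e-9:
            raise ValueError("n_other_probs must sum to 1")


def simulate_personality_study(config: StudyGenConfig) -> dict:
    """Draw one complete study: the five input tables plus a truth sidecar.

    Returns a dict with keys ``self_reports``, ``other_reports``,
    ``perceptions``, ``observability``, ``moderators`` (tidy DataFrames in
    the package's CSV conventions) and ``truth`` (the generating gammas,
    variance components, per-target random effects and design bookkeeping).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    targets = [f"t{j:03d}" for j in range(cfg.n_targets)]
    perceivers = [f"p{i:03d}" for i in range(cfg.n_perceivers)]
    items = [f"item{k:02d}" for k in range(cfg.n_items)]

    # true profiles: normative backbone + per-item distinctive deviations
    nu = rng.normal(cfg.normative_mean, cfg.normative_sd, size=cfg.n_items)
    true_profiles = nu[None, :] + rng.normal(
        0.0, cfg.distinctive_sd, size=(cfg.n_targets, cfg.n_items)
    )

    self_wide = true_profiles + rng.normal(
        0.0, cfg.self_report_sd, size=true_profiles.shape
    )
    self_reports = pd.DataFrame(
        {
            "target_id": np.repeat(targets, cfg.n_items),
            "item_id": items * cfg.n_targets,
            "value": self_wide.ravel(),
        }
    )

    n_others = rng.choice(len(cfg.n_other_probs), size=cfg.n_targets, p=cfg.n_other_probs)
    other_rows = []
    for j, cnt in enumerate(n_others):
        for r in range(cnt):
            vals = true_profiles[j] + rng.normal(
                0.0, cfg.other_report_sd, size=cfg.n_items
            )
            for k, item in enumerate(items):
                other_rows.append(
                    {
                        "target_id": targets[j],
                        "rater_id": f"{targets[j]}_o{r}",
                        "item_id": item,
                        "value": vals[k],
                    }
                )
    other_reports = pd.DataFrame(
        other_rows, columns=["target_id", "rater_id", "item_id", "value"]
    )

    # observability: integer 1-7 rater responses around a true item profile
    true_obs = rng.normal(cfg.obs_profile_mean, cfg.obs_profile_sd, size=cfg.n_items)
    raw = 8.0 - (
        true_obs[None, :]
        + rng.normal(0.0, cfg.obs_rater_sd, size=(cfg.n_obs_raters, cfg.n_items))
    )
    raw = np.clip(np.rint(raw), 1, 7)
    observability = pd.DataFrame(
        {
            "rater_id": np.repeat([f"obs{r:03d}" for r in range(cfg.n_obs_raters)], cfg.n_items),
            "item_id": items * cfg.n_obs_raters,
            "value": raw.ravel(),
        }
    )

    # analyst-side quantities, computed exactly as the fitter will
    criteria = build_accuracy_criterion(self_reports, other_reports)
    obs_profile = prepare_observability(observability)
    D = criteria.distinctive.loc[targets, items].to_numpy()
    N = criteria.normative.loc[items].to_numpy()
    O = obs_profile.centered.loc[items].to_numpy()

    m_raw = rng.lognormal(
        cfg.moderator_lognorm_mu, cfg.moderator_lognorm_sigma, size=cfg.n_targets
    )
    m_std = (m_raw - m_raw.mean()) / m_raw.std(ddof=1)
    moderators = pd.DataFrame(
        {
            "target_id": targets,
            "name": cfg.moderator_name,
            "value": m_raw,
        }
    )

    # viewing design: targets and perceivers dealt round-robin into subsets
    t_subset = np.arange(cfg.n_targets) % cfg.n_subsets
    p_subset = np.arange(cfg.n_perceivers) % cfg.n_subsets

    u = rng.normal(size=(cfg.n_targets, 3)) * np.array(cfg.target_sds)
    v = rng.normal(size=(cfg.n_perceivers, 3)) * np.array(cfg.perceiver_sds)

    g = cfg.gamma
    mname = cfg.moderator_name
    rows_p, rows_t, rows_k, y_all = [], [], [], []
    for i in range(cfg.n_perceivers):
        viewed = np.where(t_subset == p_subset[i])[0]
        for j in viewed:
            lp = (
                g["intercept"]
                + g["distinctive"] * D[j]
                + g["normative"] * N
                + g["observability"] * O
                + g["distinctive:observability"] * D[j] * O
                + g["normative:observability"] * N * O
                + g[mname] * m_std[j]
                + g[f"{mname}:distinctive"] * m_std[j] * D[j]
                + g[f"{mname}:normative"] * m_std[j] * N
                + g[f"{mname}:observability"] * m_std[j] * O
                + g[f"{mname}:distinctive:observability"] * m_std[j] * D[j] * O
                + g[f"{mname}:normative:observability"] * m_std[j] * N * O
                + u[j, 0] + u[j, 1] * D[j] + u[j, 2] * N
                + v[i, 0] + v[i, 1] * D[j] + v[i, 2] * N
            )
            yk = lp + rng.normal(0.0, cfg.residual_sd, size=cfg.n_items)
            rows_p.append(np.full(cfg.n_items, i))
            rows_t.append(np.full(cfg.n_items, j))
            rows_k.append(np.arange(cfg.n_items))
            y_all.append(yk)
    y = np.concatenate(y_all)
    if cfg.clip_ratings:
        y = np.clip(y, 1.0, 7.0)
    perceptions = pd.DataFrame(
        {
            "perceiver_id": [perceivers[i] for i in np.concatenate(rows_p)],
            "target_id": [targets[j] for j in np.concatenate(rows_t)],
            "item_id": [items[k] for k in np.concatenate(rows_k)],
            "value": y,
        }
    )

    truth = {
        "gamma": dict(g),
        "target_sds": list(cfg.target_sds),
        "perceiver_sds": list(cfg.perceiver_sds),
        "residual_sd": cfg.residual_sd,
        "moderator_name": cfg.moderator_name,
        "moderator_raw": dict(zip(targets, m_raw.tolist())),
        "target_random_effects": {
            t: u[j].tolist() for j, t in enumerate(targets)
        },
        "true_profiles": {t: true_profiles[j].tolist() for j, t in enumerate(targets)},
        "observability_centered": dict(zip(items, O.tolist())),
        "observability_profile_sd": obs_profile.sd,
        "seed": cfg.seed,
        "n_rows": int(len(perceptions)),
    }
    return {
        "self_reports": self_reports,
        "other_reports": other_reports,
        "perceptions": perceptions,
        "observability": observability,
        "moderators": moderators,
        "truth": truth,
    }
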