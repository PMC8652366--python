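"""The social accuracy model (SAM) with observability and target moderators.

A cross-classified multilevel regression of perceiver ratings Y_ijk
(perceiver i, target j, item k) on the target's distinctive criterion D_jk
and the normative profile N_k, with the centered item-observability profile
O_k as a level-1 moderator and target-level quantities M_j (e.g. IBC
variability) as level-2 moderators of both accuracy slopes:

    Y_ijk = g0 + gD D + gN N + gO O + gDO D O + gNO N O
          + sum_M [ gM M + gMD M D + gMN M N + gMO M O
                    + gMDO M D O + gMNO M N O ]
          + u0j + uDj D + uNj N          (target random effects)
          + v0i + vDi D + vNi N          (perceiver random effects)
          + e_ijk

Random intercepts and D/N slopes vary for targets and perceivers (crossed),
with an unstructured covariance within each factor; observability
interactions are fixed-only.  REML is the default; p values use the normal
reference for z = estimate/SE.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .lmm import CrossedLMM, LMMResult, RandomFactor

__all__ = [
    "SAMSpec",
    "SAMFit",
    "fit_sam",
    "simple_slopes",
    "effect_size_d",
    "empirical_bayes_accuracy",
    "design_columns",
]

_BASE = [
    "intercept",
    "distinctive",
    "normative",
    "observability",
    "distinctive:observability",
    "normative:observability",
]
_RANDOM_TERMS = ["intercept", "distinctive", "normative"]


@dataclass(frozen=True)
class SAMSpec:
    """Fixed/random structure and estimation settings for one SAM fit."""

    moderators: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    reml: bool = True
    diagonal_fallback: bool = True  # retry with diagonal RE covariance on failure
    include_observability: bool = True


@dataclass
class SAMFit:
    """A fitted SAM: the LMM result plus probe metadata."""

    result: LMMResult
    spec: SAMSpec
    observability_sd: float
    moderator_scales: dict[str, dict]
    used_diagonal: bool = False

    @property
    def converged(self) -> bool:
        return self.result.converged

    @property
    def fixed_effects(self) -> pd.DataFrame:
        return self.result.summary_frame()

    @property
    def target_distinctive_slope_sd(self) -> float:
        return self.result.re_sd("target", "distinctive")

    def coefficient(self, name: str) -> float:
        return float(self.result.fe_params[name])


def design_columns(spec: SAMSpec) -> list[str]:
    cols = list(_BASE) if spec.include_observability else _BASE[:3]
    for m in list(spec.moderators) + list(spec.covariates):
        cols += [m, f"{m}:distinctive", f"{m}:normative"]
        if spec.include_observability:
            cols += [
                f"{m}:observability",
                f"{m}:distinctive:observability",
                f"{m}:normative:observability",
            ]
    return cols


def _build_design(frame: pd.DataFrame, spec: SAMSpec) -> tuple[np.ndarray, list[str]]:
    n = len(frame)
    D = frame["distinctive"].to_numpy(dtype=float)
    N = frame["normative"].to_numpy(dtype=float)
    cols = {"intercept": np.ones(n), "distinctive": D, "normative": N}
    if spec.include_observability:
        O = frame["observability"].to_numpy(dtype=float)
        cols["observability"] = O
        cols["distinctive:observability"] = D * O
        cols["normative:observability"] = N * O
    for m in list(spec.moderators) + list(spec.covariates):
        M = frame[m].to_numpy(dtype=float)
        cols[m] = M
        cols[f"{m}:distinctive"] = M * D
        cols[f"{m}:normative"] = M * N
        if spec.include_observability:
            cols[f"{m}:observability"] = M * cols["observability"]
            cols[f"{m}:distinctive:observability"] = M * D * cols["observability"]
            cols[f"{m}:normative:observability"] = M * N * cols["observability"]
    names = design_columns(spec)
    X = np.column_stack([cols[c] for c in names])
    return X, names


def _factor(frame: pd.DataFrame, id_col: str, name: str) -> RandomFactor:
    codes, levels = pd.factorize(frame[id_col], sort=True)
    design = np.column_stack(
        [
            np.ones(len(frame)),
            frame["distinctive"].to_numpy(dtype=float),
            frame["normative"].to_numpy(dtype=float),
        ]
    )
    return RandomFactor(
        name=name, codes=codes, levels=np.asarray(levels), design=design,
        term_names=list(_RANDOM_TERMS),
    )


def fit_sam(
    frame: pd.DataFrame,
    spec: SAMSpec | None = None,
    start_theta: np.ndarray | None = None,
    reuse_theta: bool = False,
) -> SAMFit:
    """Fit the SAM on a frame from :func:`coordsam.criteria.assemble_long_data`.

    Non-convergence of the unstructured random-covariance fit triggers one
    retry with diagonal within-factor covariances (when enabled); the
    result's ``converged`` flag is always reported honestly.  ``start_theta``
    warm-starts the variance-parameter search (useful when refitting an
    equivalent reparameterization, e.g. recentered predictors).  With
    ``reuse_theta=True`` the variance parameters are held at ``start_theta``
    and only the fixed effects are re-solved — exact for reparameterizations
    (such as recentering a moderator) under which theta is invariant.
    """
    spec = spec or SAMSpec()
    for m in list(spec.moderators) + list(spec.covariates):
        if m not in frame.columns:
            raise ValueError(f"moderator {m!r} not present in the model frame")
    X, names = _build_design(frame, spec)
    y = frame["y"].to_numpy(dtype=float)
    factors = [
        _factor(frame, "target_id", "target"),
        _factor(frame, "perceiver_id", "perceiver"),
    ]
    model = CrossedLMM(X, y, factors, names, reml=spec.reml)
    if reuse_theta:
        if start_theta is None:
            raise ValueError("reuse_theta requires start_theta")
        result = model.fit(diagonal=False, start=start_theta, maxiter=0)
    else:
        result = model.fit(diagonal=False, start=start_theta)
    used_diagonal = False
    if not result.converged and spec.diagonal_fallback:
        fallback = model.fit(diagonal=True)
        if fallback.converged or fallback.deviance < result.deviance:
            result, used_diagonal = fallback, True
    return SAMFit(
        result=result,
        spec=spec,
        observability_sd=float(frame.attrs.get("observability_sd", 0.0)),
        moderator_scales=dict(frame.attrs.get("moderator_scales", {})),
        used_diagonal=used_diagonal,
    )


def _slope_contrast(
    fit: SAMFit,
    accuracy: str,
    observability_level: float,
    moderator_levels: dict[str, float],
) -> np.ndarray:
    """Contrast vector picking out the probed accuracy slope."""
    names = list(fit.result.fe_params.index)
    c = np.zeros(len(names))
    o = observability_level * fit.observability_sd
    def add(term: str, w: float) -> None:
        if term in names:
            c[names.index(term)] += w
    add(accuracy, 1.0)
    add(f"{accuracy}:observability", o)
    for m, lv in moderator_levels.items():
        add(f"{m}:{accuracy}", lv)
        add(f"{m}:{accuracy}:observability", lv * o)
    return c


def simple_slopes(
    fit: SAMFit,
    accuracy: str = "distinctive",
    observability_level: float = 0.0,
    moderator_levels: dict[str, float] | None = None,
) -> dict:
    """Probe an accuracy slope at chosen moderator/observability levels.

    ``observability_level`` is in item-profile SD units (+1 = one SD above
    the item mean); moderator levels are on their standardized (per-SD)
    entry scale, so +/-1 corresponds to +/-1 SD across targets.
    """
    if not fit.converged:
        raise RuntimeError("refusing to probe slopes of a non-converged fit")
    if accuracy not in ("distinctive", "normative"):
        raise ValueError("accuracy must be 'distinctive' or 'normative'")
    if observability_level != 0.0 and fit.observability_sd == 0.0:
        raise ValueError("observability profile has zero SD; probing disabled")
    moderator_levels = moderator_levels or {}
    for m in moderator_levels:
        if m not in fit.spec.moderators and m not in fit.spec.covariates:
            raise ValueError(f"moderator {m!r} not in the fitted spec")
    c = _slope_contrast(fit, accuracy, observability_level, moderator_levels)
    est = float(c @ fit.result.fe_params.to_numpy())
    se = float(np.sqrt(c @ fit.result.fe_cov.to_numpy() @ c))
    z = est / se if se > 0 else np.nan
    return {
        "estimate": est,
        "se": se,
        "z": z,
        "p": float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        "observability_level": observability_level,
        "moderator_levels": dict(moderator_levels),
    }


def effect_size_d(
    fit: SAMFit,
    moderator: str,
    accuracy: str = "distinctive",
    observability_level: float = 0.0,
) -> dict:
    """Moderation effect size comparable to Cohen's d, with a 95% Wald CI.

    The raw change is the difference in the probed accuracy slope for a
    2-SD increase in the moderator (which enters standardized, so the
    change is ``2 * g_mod`` at the probed observability level).  It is
    standardized by the SD of the target-level random accuracy slopes,
    the model's own scale for how much targets differ in expressive
    accuracy.  The CI carries the Wald SE of the moderation coefficient
    through the same linear scaling, hence is symmetric around d.
    """
    if moderator not in fit.spec.moderators and moderator not in fit.spec.covariates:
        raise ValueError(f"moderator {moderator!r} not in the fitted spec")
    names = list(fit.result.fe_params.index)
    c = np.zeros(len(names))
    c[names.index(f"{moderator}:{accuracy}")] = 1.0
    key3 = f"{moderator}:{accuracy}:observability"
    if key3 in names:
        c[names.index(key3)] = observability_level * fit.observability_sd
    g = float(c @ fit.result.fe_params.to_numpy())
    se_g = float(np.sqrt(c @ fit.result.fe_cov.to_numpy() @ c))
    slope_sd = fit.result.re_sd("target", accuracy)
    if slope_sd < 1e-10:
        return {
            "b": g, "d": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "reason": "zero target-level accuracy-slope variance",
        }
    scale = 2.0 / slope_sd
    d = scale * g
    half = 1.96 * scale * se_g
    return {
        "b": g,
        "d": d,
        "ci_low": d - half,
        "ci_high": d + half,
        "se_b": se_g,
        "slope_sd": slope_sd,
        "observability_level": observability_level,
    }


def empirical_bayes_accuracy(
    frame: pd.DataFrame,
    spec: SAMSpec | None = None,
    item_subset: str = "all",
) -> pd.DataFrame:
    """Per-target empirical-Bayes distinctive-slope estimates.

    ``item_subset`` selects items below (``"low_obs"``) or above
    (``"high_obs"``) the mean observability (centered profile < 0 vs >= 0),
    refits a moderator-free SAM on that subset, and returns each target's
    conditional-mode distinctive slope: the fixed distinctive effect plus
    the target's predicted random slope.  These are the shrunken accuracy
    scores plotted against IBC variability in downstream figures.
    """
    base = SAMSpec(
        moderators=(), covariates=(),
        reml=(spec.reml if spec else True),
        include_observability=False,
    )
    if item_subset == "low_obs":
        sub = frame[frame["observability"] < 0]
    elif item_subset == "high_obs":
        sub = frame[frame["observability"] >= 0]
    elif item_subset == "all":
        sub = frame
    else:
        raise ValueError("item_subset must be 'low_obs', 'high_obs' or 'all'")
    n_items = sub["item_id"].nunique()
    if n_items < 4:
        raise ValueError(f"item subset {item_subset!r} holds only {n_items} items")
    sub = sub.copy()
    sub.attrs = dict(frame.attrs)
    fit = fit_sam(sub, base)
    gd = fit.coefficient("distinctive")
    modes = fit.result.ranef["target"]["distinctive"]
    return pd.DataFrame(
        {
            "target_id": modes.index,
            "eb_distinctive_slope": gd + modes.to_numpy(),
            "item_subset": item_subset,
        }
    ).reset_index(drop=True)
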