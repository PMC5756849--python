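"""AICc-based multimodel inference over a fitted candidate space.

Akaike weights from Delta-AICc, the 99% confidence set, conditional
model-averaged coefficients with unconditional standard errors, per-covariate
relative importance, model-averaged predictions on the probability scale, and
the per-grouping weight partition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from smoltsurv.glmm import ModelFit, predict_survival
from smoltsurv.model_space import FIXED_ORDER, GROUPING_ORDER

__all__ = [
    "AveragingResult",
    "akaike_weights",
    "average_models",
    "averaged_parameters",
    "averaged_predictions",
    "confidence_set",
    "grouping_weight_table",
]

logger = logging.getLogger(__name__)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Delta-AICc Akaike weights: ``exp(-delta/2)`` normalized to sum to 1.

    The minimum AICc is subtracted before exponentiating (max-shift), so the
    computation is stable for arbitrarily large criterion values.  Non-finite
    entries receive weight 0 with a logged warning.
    """
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("empty AICc list")
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("no finite AICc values")
    if not finite.all():
        logger.warning("%d non-finite AICc values assigned zero weight", (~finite).sum())
    delta = a - a[finite].min()
    w = np.zeros_like(a)
    w[finite] = np.exp(-0.5 * delta[finite])
    return w / w.sum()


def confidence_set(weights: Sequence[float], level: float = 0.99) -> np.ndarray:
    """Membership flags for the smallest weight-ordered set reaching ``level``.

    Models are sorted by descending weight (ties broken by index) and
    accumulated until the running sum first reaches the level; the model that
    crosses the threshold is included.
    """
    w = np.asarray(weights, dtype=float)
    order = np.argsort(-w, kind="stable")
    csum = np.cumsum(w[order])
    n_in = int(np.searchsorted(csum, level - 1e-12)) + 1
    n_in = min(n_in, w.size)
    mask = np.zeros(w.size, dtype=bool)
    mask[order[:n_in]] = True
    return mask


def averaged_parameters(
    fits: Sequence[ModelFit], weights: Sequence[float], set_flags: Sequence[bool]
) -> pd.DataFrame:
    """Conditional model-averaged coefficients over the confidence set.

    For each covariate: the weighted mean of its coefficient over set models
    that contain it (weights renormalized over those models), the
    unconditional standard error
    ``sqrt(sum w'_m (se_m^2 + (beta_m - avg)^2))``, the across-model sd of
    the coefficient, the relative importance (set-renormalized weight mass of
    models containing the covariate), and a two-sided normal p-value.
    """
    w = np.asarray(weights, dtype=float)
    flags = np.asarray(set_flags, dtype=bool)
    if not flags.any():
        raise ValueError("empty confidence set")
    w_set = w[flags] / w[flags].sum()
    set_fits = [f for f, m in zip(fits, flags) if m]

    rows = []
    for name in ("intercept",) + FIXED_ORDER:
        has = np.array([name in f.beta_names for f in set_fits])
        importance = float(w_set[has].sum())
        if not has.any():
            rows.append(
                {
                    "covariate": name,
                    "averaged_beta": np.nan,
                    "unconditional_se": np.nan,
                    "across_model_sd": np.nan,
                    "relative_importance": 0.0,
                    "p_value": np.nan,
                }
            )
            continue
        wc = w_set[has] / w_set[has].sum()
        betas = np.array([f.beta[name] for f, m in zip(set_fits, has) if m])
        ses = np.array(
            [f.se_beta()[f.beta_names.index(name)] for f, m in zip(set_fits, has) if m]
        )
        avg = float(wc @ betas)
        uncond_se = float(np.sqrt(wc @ (ses**2 + (betas - avg) ** 2)))
        sd = float(np.sqrt(wc @ (betas - avg) ** 2))
        z = avg / uncond_se if uncond_se > 0 else np.nan
        p = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else np.nan
        rows.append(
            {
                "covariate": name,
                "averaged_beta": avg,
                "unconditional_se": uncond_se,
                "across_model_sd": sd,
                "relative_importance": importance,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def averaged_predictions(
    fits: Sequence[ModelFit],
    weights: Sequence[float],
    grid: pd.DataFrame,
    conditional_covariate: str | None = None,
) -> np.ndarray:
    """Weighted average of per-model survival predictions on the probability scale.

    Optionally conditioned on a covariate being present in the model
    (weights renormalized over the retained models).
    """
    w = np.asarray(weights, dtype=float)
    if conditional_covariate is not None:
        keep = np.array([conditional_covariate in f.beta_names for f in fits])
        if not keep.any():
            raise ValueError(f"no model contains covariate {conditional_covariate!r}")
        fits = [f for f, m in zip(fits, keep) if m]
        w = w[keep]
    w = w / w.sum()
    out = np.zeros(len(grid))
    for f, wm in zip(fits, w):
        out += wm * predict_survival(f, grid)
    return out


def grouping_weight_table(
    fits: Sequence[ModelFit], weights: Sequence[float], set_flags: Sequence[bool]
) -> pd.DataFrame:
    """Per-grouping partition of the model space (confidence set and full space).

    For every cumulative grouping: model counts, min/max Delta-AICc, and
    summed full-space weight — computed both within the confidence set and
    over all models.  Full-space weight sums across groupings total 1.
    """
    w = np.asarray(weights, dtype=float)
    flags = np.asarray(set_flags, dtype=bool)
    a = np.array([f.aicc for f in fits], dtype=float)
    delta = a - a[np.isfinite(a)].min()
    groups = np.array([f.spec.grouping for f in fits])

    rows = []
    for g in GROUPING_ORDER:
        in_g = groups == g
        in_gs = in_g & flags
        rows.append(
            {
                "grouping": g,
                "n_set": int(in_gs.sum()),
                "n_all": int(in_g.sum()),
                "min_delta_set": float(delta[in_gs].min()) if in_gs.any() else np.nan,
                "max_delta_set": float(delta[in_gs].max()) if in_gs.any() else np.nan,
                "min_delta_all": float(delta[in_g].min()) if in_g.any() else np.nan,
                "max_delta_all": float(delta[in_g].max()) if in_g.any() else np.nan,
                "weight_set": float(w[in_gs].sum()),
                "weight_all": float(w[in_g].sum()),
            }
        )
    return pd.DataFrame(rows).set_index("grouping")


@dataclass
class AveragingResult:
    """Weights, confidence set, averaged coefficients and grouping partition."""

    fits: list[ModelFit]
    level: float
    models: pd.DataFrame = field(repr=False)
    coefficients: pd.DataFrame = field(repr=False)
    groupings: pd.DataFrame = field(repr=False)

    @property
    def weights(self) -> np.ndarray:
        return self.models["weight"].to_numpy()

    @property
    def in_set(self) -> np.ndarray:
        return self.models["in_confidence_set"].to_numpy()

    def set_fits(self) -> list[ModelFit]:
        return [f for f, m in zip(self.fits, self.in_set) if m]

    def set_weights(self) -> np.ndarray:
        w = self.weights[self.in_set]
        return w / w.sum()

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "models": self.models.reset_index().to_dict(orient="records"),
            "coefficients": self.coefficients.reset_index().to_dict(orient="records"),
            "groupings": self.groupings.reset_index().to_dict(orient="records"),
            "fits": [f.to_dict() for f in self.fits],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "AveragingResult":
        d = json.loads(Path(path).read_text())
        return cls(
            fits=[ModelFit.from_dict(fd) for fd in d["fits"]],
            level=d["level"],
            models=pd.DataFrame(d["models"]).set_index("model"),
            coefficients=pd.DataFrame(d["coefficients"]).set_index("covariate"),
            groupings=pd.DataFrame(d["groupings"]).set_index("grouping"),
        )


def average_models(fits: Sequence[ModelFit], level: float = 0.99) -> AveragingResult:
    """Run the full averaging workflow over a list of fitted models.

    Fits flagged non-converged or separated are dropped before weighting
    (with a logged count): an unreliable log-likelihood corrupts every
    weight.
    """
    usable = [f for f in fits if f.converged and not f.separation]
    dropped = len(fits) - len(usable)
    if dropped:
        logger.warning("excluding %d non-converged/separated fits from averaging", dropped)
    if not usable:
        raise ValueError("no usable fits to average")

    a = np.array([f.aicc for f in usable])
    w = akaike_weights(a)
    flags = confidence_set(w, level)
    delta = a - a.min()

    models = pd.DataFrame(
        {
            "model": [f.spec.label for f in usable],
            "grouping": [f.spec.grouping for f in usable],
            "aicc": a,
            "delta_aicc": delta,
            "weight": w,
            "in_confidence_set": flags,
        }
    ).set_index("model")

    return AveragingResult(
        fits=list(usable),
        level=level,
        models=models,
        coefficients=averaged_parameters(usable, w, flags),
        groupings=grouping_weight_table(usable, w, flags),
    )
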