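"""Anchoring latent probit severities onto the 0-to-1 disability-weight scale.

The probit coefficients live on an arbitrary latent scale.  They are
located on the disability-weight scale by a locally weighted regression
(loess) of logit-transformed reference weights on the coefficients of the
anchor states (states with a published reference weight), followed by an
inverse-logit back-transform of the predictions.

Uncertainty is propagated by a parametric bootstrap: on each replicate,
every state's coefficient is redrawn from a normal law centred at its
point estimate with the probit standard error as spread, the loess is
refitted on the anchor states' redrawn coefficients, predictions for all
states are back-transformed to (0, 1), and the 95% uncertainty interval
is read off the 2.5th/97.5th percentiles of the replicate weights.  The
point estimate is the inverse logit of the mean logit-scale prediction
(a mean on the weight scale is available as a sensitivity option).

The loess here is the conventional parameterization: tricube weights over
a span-fraction nearest-neighbour window, local polynomial degree 1
(local linear, exact on collinear data) or 2.  Predictions outside the
anchor coefficient range use the boundary local polynomial and are
flagged as extrapolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit as _scipy_logit

from .data_model import DisabilityWeightEstimate, HealthState
from .probit_engine import ProbitFit

__all__ = [
    "AnchorError",
    "AnchorModel",
    "BootstrapEnsemble",
    "logit",
    "inverse_logit",
    "fit_anchor",
    "bootstrap_weights",
    "summarize_weights",
]

REFERENCE_CLIP = 1e-6   # reference weights of exactly 0/1 are clipped here
MIN_ANCHORS = 10
OUTPUT_CLIP = 1e-12     # keeps back-transformed weights strictly inside (0,1)


class AnchorError(ValueError):
    """Anchor model cannot be built or applied."""


def logit(p: float) -> float:
    """log(p / (1-p)); requires p strictly inside (0, 1)."""
    if not 0.0 < p < 1.0:
        raise AnchorError(f"logit requires p in (0, 1); got {p!r} "
                          f"(clip boundary values by {REFERENCE_CLIP} first)")
    return float(_scipy_logit(p))


def inverse_logit(x: float) -> float:
    """Exact inverse of :func:`logit`: 1 / (1 + exp(-x))."""
    return float(expit(x))


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def _loess_predict(
    x: np.ndarray, y: np.ndarray, x0: np.ndarray, span: float, degree: int,
) -> np.ndarray:
    """Local polynomial regression with tricube nearest-neighbour weights.

    For each prediction point the window half-width is the distance to the
    ceil(span * n)-th nearest anchor; a zero half-width (duplicated x)
    falls back to the mean response at that location.
    """
    n = len(x)
    k = min(n, max(degree + 1, math.ceil(span * n)))
    d = np.abs(x0[:, None] - x[None, :])          # (m, n)
    h = np.sort(d, axis=1)[:, k - 1]              # (m,)
    pred = np.empty(len(x0))
    degenerate = h <= 0
    if degenerate.any():
        for i in np.nonzero(degenerate)[0]:
            pred[i] = y[d[i] == 0].mean()
    live = ~degenerate
    if not live.any():
        return pred
    w = _tricube(d[live] / h[live, None])         # (m', n)
    if degree == 1:
        s0 = w.sum(axis=1)
        s1 = w @ x
        s2 = w @ (x * x)
        t0 = w @ y
        t1 = w @ (x * y)
        det = s0 * s2 - s1 * s1
        x0l = x0[live]
        # fall back to the weighted mean when the window is x-degenerate
        safe = det > 1e-12 * np.maximum(s0 * s2, 1e-300)
        num = (s2 * t0 - s1 * t1) + x0l * (s0 * t1 - s1 * t0)
        pred[live] = np.where(safe, num / np.where(safe, det, 1.0), t0 / s0)
    elif degree == 2:
        idx = np.nonzero(live)[0]
        for row, i in enumerate(idx):
            ww = w[row]
            keep = ww > 0
            basis = np.vander(x[keep] - x0[i], 3, increasing=True)
            wb = basis * ww[keep, None]
            coef, *_ = np.linalg.lstsq(wb.T @ basis, wb.T @ y[keep], rcond=None)
            pred[i] = coef[0]
    else:
        raise AnchorError(f"degree must be 1 or 2; got {degree!r}")
    return pred


@dataclass
class AnchorModel:
    """Fitted loess mapping from probit coefficient to logit reference weight."""

    anchor_states: list[str]
    anchor_beta: np.ndarray
    anchor_logit_dw: np.ndarray
    span: float
    degree: int

    def predict(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predict logit-weights at new coefficients.

        Returns (predictions, extrapolated) where ``extrapolated`` flags
        points outside the anchor coefficient range.
        """
        beta = np.asarray(beta, dtype=float)
        pred = _loess_predict(self.anchor_beta, self.anchor_logit_dw,
                              beta, self.span, self.degree)
        extrapolated = (beta < self.anchor_beta.min()) | (beta > self.anchor_beta.max())
        return pred, extrapolated


def fit_anchor(
    fit: ProbitFit,
    catalog: Sequence[HealthState],
    span: float = 0.75,
    degree: int = 1,
) -> AnchorModel:
    """Fit the anchoring loess over states with a reference weight.

    Requires at least 10 anchor states present in both the catalog and the
    probit fit, a non-degenerate coefficient spread, and span in (0, 1].
    Reference weights exactly at 0 or 1 are clipped by 1e-6 before the
    logit transform.
    """
    if not (0.0 < span <= 1.0):
        raise AnchorError(f"span must lie in (0, 1]; got {span!r}")
    if degree not in (1, 2):
        raise AnchorError(f"degree must be 1 or 2; got {degree!r}")
    anchors = [s for s in catalog
               if s.reference_dw is not None and s.state_id in fit.coefficients.index]
    if len(anchors) < MIN_ANCHORS:
        raise AnchorError(
            f"anchoring needs >= {MIN_ANCHORS} anchor states; got {len(anchors)}")
    beta = fit.coefficients.loc[[s.state_id for s in anchors]].to_numpy(dtype=float)
    if np.ptp(beta) <= 0:
        raise AnchorError("anchor coefficients are all equal; loess is degenerate")
    ref = np.clip([s.reference_dw for s in anchors],
                  REFERENCE_CLIP, 1.0 - REFERENCE_CLIP)
    return AnchorModel(
        anchor_states=[s.state_id for s in anchors],
        anchor_beta=beta,
        anchor_logit_dw=_scipy_logit(ref),
        span=span,
        degree=degree,
    )


@dataclass
class BootstrapEnsemble:
    """Per-state bootstrap replicate disability weights.

    ``logit_replicates`` is an (n_states, n_replicates) array of
    logit-scale predictions; ``replicate_dws`` its inverse-logit image in
    (0, 1).
    """

    state_ids: list[str]
    logit_replicates: np.ndarray
    seed: int

    @property
    def n_replicates(self) -> int:
        return self.logit_replicates.shape[1]

    @property
    def replicate_dws(self) -> np.ndarray:
        return np.clip(expit(self.logit_replicates),
                       OUTPUT_CLIP, 1.0 - OUTPUT_CLIP)


def bootstrap_weights(
    fit: ProbitFit,
    model: AnchorModel,
    n_replicates: int = 1000,
    seed: int = 0,
) -> BootstrapEnsemble:
    """Parametric bootstrap of the anchored weights.

    Each replicate redraws every state's coefficient from
    Normal(beta_hat, se), refits the loess on the anchor states' redrawn
    coefficients, and predicts logit-weights for all states at their
    redrawn coefficients.  Deterministic given ``seed``.
    """
    if n_replicates < 2:
        raise AnchorError("n_replicates must be >= 2")
    states = list(fit.coefficients.index)
    beta = fit.coefficients.to_numpy(dtype=float)
    se = fit.standard_errors.reindex(states).to_numpy(dtype=float)
    if not np.all(np.isfinite(se)):
        bad = [s for s, v in zip(states, se) if not np.isfinite(v)]
        raise AnchorError(f"non-finite standard errors for states {bad[:10]}")
    anchor_pos = [states.index(s) for s in model.anchor_states]
    rng = np.random.default_rng(seed)
    out = np.empty((len(states), n_replicates))
    for r in range(n_replicates):
        beta_r = beta + se * rng.standard_normal(len(states))
        replicate_model = AnchorModel(
            anchor_states=model.anchor_states,
            anchor_beta=beta_r[anchor_pos],
            anchor_logit_dw=model.anchor_logit_dw,
            span=model.span,
            degree=model.degree,
        )
        out[:, r], _ = replicate_model.predict(beta_r)
    return BootstrapEnsemble(state_ids=states, logit_replicates=out, seed=seed)


def summarize_weights(
    ensemble: BootstrapEnsemble,
    mean_scale: str = "logit",
) -> list[DisabilityWeightEstimate]:
    """Collapse a bootstrap ensemble into point estimates with 95% UIs.

    The point estimate averages replicate predictions on the logit scale
    before back-transforming (``mean_scale="dw"`` averages the
    back-transformed weights instead, as a sensitivity analysis); the UI
    bounds are the 2.5th/97.5th percentiles of the replicate weights.
    """
    if mean_scale not in ("logit", "dw"):
        raise AnchorError("mean_scale must be 'logit' or 'dw'")
    dws = ensemble.replicate_dws
    if mean_scale == "logit":
        point = expit(ensemble.logit_replicates.mean(axis=1))
    else:
        point = dws.mean(axis=1)
    point = np.clip(point, OUTPUT_CLIP, 1.0 - OUTPUT_CLIP)
    lo = np.percentile(dws, 2.5, axis=1)
    hi = np.percentile(dws, 97.5, axis=1)
    return [
        DisabilityWeightEstimate(sid, float(p), float(l), float(h))
        for sid, p, l, h in zip(ensemble.state_ids, point, lo, hi)
    ]
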