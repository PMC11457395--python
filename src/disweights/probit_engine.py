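"""Paired-comparison probit regression on the latent severity scale.

Each response is one Bernoulli observation: the first-listed state is
judged healthier with probability Phi(beta_second - beta_first), where
beta is a per-state latent severity (larger = more severe).  The design
is the classical signed incidence coding: +1 in the first state's column,
-1 in the second's, 0 elsewhere, outcome 1 iff the first state was chosen
as healthier.  One designated reference state is fixed at 0 for
identifiability; all contrasts are invariant to that choice.

Estimation is exact Newton iteration on the probit log-likelihood over
the comparison-graph component containing the reference state
(disconnected states are reported, not silently dropped into the fit).
Complete separation — a state judged healthier in all or none of its
comparisons — makes the MLE diverge; when detected, a weakly informative
ridge penalty (strength 1e-4) caps the affected coefficients and the fit
metadata records it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.special import log_ndtr
from scipy.stats import norm

from .data_model import IntegrityError

__all__ = [
    "Design",
    "ProbitFit",
    "ResponseProbabilityMatrix",
    "build_design",
    "fit_probit",
    "response_matrix",
]

SEPARATION_RIDGE = 1e-4
LOGLIK_TOL = 1e-8
GRAD_TOL = 1e-6
MAX_ITER = 100


@dataclass
class Design:
    """Signed incidence design with outcomes.

    ``matrix`` has one row per response: +1 at the first-listed state's
    column, -1 at the second's; the reference state's column is dropped.
    ``outcomes`` is 1 iff the first-listed state was chosen as healthier.
    """

    matrix: sp.csr_matrix
    outcomes: np.ndarray
    state_ids: list[str]          # all states, reference included
    reference_state: str
    free_states: list[str]        # column order of ``matrix``
    first_idx: np.ndarray         # index into state_ids per response
    second_idx: np.ndarray


@dataclass
class ProbitFit:
    """Latent severities on an arbitrary scale, reference fixed at 0."""

    coefficients: pd.Series       # per state, reference included (exactly 0)
    standard_errors: pd.Series    # reference se = 0 by convention
    reference_state: str
    log_likelihood: float
    n_responses: int
    converged: bool
    n_iterations: int
    separated_states: list[str] = field(default_factory=list)
    ridge: float = 0.0
    disconnected_states: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "state_id": self.coefficients.index,
            "beta": self.coefficients.to_numpy(),
            "se": self.standard_errors.reindex(self.coefficients.index).to_numpy(),
        })


def build_design(
    responses: pd.DataFrame,
    states: Optional[Sequence[str]] = None,
    reference_state: Optional[str] = None,
) -> Design:
    """Assemble the signed incidence design from a response table.

    ``states`` fixes the column universe (defaults to all states appearing
    in the responses); referencing a state outside it is an integrity
    error.  ``reference_state`` defaults to the most frequently compared
    state, a choice that maximises the chance of a well-connected
    reference.
    """
    observed = pd.concat([responses["first_state"], responses["second_state"]])
    if states is None:
        state_ids = sorted(observed.unique())
    else:
        state_ids = list(states)
        unknown = set(observed.unique()) - set(state_ids)
        if unknown:
            raise IntegrityError(
                f"responses reference unknown states: {sorted(unknown)[:10]}")
    pos = {s: k for k, s in enumerate(state_ids)}
    first_idx = responses["first_state"].map(pos).to_numpy()
    second_idx = responses["second_state"].map(pos).to_numpy()

    if reference_state is None:
        reference_state = observed.value_counts().idxmax()
    elif reference_state not in pos:
        raise IntegrityError(f"reference state {reference_state!r} not in catalog")

    free_states = [s for s in state_ids if s != reference_state]
    n = len(responses)
    ref = pos[reference_state]
    col_of_state = np.full(len(state_ids), -1)
    for k, s in enumerate(free_states):
        col_of_state[pos[s]] = k
    rows, cols, vals = [], [], []
    for idx, sign in ((first_idx, 1.0), (second_idx, -1.0)):
        keep = idx != ref
        rows.append(np.nonzero(keep)[0])
        cols.append(col_of_state[idx[keep]])
        vals.append(np.full(int(keep.sum()), sign))
    matrix = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, len(free_states)))
    outcomes = (responses["choice"] == "first").to_numpy().astype(float)
    return Design(matrix=matrix, outcomes=outcomes, state_ids=state_ids,
                  reference_state=reference_state, free_states=free_states,
                  first_idx=first_idx, second_idx=second_idx)


def _connected_to_reference(design: Design) -> np.ndarray:
    """Boolean mask over state_ids of the component containing the reference."""
    m = len(design.state_ids)
    adj = sp.coo_matrix(
        (np.ones(len(design.first_idx)), (design.first_idx, design.second_idx)),
        shape=(m, m))
    n_comp, labels = connected_components(adj, directed=False)
    ref = design.state_ids.index(design.reference_state)
    return labels == labels[ref]


def _detect_separation(design: Design, fit_mask: np.ndarray) -> list[str]:
    m = len(design.state_ids)
    wins = np.zeros(m)
    appearances = np.zeros(m)
    y = design.outcomes
    np.add.at(appearances, design.first_idx, 1)
    np.add.at(appearances, design.second_idx, 1)
    np.add.at(wins, design.first_idx, y)         # chosen healthier as first
    np.add.at(wins, design.second_idx, 1 - y)    # chosen healthier as second
    separated = (appearances > 0) & ((wins == 0) | (wins == appearances))
    return [s for k, s in enumerate(design.state_ids) if separated[k] and fit_mask[k]]


def fit_probit(
    design: Design,
    outcomes: Optional[np.ndarray] = None,
    ridge: Optional[float] = None,
) -> ProbitFit:
    """Maximum-likelihood probit fit by Newton iteration with step halving.

    Convergence is declared when the log-likelihood improves by less than
    1e-8 or the gradient norm falls below 1e-6.  ``ridge`` overrides the
    automatic separation fallback (pass 0 to force the unpenalised MLE).
    """
    y = design.outcomes if outcomes is None else np.asarray(outcomes, dtype=float)
    mask = _connected_to_reference(design)
    disconnected = [s for k, s in enumerate(design.state_ids) if not mask[k]]
    in_component = mask[design.first_idx] & mask[design.second_idx]
    X_full = design.matrix
    pos = {s: k for k, s in enumerate(design.state_ids)}
    fit_cols = [k for k, s in enumerate(design.free_states) if mask[pos[s]]]
    X = X_full[in_component][:, fit_cols].tocsr()
    y = y[in_component]
    q = 2.0 * y - 1.0

    separated = _detect_separation(design, mask)
    if ridge is None:
        ridge = SEPARATION_RIDGE if separated else 0.0

    p = X.shape[1]
    beta = np.zeros(p)

    def loglik_parts(b):
        # model: P(first healthier) = Phi(beta_second - beta_first) = Phi(-X b)
        eta = -(X @ b)
        z = q * eta
        ll = log_ndtr(z).sum() - 0.5 * ridge * (b @ b)
        lam = np.exp(norm.logpdf(z) - log_ndtr(z))
        grad_eta = q * lam
        w = lam * (lam + z)
        return ll, eta, grad_eta, w

    ll, _, grad_eta, w = loglik_parts(beta)
    n_iter = 0
    converged = False
    for n_iter in range(1, MAX_ITER + 1):
        grad = -(X.T @ grad_eta) - ridge * beta
        if np.linalg.norm(grad) < GRAD_TOL:
            converged = True
            break
        H = (X.T @ sp.diags(w) @ X).toarray() + ridge * np.eye(p)
        step = np.linalg.solve(H, grad)
        # step halving keeps the iteration ascending
        scale = 1.0
        for _ in range(30):
            ll_new, _, g_new, w_new = loglik_parts(beta + scale * step)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        improvement = ll_new - ll
        ll, grad_eta, w = ll_new, g_new, w_new
        if abs(improvement) < LOGLIK_TOL:
            converged = True
            break

    H = (X.T @ sp.diags(w) @ X).toarray() + ridge * np.eye(p)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    fitted_states = [design.free_states[k] for k in fit_cols]
    coeffs = pd.Series(0.0, index=pd.Index([design.reference_state] + fitted_states,
                                           name="state_id"))
    errors = pd.Series(0.0, index=coeffs.index)
    coeffs.loc[fitted_states] = beta
    errors.loc[fitted_states] = se
    # present in catalog order
    order = [s for s in design.state_ids if s in set(coeffs.index)]
    return ProbitFit(
        coefficients=coeffs.reindex(order),
        standard_errors=errors.reindex(order),
        reference_state=design.reference_state,
        log_likelihood=float(ll),
        n_responses=int(len(y)),
        converged=converged,
        n_iterations=n_iter,
        separated_states=separated,
        ridge=float(ridge),
        disconnected_states=disconnected,
    )


@dataclass
class ResponseProbabilityMatrix:
    """Empirical choice probabilities per ordered state pair.

    ``prob[(i, j)]`` is the fraction of responses in which ``i``, listed
    first, was chosen as the healthier state; unobserved pairs are absent,
    not zero.  ``states`` orders rows/columns (by increasing fitted
    severity when a fit is supplied) so a consistent dataset shows the
    blue-to-red heatmap gradient; the conventional colour-band thresholds
    (below 0.25 / above 0.75) ship as metadata.
    """

    states: list[str]
    prob: dict[tuple[str, str], float]
    counts: dict[tuple[str, str], int]
    thresholds: tuple[float, float] = (0.25, 0.75)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(np.nan, index=self.states, columns=self.states)
        for (i, j), p in self.prob.items():
            frame.loc[i, j] = p
        return frame


def response_matrix(
    responses: pd.DataFrame,
    ordering: Optional[ProbitFit] = None,
    pooled: bool = True,
) -> ResponseProbabilityMatrix:
    """Empirical response-probability matrix.

    With ``pooled`` (default) both presentation orders of a state pair are
    combined, so symmetric entries satisfy prob(i,j) + prob(j,i) = 1; with
    ``pooled=False`` each presented order is tabulated separately.
    """
    if len(responses) == 0:
        return ResponseProbabilityMatrix(states=[], prob={}, counts={})
    first = responses["first_state"].to_numpy()
    second = responses["second_state"].to_numpy()
    chose_first = (responses["choice"] == "first").to_numpy()

    wins: dict[tuple[str, str], int] = {}
    totals: dict[tuple[str, str], int] = {}
    for f, s, cf in zip(first, second, chose_first):
        key = (f, s) if not pooled else ((f, s) if f <= s else (s, f))
        i_chosen = cf if key == (f, s) else not cf
        totals[key] = totals.get(key, 0) + 1
        wins[key] = wins.get(key, 0) + bool(i_chosen)

    prob: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for key, n in totals.items():
        p = wins[key] / n
        prob[key] = p
        counts[key] = n
        if pooled:
            i, j = key
            prob[(j, i)] = 1.0 - p
            counts[(j, i)] = n

    if ordering is not None:
        ranked = ordering.coefficients.sort_values().index.tolist()
        seen = set(ranked)
        states = ranked + sorted(
            {s for pair in prob for s in pair if s not in seen})
    else:
        states = sorted({s for pair in prob for s in pair})
    return ResponseProbabilityMatrix(states=states, prob=prob, counts=counts)
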