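"""Maximum-likelihood fitting of confidence-rating ROC models.

Two standard models of recognition memory are implemented:

* **DPSD** (dual-process signal detection): old items are recollected with
  probability ``Ro`` — an all-or-none threshold event mapped to the
  most-confident "old" response — and otherwise judged on a graded
  familiarity signal ``Normal(d', 1)``; new items on ``Normal(0, 1)``.
* **UVSD** (unequal-variance signal detection): a single strength axis where
  old items are drawn from ``Normal(d', Vo)`` with ``Vo`` typically > 1.

Both observers partition the strength axis with ``B - 1`` ordered criteria
into ``B`` confidence bins (1 = sure new … B = sure old).  The sufficient
statistic is a 2×B table of response counts (old row, new row), and the
likelihood is product-multinomial: the two rows are independent multinomials
given the parameters.

Fitting maximises that likelihood under an unconstrained reparameterisation
(logit for Ro, log for Vo and for DPSD d', first-criterion + log-gaps for
the ordered thresholds) with multiple jittered restarts around moment-based
starting values.  Goodness of fit is the G statistic (likelihood-ratio test
against the saturated multinomial) and models are compared with BIC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit, ndtr, ndtri

__all__ = [
    "DPSDParams",
    "UVSDParams",
    "FitResult",
    "dpsd_response_probs",
    "uvsd_response_probs",
    "log_likelihood",
    "g_statistic",
    "fit_model",
    "select_winning_model",
]

ModelName = Literal["DPSD", "UVSD"]

#: Reject a model when the G test p-value falls below this level.
G_TEST_ALPHA = 0.05
#: Fraction of subjects that must prefer (lower BIC) the winning model.
BIC_WIN_SHARE = 0.80
#: Fraction of subjects with an acceptable G fit required of the winner
#: (strict inequality).
G_ACCEPT_SHARE = 0.80


# ---------------------------------------------------------------------------
# Parameter bundles
# ---------------------------------------------------------------------------

def _check_criteria(criteria: Sequence[float]) -> tuple[float, ...]:
    c = tuple(float(x) for x in criteria)
    if len(c) < 1:
        raise ValueError("at least one criterion is required")
    if any(b <= a for a, b in zip(c, c[1:])):
        raise ValueError(f"criteria must be strictly increasing, got {c}")
    return c


@dataclass(frozen=True)
class DPSDParams:
    """Dual-process parameters: recollection ``ro``, familiarity ``dprime``
    (constrained non-negative), and ``B - 1`` ordered criteria."""

    ro: float
    dprime: float
    criteria: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "criteria", _check_criteria(self.criteria))
        if not 0.0 <= self.ro <= 1.0:
            raise ValueError(f"ro must be in [0, 1], got {self.ro}")
        if self.dprime < 0:
            raise ValueError(f"DPSD dprime must be >= 0, got {self.dprime}")


@dataclass(frozen=True)
class UVSDParams:
    """Unequal-variance parameters: ``dprime`` (unconstrained), old-item SD
    ``vo`` > 0, and ``B - 1`` ordered criteria."""

    dprime: float
    vo: float
    criteria: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "criteria", _check_criteria(self.criteria))
        if self.vo <= 0:
            raise ValueError(f"vo must be > 0, got {self.vo}")


@dataclass(frozen=True)
class FitResult:
    """A fitted ROC model with its fit diagnostics.

    ``bic = -2 logL + n_params ln(n_trials)`` with ``n_trials`` the total
    of old and new trials; ``df = 2(B - 1) - n_params`` for the G test.
    ``logL`` is the product-multinomial kernel (multinomial coefficients
    omitted; they cancel in all comparisons made here).
    """

    model: ModelName
    params: DPSDParams | UVSDParams
    logL: float
    g: float
    df: int
    p: float
    bic: float
    n_params: int
    n_trials: int
    converged: bool
    n_restarts_used: int

    @property
    def rejected(self) -> bool:
        """True when the G test rejects the model at the 5% level."""
        return bool(self.p < G_TEST_ALPHA)


# ---------------------------------------------------------------------------
# Predicted response probabilities
# ---------------------------------------------------------------------------

def _bin_probs_from_upper_cum(upper: np.ndarray) -> np.ndarray:
    """Turn P(response > bin j) at each criterion into B bin probabilities."""
    cum = np.concatenate(([1.0], upper, [0.0]))  # P(response >= bin 1) = 1
    p = cum[:-1] - cum[1:]
    return np.clip(p, 0.0, 1.0)


def dpsd_response_probs(params: DPSDParams, B: int | None = None) -> np.ndarray:
    """Predicted 2×B response-probability table for a DPSD observer.

    Row 0 is the old-item distribution, row 1 the new-item distribution;
    columns are confidence bins 1..B.  Recollection mass loads entirely on
    bin B: cumulative P(resp > c_j | old) = Ro + (1 - Ro)(1 - Phi(c_j - d')).
    """
    c = np.asarray(params.criteria, dtype=float)
    if B is not None and len(c) != B - 1:
        raise ValueError(f"expected {B - 1} criteria, got {len(c)}")
    old_upper = params.ro + (1.0 - params.ro) * (1.0 - ndtr(c - params.dprime))
    new_upper = 1.0 - ndtr(c)
    return np.vstack(
        [_bin_probs_from_upper_cum(old_upper), _bin_probs_from_upper_cum(new_upper)]
    )


def uvsd_response_probs(params: UVSDParams, B: int | None = None) -> np.ndarray:
    """Predicted 2×B table for a UVSD observer: old strength ~ N(d', Vo²)."""
    c = np.asarray(params.criteria, dtype=float)
    if B is not None and len(c) != B - 1:
        raise ValueError(f"expected {B - 1} criteria, got {len(c)}")
    old_upper = 1.0 - ndtr((c - params.dprime) / params.vo)
    new_upper = 1.0 - ndtr(c)
    return np.vstack(
        [_bin_probs_from_upper_cum(old_upper), _bin_probs_from_upper_cum(new_upper)]
    )


def response_probs(params: DPSDParams | UVSDParams) -> np.ndarray:
    if isinstance(params, DPSDParams):
        return dpsd_response_probs(params)
    return uvsd_response_probs(params)


# ---------------------------------------------------------------------------
# Likelihood and goodness of fit
# ---------------------------------------------------------------------------

_LOG_FLOOR = 1e-300


def log_likelihood(params: DPSDParams | UVSDParams, counts: np.ndarray) -> float:
    """Product-multinomial log-likelihood kernel of a 2×B count table."""
    counts = _validate_counts(counts)
    probs = response_probs(params)
    if probs.shape != counts.shape:
        raise ValueError(
            f"counts shape {counts.shape} does not match {probs.shape[1]} bins"
        )
    return float(np.sum(counts * np.log(np.maximum(probs, _LOG_FLOOR))))


def _validate_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] < 2:
        raise ValueError(f"counts must be a 2×B table with B >= 2, got {counts.shape}")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    return counts


def g_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    """Likelihood-ratio goodness-of-fit statistic ``2 Σ O ln(O/E)``.

    Cells with zero observed count contribute nothing; expected counts are
    used as given (no flooring).
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and expected must have the same shape")
    if np.any(o < 0) or np.any(e < 0):
        raise ValueError("counts must be nonnegative")
    mask = o > 0
    if np.any(e[mask] <= 0):
        raise ValueError("expected must be positive wherever observed is positive")
    return float(2.0 * np.sum(o[mask] * np.log(o[mask] / e[mask])))


def _saturated_loglik(counts: np.ndarray) -> float:
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / totals, 0.0)
    mask = counts > 0
    return float(np.sum(counts[mask] * np.log(p[mask])))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------
# Unconstrained parameter vector theta:
#   DPSD: [logit(ro), log(dprime), c1, log(gap_1), ..., log(gap_{B-2})]
#   UVSD: [dprime, log(vo),        c1, log(gap_1), ..., log(gap_{B-2})]

def _theta_to_params(theta: np.ndarray, model: ModelName) -> DPSDParams | UVSDParams:
    c1 = theta[2]
    gaps = np.exp(theta[3:])
    criteria = tuple(c1 + np.concatenate(([0.0], np.cumsum(gaps))))
    if model == "DPSD":
        return DPSDParams(ro=float(expit(theta[0])), dprime=float(np.exp(theta[1])),
                          criteria=criteria)
    return UVSDParams(dprime=float(theta[0]), vo=float(np.exp(theta[1])),
                      criteria=criteria)


def _params_to_theta(params: DPSDParams | UVSDParams) -> np.ndarray:
    c = np.asarray(params.criteria)
    tail = np.concatenate(([c[0]], np.log(np.diff(c))))
    if isinstance(params, DPSDParams):
        head = [logit(np.clip(params.ro, 1e-6, 1 - 1e-6)),
                np.log(max(params.dprime, 1e-6))]
    else:
        head = [params.dprime, np.log(params.vo)]
    return np.concatenate((head, tail))


def _moment_start(counts: np.ndarray, model: ModelName) -> DPSDParams | UVSDParams:
    """Moment-based starting values from the corrected cumulative rates.

    Criteria come from the inverse-normal of the new-item cumulative
    distribution; d' from the mean z-ROC gap; Vo from the inverse z-ROC
    slope; Ro starts small (most mass attributed to familiarity).
    """
    counts = _validate_counts(counts)
    B = counts.shape[1]
    n_old, n_new = counts.sum(axis=1)
    # cumulative P(response <= j), corrected away from 0/1
    cum_old = (np.cumsum(counts[0, :-1]) + 0.5) / (n_old + 1.0)
    cum_new = (np.cumsum(counts[1, :-1]) + 0.5) / (n_new + 1.0)
    z_old, z_new = ndtri(cum_old), ndtri(cum_new)
    criteria = np.sort(z_new)
    criteria = _strictify(criteria)
    if B > 2 and np.ptp(z_new) > 1e-9:
        slope = float(np.polyfit(z_new, z_old, 1)[0])
    else:
        slope = 1.0
    dprime = float(np.mean(z_new - z_old))
    if model == "DPSD":
        return DPSDParams(ro=0.1, dprime=max(dprime, 0.05), criteria=tuple(criteria))
    vo = float(np.clip(1.0 / max(slope, 1e-3), 0.2, 5.0))
    return UVSDParams(dprime=dprime, vo=vo, criteria=tuple(criteria))


def _strictify(c: np.ndarray, min_gap: float = 1e-3) -> np.ndarray:
    out = c.astype(float).copy()
    for i in range(1, len(out)):
        if out[i] <= out[i - 1] + min_gap:
            out[i] = out[i - 1] + min_gap
    return out


def fit_model(
    counts: np.ndarray,
    model: ModelName,
    *,
    n_restarts: int = 10,
    seed: int | np.random.Generator | None = 0,
    early_stop: int = 3,
) -> FitResult:
    """Fit a DPSD or UVSD model to a 2×B rating-count table by maximum
    likelihood.

    Up to ``n_restarts`` optimisations are run: the first from moment-based
    starting values, the rest from randomly jittered copies.  Restarting
    stops early once ``early_stop`` starts have reproduced the best
    log-likelihood within 1e-4 (ordered-threshold likelihoods are
    multimodal, so a single start is not trusted).

    Degenerate tables (all mass in one bin for both rows) are not
    identifiable; the fit is still returned but flagged ``converged=False``.
    """
    counts = _validate_counts(counts)
    B = counts.shape[1]
    n_trials = int(round(counts.sum()))
    n_params = (B - 1) + 2
    df = 2 * (B - 1) - n_params
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    degenerate = all(np.count_nonzero(row) <= 1 for row in counts)

    theta0 = _params_to_theta(_moment_start(counts, model))

    def nll(theta: np.ndarray) -> float:
        try:
            params = _theta_to_params(theta, model)
        except (ValueError, FloatingPointError, OverflowError):
            return np.inf
        return -log_likelihood(params, counts)

    best_val = np.inf
    best_theta = theta0
    any_success = False
    n_confirm = 0
    n_used = 0
    for k in range(n_restarts):
        start = theta0 if k == 0 else theta0 + rng.normal(0.0, 0.25, size=theta0.size)
        res = optimize.minimize(nll, start, method="L-BFGS-B")
        n_used += 1
        if np.isfinite(res.fun):
            any_success = any_success or bool(res.success)
            if res.fun < best_val - 1e-4:
                best_val, best_theta = res.fun, res.x
                n_confirm = 1
            elif res.fun < best_val + 1e-4:
                n_confirm += 1
                if res.fun < best_val:
                    best_val, best_theta = res.fun, res.x
        if n_confirm >= early_stop:
            break

    params = _theta_to_params(best_theta, model)
    logL = -best_val
    probs = response_probs(params)
    expected = probs * counts.sum(axis=1, keepdims=True)
    g = g_statistic(counts, np.maximum(expected, _LOG_FLOOR))
    p = float(stats.chi2.sf(g, df)) if df > 0 else float("nan")
    bic = -2.0 * logL + n_params * np.log(max(n_trials, 1))
    return FitResult(
        model=model,
        params=params,
        logL=float(logL),
        g=float(g),
        df=df,
        p=p,
        bic=float(bic),
        n_params=n_params,
        n_trials=n_trials,
        converged=bool(any_success and np.isfinite(logL) and not degenerate),
        n_restarts_used=n_used,
    )


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSelection:
    """Outcome of the 80%-majority winning-model rule."""

    winner: Literal["DPSD", "UVSD", "inconclusive"]
    n_subjects: int
    dpsd_bic_share: float
    uvsd_bic_share: float
    dpsd_accept_share: float
    uvsd_accept_share: float


def select_winning_model(
    fits: Sequence[tuple[FitResult, FitResult]],
) -> ModelSelection:
    """Apply the winning-model rule to per-subject (DPSD, UVSD) fit pairs.

    A model wins when it attains the lower BIC in at least 80% of subjects
    *and* the G test fails to reject it in more than 80% of subjects;
    otherwise the comparison is inconclusive.  BIC ties count for neither
    model.
    """
    if not fits:
        raise ValueError("no fits supplied")
    n = len(fits)
    dpsd_lower = uvsd_lower = dpsd_ok = uvsd_ok = 0
    for pair in fits:
        d, u = pair
        if d.model != "DPSD" or u.model != "UVSD":
            raise ValueError("each pair must be (DPSD fit, UVSD fit)")
        if d.bic < u.bic:
            dpsd_lower += 1
        elif u.bic < d.bic:
            uvsd_lower += 1
        dpsd_ok += not d.rejected
        uvsd_ok += not u.rejected
    shares = {
        "dpsd_bic_share": dpsd_lower / n,
        "uvsd_bic_share": uvsd_lower / n,
        "dpsd_accept_share": dpsd_ok / n,
        "uvsd_accept_share": uvsd_ok / n,
    }
    winner: str = "inconclusive"
    if shares["dpsd_bic_share"] >= BIC_WIN_SHARE and shares["dpsd_accept_share"] > G_ACCEPT_SHARE:
        winner = "DPSD"
    elif shares["uvsd_bic_share"] >= BIC_WIN_SHARE and shares["uvsd_accept_share"] > G_ACCEPT_SHARE:
        winner = "UVSD"
    return ModelSelection(winner=winner, n_subjects=n, **shares)
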