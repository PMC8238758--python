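"""Memorability-quantile ROC fits and ordinal regression.

Items are rank-ordered by memorability and packed into Q quantiles of
(near-)equal trial numbers; rating counts are pooled over subjects within
each quantile so that both ROC models can be fitted per quantile.  The
recovered parameters then predict quantile rank in a proportional-odds
(cumulative-logit) ordinal regression, and each model's parameter set is
scored by how much rank variance it explains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .descriptives import rating_counts
from .roc_models import DPSDParams, FitResult, UVSDParams, fit_model

__all__ = [
    "quantile_bin",
    "fit_quantiles",
    "QuantileFit",
    "ordinal_regression",
    "OrdinalFit",
]


def quantile_bin(items: pd.DataFrame, Q: int) -> pd.Series:
    """Assign each item to a memorability quantile 1..Q of equal trial mass.

    ``items`` needs columns ``image``, ``memorability`` and ``n_trials``.
    Items are sorted by memorability (stable on ties, so the assignment is
    deterministic for a fixed input order of tied items after a stable
    pre-sort on image id); each item goes to the quantile containing the
    midpoint of its cumulative trial span, which keeps quantile totals
    within one item's trial count of each other.

    Returns a Series of quantile ranks indexed like ``items``.
    """
    if Q < 2:
        raise ValueError("Q must be at least 2")
    if Q > len(items):
        raise ValueError(f"Q={Q} exceeds the number of items ({len(items)})")
    # stable pre-sort on image id makes tied memorability scores order-free
    ordered = items.sort_values("image", kind="mergesort").sort_values(
        "memorability", kind="mergesort"
    )
    n = ordered["n_trials"].to_numpy(dtype=float)
    total = n.sum()
    if total < Q:
        raise ValueError("fewer trials than quantiles")
    cum_before = np.concatenate(([0.0], np.cumsum(n)[:-1]))
    mid = cum_before + n / 2.0
    ranks = np.minimum(Q, np.floor(Q * mid / total).astype(int) + 1)
    return pd.Series(ranks, index=ordered.index).reindex(items.index)


@dataclass(frozen=True)
class QuantileFit:
    """Both models fitted to one memorability quantile's pooled counts."""

    quantile: int
    n_trials: int
    mean_memorability: float
    dpsd: FitResult
    uvsd: FitResult


def fit_quantiles(
    trials: pd.DataFrame,
    assignment: pd.Series | None = None,
    Q: int = 30,
    B: int = 6,
    seed: int = 0,
) -> list[QuantileFit]:
    """Pool rating counts per memorability quantile and fit both models.

    ``assignment`` maps image id -> quantile rank; if omitted it is built
    from the trial table with :func:`quantile_bin`.  Quantiles whose fit is
    degenerate are still returned (flagged by ``converged=False`` on the
    fit) — downstream regression should drop them.
    """
    if assignment is None:
        per_image = (
            trials.groupby("image", sort=True)
            .agg(memorability=("memorability", "first"), n_trials=("image", "size"))
            .reset_index()
        )
        ranks = quantile_bin(per_image, Q)
        assignment = pd.Series(ranks.to_numpy(), index=per_image["image"])
    q_of_trial = trials["image"].map(assignment)
    fits = []
    for q in sorted(assignment.unique()):
        g = trials.loc[q_of_trial == q]
        counts = rating_counts(g, B=B)
        fits.append(
            QuantileFit(
                quantile=int(q),
                n_trials=len(g),
                mean_memorability=float(g["memorability"].mean()),
                dpsd=fit_model(counts, "DPSD", seed=seed + int(q)),
                uvsd=fit_model(counts, "UVSD", seed=seed + int(q)),
            )
        )
    return fits


def quantile_parameter_table(fits: Sequence[QuantileFit]) -> pd.DataFrame:
    """Flatten per-quantile fits into a parameter table."""
    rows = []
    for f in fits:
        d: DPSDParams = f.dpsd.params  # type: ignore[assignment]
        u: UVSDParams = f.uvsd.params  # type: ignore[assignment]
        rows.append(
            {
                "quantile": f.quantile,
                "n_trials": f.n_trials,
                "mean_memorability": f.mean_memorability,
                "dpsd_ro": d.ro,
                "dpsd_dprime": d.dprime,
                "dpsd_bic": f.dpsd.bic,
                "dpsd_converged": f.dpsd.converged,
                "uvsd_dprime": u.dprime,
                "uvsd_vo": u.vo,
                "uvsd_bic": f.uvsd.bic,
                "uvsd_converged": f.uvsd.converged,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OrdinalFit:
    """A proportional-odds regression of quantile rank on model parameters.

    ``chi2`` is the likelihood-ratio statistic against the intercept-only
    model; ``r2_nagelkerke`` the Nagelkerke pseudo-R² and ``r2_adjusted``
    its small-sample adjusted variant; ``std_coef`` are raw coefficients ×
    predictor SD (latent-scale standardisation).
    """

    predictors: tuple[str, ...]
    coef: dict[str, float]
    se: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    std_coef: dict[str, float]
    chi2: float
    df: int
    p_model: float
    r2_nagelkerke: float
    r2_adjusted: float
    llf: float
    llnull: float
    converged: bool


def ordinal_regression(
    table: pd.DataFrame, predictors: Sequence[str], rank_col: str = "quantile"
) -> OrdinalFit:
    """Cumulative-logit ML regression of ordered ranks on predictors.

    The intercept-only log-likelihood has a closed form (thresholds can
    match the marginal rank frequencies exactly), giving the LR chi-square
    without a second optimisation.  Predictors are entered raw; standardised
    coefficients are reported as coefficient × predictor SD.
    """
    table = table.dropna(subset=list(predictors) + [rank_col])
    y = table[rank_col].to_numpy()
    if len(np.unique(y)) < 5:
        raise ValueError("need at least 5 distinct ranks")
    X = table[list(predictors)].astype(float)
    if any(np.ptp(X[c].to_numpy()) == 0 for c in predictors):
        raise ValueError("constant predictor")
    n = len(table)

    model = OrderedModel(
        pd.Categorical(y, ordered=True), X, distr="logit"
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        # convergence is reported explicitly on the result; near-separation
        # warnings from the optimizer are expected with few quantiles
        _warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=500, disp=False)

    k = len(predictors)
    coef = {c: float(res.params[c]) for c in predictors}
    se = {c: float(res.bse[c]) for c in predictors}
    z = {c: coef[c] / se[c] for c in predictors}
    pvals = {c: float(2 * stats.norm.sf(abs(z[c]))) for c in predictors}
    std_coef = {c: coef[c] * float(np.std(X[c].to_numpy(), ddof=1)) for c in predictors}

    # intercept-only cumulative-logit logL: thresholds reproduce the
    # marginal category frequencies exactly
    _, counts = np.unique(y, return_counts=True)
    llnull = float(np.sum(counts * np.log(counts / n)))
    llf = float(res.llf)
    chi2 = max(0.0, 2.0 * (llf - llnull))
    p_model = float(stats.chi2.sf(chi2, k))
    r2_cs = 1.0 - np.exp(-chi2 / n)
    r2_max = 1.0 - np.exp(2.0 * llnull / n)
    r2_nag = float(r2_cs / r2_max) if r2_max > 0 else float("nan")
    # small-sample adjustment analogous to adjusted R²
    r2_adj = (
        float(1.0 - (1.0 - r2_nag) * (n - 1) / (n - k - 1))
        if n - k - 1 > 0
        else float("nan")
    )
    return OrdinalFit(
        predictors=tuple(predictors),
        coef=coef,
        se=se,
        z=z,
        p=pvals,
        std_coef=std_coef,
        chi2=float(chi2),
        df=k,
        p_model=p_model,
        r2_nagelkerke=r2_nag,
        r2_adjusted=max(0.0, r2_adj),
        llf=llf,
        llnull=llnull,
        converged=bool(res.mle_retvals.get("converged", True)),
    )
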