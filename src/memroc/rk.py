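"""Scaled-difference analysis of remember/know and detailed-new/unfamiliar
statements, with one-sided JZS Bayes-factor t tests.

Because a "know" statement implies "not remember" (and vice versa), the R
and K proportions are interdependent and cannot be analysed as independent
factors.  The scaled difference collapses them into one outcome per
subject and condition::

    Yold = (r - k) / (r + k)        Ynew = (d - u) / (d + u)

where r, k (d, u) are the proportions of remember/know (detailed-new/
unfamiliar) statements within a response basis — hits, false alarms,
correct rejections, or false rejections.  Positive scores mean a propensity
for remember (detailed-new) statements; zero means no propensity.

Group-level evidence is quantified with the default JZS Bayes factor for
one-sample/paired t designs: a Cauchy prior with scale ``r`` on the
standardised effect size, truncated to the hypothesised direction for
one-sided tests, integrated numerically against the noncentral-t
likelihood of the observed t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .descriptives import bin_memorability, classify_old

__all__ = [
    "scaled_difference",
    "statement_counts",
    "subject_scaled_differences",
    "bayes_t_test",
    "BayesFactorResult",
    "image_statement_scores",
    "table3_style_summary",
]

#: Default Cauchy prior scale on the standardised effect size
#: ("medium" default of common Bayes-factor software).
DEFAULT_PRIOR_SCALE = float(np.sqrt(2) / 2)

Basis = Literal["hits", "false_alarms", "correct_rejections", "false_rejections"]

#: basis -> (item status, response classified old?, statement pair)
_BASIS_DEF: dict[str, tuple[str, bool, tuple[str, str]]] = {
    "hits": ("old", True, ("R", "K")),
    "false_alarms": ("new", True, ("R", "K")),
    "correct_rejections": ("new", False, ("D", "U")),
    "false_rejections": ("old", False, ("D", "U")),
}


def scaled_difference(a: float, b: float) -> float:
    """``(a - b) / (a + b)`` for nonnegative counts or proportions.

    Antisymmetric in (a, b) and invariant to common rescaling.  Undefined
    (NaN) when both are zero.
    """
    if a < 0 or b < 0:
        raise ValueError("inputs must be nonnegative")
    if a + b == 0:
        return float("nan")
    return (a - b) / (a + b)


def statement_counts(trials: pd.DataFrame, basis: Basis, B: int = 6) -> pd.DataFrame:
    """Per subject × memorability bin counts of the two statements of a basis.

    Columns: ``subject, mem_bin, n_first, n_second, n`` where the statement
    pair is (R, K) for old-response bases and (D, U) for new-response bases.
    """
    if basis not in _BASIS_DEF:
        raise ValueError(f"unknown basis {basis!r}")
    status, wants_old_resp, (s1, s2) = _BASIS_DEF[basis]
    said_old = classify_old(trials["response"].to_numpy(), B=B)
    sel = (trials["status"].to_numpy() == status) & (said_old == wants_old_resp)
    sub = trials.loc[sel].copy()
    sub["mem_bin"] = [bin_memorability(m) for m in sub["memorability"]]
    rows = []
    for (subject, mem_bin), g in sub.groupby(["subject", "mem_bin"], sort=True):
        st = g["statement"].to_numpy()
        rows.append(
            {
                "subject": subject,
                "mem_bin": mem_bin,
                "n_first": int(np.sum(st == s1)),
                "n_second": int(np.sum(st == s2)),
                "n": len(g),
            }
        )
    return pd.DataFrame(rows, columns=["subject", "mem_bin", "n_first", "n_second", "n"])


def subject_scaled_differences(
    trials: pd.DataFrame, basis: Basis, B: int = 6
) -> pd.DataFrame:
    """Per-subject × memorability-bin scaled differences for a basis.

    ``y`` is Yold for old-response bases and Ynew for new-response bases;
    cells with no qualifying trials are absent (undefined, not zero).
    """
    counts = statement_counts(trials, basis, B=B)
    if counts.empty:
        return counts.assign(y=pd.Series(dtype=float))
    counts["y"] = [
        scaled_difference(a, b)
        for a, b in zip(counts["n_first"], counts["n_second"])
    ]
    return counts


@dataclass(frozen=True)
class BayesFactorResult:
    """A JZS Bayes-factor t test: ``bf10`` is evidence for the alternative
    over the null; ``bf01 = 1/bf10``.  ``cohens_d`` is the paired-design
    d_z = mean difference / SD of differences."""

    t: float
    n: int
    prior_scale: float
    bf10: float
    direction: Literal["greater", "less", "two-sided"]
    cohens_d: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def _jzs_bf10(
    t: float, n: int, prior_scale: float, direction: str
) -> float:
    """JZS Bayes factor by quadrature over the effect-size prior.

    Marginal likelihood under H1 integrates the noncentral-t density of the
    observed t (df = n − 1, noncentrality δ√n) against a Cauchy(0, r) prior
    on δ, truncated to δ > 0 ("greater") or δ < 0 ("less") for one-sided
    tests.  H0 is the central t density.
    """
    nu = n - 1

    # substitute delta = r tan(u): the Cauchy prior becomes uniform on
    # (-pi/2, pi/2), giving a finite, well-conditioned integration range
    def integrand(u: float) -> float:
        delta = prior_scale * np.tan(u)
        val = stats.nct.pdf(t, nu, delta * np.sqrt(n)) / np.pi
        return float(val) if np.isfinite(val) else 0.0

    half_pi = np.pi / 2
    if direction == "greater":
        lo, hi, norm = 0.0, half_pi, 0.5
    elif direction == "less":
        lo, hi, norm = -half_pi, 0.0, 0.5
    elif direction == "two-sided":
        lo, hi, norm = -half_pi, half_pi, 1.0
    else:
        raise ValueError(f"unknown direction {direction!r}")
    m1, _ = integrate.quad(integrand, lo, hi, limit=200)
    m1 /= norm  # renormalise the truncated prior
    m0 = stats.t.pdf(t, nu)
    return float(m1 / m0)


def bayes_t_test(
    diffs: np.ndarray,
    direction: Literal["greater", "less", "two-sided"] = "greater",
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> BayesFactorResult:
    """One-sample (paired-difference) JZS Bayes-factor t test.

    ``diffs`` are per-subject paired differences; NaNs are dropped.  The
    classical t statistic and Cohen's d_z are reported alongside the Bayes
    factor.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 finite differences")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValueError("zero-variance differences: t is undefined")
    mean = float(np.mean(d))
    t = mean / (sd / np.sqrt(n))
    bf10 = _jzs_bf10(t, n, prior_scale, direction)
    return BayesFactorResult(
        t=float(t),
        n=n,
        prior_scale=float(prior_scale),
        bf10=bf10,
        direction=direction,
        cohens_d=mean / sd,
    )


def image_statement_scores(trials: pd.DataFrame, B: int = 6) -> pd.DataFrame:
    """Per-image Yold (from hits) and Ynew (from correct rejections),
    pooled over subjects.

    Yold contrasts R vs K statements on trials where the image was a
    correctly recognised target; Ynew contrasts D vs U statements on trials
    where it was a correctly rejected foil.  Images with no qualifying
    trials for a score carry NaN there.
    """
    said_old = classify_old(trials["response"].to_numpy(), B=B)
    status = trials["status"].to_numpy()
    df = trials.assign(_hit=(status == "old") & said_old,
                       _cr=(status == "new") & ~said_old)
    rows = []
    for image, g in df.groupby("image", sort=True):
        stg = g["statement"].to_numpy()
        hit = g["_hit"].to_numpy()
        cr = g["_cr"].to_numpy()
        rows.append(
            {
                "image": image,
                "memorability": float(g["memorability"].iloc[0]),
                "yold": scaled_difference(
                    int(np.sum(hit & (stg == "R"))), int(np.sum(hit & (stg == "K")))
                ),
                "ynew": scaled_difference(
                    int(np.sum(cr & (stg == "D"))), int(np.sum(cr & (stg == "U")))
                ),
            }
        )
    scores = pd.DataFrame(rows)
    if (scores[["yold", "ynew"]].notna().any(axis=1)).sum() < 3:
        raise ValueError("need at least 3 images with defined scores")
    return scores


def image_score_correlations(scores: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Pearson correlations of per-image Yold and Ynew with memorability,
    and of Yold with Ynew."""
    out: dict[str, tuple[float, float]] = {}
    for name, (xcol, ycol) in {
        "yold_memorability": ("memorability", "yold"),
        "ynew_memorability": ("memorability", "ynew"),
        "yold_ynew": ("yold", "ynew"),
    }.items():
        sub = scores[[xcol, ycol]].dropna()
        r = stats.pearsonr(sub[xcol], sub[ycol])
        out[name] = (float(r.statistic), float(r.pvalue))
    return out


def table3_style_summary(trials: pd.DataFrame, B: int = 6) -> pd.DataFrame:
    """Statement proportions and scaled differences by memorability bin.

    One row per bin with mean per-subject statement proportions and two
    flavours of group scaled difference for each basis: the mean of
    per-subject scaled differences (``*_y_mean``) and the scaled difference
    of the mean proportions (``*_y_of_means``) — the two conventions can
    differ, so both are reported.
    """
    pieces: dict[str, pd.DataFrame] = {
        basis: subject_scaled_differences(trials, basis, B=B)
        for basis in _BASIS_DEF
    }
    bins = ["low", "mid", "high"]
    rows = []
    for mem_bin in bins:
        row: dict[str, float | str] = {"mem_bin": mem_bin}
        for basis, tab in pieces.items():
            g = tab[tab["mem_bin"] == mem_bin]
            if g.empty:
                continue
            p1 = (g["n_first"] / g["n"]).mean()
            p2 = (g["n_second"] / g["n"]).mean()
            row[f"{basis}_p_first"] = float(p1)
            row[f"{basis}_p_second"] = float(p2)
            row[f"{basis}_y_mean"] = float(g["y"].mean())
            row[f"{basis}_y_of_means"] = scaled_difference(float(p1), float(p2))
        rows.append(row)
    return pd.DataFrame(rows)
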