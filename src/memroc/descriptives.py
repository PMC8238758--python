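"""Descriptive recognition-memory statistics.

Corrected hit/false-alarm rates, d', memorability binning, at-chance
subject exclusion, empirical ROC/zROC points and trapezoidal AUC — per
subject and per image.

Rates use the Snodgrass–Corwin correction (add 0.5 to hit and false-alarm
counts, 1 to the old and new totals) so that proportions never reach 0 or 1
and the inverse-normal transform stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

__all__ = [
    "corrected_rates",
    "dprime",
    "bin_memorability",
    "exclude_at_chance",
    "rating_counts",
    "roc_points",
    "z_transform",
    "trapezoid_auc",
    "subject_stats",
    "image_stats",
    "image_level_association",
    "classify_old",
]

MEM_HIGH_THRESHOLD = 0.75
MEM_MID_THRESHOLD = 0.55


def classify_old(response: np.ndarray | int, B: int = 6) -> np.ndarray | bool:
    """Map a 1..B confidence response to the binary old/new decision.

    Responses above the scale midpoint (4..6 on the 6-point scale) count as
    "old" decisions.
    """
    return np.asarray(response) > B // 2


def corrected_rates(
    hits: int, n_old: int, fas: int, n_new: int
) -> tuple[float, float]:
    """Snodgrass–Corwin corrected hit and false-alarm rates.

    ``hit_rate = (hits + 0.5)/(n_old + 1)``, same for false alarms; both lie
    strictly inside (0, 1) for any admissible counts.
    """
    if n_old < 1 or n_new < 1:
        raise ValueError("need at least one old and one new trial")
    if not 0 <= hits <= n_old:
        raise ValueError(f"hits={hits} outside [0, {n_old}]")
    if not 0 <= fas <= n_new:
        raise ValueError(f"fas={fas} outside [0, {n_new}]")
    return (hits + 0.5) / (n_old + 1), (fas + 0.5) / (n_new + 1)


def dprime(hit_rate: float, fa_rate: float) -> float:
    """Sensitivity ``d' = z(hit rate) − z(false-alarm rate)``.

    Rates must lie strictly inside (0, 1); apply :func:`corrected_rates`
    first.
    """
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError("rates must lie strictly inside (0, 1); correct them first")
    return float(ndtri(hit_rate) - ndtri(fa_rate))


def bin_memorability(score: float) -> Literal["low", "mid", "high"]:
    """Categorise a memorability score: > .75 high, (.55, .75] mid, else low.

    Boundary scores go to the lower bin (the thresholds are strict
    inequalities on the high side).
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"memorability must be in [0, 1], got {score}")
    if score > MEM_HIGH_THRESHOLD:
        return "high"
    if score > MEM_MID_THRESHOLD:
        return "mid"
    return "low"


def exclude_at_chance(
    trials: pd.DataFrame, alpha: float = 0.05, B: int = 6
) -> tuple[list[str], list[str]]:
    """Split subjects into (kept, excluded) by an exact binomial test.

    A subject is kept only when their overall old/new accuracy is
    significantly above 0.5 (one-sided exact binomial test at ``alpha``);
    at-chance performers are excluded.
    """
    kept: list[str] = []
    excluded: list[str] = []
    for subject, sub in trials.groupby("subject", sort=True):
        said_old = classify_old(sub["response"].to_numpy(), B=B)
        correct = int(np.sum(said_old == (sub["status"].to_numpy() == "old")))
        n = len(sub)
        p = stats.binomtest(correct, n, 0.5, alternative="greater").pvalue
        (kept if p < alpha else excluded).append(str(subject))
    return kept, excluded


# ---------------------------------------------------------------------------
# ROC construction
# ---------------------------------------------------------------------------

def rating_counts(trials: pd.DataFrame, B: int = 6) -> np.ndarray:
    """2×B response-count table (row 0: old items, row 1: new items)."""
    resp = trials["response"].to_numpy()
    if np.any((resp < 1) | (resp > B)):
        raise ValueError(f"responses outside 1..{B}")
    counts = np.zeros((2, B), dtype=int)
    for row, status in enumerate(("old", "new")):
        sel = resp[trials["status"].to_numpy() == status]
        counts[row] = np.bincount(sel, minlength=B + 1)[1:]
    return counts


@dataclass(frozen=True)
class ROCPoints:
    """Cumulative (false-alarm, hit) pairs from the most to the least
    conservative criterion; length B − 1, anchors (0,0)/(1,1) not included."""

    fa: np.ndarray
    hit: np.ndarray


def roc_points(counts: np.ndarray) -> ROCPoints:
    """Empirical ROC points from a 2×B rating-count table.

    Point j is the proportion of responses in bins B..B−j, i.e. cumulative
    sums from the "sure old" end, one point per interior criterion.
    """
    counts = np.asarray(counts, dtype=float)
    n_old, n_new = counts.sum(axis=1)
    if n_old <= 0 or n_new <= 0:
        raise ValueError("both old and new rows must contain trials")
    hit = np.cumsum(counts[0, ::-1])[:-1] / n_old
    fa = np.cumsum(counts[1, ::-1])[:-1] / n_new
    return ROCPoints(fa=fa, hit=hit)


def z_transform(points: ROCPoints) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-normal transform of the ROC points (zROC).

    Pairs where either coordinate is 0 or 1 are dropped: the transform
    diverges there.
    """
    interior = (
        (points.fa > 0) & (points.fa < 1) & (points.hit > 0) & (points.hit < 1)
    )
    return ndtri(points.fa[interior]), ndtri(points.hit[interior])


def trapezoid_auc(points: ROCPoints) -> float:
    """Area under the empirical ROC by the trapezoidal rule.

    Anchors (0,0) and (1,1) are appended; points are sorted by false-alarm
    rate (hit rate as tie-break).  0.5 for a chance ROC on the diagonal,
    1.0 for a perfect step function.
    """
    fa = np.concatenate(([0.0], np.asarray(points.fa, float), [1.0]))
    hit = np.concatenate(([0.0], np.asarray(points.hit, float), [1.0]))
    order = np.lexsort((hit, fa))
    return float(np.trapezoid(hit[order], fa[order]))


# ---------------------------------------------------------------------------
# Per-subject and per-image summary tables
# ---------------------------------------------------------------------------

def _pooled_rates(sub: pd.DataFrame, B: int) -> tuple[float, float, int, int]:
    is_old = sub["status"].to_numpy() == "old"
    said_old = classify_old(sub["response"].to_numpy(), B=B)
    n_old = int(is_old.sum())
    n_new = int((~is_old).sum())
    hits = int((said_old & is_old).sum())
    fas = int((said_old & ~is_old).sum())
    hr, far = corrected_rates(hits, n_old, fas, n_new)
    return hr, far, n_old, n_new


def subject_stats(trials: pd.DataFrame, B: int = 6) -> pd.DataFrame:
    """Per-subject × memorability-bin corrected rates, d', and trapezoidal
    AUC (plus an ``overall`` row per subject)."""
    trials = trials.assign(
        mem_bin=[bin_memorability(m) for m in trials["memorability"]]
    )
    rows = []
    for subject, sub in trials.groupby("subject", sort=True):
        groups = [("overall", sub)] + [
            (b, g) for b, g in sub.groupby("mem_bin", sort=True)
        ]
        for label, g in groups:
            if not ((g["status"] == "old").any() and (g["status"] == "new").any()):
                continue
            hr, far, n_old, n_new = _pooled_rates(g, B)
            auc = trapezoid_auc(roc_points(rating_counts(g, B)))
            rows.append(
                {
                    "subject": subject,
                    "mem_bin": label,
                    "n_old": n_old,
                    "n_new": n_new,
                    "hit_rate": hr,
                    "fa_rate": far,
                    "dprime": dprime(hr, far),
                    "auc": auc,
                }
            )
    return pd.DataFrame(rows)


def image_stats(trials: pd.DataFrame, B: int = 6) -> pd.DataFrame:
    """Per-image statistics pooled over subjects.

    For each image, trials where it was a target contribute hits and trials
    where it was a foil contribute false alarms; the correction is applied
    after pooling.  AUC is computed from the pooled rating counts.
    """
    rows = []
    for image, g in trials.groupby("image", sort=True):
        is_old = g["status"].to_numpy() == "old"
        if not (is_old.any() and (~is_old).any()):
            continue
        hr, far, n_old, n_new = _pooled_rates(g, B)
        auc = trapezoid_auc(roc_points(rating_counts(g, B)))
        mem = float(g["memorability"].iloc[0])
        rows.append(
            {
                "image": image,
                "memorability": mem,
                "mem_bin": bin_memorability(mem),
                "n_old": n_old,
                "n_new": n_new,
                "hit_rate": hr,
                "fa_rate": far,
                "dprime": dprime(hr, far),
                "auc": auc,
            }
        )
    return pd.DataFrame(rows)


def plot_roc(
    points: ROCPoints | Sequence[ROCPoints],
    path: str | None = None,
    labels: Sequence[str] | None = None,
    z: bool = False,
):
    """Plot one or more ROC curves (or zROCs with ``z=True``).

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(points, ROCPoints):
        points = [points]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for i, pts in enumerate(points):
        label = labels[i] if labels else None
        if z:
            zf, zh = z_transform(pts)
            ax.plot(zf, zh, "o-", label=label)
        else:
            fa = np.concatenate(([0.0], pts.fa, [1.0]))
            hit = np.concatenate(([0.0], pts.hit, [1.0]))
            order = np.lexsort((hit, fa))
            ax.plot(fa[order], hit[order], "o-", label=label)
    if z:
        ax.set_xlabel("z(false-alarm rate)")
        ax.set_ylabel("z(hit rate)")
    else:
        ax.plot([0, 1], [0, 1], "k:", lw=1)
        ax.set_xlabel("false-alarm rate")
        ax.set_ylabel("hit rate")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
    if labels:
        ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def image_level_association(
    table: pd.DataFrame,
    field: str,
    method: Literal["pearson", "spearman"] = "pearson",
    against: str = "memorability",
) -> tuple[float, float]:
    """Correlate a per-image statistic with memorability (or another column).

    Returns (coefficient, two-sided p).  Requires at least 3 images and
    non-constant columns.
    """
    x = table[against].to_numpy(dtype=float)
    y = table[field].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 images with defined values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vectors have no defined correlation")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)
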