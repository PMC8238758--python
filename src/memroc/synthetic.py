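"""Synthetic recognition-memory observers with memorability-linked parameters.

The generator emulates a scene-recognition study: each image carries an
intrinsic *memorability* score in [0, 1] (its hit rate in large-sample
recognition experiments), and simulated observers respond on a B-point
confidence scale (1 = sure new … B = sure old) and give a remember/know
statement for "old" responses or a detailed-new/unfamiliar statement for
"new" responses.

Observers are generative DPSD or UVSD processes whose parameters are linked
to item memorability:

* ``Ro(m) = expit(a + b·m)`` — recollection probability (DPSD),
* ``d'(m) = a + b·m``        — familiarity / sensitivity,
* ``P(D|m) = expit(a + b·m)`` — probability of a detailed-new statement
  given a "new" response.

A DPSD recollection event always produces the most-confident "old"
response with statement R; non-recollected "old" responses get K.  UVSD
observers have no recollection event, so R is assigned by the confidence
convention "R iff response = B".  D/U statements use a single logistic link
on memorability for both models (no recollect-to-reject mechanism).

Each simulated subject runs on its own RNG stream spawned from the master
seed, so tables are reproducible independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ItemSpec",
    "ObserverSpec",
    "SimDesign",
    "simulate_memorability",
    "simulate_observer",
    "simulate_experiment",
    "default_observer_population",
    "DEFAULT_CRITERIA",
]

#: Default decision criteria (B = 6). Placed so that a mid-memorability
#: observer produces hit rates near .7 and false-alarm rates near .2,
#: matching the rates typical of scene-recognition studies with separate
#: encoding and test phases.
DEFAULT_CRITERIA: tuple[float, ...] = (-0.5, 0.2, 0.85, 1.5, 2.2)

#: Default memorability→parameter links (logit scale for ro and p_detailed,
#: linear for d').  Memorability acts mainly on recollection and only weakly
#: on familiarity — the pattern found with facilitated encoding: at the
#: low/high bin means (.45 / .87) of FIGRIM-style image sets these give
#: Ro ≈ .12 / .48, d' ≈ .97 / 1.18, P(D|new) ≈ .2 / .45, and hit /
#: false-alarm rates near .6-.8 / .2 under the default criteria.
DEFAULT_RO_LINK: tuple[float, float] = (-4.0, 4.5)
DEFAULT_DPRIME_LINK: tuple[float, float] = (0.75, 0.5)
DEFAULT_P_DETAILED_LINK: tuple[float, float] = (-2.6, 2.8)


@dataclass(frozen=True)
class ItemSpec:
    """One stimulus image: identifier, memorability score, old/new status."""

    image_id: str
    memorability: float
    status: Literal["old", "new"] = "new"

    def __post_init__(self) -> None:
        if not 0.0 <= self.memorability <= 1.0:
            raise ValueError(
                f"memorability must be in [0, 1], got {self.memorability}"
            )
        if self.status not in ("old", "new"):
            raise ValueError(f"status must be 'old' or 'new', got {self.status!r}")


@dataclass(frozen=True)
class ObserverSpec:
    """A generative DPSD or UVSD observer with memorability-linked parameters."""

    model: Literal["DPSD", "UVSD"] = "DPSD"
    ro_link: tuple[float, float] = DEFAULT_RO_LINK
    dprime_link: tuple[float, float] = DEFAULT_DPRIME_LINK
    vo: float = 1.0
    criteria: tuple[float, ...] = DEFAULT_CRITERIA
    p_detailed_link: tuple[float, float] = DEFAULT_P_DETAILED_LINK
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("DPSD", "UVSD"):
            raise ValueError(f"model must be DPSD or UVSD, got {self.model!r}")
        if self.vo <= 0:
            raise ValueError(f"vo must be > 0, got {self.vo}")
        c = self.criteria
        if any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError(f"criteria must be strictly increasing, got {c}")

    def ro(self, m: np.ndarray | float) -> np.ndarray | float:
        return expit(self.ro_link[0] + self.ro_link[1] * np.asarray(m, dtype=float))

    def dprime(self, m: np.ndarray | float) -> np.ndarray | float:
        return self.dprime_link[0] + self.dprime_link[1] * np.asarray(m, dtype=float)

    def p_detailed(self, m: np.ndarray | float) -> np.ndarray | float:
        a, b = self.p_detailed_link
        return expit(a + b * np.asarray(m, dtype=float))


@dataclass(frozen=True)
class SimDesign:
    """Experiment geometry: subjects, old/new counts per subject, confidence
    bins, and the distribution memorability scores are drawn from.

    ``memorability`` is a distribution spec: ``("uniform", a, b)``,
    ``("beta", alpha, beta)`` or ``("explicit", [scores...])``.
    """

    n_subjects: int = 45
    n_old: int = 180
    n_new: int = 180
    n_bins: int = 6
    memorability: tuple = ("uniform", 0.3, 0.95)

    def __post_init__(self) -> None:
        if self.n_old <= 0 or self.n_new <= 0:
            raise ValueError("n_old and n_new must be positive")
        if self.n_bins < 2:
            raise ValueError("need at least 2 confidence bins")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")


def exp1_design(n_subjects: int = 45) -> SimDesign:
    """330 old + 330 foils per subject (three memorability bins' worth)."""
    return SimDesign(n_subjects=n_subjects, n_old=330, n_new=330)


def exp2_design(n_subjects: int = 42) -> SimDesign:
    """180 old + 180 foils per subject."""
    return SimDesign(n_subjects=n_subjects, n_old=180, n_new=180)


# ---------------------------------------------------------------------------
# Item generation
# ---------------------------------------------------------------------------

def simulate_memorability(
    n_images: int,
    dist: tuple = ("uniform", 0.3, 0.95),
    seed: int | np.random.Generator = 0,
) -> list[ItemSpec]:
    """Draw per-image memorability scores from a distribution spec.

    ``dist`` is ``("uniform", a, b)`` with ``0 <= a <= b <= 1``,
    ``("beta", alpha, beta)``, or ``("explicit", scores)`` which returns the
    given scores verbatim (``n_images`` must match their number).
    """
    if n_images <= 0:
        raise ValueError(f"n_images must be positive, got {n_images}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kind = dist[0]
    if kind == "uniform":
        _, a, b = dist
        if not (0.0 <= a <= b <= 1.0):
            raise ValueError(f"uniform bounds must satisfy 0 <= a <= b <= 1, got {dist}")
        scores = rng.uniform(a, b, size=n_images)
    elif kind == "beta":
        _, alpha, beta = dist
        if alpha <= 0 or beta <= 0:
            raise ValueError(f"beta shape parameters must be positive, got {dist}")
        scores = rng.beta(alpha, beta, size=n_images)
    elif kind == "explicit":
        scores = np.asarray(dist[1], dtype=float)
        if len(scores) != n_images:
            raise ValueError(
                f"explicit list has {len(scores)} scores but n_images={n_images}"
            )
        if np.any(scores < 0) or np.any(scores > 1):
            raise ValueError("explicit scores must lie in [0, 1]")
    else:
        raise ValueError(f"unknown distribution kind {kind!r}")
    width = max(4, len(str(n_images)))
    return [
        ItemSpec(image_id=f"img{i:0{width}d}", memorability=float(s))
        for i, s in enumerate(scores)
    ]


# ---------------------------------------------------------------------------
# Observer simulation
# ---------------------------------------------------------------------------

def simulate_observer(
    obs: ObserverSpec,
    items: Sequence[ItemSpec],
    B: int = 6,
    rng: np.random.Generator | None = None,
    subject: str = "s01",
) -> pd.DataFrame:
    """Simulate one observer's test-phase responses to ``items``.

    Returns a trial table with columns
    ``subject, image, status, memorability, response, statement``.

    The random draws are consumed in fixed blocks (strength noise,
    recollection uniforms, statement uniforms) so that a DPSD observer with
    ``Ro = 0`` and a UVSD observer with ``vo = 1`` produce identical
    response columns under the same seed.
    """
    if not items:
        raise ValueError("items must be nonempty")
    if len(obs.criteria) != B - 1:
        raise ValueError(
            f"observer has {len(obs.criteria)} criteria but B={B} needs {B - 1}"
        )
    if rng is None:
        rng = np.random.default_rng(obs.seed)

    m = np.array([it.memorability for it in items], dtype=float)
    is_old = np.array([it.status == "old" for it in items])
    n = len(items)

    ro = np.asarray(obs.ro(m), dtype=float)
    dprime = np.asarray(obs.dprime(m), dtype=float)
    p_det = np.asarray(obs.p_detailed(m), dtype=float)
    if np.any((ro < 0) | (ro > 1)) or np.any((p_det < 0) | (p_det > 1)):
        raise ValueError("link functions produced probabilities outside [0, 1]")

    noise = rng.standard_normal(n)
    recollect_u = rng.uniform(size=n)  # drawn for both models to align streams
    statement_u = rng.uniform(size=n)

    sd_old = obs.vo if obs.model == "UVSD" else 1.0
    strength = np.where(is_old, dprime + sd_old * noise, noise)

    criteria = np.asarray(obs.criteria, dtype=float)
    response = np.searchsorted(criteria, strength, side="left") + 1

    if obs.model == "DPSD":
        recollected = is_old & (recollect_u < ro)
        response = np.where(recollected, B, response)
    else:
        recollected = np.zeros(n, dtype=bool)

    said_old = response > B // 2
    statement = np.empty(n, dtype=object)
    if obs.model == "DPSD":
        statement[said_old] = np.where(recollected[said_old], "R", "K")
    else:
        statement[said_old] = np.where(response[said_old] == B, "R", "K")
    statement[~said_old] = np.where(statement_u[~said_old] < p_det[~said_old], "D", "U")

    return pd.DataFrame(
        {
            "subject": subject,
            "image": [it.image_id for it in items],
            "status": np.where(is_old, "old", "new"),
            "memorability": m,
            "response": response.astype(int),
            "statement": statement,
        }
    )


def default_observer_population(
    n_subjects: int,
    model: Literal["DPSD", "UVSD"] = "DPSD",
    master_seed: int = 0,
    **overrides,
) -> list[ObserverSpec]:
    """A homogeneous population of observers sharing the default links."""
    return [
        ObserverSpec(model=model, seed=master_seed + i, **overrides)
        for i in range(n_subjects)
    ]


def simulate_experiment(
    design: SimDesign,
    obs_population: Sequence[ObserverSpec],
    master_seed: int = 0,
) -> pd.DataFrame:
    """Simulate a full experiment: one trial table over all subjects.

    A shared pool of ``n_old + n_new`` items is generated once; each item is
    a target for (roughly) half of the subjects and a foil for the other
    half, by alternating which half of the pool is "old" across subjects
    (exact counterbalancing requires ``n_old == n_new``).  Subject streams
    are spawned from ``master_seed`` so per-subject data are reproducible.
    """
    if len(obs_population) != design.n_subjects:
        raise ValueError(
            f"population size {len(obs_population)} != n_subjects {design.n_subjects}"
        )
    n_pool = design.n_old + design.n_new
    pool = simulate_memorability(
        n_pool, design.memorability,
        seed=np.random.default_rng(np.random.SeedSequence([master_seed, n_pool])),
    )
    tables = []
    for i, obs in enumerate(obs_population):
        rng = np.random.default_rng(np.random.SeedSequence([master_seed, i]))
        old_mask = np.zeros(n_pool, dtype=bool)
        if design.n_old == design.n_new:
            if i % 2 == 0:
                old_mask[: design.n_old] = True
            else:
                old_mask[design.n_old:] = True
        else:  # unequal designs cannot counterbalance exactly; randomise
            old_mask[rng.choice(n_pool, size=design.n_old, replace=False)] = True
        items = [
            ItemSpec(
                image_id=it.image_id,
                memorability=it.memorability,
                status="old" if old_mask[j] else "new",
            )
            for j, it in enumerate(pool)
        ]
        tables.append(
            simulate_observer(
                obs, items, B=design.n_bins, rng=rng, subject=f"s{i + 1:03d}"
            )
        )
    return pd.concat(tables, ignore_index=True)
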