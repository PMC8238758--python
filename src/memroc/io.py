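"""Trial-table readers/writers, run configuration, and the end-to-end
pipeline.

The on-disk trial format is a UTF-8 comma-separated table with a header and
columns ``subject,image,status,memorability,response,statement``: status is
old/new, responses are 1..B (1 = sure new … B = sure old), and the
statement is R/K for responses classified "old", D/U for responses
classified "new" (``none`` is accepted where a statement was not
collected).  Tables written with a separate old/new decision plus a
3-point confidence column ("Exp-1 style") are mapped onto the 6-point
scale as ``("new", c) -> 4 - c`` and ``("old", c) -> 3 + c``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import descriptives, quantiles, rk, roc_models, synthetic

logger = logging.getLogger("memroc")

REQUIRED_COLUMNS = ("subject", "image", "status", "memorability", "response", "statement")
EXP1_COLUMNS = ("subject", "image", "status", "memorability", "oldnew", "confidence")

__all__ = [
    "read_trials",
    "write_trials",
    "RunConfig",
    "run_pipeline",
]


class TrialValidationError(ValueError):
    """Raised when a trial table violates the schema; names offending rows."""


def _map_exp1_scale(oldnew: pd.Series, confidence: pd.Series) -> pd.Series:
    """Collapse an old/new decision + 3-point confidence onto the 6-point scale."""
    conf = confidence.astype(int)
    if ((conf < 1) | (conf > 3)).any():
        raise TrialValidationError("Exp-1-style confidence must be in 1..3")
    return pd.Series(
        np.where(oldnew.str.lower() == "old", 3 + conf, 4 - conf),
        index=oldnew.index,
    )


def validate_trials(trials: pd.DataFrame, B: int = 6) -> pd.DataFrame:
    """Validate (and lightly normalise) an in-memory trial table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialValidationError(f"missing required columns: {missing}")
    t = trials.copy()
    t["status"] = t["status"].astype(str).str.lower()
    t["statement"] = t["statement"].astype(str)
    bad_rows: list[str] = []
    if not t["status"].isin(["old", "new"]).all():
        rows = t.index[~t["status"].isin(["old", "new"])].tolist()[:5]
        bad_rows.append(f"status not old/new at rows {rows}")
    resp = pd.to_numeric(t["response"], errors="coerce")
    bad = resp.isna() | (resp < 1) | (resp > B) | (resp != resp.round())
    if bad.any():
        bad_rows.append(f"responses outside 1..{B} at rows {t.index[bad].tolist()[:5]}")
    else:
        t["response"] = resp.astype(int)
    mem = pd.to_numeric(t["memorability"], errors="coerce")
    if (mem.isna() | (mem < 0) | (mem > 1)).any():
        rows = t.index[mem.isna() | (mem < 0) | (mem > 1)].tolist()[:5]
        bad_rows.append(f"memorability outside [0, 1] at rows {rows}")
    if not bad_rows:
        said_old = descriptives.classify_old(t["response"].to_numpy(), B=B)
        ok_old = t["statement"].isin(["R", "K", "none"]).to_numpy()
        ok_new = t["statement"].isin(["D", "U", "none"]).to_numpy()
        mismatch = np.where(said_old, ~ok_old, ~ok_new)
        if mismatch.any():
            rows = t.index[mismatch].tolist()[:5]
            bad_rows.append(
                f"statement/response class mismatch at rows {rows} "
                "(R/K require an 'old' response, D/U a 'new' response)"
            )
    if bad_rows:
        raise TrialValidationError("; ".join(bad_rows))
    return t


def read_trials(path: str | Path, B: int = 6) -> pd.DataFrame:
    """Read and validate a trial table; Exp-1-style columns are auto-mapped."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    if "response" not in raw.columns and {"oldnew", "confidence"} <= set(raw.columns):
        raw["response"] = _map_exp1_scale(raw["oldnew"].astype(str), raw["confidence"])
        raw["statement"] = raw.get("statement", "none")
        raw = raw.drop(columns=["oldnew", "confidence"])
    return validate_trials(raw, B=B)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as UTF-8 CSV with the canonical column order."""
    trials[list(REQUIRED_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All knobs of an end-to-end analysis run.

    ``input`` may be a trial-table path; when None a synthetic experiment is
    generated (``sim_*`` fields).  All randomness flows from ``seed``.
    """

    input: str | None = None
    output_dir: str = "memroc_out"
    B: int = 6
    Q: int = 30
    prior_scale: float = rk.DEFAULT_PRIOR_SCALE
    alpha: float = 0.05
    seed: int = 0
    sim_model: str = "DPSD"
    sim_n_subjects: int = 42
    sim_n_old: int = 180
    sim_n_new: int = 180

    def __post_init__(self) -> None:
        if self.B < 2 or self.Q < 2:
            raise ValueError("B and Q must both be at least 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_or_simulate(config: RunConfig) -> pd.DataFrame:
    if config.input is not None:
        return read_trials(config.input, B=config.B)
    design = synthetic.SimDesign(
        n_subjects=config.sim_n_subjects,
        n_old=config.sim_n_old,
        n_new=config.sim_n_new,
        n_bins=config.B,
    )
    pop = synthetic.default_observer_population(
        design.n_subjects, model=config.sim_model, master_seed=config.seed
    )
    return synthetic.simulate_experiment(design, pop, master_seed=config.seed)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all outputs.

    Stages: at-chance exclusion → descriptives → per-subject model fits →
    winning-model verdict → scaled differences + Bayes factors → quantile
    regression.  Writes delimited tables, a JSON manifest recording the
    config hash, seed and stage results, and returns the manifest dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "stages": {},
    }
    stage = "load"
    try:
        trials = _load_or_simulate(config)
        write_trials(trials, out / "trials.csv")
        config.to_yaml(out / "config.yaml")

        stage = "exclusion"
        kept, excluded = descriptives.exclude_at_chance(trials, alpha=config.alpha, B=config.B)
        manifest["stages"]["exclusion"] = {"kept": kept, "excluded": excluded}
        trials = trials[trials["subject"].isin(kept)]
        logger.info("excluded %d at-chance subjects", len(excluded))

        stage = "descriptives"
        subj = descriptives.subject_stats(trials, B=config.B)
        img = descriptives.image_stats(trials, B=config.B)
        subj.to_csv(out / "subject_stats.csv", index=False)
        img.to_csv(out / "image_stats.csv", index=False)
        r_hit, p_hit = descriptives.image_level_association(img, "hit_rate")
        manifest["stages"]["descriptives"] = {
            "n_subjects": int(subj["subject"].nunique()),
            "n_images": len(img),
            "memorability_hit_rate_r": r_hit,
            "memorability_hit_rate_p": p_hit,
        }

        stage = "roc_fits"
        pairs = []
        fit_rows = []
        for subject, g in trials.groupby("subject", sort=True):
            counts = descriptives.rating_counts(g, B=config.B)
            d = roc_models.fit_model(counts, "DPSD", seed=config.seed)
            u = roc_models.fit_model(counts, "UVSD", seed=config.seed)
            pairs.append((d, u))
            fit_rows.append(
                {
                    "subject": subject,
                    "dpsd_ro": d.params.ro,
                    "dpsd_dprime": d.params.dprime,
                    "dpsd_bic": d.bic,
                    "dpsd_g_p": d.p,
                    "uvsd_dprime": u.params.dprime,
                    "uvsd_vo": u.params.vo,
                    "uvsd_bic": u.bic,
                    "uvsd_g_p": u.p,
                }
            )
        pd.DataFrame(fit_rows).to_csv(out / "subject_fits.csv", index=False)
        selection = roc_models.select_winning_model(pairs)
        manifest["stages"]["model_selection"] = dataclasses.asdict(selection)

        stage = "rk"
        summary = rk.table3_style_summary(trials, B=config.B)
        summary.to_csv(out / "statement_summary.csv", index=False)
        ytab = rk.subject_scaled_differences(trials, "hits", B=config.B)
        wide = ytab.pivot(index="subject", columns="mem_bin", values="y")
        bf_report = {}
        if {"high", "low"} <= set(wide.columns):
            diffs = (wide["high"] - wide["low"]).to_numpy()
            bf = rk.bayes_t_test(diffs, direction="greater", prior_scale=config.prior_scale)
            bf_report["yold_high_vs_low"] = {
                "t": bf.t, "n": bf.n, "bf10": bf.bf10, "cohens_d": bf.cohens_d,
            }
        scores = rk.image_statement_scores(trials, B=config.B)
        scores.to_csv(out / "image_statement_scores.csv", index=False)
        corrs = rk.image_score_correlations(scores)
        manifest["stages"]["rk"] = {
            "bayes_factors": bf_report,
            "image_correlations": {k: {"r": v[0], "p": v[1]} for k, v in corrs.items()},
        }

        stage = "quantile_regression"
        qfits = quantiles.fit_quantiles(trials, Q=config.Q, B=config.B, seed=config.seed)
        qtab = quantiles.quantile_parameter_table(qfits)
        qtab.to_csv(out / "quantile_params.csv", index=False)
        usable = qtab[qtab["dpsd_converged"] & qtab["uvsd_converged"]]
        dpsd_reg = quantiles.ordinal_regression(usable, ["dpsd_ro", "dpsd_dprime"])
        uvsd_reg = quantiles.ordinal_regression(usable, ["uvsd_dprime", "uvsd_vo"])
        manifest["stages"]["quantile_regression"] = {
            "exploratory": True,
            "dpsd": dataclasses.asdict(dpsd_reg),
            "uvsd": dataclasses.asdict(uvsd_reg),
        }
    except Exception as exc:  # preserve partial outputs, name the stage
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
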