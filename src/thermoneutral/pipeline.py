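"""End-to-end orchestration: traces -> msRMR table -> TNZ -> status model.

Every stage is a pure function of (inputs, config, seed): the root seed is
split deterministically per stage via ``numpy.random.SeedSequence`` so a
stage can be re-run in isolation, and all written artifacts are
byte-reproducible (no timestamps inside output files; wall-clock time goes
to the log only).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .glmm import filter_to_tnz, forward_select, selection_table, status_contrast
from .respirometry import (
    extract_rmr,
    read_calibration_csv,
    read_trace_csv,
    trace_to_vo2,
)
from .trend import (
    NoTnzDetectedError,
    TemperatureGroups,
    TnzEstimate,
    step_down_tnz,
    steps_table,
)

log = logging.getLogger("thermoneutral")

STATUSES = ("NR", "R")


class NotEstimableError(RuntimeError):
    """A stage's preconditions hold but the quantity cannot be estimated."""


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; ``seed`` is mandatory because the
    permutation tests are stochastic."""

    seed: int
    output_dir: str = "out"
    # respirometry inputs (either these ...)
    traces_dir: str | None = None
    trials_csv: str | None = None
    calibration_csv: str | None = None
    metadata_csv: str | None = None
    # ... or a ready-made tidy table
    msrmr_csv: str | None = None
    # respirometry settings
    window_s: float = 600.0
    acclimation_s: float = 1800.0
    stability_cv: float = 0.10
    # TNZ settings
    alpha: float = 0.05
    min_group_n: int = 5
    n_perm: int = 10_000
    # model settings
    candidates: list[str] = field(
        default_factory=lambda: ["sqrt_body_mass", "ta_factor", "status"])
    n_quad: int = 11

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.n_perm < 1 or self.min_group_n < 1:
            raise ValueError("n_perm and min_group_n must be >= 1")
        if self.window_s <= 0 or self.stability_cv <= 0:
            raise ValueError("window_s and stability_cv must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def rng_for(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the root seed."""
        digest = int(hashlib.sha256(stage.encode()).hexdigest()[:8], 16)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(digest,)))


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Stage 1: respirometry

def run_respirometry(config: PipelineConfig) -> pd.DataFrame:
    """Process every trial listed in the trials manifest into msRMR.

    Writes ``respirometry.tsv`` (one row per trial, invalid trials retained
    with a reason) and ``msrmr.csv`` (valid trials only, tidy schema).
    Returns the tidy table.
    """
    for name in ("traces_dir", "trials_csv", "calibration_csv", "metadata_csv"):
        if getattr(config, name) is None:
            raise ValueError(f"config.{name} is required for run_respirometry")
    trials = pd.read_csv(config.trials_csv)
    if trials.empty:
        raise ValueError(f"{config.trials_csv}: no trials listed")
    meta = pd.read_csv(config.metadata_csv).set_index("animal_id")
    cals = read_calibration_csv(config.calibration_csv)
    traces_dir = Path(config.traces_dir)

    rows = []
    for _, trial in trials.iterrows():
        trial_id = str(trial["trial_id"])
        animal_id = str(trial["animal_id"])
        if animal_id not in meta.index:
            raise ValueError(
                f"trial {trial_id}: animal {animal_id!r} missing from metadata")
        if trial_id not in cals or "start" not in cals[trial_id]:
            raise ValueError(f"trial {trial_id}: no start calibration")
        path = traces_dir / str(trial["trace_file"])
        if not path.exists():
            raise ValueError(f"trial {trial_id}: trace file {path} not found")
        mass = float(meta.loc[animal_id, "body_mass_g"])
        trace = read_trace_csv(path, animal_id=animal_id, trial_id=trial_id,
                               body_mass_g=mass)
        series = trace_to_vo2(trace, cals[trial_id]["start"],
                              cals[trial_id].get("end"))
        acclim = float(trial.get("acclimation_s", config.acclimation_s))
        res = extract_rmr(series, mass, window_s=config.window_s,
                          acclimation_s=acclim,
                          stability_cv=config.stability_cv)
        rows.append({
            "animal_id": animal_id,
            "trial_id": trial_id,
            "ta_c": float(trial["ta_c"]),
            "rmr_ml_h": res.rmr_ml_h,
            "msrmr": res.msrmr,
            "window_start_s": res.window_start_s,
            "window_cv": res.window_cv,
            "valid": res.valid,
            "reason": res.reason,
        })
    report = pd.DataFrame(rows)
    out = _outdir(config)
    report.to_csv(out / "respirometry.tsv", sep="\t", index=False)

    valid = report[report["valid"]].copy()
    tidy = valid.merge(meta.reset_index(), on="animal_id", how="left")
    tidy = tidy[["animal_id", "sex", "status", "body_mass_g", "age_y",
                 "ta_c", "msrmr"]]
    tidy.to_csv(out / "msrmr.csv", index=False)
    n_bad = int((~report["valid"]).sum())
    log.info("respirometry: %d trials, %d invalid", len(report), n_bad)
    return tidy


def load_msrmr_table(config: PipelineConfig) -> pd.DataFrame:
    if config.msrmr_csv is None:
        raise ValueError("config.msrmr_csv is not set")
    table = pd.read_csv(config.msrmr_csv)
    missing = {"animal_id", "status", "ta_c", "msrmr"} - set(table.columns)
    if missing:
        raise ValueError(f"{config.msrmr_csv}: missing columns {sorted(missing)}")
    return table


# ---------------------------------------------------------------------------
# Stage 2: TNZ

def run_tnz(config: PipelineConfig,
            table: pd.DataFrame) -> dict[str, TnzEstimate | None]:
    """Step-down TNZ estimation per reproductive status.

    A status failing its preconditions (too few qualifying temperatures, or
    a step-down that exhausts the design) is reported not-estimable and the
    run continues. Writes ``tnz_<status>.json`` and a combined ``steps.tsv``
    step trail.
    """
    out = _outdir(config)
    estimates: dict[str, TnzEstimate | None] = {}
    trails = []
    for status in STATUSES:
        sub = table[table["status"] == status]
        if sub.empty:
            estimates[status] = None
            _write_json(out / f"tnz_{status}.json",
                        {"status": status, "estimable": False,
                         "reason": "no data for this status"})
            continue
        rng = config.rng_for(f"tnz-{status}")
        try:
            est = step_down_tnz(TemperatureGroups.from_table(sub),
                                alpha=config.alpha,
                                min_group_n=config.min_group_n,
                                n_perm=config.n_perm, rng=rng)
        except (ValueError, NoTnzDetectedError) as exc:
            log.warning("TNZ not estimable for %s: %s", status, exc)
            estimates[status] = None
            payload = {"status": status, "estimable": False, "reason": str(exc)}
            if isinstance(exc, NoTnzDetectedError):
                t = steps_table(exc.steps)
                t.insert(0, "status", status)
                trails.append(t)
            _write_json(out / f"tnz_{status}.json", payload)
            continue
        estimates[status] = est
        _write_json(out / f"tnz_{status}.json",
                    {"status": status, "estimable": True, **est.to_dict()})
        t = steps_table(est.steps)
        t.insert(0, "status", status)
        trails.append(t)
    if trails:
        pd.concat(trails, ignore_index=True).to_csv(
            out / "steps.tsv", sep="\t", index=False)
    return estimates


# ---------------------------------------------------------------------------
# Stage 3: status comparison

def run_status_comparison(config: PipelineConfig, table: pd.DataFrame,
                          tnz_estimates: dict[str, TnzEstimate | None]) -> dict:
    """Forward-selected Gamma GLMM on within-TNZ records plus the status
    contrast; writes ``model_report.json`` and ``selection.tsv``."""
    missing = [s for s in STATUSES if tnz_estimates.get(s) is None]
    if missing:
        raise NotEstimableError(
            f"TNZ estimate missing for status {', '.join(missing)}")
    data = filter_to_tnz(table, tnz_estimates)
    if data["animal_id"].nunique() < 3 or len(data) < 6 \
            or data["status"].nunique() < 2:
        raise NotEstimableError(
            "too few within-TNZ records for the mixed model")
    fit, trace, interaction = forward_select(
        data, candidates=tuple(config.candidates), alpha=config.alpha,
        n_quad=config.n_quad)
    if any(c.startswith("status[") for c in fit.design_columns):
        contrast_fit, supplementary = fit, False
    else:
        from .glmm import fit_gamma_glmm
        contrast_fit = fit_gamma_glmm(data, fit.terms + ("status",),
                                      n_quad=config.n_quad)
        supplementary = True
    contrast = status_contrast(contrast_fit)

    out = _outdir(config)
    selection_table(trace).to_csv(out / "selection.tsv", sep="\t", index=False)
    report = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "package_version": __version__,
        },
        "tnz": {s: (tnz_estimates[s].to_dict() if tnz_estimates[s] else None)
                for s in STATUSES},
        "n_within_tnz_records": int(len(data)),
        "selected_fit": fit.to_dict(),
        "selection_trace": [asdict(s) for s in trace],
        "interaction_fit": interaction.to_dict() if interaction else None,
        "status_contrast": {
            "difference": contrast.difference,
            "se": contrast.se,
            "t": contrast.t,
            "p": contrast.p,
            "reference": contrast.reference,
            "from_supplementary_fit": supplementary,
        },
    }
    _write_json(out / "model_report.json", report)
    return report


def run_all(config: PipelineConfig) -> dict:
    """Full chain; input is either raw traces or a tidy msRMR table."""
    if config.msrmr_csv is not None:
        table = load_msrmr_table(config)
    else:
        table = run_respirometry(config)
    estimates = run_tnz(config, table)
    report = run_status_comparison(config, table, estimates)
    _write_json(_outdir(config) / "run_report.json", report)
    return report


def plot_msrmr(table: pd.DataFrame, path) -> None:
    """Diagnostic msRMR-vs-temperature scatter with per-status mean curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for status, color in (("NR", "tab:blue"), ("R", "tab:red")):
        sub = table[table["status"] == status]
        if sub.empty:
            continue
        ax.scatter(sub["ta_c"], sub["msrmr"], s=8, alpha=0.4, color=color,
                   label=status)
        means = sub.groupby("ta_c")["msrmr"].mean()
        ax.plot(means.index, means.values, color=color)
    ax.set_xlabel("ambient temperature (deg C)")
    ax.set_ylabel("msRMR (ml O2 g$^{-1}$ h$^{-1}$)")
    ax.legend(title="status")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
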