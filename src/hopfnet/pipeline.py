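"""Experiment orchestration: configuration, staging, manifests.

The pipeline ties the library modules into the study's three experiments:

* ``fit`` — grid search of (K, lambda) against an empirical PLI target,
  optimal-coupling curve, and the K = k sqrt(lambda) regression;
* ``scaling`` — the square-root invariance check: PLI correlation between
  matched-k simulations at two excitability values, plus the ratio of
  per-excitability optimal couplings;
* ``connectotomy`` — per-patient masking of tumor regions out of the fit
  objective at fixed excitability, paired with a control arm;

plus ``synth`` (generate a ground-truth cohort), ``compare`` (nonparametric
tests between optimal-parameter samples) and ``validate`` (re-check a cohort
directory's invariants).

Inputs follow the cohort directory layout (atlas.csv, connectome.csv,
omega.csv, subjects/*.csv, masks.json). Every run writes a manifest
(parameters, seeds, package version) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import read_atlas, read_connectome, read_tumor_masks
from .connectotomy import connectotomy_refit, pair_with_control
from .errors import ValidationError
from .fitting import (
    DEFAULT_K_GRID,
    DEFAULT_LAMBDA_GRID,
    fit_normalized_coupling,
    grid_search,
    matched_pair_pli_correlation,
    optimal_coupling_curve,
)
from .model import SimulationSettings
from .spectral import epoch_average_pli, median_threshold_pli, read_pli, threshold_pli
from .stats import comparison_table, pool_across_lambda, wilcoxon_rank_sum, wilcoxon_signed_rank
from .synthetic import SyntheticCohortSpec, load_cohort, make_cohort, write_cohort

logger = logging.getLogger(__name__)

EXPERIMENTS = ("synth", "fit", "scaling", "connectotomy", "compare", "validate")


@dataclass
class ExperimentConfig:
    """Validated configuration for one experiment run."""

    out_dir: Path = Path("results")
    data_dir: Path | None = None
    seed: int = 0
    n_ic: int = 10
    target: str = "control_average"  # subject id, or control_average
    threshold: tuple[str, float] | None = None  # ("percentile", X) | ("median", 0)
    K_grid: np.ndarray = field(default_factory=lambda: DEFAULT_K_GRID.copy())
    lambda_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA_GRID.copy())
    lambda_fixed: float = 40.0
    lambda_min_fit: float = 5.0
    C: float = 20.0
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    scaling_k: float = 8.0 / np.sqrt(40.0)
    scaling_lambda_pair: tuple[float, float] = (10.0, 40.0)
    synth: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)
    compare_a: Path | None = None
    compare_b: Path | None = None
    compare_paired: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        problems: list[str] = []
        kwargs: dict = {}
        known = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known and key not in ("model",):
                problems.append(f"unknown config key: {key}")
        for key in ("out_dir", "data_dir", "compare_a", "compare_b"):
            if raw.get(key) is not None:
                kwargs[key] = Path(raw[key])
        for key in ("seed", "n_ic"):
            if key in raw:
                kwargs[key] = int(raw[key])
        for key in ("lambda_fixed", "lambda_min_fit", "C", "scaling_k"):
            if key in raw:
                kwargs[key] = float(raw[key])
        if "target" in raw:
            kwargs["target"] = str(raw["target"])
        if "compare_paired" in raw:
            kwargs["compare_paired"] = bool(raw["compare_paired"])
        if "threshold" in raw and raw["threshold"] is not None:
            kwargs["threshold"] = _parse_threshold(raw["threshold"], problems)
        if "K_grid" in raw:
            kwargs["K_grid"] = _parse_grid(raw["K_grid"], log=True, problems=problems)
        if "lambda_grid" in raw:
            kwargs["lambda_grid"] = _parse_grid(raw["lambda_grid"], log=False,
                                                problems=problems)
        if "scaling_lambda_pair" in raw:
            pair = raw["scaling_lambda_pair"]
            kwargs["scaling_lambda_pair"] = (float(pair[0]), float(pair[1]))
        if "model" in raw and raw["model"]:
            m = dict(raw["model"])
            kwargs["C"] = float(m.pop("C", kwargs.get("C", 20.0)))
            try:
                kwargs["settings"] = SimulationSettings(**{k: float(v) for k, v in m.items()})
            except (TypeError, ValidationError) as exc:
                problems.append(f"model: {exc}")
        if "synth" in raw and raw["synth"]:
            s = dict(raw["synth"])
            for tup_key in ("tumor_size_range", "band_hz"):
                if tup_key in s:
                    s[tup_key] = tuple(s[tup_key])
            try:
                kwargs["synth"] = SyntheticCohortSpec(**s)
            except (TypeError, ValidationError) as exc:
                problems.append(f"synth: {exc}")
        cfg = cls(**kwargs)
        if cfg.n_ic < 1:
            problems.append("n_ic must be >= 1")
        if cfg.K_grid.size == 0 or cfg.lambda_grid.size == 0:
            problems.append("parameter grids must be nonempty")
        if problems:
            raise ValidationError("invalid config:\n  - " + "\n  - ".join(problems))
        return cfg


def _parse_threshold(raw, problems: list[str]):
    if isinstance(raw, str):
        if raw == "median":
            return ("median", 0.0)
        if raw == "none":
            return None
        if raw.startswith("percentile:"):
            return ("percentile", float(raw.split(":", 1)[1]))
        problems.append(f"unrecognized threshold spec: {raw!r}")
        return None
    kind = raw.get("kind")
    if kind == "median":
        return ("median", 0.0)
    if kind == "percentile":
        return ("percentile", float(raw.get("level", 0.0)))
    problems.append(f"unrecognized threshold kind: {kind!r}")
    return None


def _parse_grid(raw, log: bool, problems: list[str]) -> np.ndarray:
    if isinstance(raw, (list, tuple)):
        return np.asarray(raw, dtype=float)
    if isinstance(raw, str):
        return np.asarray([float(x) for x in raw.split(",")], dtype=float)
    if isinstance(raw, dict):
        if "num" in raw:
            lo, hi, num = float(raw["min"]), float(raw["max"]), int(raw["num"])
            return np.geomspace(lo, hi, num) if log else np.linspace(lo, hi, num)
        return np.arange(float(raw["min"]), float(raw["max"]) + 1e-12,
                         float(raw.get("step", 1.0)))
    problems.append(f"cannot parse grid spec: {raw!r}")
    return np.asarray([])


def _apply_threshold(pli, spec):
    if spec is None:
        return pli
    kind, level = spec
    return median_threshold_pli(pli) if kind == "median" else threshold_pli(pli, level)


def _load_inputs(cfg: ExperimentConfig):
    if cfg.data_dir is None:
        raise ValidationError("data_dir is required for this experiment")
    atlas = read_atlas(cfg.data_dir / "atlas.csv")
    conn = read_connectome(cfg.data_dir / "connectome.csv", atlas)
    freq = pd.read_csv(cfg.data_dir / "omega.csv", float_precision="round_trip")
    omega = 2 * np.pi * freq["peak_hz"].to_numpy(dtype=float)
    return atlas, conn, omega


def _load_target_pli(cfg: ExperimentConfig, atlas, target: str | None = None):
    target = target or cfg.target
    subject_dir = cfg.data_dir / "subjects"
    if target == "control_average":
        controls = sorted(subject_dir.glob("control_*.csv"))
        if not controls:
            raise ValidationError(f"no control PLIs under {subject_dir}")
        return epoch_average_pli([read_pli(p, labels=atlas.labels) for p in controls])
    path = subject_dir / f"{target}.csv"
    if not path.exists():
        path = Path(target)
    return read_pli(path, labels=atlas.labels)


def _write_manifest(cfg: ExperimentConfig, experiment: str, out: Path, extra=None):
    def _clean(v):
        if isinstance(v, Path):
            return str(v)
        if isinstance(v, np.ndarray):
            return v.tolist()
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {k: _clean(x) for k, x in dataclasses.asdict(v).items()}
        if isinstance(v, (tuple, list)):
            return [_clean(x) for x in v]
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        return v

    manifest = {
        "package": "hopfnet",
        "version": __version__,
        "experiment": experiment,
        "config": {f.name: _clean(getattr(cfg, f.name))
                   for f in dataclasses.fields(cfg)},
    }
    if extra:
        manifest.update(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def run_experiment(cfg: ExperimentConfig, experiment: str) -> Path:
    """Execute one named experiment end-to-end; returns the output directory."""
    if experiment not in EXPERIMENTS:
        raise ValidationError(f"unknown experiment {experiment!r}; "
                              f"choose from {EXPERIMENTS}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        result = _STAGES[experiment](cfg, out)
    except Exception:
        (out / "FAILED").write_text(f"experiment {experiment} failed\n")
        raise
    _write_manifest(cfg, experiment, out, extra=result)
    return out


def _stage_synth(cfg: ExperimentConfig, out: Path):
    cohort = make_cohort(cfg.synth, settings=cfg.settings)
    write_cohort(cohort, out / "cohort")
    return {"subjects": sorted(cohort.plis)}


def _stage_validate(cfg: ExperimentConfig, out: Path):
    directory = cfg.data_dir or (out / "cohort")
    cohort = load_cohort(directory)  # type validation happens on load
    report = {
        "directory": str(directory),
        "n_regions": cohort.connectome.n_regions,
        "subjects": sorted(cohort.plis),
        "valid": True,
    }
    (out / "validation.json").write_text(json.dumps(report, indent=1))
    return {"validation": report}


def _stage_fit(cfg: ExperimentConfig, out: Path):
    atlas, conn, omega = _load_inputs(cfg)
    emp = _apply_threshold(_load_target_pli(cfg, atlas), cfg.threshold)
    grid = grid_search(conn, omega, emp, cfg.K_grid, cfg.lambda_grid,
                       n_ic=cfg.n_ic, seed=cfg.seed, settings=cfg.settings, C=cfg.C)
    rows = [
        {"lambda": lam, "K": K, "ic": ii, "r": grid.r[il, ik, ii]}
        for il, lam in enumerate(grid.lambda_values)
        for ik, K in enumerate(grid.K_values)
        for ii in range(grid.n_ic)
    ]
    pd.DataFrame(rows).to_csv(out / "fit_grid.csv", index=False)
    curve = optimal_coupling_curve(grid)
    pd.DataFrame({
        "lambda": curve.lambda_values,
        "K_opt_mean": curve.mean,
        "K_opt_sd": curve.sd,
    }).to_csv(out / "coupling_curve.csv", index=False)
    samples = pd.DataFrame({
        "lambda": np.repeat(curve.lambda_values, curve.optimal_K.shape[1]),
        "ic": np.tile(np.arange(curve.optimal_K.shape[1]), len(curve.lambda_values)),
        "K_opt": curve.optimal_K.ravel(),
    })
    samples.to_csv(out / "optimal_K_samples.csv", index=False)
    summary: dict = {"best_mean_r": float(grid.mean_surface().max())}
    positive = curve.lambda_values[curve.lambda_values >= cfg.lambda_min_fit]
    if len(positive) >= 1:
        fit = fit_normalized_coupling(curve, lambda_min=cfg.lambda_min_fit)
        summary.update(k=fit.k, residual_ss=fit.residual_ss,
                       lambda_used=fit.lambda_used.tolist())
    (out / "normalized_coupling.json").write_text(json.dumps(summary, indent=1))
    return {"fit": summary}


def _stage_scaling(cfg: ExperimentConfig, out: Path):
    _, conn, omega = _load_inputs(cfg)
    corr = matched_pair_pli_correlation(
        conn, omega, cfg.scaling_k, cfg.scaling_lambda_pair,
        n_ic=cfg.n_ic, seed=cfg.seed, settings=cfg.settings, C=cfg.C,
    )
    result = {
        "k": cfg.scaling_k,
        "lambda_pair": list(cfg.scaling_lambda_pair),
        "n_ic": cfg.n_ic,
        "mean_pli_correlation": corr,
        "expected_K_ratio": float(np.sqrt(cfg.scaling_lambda_pair[1]
                                          / cfg.scaling_lambda_pair[0])),
    }
    (out / "scaling.json").write_text(json.dumps(result, indent=1))
    return {"scaling": result}


def _stage_connectotomy(cfg: ExperimentConfig, out: Path):
    atlas, conn, omega = _load_inputs(cfg)
    masks = read_tumor_masks(cfg.data_dir / "masks.json", atlas)
    control_emp = _apply_threshold(
        _load_target_pli(cfg, atlas, "control_average"), cfg.threshold)
    rows = []
    summary = {}
    for sid, mask in sorted(masks.items()):
        emp = _apply_threshold(_load_target_pli(cfg, atlas, sid), cfg.threshold)
        patient = connectotomy_refit(
            emp, mask, conn, omega, cfg.K_grid, cfg.lambda_fixed,
            n_ic=cfg.n_ic, seed=cfg.seed, settings=cfg.settings, C=cfg.C,
            subject_id=sid,
        )
        outcome = pair_with_control(patient, control_emp, conn, omega,
                                    settings=cfg.settings, C=cfg.C)
        for arm, half in (("patient", outcome.patient), ("control", outcome.control)):
            for ii in range(half.n_ic):
                rows.append({
                    "subject": sid, "arm": arm, "ic": ii,
                    "K_before": half.K_before[ii], "K_after": half.K_after[ii],
                    "delta": half.delta[ii],
                })
        diffs = outcome.paired_differences
        stat = (wilcoxon_signed_rank(diffs) if np.any(diffs != 0) else None)
        summary[sid] = {
            "mask": sorted(atlas.labels[i] for i in mask.regions),
            "mean_paired_difference": float(diffs.mean()),
            "signed_rank_p": None if stat is None else stat.p_value,
            "signed_rank_statistic": None if stat is None else stat.statistic,
        }
    pd.DataFrame(rows).to_csv(out / "connectotomy.csv", index=False)
    (out / "connectotomy_summary.json").write_text(json.dumps(summary, indent=1))
    return {"connectotomy": summary}


def _stage_compare(cfg: ExperimentConfig, out: Path):
    if cfg.compare_a is None or cfg.compare_b is None:
        raise ValidationError("compare needs compare_a and compare_b sample CSVs")
    a = pd.read_csv(cfg.compare_a)
    b = pd.read_csv(cfg.compare_b)
    value_col = "K_opt" if "K_opt" in a.columns else a.columns[-1]
    rows = {}
    lambdas = sorted(set(a["lambda"]) & set(b["lambda"])) if "lambda" in a.columns else []
    for lam in lambdas:
        xa = a.loc[a["lambda"] == lam, value_col].to_numpy()
        xb = b.loc[b["lambda"] == lam, value_col].to_numpy()
        if cfg.compare_paired and len(xa) == len(xb):
            rows[f"lambda={lam:g}"] = wilcoxon_signed_rank(xa - xb)
        else:
            rows[f"lambda={lam:g}"] = wilcoxon_rank_sum(xa, xb)
    pooled_a = pool_across_lambda(
        {lam: a.loc[a["lambda"] == lam, value_col].to_numpy() for lam in lambdas}
    )["value"].to_numpy() if lambdas else a[value_col].to_numpy()
    pooled_b = pool_across_lambda(
        {lam: b.loc[b["lambda"] == lam, value_col].to_numpy() for lam in lambdas}
    )["value"].to_numpy() if lambdas else b[value_col].to_numpy()
    if cfg.compare_paired and len(pooled_a) == len(pooled_b):
        rows["pooled"] = wilcoxon_signed_rank(pooled_a - pooled_b)
    else:
        rows["pooled"] = wilcoxon_rank_sum(pooled_a, pooled_b)
    table = comparison_table(rows)
    table.to_csv(out / "comparisons.csv", index=False)
    return {"comparisons": table.to_dict(orient="records")}


_STAGES = {
    "synth": _stage_synth,
    "fit": _stage_fit,
    "scaling": _stage_scaling,
    "connectotomy": _stage_connectotomy,
    "compare": _stage_compare,
    "validate": _stage_validate,
}
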