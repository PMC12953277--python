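"""Study orchestration: simulate or ingest a cohort, build the three risk
models, evaluate discrimination / calibration / clinical utility, stratify
by the Youden cut-off and compare survival.

Outputs are deterministic given the master seed: metrics JSON is written
with sorted keys and contains the seed and a config hash, so two runs with
the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import stats_models as sm
from .synthetic import SimulationConfig, simulate_cohort, simulate_voxel_cohort

__all__ = ["RunConfig", "validate_config", "run_study", "MODEL_VARIABLES"]

MODEL_VARIABLES = {
    "clinical": ["afp_high", "size_gt5", "multiple_tumors"],
    "fd": ["fd"],
    "combined": ["afp_high", "size_gt5", "multiple_tumors", "fd"],
}
SCREEN_CANDIDATES = ["afp_high", "size_gt5", "multiple_tumors", "fd"]
VALID_MODES = ("simulate_table", "simulate_voxel", "real_data")


@dataclass
class RunConfig:
    mode: str = "simulate_table"
    n_train: int = 406
    n_test: int = 170
    seed: int = 0
    out_dir: str = "study_out"
    alpha: float = 0.05
    hl_bins: int = 10
    dca_thresholds: list = field(default_factory=lambda: [round(0.05 * i, 2) for i in range(1, 19)])
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cohort_csv: str | None = None  # real_data mode
    test_cohort_csv: str | None = None

    def validate(self) -> "RunConfig":
        if self.mode not in VALID_MODES:
            raise ValueError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        if self.n_train < 10 or self.n_test < 10:
            raise ValueError("n_train and n_test must be >= 10")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.hl_bins < 3:
            raise ValueError("hl_bins must be >= 3")
        if any(not 0 < t < 1 for t in self.dca_thresholds):
            raise ValueError("DCA thresholds must lie in (0, 1)")
        self.simulation.validate()
        if self.mode == "real_data":
            if not self.cohort_csv or not Path(self.cohort_csv).exists():
                raise ValueError("real_data mode requires an existing cohort_csv")
            if self.test_cohort_csv and not Path(self.test_cohort_csv).exists():
                raise ValueError(f"test_cohort_csv does not exist: {self.test_cohort_csv}")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "simulation" in kwargs and not isinstance(kwargs["simulation"], SimulationConfig):
            kwargs["simulation"] = SimulationConfig.from_dict(kwargs["simulation"] or {})
        return cls(**kwargs).validate()

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(path) -> RunConfig:
    """Load a YAML run config, fill defaults and range-check everything."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.from_dict(raw or {})


def _derived_seed(master: int, stream: int) -> int:
    return int(np.random.SeedSequence([int(master), stream]).generate_state(1)[0])


def _nonconstant(table: pd.DataFrame, variables: list[str], log) -> list[str]:
    kept = []
    for v in variables:
        if table[v].nunique() > 1:
            kept.append(v)
        else:
            log(f"dropping constant covariate {v!r}")
    return kept


def _make_cohorts(config: RunConfig, log) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.mode == "real_data":
        train = pd.read_csv(config.cohort_csv)
        test = pd.read_csv(config.test_cohort_csv) if config.test_cohort_csv else train
        return train, test
    sim = config.simulation
    if config.mode == "simulate_table":
        train_cfg = SimulationConfig(**{**sim.to_dict(), "fd_bounds": sim.fd_bounds,
                                        "n_patients": config.n_train,
                                        "seed": _derived_seed(config.seed, 0)})
        test_cfg = SimulationConfig(**{**sim.to_dict(), "fd_bounds": sim.fd_bounds,
                                       "n_patients": config.n_test,
                                       "seed": _derived_seed(config.seed, 1)})
        return simulate_cohort(train_cfg), simulate_cohort(test_cfg)
    # simulate_voxel: one voxel cohort split in two (mask generation is costly)
    log(f"voxel mode: generating {config.n_train + config.n_test} tumor masks")
    full = simulate_voxel_cohort(sim, n=config.n_train + config.n_test,
                                 seed=_derived_seed(config.seed, 2))
    return full.iloc[: config.n_train].copy(), full.iloc[config.n_train :].copy()


def run_study(config: RunConfig, out_dir=None) -> dict:
    """Execute the full replica study and write a report bundle.

    Stages: cohorts -> univariable screen -> three models (clinical / fd /
    combined) -> ROC + DeLong + Hosmer-Lemeshow + decision curve on the test
    cohort -> Youden stratification -> Kaplan-Meier / log-rank.  Returns the
    metrics dictionary (also written as ``metrics.json``).
    """
    config = config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    stage = "simulate"
    try:
        train, test = _make_cohorts(config, log)
        log(f"simulate: train={len(train)} rows, test={len(test)} rows")
        train.to_csv(out / "cohort_train.csv", index=False)
        test.to_csv(out / "cohort_test.csv", index=False)

        stage = "univariable_screen"
        candidates = _nonconstant(train, SCREEN_CANDIDATES, log)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            uni_fits = [sm.fit_univariable(train, v) for v in candidates]
            selected = sm.select_variables(uni_fits, alpha=config.alpha)
        log(f"univariable_screen: {len(candidates)} candidates, selected {selected}")

        stage = "fit_models"
        fits: dict[str, sm.LogisticFit] = {}
        for name, variables in MODEL_VARIABLES.items():
            usable = _nonconstant(train, variables, log)
            if not usable:
                raise ValueError(f"model {name!r} has no usable covariates")
            fits[name] = sm.fit_multivariable(train, usable)
            log(f"fit_models: {name} on {usable} converged={fits[name].converged}")

        stage = "evaluate"
        metrics: dict = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "mode": config.mode,
            "n_train": len(train),
            "n_test": len(test),
            "univariable_screen": {
                v: {"p": float(f.p_values[0]), "or": float(f.odds_ratios[0])}
                for v, f in zip(candidates, uni_fits)
            },
            "selected_variables": selected,
            "models": {},
        }
        scores = {}
        for name, fit in fits.items():
            if not fit.converged:
                log(f"evaluate: scoring non-converged (separated) {name} model; "
                    "probabilities saturate but the ranking remains usable")
            sc_train = sm.predict_risk(fit, train, model=name, allow_nonconverged=True)
            sc_test = sm.predict_risk(fit, test, model=name, allow_nonconverged=True)
            scores[name] = (sc_train, sc_test)
            roc = ev.roc_auc_delong(sc_test["probability"], test["mvi"])
            metrics["models"][name] = {
                "fit": fit.to_dict(),
                "auc": roc.auc,
                "auc_ci": [roc.ci_low, roc.ci_high],
            }
        sc_test_all = pd.concat([s for _, s in scores.values()])
        sc_test_all.to_csv(out / "scores_test.csv", index=False)

        z, p = ev.delong_paired_test(
            scores["combined"][1]["probability"], scores["clinical"][1]["probability"], test["mvi"]
        )
        metrics["delong_combined_vs_clinical"] = {"z": z, "p": p}
        if fits["combined"].converged:
            chi2, df, hp = ev.hosmer_lemeshow(
                scores["combined"][1]["probability"], test["mvi"], g=config.hl_bins
            )
            metrics["hosmer_lemeshow_combined"] = {"chi2": chi2, "df": df, "p": hp}
        else:
            metrics["hosmer_lemeshow_combined"] = {"flag": "skipped: non-converged model"}
            log("evaluate: Hosmer-Lemeshow skipped (combined model separated)")
        dca = ev.decision_curve(
            scores["combined"][1]["probability"], test["mvi"], config.dca_thresholds
        )
        dca.to_csv(out / "decision_curve.csv", index=False)

        stage = "stratify"
        cut = sm.youden_cutoff(scores["combined"][0]["linear_predictor"], train["mvi"])
        metrics["youden_cutoff"] = {
            "threshold": cut.threshold,
            "j": cut.youden_j,
            "sensitivity": cut.sensitivity,
            "specificity": cut.specificity,
        }
        high = scores["combined"][1]["linear_predictor"].to_numpy() >= cut.threshold
        sens, spec, acc = ev.performance_at_cutoff(
            scores["combined"][1]["linear_predictor"], test["mvi"], cut.threshold
        )
        metrics["test_performance_combined"] = {
            "sensitivity": sens, "specificity": spec, "accuracy": acc,
        }

        stage = "survival"
        surv = {}
        for endpoint in ("rfs", "os"):
            t, e = test[f"{endpoint}_months"].to_numpy(), test[f"{endpoint}_event"].to_numpy()
            km_rows = []
            group_stats = {}
            for label, sel in (("high_risk", high), ("low_risk", ~high)):
                if sel.sum() == 0:
                    raise ValueError(f"empty {label} group at the Youden cut-off")
                curve = ev.km_curve(t[sel], e[sel])
                group_stats[label] = {
                    "n": int(sel.sum()),
                    "median": curve.median,
                    "q25": curve.q25,
                    "q75": curve.q75,
                }
                for ti, si, ri in zip(curve.times, curve.survival, curve.at_risk):
                    km_rows.append({"endpoint": endpoint, "group": label,
                                    "time": ti, "survival": si, "at_risk": ri})
            chi2, p = ev.logrank_test(t[high], e[high], t[~high], e[~high])
            surv[endpoint] = {"groups": group_stats, "logrank_chi2": chi2, "logrank_p": p}
            pd.DataFrame(km_rows).to_csv(out / f"km_{endpoint}.csv", index=False)
        metrics["survival"] = surv
    except Exception as exc:
        raise RuntimeError(f"run_study failed at stage {stage!r}: {exc}") from exc

    (out / "metrics.json").write_text(json.dumps(metrics, sort_keys=True, indent=2) + "\n")
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return metrics
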