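"""End-to-end orchestration: simulate -> QC -> RTI -> MLM -> slopes ->
status -> outcomes, with persisted artifacts and a reproducibility
manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import BRT, CRT, BurstDesign, generate_design
from .mlm import MLMSpec, fit_conditional, fit_unconditional, prepare_rti_data
from .outcomes import (compare_baseline_predictor, fit_multinomial,
                       DegenerateDesignError, SeparationError)
from .qc import QCRules, screen_trials
from .rti import ResidualSpec, TStandardizer, compute_rti
from .simulate import GeneratingParams, TrialNoiseModel, generate_dataset
from .slopes import extract_person_slopes, slope_correlation
from .status import CognitiveStatusClassifier, StatusRules


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Serializable description of one full run."""

    seed: int = 0
    design: dict = field(default_factory=dict)
    crt_params: dict = field(default_factory=dict)
    brt_params: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    residual: dict = field(default_factory=dict)
    status_rules: dict = field(default_factory=dict)
    short_term_scale: float = 1.0
    out_dir: str = "run"
    verbosity: int = 1

    def build_design(self) -> BurstDesign:
        return generate_design(self.design)

    @staticmethod
    def _coerce(over: dict) -> dict:
        out = dict(over)
        tnm = out.get("trial_noise_model")
        if isinstance(tnm, dict):
            out["trial_noise_model"] = TrialNoiseModel(**tnm)
        if "level3_cov" in out:
            out["level3_cov"] = np.asarray(out["level3_cov"], float)
        for key in ("level2_vars", "attrition_hazard", "group_mix"):
            if key in out:
                out[key] = tuple(out[key])
        return out

    def build_params(self) -> dict[str, GeneratingParams]:
        return {CRT: GeneratingParams.crt_like(**self._coerce(self.crt_params)),
                BRT: GeneratingParams.brt_like(**self._coerce(self.brt_params))}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a results dict and persists all
    artifacts (tables, fit summaries, manifest) under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    results: dict = {"seed": config.seed}

    def save(df, name):
        p = out / name
        _write_csv(df, p)
        files.append(p)
        return p

    def save_json(obj, name):
        p = out / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=2, default=float)
        files.append(p)
        return p

    stage = "simulate"
    try:
        design = config.build_design()
        params = config.build_params()
        data = generate_dataset(design, params, seed=config.seed)
        save(data["trials"], "trials.csv")
        save(data["covariates"], "covariates.csv")
        save(data["domain_scores"], "domain_scores.csv")
        save(data["norms"], "norms.csv")

        stage = "qc"
        rules = QCRules(**config.qc)
        clean, report = screen_trials(data["trials"], rules)
        save_json(report.to_dict(), "exclusion_report.json")
        (out / "exclusion_report.txt").write_text(report.summary() + "\n")
        files.append(out / "exclusion_report.txt")
        results["exclusions"] = report.to_dict()

        stage = "rti"
        std = TStandardizer()
        rti = compute_rti(clean, ResidualSpec(**config.residual), std)
        save(rti, "rti.csv")
        std.to_json(out / "t_standardizer.json")
        files.append(out / "t_standardizer.json")

        covariates = data["covariates"]
        slope_cols = {}
        for task in design.tasks:
            stage = f"fit-{task}"
            mdata = prepare_rti_data(rti, covariates, task)
            decomp, _ = fit_unconditional(mdata)
            model = fit_conditional(mdata)
            fitres = model.result_
            save_json({"decomposition": decomp.as_dict(),
                       "fit": fitres.as_dict()}, f"fit_{task.lower()}.json")
            (out / f"fit_{task.lower()}.txt").write_text(
                fitres.summary() + "\n")
            files.append(out / f"fit_{task.lower()}.txt")
            results[f"fit_{task}"] = fitres
            results[f"decomposition_{task}"] = decomp

            stage = f"slopes-{task}"
            eb = model.random_effects()
            save(eb["person"], f"random_effects_person_{task.lower()}.csv")
            save(eb["person_year"],
                 f"random_effects_person_year_{task.lower()}.csv")
            slopes = extract_person_slopes(model, eb,
                                           config.short_term_scale)
            save(slopes, f"slopes_{task.lower()}.csv")
            r, p = slope_correlation(slopes)
            results[f"slope_correlation_{task}"] = {"r": r, "p": p}
            slope_cols[f"weekly_{task.lower()}"] = slopes.set_index(
                "person_id")["short_term"]
            slope_cols[f"yearly_{task.lower()}"] = slopes.set_index(
                "person_id")["long_term"]

        stage = "classify"
        clf = CognitiveStatusClassifier(StatusRules(**config.status_rules))
        clf.fit(data["norms"], covariates)
        status = clf.transform(data["domain_scores"])
        save(status, "status.csv")
        results["status_counts"] = (status.groupby(["year", "label"])
                                    .size().to_dict())

        stage = "predict"
        preds = pd.DataFrame(slope_cols).reset_index()
        preds = preds.merge(covariates[["person_id", "age_baseline", "sex",
                                        "mmse_baseline"]], on="person_id")
        preds["age_c"] = preds["age_baseline"] - 74.0
        outcome_years = [y for y in design.followup_years
                         if y in set(status["year"])]
        rows = []
        for year in outcome_years:
            for pred_name in slope_cols:
                try:
                    res = fit_multinomial(status, preds, pred_name, year)
                except (DegenerateDesignError, SeparationError) as exc:
                    rows.append({"outcome_year": year, "predictor": pred_name,
                                 "error": str(exc)})
                    continue
                for _, r_ in res.table.iterrows():
                    if r_["term"] != pred_name:
                        continue
                    rows.append({
                        "outcome_year": year, "predictor": pred_name,
                        "category": r_["category"], "or": r_["or"],
                        "ci_low": r_["ci_low"], "ci_high": r_["ci_high"],
                        "p": r_["p"]})
            try:
                mm = compare_baseline_predictor(status, preds,
                                                outcome_year=year)
                rows.append({"outcome_year": year,
                             "predictor": "mmse_baseline",
                             "lr_stat": mm.lr_stat, "lr_p": mm.lr_p})
            except (DegenerateDesignError, SeparationError) as exc:
                rows.append({"outcome_year": year,
                             "predictor": "mmse_baseline",
                             "error": str(exc)})
        outcome_table = pd.DataFrame(rows)
        save(outcome_table, "outcomes.csv")
        results["outcomes"] = outcome_table

        stage = "manifest"
        config.to_yaml(out / "config.yaml")
        files.append(out / "config.yaml")
        manifest = {
            "package": "burstrti", "version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__, "pandas": pd.__version__,
            "seed": config.seed,
            "files": {f.name: _sha256(f) for f in files},
        }
        save_json(manifest, "manifest.json")
        results["manifest"] = manifest
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return results


# ---------------------------------------------------------------------------
# input validation

_SCHEMAS = {
    "trials": {
        "required": ["person_id", "task", "year", "session", "trial",
                     "rt_ms", "correct", "missing"],
        "numeric": ["person_id", "year", "session", "trial", "rt_ms",
                    "correct", "missing"],
        "key": ["person_id", "task", "year", "session", "trial"],
    },
    "covariates": {
        "required": ["person_id", "age_baseline", "sex", "education"],
        "numeric": ["person_id", "age_baseline", "sex", "education"],
        "key": ["person_id"],
    },
    "domain_scores": {
        "required": ["person_id", "year", "domain", "score"],
        "numeric": ["person_id", "year", "score"],
        "key": ["person_id", "year", "domain"],
    },
    "norms": {
        "required": ["age_band", "edu_band", "domain", "mean", "sd"],
        "numeric": ["mean", "sd"],
        "key": ["age_band", "edu_band", "domain"],
    },
    "rti": {
        "required": ["person_id", "task", "year", "session", "isd_raw",
                     "t_score"],
        "numeric": ["person_id", "year", "session", "isd_raw", "t_score"],
        "key": ["person_id", "task", "year", "session"],
    },
}


@dataclass
class ValidationReport:
    failures: list[dict] = field(default_factory=list)
    checked: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def summary(self) -> str:
        if self.ok:
            return f"all checks passed ({', '.join(self.checked)})"
        return "\n".join(
            f"{f['file']}: {f['check']}: {f['detail']}" for f in self.failures)


def validate_inputs(paths: dict[str, str]) -> ValidationReport:
    """Schema, dtype and key-uniqueness checks on input CSVs.

    ``paths`` maps schema names (trials, covariates, domain_scores,
    norms, rti) to file paths.
    """
    rep = ValidationReport()
    for kind, path in paths.items():
        schema = _SCHEMAS.get(kind)
        if schema is None:
            rep.failures.append({"file": str(path), "check": "schema",
                                 "detail": f"unknown input kind {kind!r}"})
            continue
        rep.checked.append(kind)
        p = Path(path)
        if not p.exists():
            rep.failures.append({"file": str(path), "check": "exists",
                                 "detail": "file not found"})
            continue
        df = pd.read_csv(p)
        missing = [c for c in schema["required"] if c not in df.columns]
        if missing:
            rep.failures.append({"file": str(path), "check": "columns",
                                 "detail": f"missing columns {missing}"})
            continue
        for col in schema["numeric"]:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                rows = (df.index[bad] + 2).tolist()[:10]  # 1-based + header
                rep.failures.append({
                    "file": str(path), "check": f"numeric:{col}",
                    "detail": f"non-numeric values at rows {rows}"})
        dup = df.duplicated(subset=schema["key"])
        if dup.any():
            rep.failures.append({
                "file": str(path), "check": "key-unique",
                "detail": f"{int(dup.sum())} duplicate "
                          f"{tuple(schema['key'])} keys"})
    return rep
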