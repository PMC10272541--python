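"""End-to-end orchestration: simulate -> quantify -> co-localize -> index -> evaluate.

A run is fully determined by its configuration and seed: the global seed is
expanded into per-sample seeds by fixed offsets and the quantification
stages contain no hidden randomness.  Each stage's outputs are written
before the next stage reads them; the log records the config hash and
per-stage timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .colocalize import coloc_params, colocalize
from .config import AnalysisConfig, ConfigError
from .evaluate import evaluate_table
from .fibrosis import classify_strings, compute_fibrosis_params, extract_strings, segment_collagen
from .indices import CollinearityError, IndexModel, apply_index, fit_linear_index, rank_features, select_shared
from .io_core import TissueSample, write_param_table
from .steatosis import classify_vacuoles, compute_steatosis_params, detect_vacuole_candidates
from .synthetic import SyntheticSpec, generate_cohort

#: Fibrosis feature columns eligible for qFibrosis selection.
QFIBROSIS_CANDIDATES = (
    "CPA", "#Str", "#StrCV", "#StrPT", "#StrPS",
    "#LongStrPS", "#ThinStrPS", "#ThinStrPSAgg", "#LongStrPSDis",
    "TotalLengthPS", "MeanWidthPS", "#BranchPoints",
)
#: The four shared collagen-string parameters combined into qFibrosis.
QFIBROSIS_SHARED = ("#LongStrPS", "#ThinStrPS", "#ThinStrPSAgg", "#LongStrPSDis")
QSTEATOSIS_CANDIDATES = (
    "%Area", "%MacroArea", "%MicroArea", "%AreaPS", "%MacroAreaPS", "%MicroAreaPS",
    "#Macro", "#Micro", "MacroDiam", "MicroDiam", "%SteatosisRegion",
)


def quantify_sample(sample: TissueSample, config: Optional[AnalysisConfig] = None) -> dict[str, float]:
    """Run steatosis, fibrosis and co-localization quantification on one sample.

    Returns a flat named-parameter row (plus ground-truth grade/stage when
    the sample carries synthetic truth).
    """
    config = config or AnalysisConfig()
    regions = sample.regions
    ps = sample.pixel_size_um
    vessel_mask = regions.central_vein | regions.portal_tract
    collagen = segment_collagen(sample.shg, regions.tissue, config)
    candidates = detect_vacuole_candidates(
        sample.tpef, regions.tissue, vessel_mask=vessel_mask, collagen_mask=collagen.mask, config=config
    )
    classify_vacuoles(candidates, config=config)
    steat = compute_steatosis_params(candidates, regions, config.dilation_radius_um, ps)
    strings = extract_strings(collagen, regions, ps)
    classify_strings(strings, config, pixel_size_um=ps)
    fib = compute_fibrosis_params(strings, collagen, regions)
    coloc = colocalize(collagen, steat, regions, config.coloc_distance_um, strings, ps, config)
    row: dict[str, float] = {}
    row.update(steat.params)
    row.update(fib)
    row.update(coloc_params(coloc))
    row["sample_id"] = sample.sample_id
    row["group"] = sample.group
    row["week"] = sample.week
    if sample.truth is not None:
        row["grade"] = sample.truth.steatosis_grade
        row["stage"] = sample.truth.fibrosis_stage
    return row


def quantify_cohort(samples: Sequence[TissueSample], config: Optional[AnalysisConfig] = None) -> pd.DataFrame:
    """Quantify every sample into one parameter table."""
    rows = [quantify_sample(s, config) for s in samples]
    frame = pd.DataFrame(rows)
    meta = [c for c in ("sample_id", "group", "week", "grade", "stage") if c in frame.columns]
    return frame[meta + [c for c in frame.columns if c not in meta]]


def _prune_features(table: pd.DataFrame, features: Sequence[str]) -> list[str]:
    """Drop constant columns and exact duplicates before an OLS fit."""
    kept: list[str] = []
    seen: list[np.ndarray] = []
    for f in features:
        x = table[f].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            continue
        if any(np.array_equal(x, s) for s in seen):
            continue
        kept.append(f)
        seen.append(x)
    return kept


def select_and_fit(
    table: pd.DataFrame,
    candidates: Sequence[str],
    target: str,
    top_k: int = 10,
    top_k_step: int = 5,
) -> tuple[IndexModel, list[str]]:
    """Rank candidates per group, intersect top-k, and fit the linear index.

    With a single group the top-k of its one ranking is used directly.
    Constant and duplicated columns are pruned before fitting; if the fit
    is still collinear, the named offenders are removed and the fit
    retried.
    """
    candidates = [c for c in candidates if c in table.columns]
    groups = table["group"].unique() if "group" in table.columns else ["all"]
    usable_groups = []
    rankings = {}
    for g in groups:
        sub = table[table["group"] == g] if "group" in table.columns and g != "all" else table
        if len(sub) < 3 or sub[target].nunique() < 2:
            continue
        rankings[str(g)] = [name for name, _, _ in rank_features(sub, target, candidates)]
        usable_groups.append(g)
    if not rankings:
        rankings["all"] = [name for name, _, _ in rank_features(table, target, candidates)]
    if len(rankings) >= 2:
        features = select_shared(rankings, top_k, top_k_step)
    else:
        features = next(iter(rankings.values()))[:top_k]
    features = _prune_features(table, features)
    features = features[: max(1, len(table) - 2)]  # keep the OLS overdetermined
    while True:
        try:
            model = fit_linear_index(table, features, target)
            return model, features
        except CollinearityError as err:
            features = [f for f in features if f not in err.features]
            if not features:
                raise


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    cohort: list[dict]  # row keys: group, week, n + SyntheticSpec overrides
    seed: int
    out_dir: str = "run"
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    shape: tuple[int, int] = (512, 512)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in data:
            raise ConfigError("run config must set a seed")
        analysis = AnalysisConfig.from_dict(data.get("analysis", {}))
        return cls(
            cohort=list(data.get("cohort", [])),
            seed=int(data["seed"]),
            out_dir=str(data.get("out_dir", "run")),
            analysis=analysis,
            shape=tuple(data.get("shape", (512, 512))),
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            {"cohort": self.cohort, "seed": self.seed, "analysis": self.analysis.to_dict(), "shape": list(self.shape)},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def expand_design(self) -> list[tuple[str, int, SyntheticSpec]]:
        spec_fields = {f.name for f in dataclasses.fields(SyntheticSpec)}
        design = []
        for row in self.cohort:
            n = int(row.get("n", 1))
            overrides = {k: v for k, v in row.items() if k in spec_fields}
            for key in ("macro_diameter_um", "micro_diameter_um"):
                if key in overrides:
                    overrides[key] = tuple(overrides[key])
            spec = SyntheticSpec(shape=tuple(self.shape), **overrides)
            for _ in range(n):
                design.append((str(row.get("group", "grp")), int(row.get("week", 0)), spec))
        if not design:
            raise ConfigError("cohort design is empty")
        return design


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write all artifacts into the run directory.

    Writes ``params.csv``, ``coloc.csv``, ``model_qfibrosis.json``,
    ``model_qsteatosis.json`` (when fittable), ``report.csv`` and
    ``run.log``.  Byte-identical outputs for identical config and seed.
    """
    if config.seed is None:
        raise ConfigError("run config must set a seed")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash={config.config_hash()}", f"seed={config.seed}"]

    def _stage(name, fn):
        t0 = time.perf_counter()
        result = fn()
        log_lines.append(f"stage={name} elapsed_s={time.perf_counter() - t0:.2f}")
        return result

    try:
        design = config.expand_design()
        samples, truth = _stage("simulate", lambda: generate_cohort(design, config.seed))
        table = _stage("quantify", lambda: quantify_cohort(samples, config.analysis))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage simulate/quantify: {exc}") from exc
    write_param_table(table, out / "params.csv")
    coloc_cols = [c for c in table.columns if "CoLoc" in c or c.startswith("ColocFrac")]
    table[["sample_id"] + coloc_cols].to_csv(out / "coloc.csv", index=False, float_format="%.12g")

    report_frames = []
    # qFibrosis and the co-localized variants -------------------------------
    if "stage" in table.columns and table["stage"].nunique() >= 2:
        def _fit_fibrosis():
            models = {}
            model, feats = select_and_fit(table, QFIBROSIS_CANDIDATES, "stage", config.analysis.top_k, config.analysis.top_k_step)
            models["qFibrosis"] = model
            for suffix, name in (("-MacroCoLoc", "qFibrosis-MacroCoLoc"), ("-MicroCoLoc", "qFibrosis-MicroCoLoc")):
                cand = [f"{c}{suffix}" for c in QFIBROSIS_SHARED]
                try:
                    m, _ = select_and_fit(table, cand, "stage", config.analysis.top_k, config.analysis.top_k_step)
                    models[name] = m
                except (ValueError, CollinearityError):
                    pass
            return models
        models = _stage("fit-qfibrosis", _fit_fibrosis)
        models["qFibrosis"].to_json(out / "model_qfibrosis.json")
        for name, model in models.items():
            table[name] = apply_index(model, table)
        cols = ["CPA"] + [n for n in ("qFibrosis", "qFibrosis-MacroCoLoc", "qFibrosis-MicroCoLoc") if n in table.columns]
        rep = _stage("evaluate-fibrosis", lambda: evaluate_table(table, cols, "stage"))
        frame = rep.table.copy()
        frame.insert(0, "target", "stage")
        report_frames.append(frame)
    # qSteatosis -------------------------------------------------------------
    if "grade" in table.columns and table["grade"].nunique() >= 2:
        def _fit_steatosis():
            model, _ = select_and_fit(table, QSTEATOSIS_CANDIDATES, "grade", config.analysis.top_k, config.analysis.top_k_step)
            return model
        model = _stage("fit-qsteatosis", _fit_steatosis)
        model.to_json(out / "model_qsteatosis.json")
        table["qSteatosis"] = apply_index(model, table)
        rep = _stage("evaluate-steatosis", lambda: evaluate_table(table, ["%Area", "%MacroArea", "%MicroArea", "qSteatosis"], "grade"))
        frame = rep.table.copy()
        frame.insert(0, "target", "grade")
        report_frames.append(frame)

    # refresh params.csv with the fitted index columns so the evaluation
    # stage can be reproduced from it alone
    write_param_table(table, out / "params.csv")
    if report_frames:
        pd.concat(report_frames).to_csv(out / "report.csv", float_format="%.12g")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
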