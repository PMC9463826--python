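"""Validation stage: matching, frozen-classifier evaluation, stratification.

Cases are matched 1:``ratio`` to controls on fetal sex (exact) and
gestational week at blood draw (within a tolerance), the frozen training
classifier is applied unchanged to internal/external cohorts, per-cohort ROC
reports are produced together with a pooled "all" row over concatenated
scores, and samples can be stratified by gestational week around a cutoff
(week >= cutoff goes to the late stratum).  ``run_pipeline`` strings the
whole analysis together on simulated data: simulate -> count -> discover ->
train -> validate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classifier_builder as cb
from . import differential_promoters as dp
from . import genome_regions as gr
from . import promoter_coverage as pc
from . import synthetic_cfdna as sim

logger = logging.getLogger(__name__)

__all__ = [
    "MatchedDesign",
    "validate_design",
    "match_controls",
    "apply_classifier",
    "evaluate_cohorts",
    "stratify_by_week",
    "run_pipeline",
    "DEFAULT_CONFIG",
]

REQUIRED_DESIGN_COLUMNS = ("sample_id", "label", "cohort", "gestational_week", "fetal_sex")


@dataclass(frozen=True)
class MatchedDesign:
    """1:ratio matched case-control assignment.

    ``pairs`` holds (case_id, controls) with exactly ``ratio`` controls each;
    cases whose eligible pool was too small appear in ``unmatched_cases``
    (with the deficient pool size) instead of receiving a partial match.
    """

    pairs: tuple[tuple[str, tuple[str, ...]], ...]
    unmatched_cases: tuple[tuple[str, int], ...]

    def matched_controls(self) -> list[str]:
        return [c for _, controls in self.pairs for c in controls]


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design is missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        dupes = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_ids: {dupes}")
    bad = set(design["label"]) - {"macrosomia", "control"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    if "birth_weight" in design.columns:
        bw = design["birth_weight"].dropna()
        labels = design.loc[bw.index, "label"]
        inconsistent = (bw > 4000) != (labels == "macrosomia")
        if inconsistent.any():
            raise ValueError(
                "label/birth_weight mismatch (macrosomia <=> birth weight > 4000 g) for: "
                f"{design.loc[bw.index[inconsistent], 'sample_id'].tolist()}"
            )
    return design


def match_controls(
    design: pd.DataFrame,
    ratio: int = 4,
    week_tolerance: float = 1.0,
    seed: int = 0,
) -> MatchedDesign:
    """Randomly match each case to ``ratio`` controls without replacement.

    Eligibility requires the same fetal sex and |gestational week difference|
    <= ``week_tolerance``.  Cases are processed in a seeded random order to
    avoid systematically starving late cases of controls.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    validate_design(design)
    rng = np.random.default_rng(seed)
    cases = design[design["label"] == "macrosomia"]
    controls = design[design["label"] == "control"]
    available = set(controls["sample_id"])
    ctrl = controls.set_index("sample_id")

    pairs = []
    unmatched = []
    order = rng.permutation(len(cases))
    for i in order:
        case = cases.iloc[i]
        pool = ctrl[
            (ctrl["fetal_sex"] == case["fetal_sex"])
            & ((ctrl["gestational_week"] - case["gestational_week"]).abs() <= week_tolerance)
        ]
        pool_ids = sorted(set(pool.index) & available)
        if len(pool_ids) < ratio:
            unmatched.append((case["sample_id"], len(pool_ids)))
            continue
        chosen = rng.choice(pool_ids, size=ratio, replace=False)
        available -= set(chosen)
        pairs.append((case["sample_id"], tuple(chosen.tolist())))
    # report in the original case order
    case_order = {sid: k for k, sid in enumerate(cases["sample_id"])}
    pairs.sort(key=lambda p: case_order[p[0]])
    unmatched.sort(key=lambda u: case_order[u[0]])
    return MatchedDesign(tuple(pairs), tuple(unmatched))


def apply_classifier(spec: cb.ClassifierSpec, norm: pc.NormalizedMatrix) -> pd.Series:
    """Score samples with a frozen classifier (no refitting, frozen z-scoring)."""
    return cb.decision_scores(spec, norm)


def evaluate_cohorts(
    spec: cb.ClassifierSpec,
    norm: pc.NormalizedMatrix,
    design: pd.DataFrame,
    threshold_rule: str = "native",
    loocv_seed: int = 0,
) -> dict[str, cb.PerformanceReport]:
    """Per-cohort performance of a frozen classifier, plus a pooled "all" row.

    The training cohort is scored by LOOCV (refitting within its own folds);
    every other cohort is scored by the frozen model.  The pooled report
    concatenates all per-sample scores rather than averaging AUCs.
    """
    validate_design(design)
    design = design.set_index("sample_id").loc[norm.samples].reset_index()
    reports: dict[str, cb.PerformanceReport] = {}
    all_scores, all_labels = [], []
    for cohort, sub in design.groupby("cohort", sort=False):
        labels = sub["label"].to_numpy()
        if len(set(labels)) < 2:
            raise ValueError(f"cohort {cohort!r} does not contain both classes")
        sub_norm = pc.NormalizedMatrix(norm.values.loc[sub["sample_id"]])
        if cohort == "training":
            scores = cb.loocv_scores(sub_norm, labels, spec.genes, spec.model_type, seed=loocv_seed)
        else:
            scores = apply_classifier(spec, sub_norm)
        reports[cohort] = cb.roc_metrics(
            scores.to_numpy(), labels, threshold_rule, native_threshold=spec.native_threshold
        )
        all_scores.append(scores.to_numpy())
        all_labels.append(labels)
    if len(reports) > 1:
        reports["all"] = cb.roc_metrics(
            np.concatenate(all_scores),
            np.concatenate(all_labels),
            threshold_rule,
            native_threshold=spec.native_threshold,
        )
    return reports


def stratify_by_week(
    design: pd.DataFrame, cutoff_week: float = 17.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split samples into early (< cutoff) and late (>= cutoff) strata."""
    if not 12.0 <= cutoff_week < 28.0:
        raise ValueError("cutoff_week must lie in [12, 28)")
    early = design[design["gestational_week"] < cutoff_week].reset_index(drop=True)
    late = design[design["gestational_week"] >= cutoff_week].reset_index(drop=True)
    return early, late


# --------------------------------------------------------------------------
# End-to-end pipeline on simulated data

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "results",
    "genome": {"n_genes": 2000, "spacing": 5000},
    "simulate": {
        "n_planted": 50,
        "effect": 0.8 / 3,
        "base_depletion": 0.2,
        "depth": 0.3,
        "cohorts": {
            "training": {"n_cases": 47, "n_controls": 47},
            "internal": {"n_cases": 21, "n_controls": 84},
            "external1": {"n_cases": 43, "n_controls": 172},
            "external2": {"n_cases": 51, "n_controls": 204},
        },
    },
    "discovery": {"fc_threshold": 1.3, "fdr_threshold": 0.05},
    "training": {"max_genes": 12, "models": ["lr", "svm"], "objective": "loocv"},
    "validation": {"threshold_rule": "native", "week_cutoff": 17.0},
}


def _merge_config(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        # "cohorts" is a table, not a set of tunables: replace it wholesale
        if isinstance(v, Mapping) and isinstance(out.get(k), dict) and k != "cohorts":
            out[k] = _merge_config(out[k], v)
        else:
            out[k] = dict(v) if isinstance(v, Mapping) else v
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return _merge_config(DEFAULT_CONFIG, yaml.safe_load(fh) or {})


def run_pipeline(config: Mapping | str | Path | None = None, write: bool = True) -> dict:
    """Run simulate -> count -> discover -> train -> validate end to end.

    ``config`` may be a mapping of overrides to :data:`DEFAULT_CONFIG` or a
    YAML path.  Returns a summary dict (discovery counts, selected genes,
    per-cohort and per-stratum performance); when ``write`` is true every
    intermediate table plus a run log is written under ``outdir``.

    If no promoter passes discovery (e.g. a null simulation), stepwise search
    has no candidates; the pipeline then fits both models on a label-free
    fallback panel (the ``max_genes`` highest-variance promoters, no
    selection) so the report still carries calibration AUCs, and flags this.
    """
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = _merge_config(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    outdir = Path(cfg["outdir"])
    log: list[str] = [f"cfpromoter pipeline; seed={seed}"]

    # -- simulate -----------------------------------------------------------
    genome = sim.simulate_genome(
        cfg["genome"]["n_genes"], cfg["genome"]["spacing"], seed=rng.integers(2**31 - 1)
    )
    simcfg = cfg["simulate"]
    cohorts: list[sim.SimulatedCohort] = []
    planted = None
    for name, sizes in simcfg["cohorts"].items():
        c = sim.simulate_cohort(
            genome,
            n_cases=sizes["n_cases"],
            n_controls=sizes["n_controls"],
            n_planted=simcfg["n_planted"],
            effect=simcfg["effect"],
            base_depletion=simcfg["base_depletion"],
            depth=simcfg["depth"],
            seed=int(rng.integers(2**31 - 1)),
            cohort=name,
            planted_genes=planted,
        )
        planted = c.truth.planted_genes  # share one truth across cohorts
        cohorts.append(c)
    merged = sim.merge_cohorts(cohorts)
    log.append(f"simulated {len(merged.design)} samples over {len(cohorts)} cohort(s)")

    # -- count + normalize --------------------------------------------------
    regions = gr.regions_from_genome(genome)
    coverage = pc.build_coverage_matrix(merged.fragments, regions)
    norm = pc.normalize_ptss(coverage)

    # -- discovery (training cohort only) -----------------------------------
    training_ids = merged.design.loc[merged.design["cohort"] == "training", "sample_id"]
    train_norm = pc.NormalizedMatrix(norm.values.loc[training_ids])
    discovery = dp.run_discovery(
        train_norm,
        merged.design,
        fc_threshold=cfg["discovery"]["fc_threshold"],
        fdr_threshold=cfg["discovery"]["fdr_threshold"],
    )
    candidates = dp.significant_genes(discovery)
    log.append(f"discovery: {len(candidates)} significant promoter(s)")

    # -- training -----------------------------------------------------------
    train_labels = merged.design.set_index("sample_id").loc[training_ids, "label"].to_numpy()
    traincfg = cfg["training"]
    fallback = not candidates
    specs: dict[str, cb.ClassifierSpec] = {}
    traces: dict[str, pd.DataFrame] = {}
    train_reports: dict[str, cb.PerformanceReport] = {}
    for model_type in traincfg["models"]:
        if fallback:
            panel = train_norm.values.var(axis=0).nlargest(traincfg["max_genes"]).index.tolist()
            genes, trace = panel, pd.DataFrame(columns=["step", "gene_id", "loocv_auc"])
            log.append(
                f"{model_type}: no significant promoters; fallback variance panel of "
                f"{len(panel)} genes (no stepwise selection)"
            )
        else:
            genes, trace = cb.stepwise_select(
                train_norm,
                train_labels,
                candidates,
                model_type=model_type,
                max_genes=traincfg["max_genes"],
                seed=seed,
                objective=traincfg.get("objective", "loocv"),
            )
        spec = cb.fit_classifier(train_norm, train_labels, genes, model_type, seed=seed)
        scores = cb.loocv_scores(train_norm, train_labels, genes, model_type, seed=seed)
        train_reports[model_type] = cb.roc_metrics(
            scores.to_numpy(),
            train_labels,
            cfg["validation"]["threshold_rule"],
            native_threshold=spec.native_threshold,
        )
        specs[model_type], traces[model_type] = spec, trace
        log.append(
            f"{model_type}: {len(genes)} gene(s), training LOOCV AUC "
            f"{train_reports[model_type].auc:.4f}"
        )
    optimal = cb.select_optimal_classifier(train_reports)
    log.append(f"optimal classifier: {optimal}")

    # -- validation ---------------------------------------------------------
    cohort_reports = evaluate_cohorts(
        specs[optimal], norm, merged.design, threshold_rule=cfg["validation"]["threshold_rule"],
        loocv_seed=seed,
    )
    early, late = stratify_by_week(merged.design, cfg["validation"]["week_cutoff"])
    strata_reports: dict[str, cb.PerformanceReport] = {}
    for name, stratum in (("early", early), ("late", late)):
        if (stratum["label"] == "macrosomia").sum() < 2 or (stratum["label"] == "control").sum() < 2:
            log.append(f"stratum {name}: fewer than 2 samples in a class; skipped")
            continue
        stratum_norm = pc.NormalizedMatrix(norm.values.loc[stratum["sample_id"]])
        scores = apply_classifier(specs[optimal], stratum_norm)
        strata_reports[name] = cb.roc_metrics(
            scores.to_numpy(),
            stratum["label"].to_numpy(),
            cfg["validation"]["threshold_rule"],
            native_threshold=specs[optimal].native_threshold,
        )

    summary = {
        "seed": seed,
        "n_samples": int(len(merged.design)),
        "n_significant": len(candidates),
        "fallback_panel": fallback,
        "selected_genes": {m: specs[m].genes for m in specs},
        "optimal_model": optimal,
        "training": {m: r.to_dict() for m, r in train_reports.items()},
        "cohorts": {c: r.to_dict() for c, r in cohort_reports.items()},
        "strata": {s: r.to_dict() for s, r in strata_reports.items()},
        "truth_planted": sorted(merged.truth.planted_genes),
    }

    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        merged.design.to_csv(outdir / "design.tsv", sep="\t", index=False)
        merged.truth.to_frame(genome.gene_ids()).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        pc.write_matrix_tsv(coverage.counts, outdir / "counts.tsv")
        pc.write_matrix_tsv(norm.values, outdir / "normalized.tsv")
        pc.coverage_qc(coverage).to_csv(outdir / "qc.tsv", sep="\t", index=False)
        discovery.to_csv(outdir / "discovery.tsv", sep="\t", index=False)
        for m, trace in traces.items():
            trace.to_csv(outdir / f"selection_trace_{m}.tsv", sep="\t", index=False)
        _write_report_table(cohort_reports, outdir / "cohort_performance.tsv")
        _write_report_table(strata_reports, outdir / "strata_performance.tsv")
        for m, spec in specs.items():
            _write_classifier(spec, outdir / f"classifier_{m}")
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        (outdir / "run.log").write_text("\n".join(log) + "\n")
    return summary


def _write_report_table(reports: Mapping[str, cb.PerformanceReport], path: Path) -> None:
    rows = [{"cohort": name, **rep.to_dict()} for name, rep in reports.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_classifier(spec: cb.ClassifierSpec, outdir: Path) -> None:
    """Serialize a classifier: metadata JSON + per-gene standardization/coefs.

    Both model types are linear, so coefficients + intercept fully determine
    the frozen decision scores.
    """
    outdir.mkdir(parents=True, exist_ok=True)
    coef = np.asarray(spec.model.coef_).ravel()
    meta = {
        "model_type": spec.model_type,
        "genes": spec.genes,
        "threshold": spec.threshold,
        "intercept": float(np.asarray(spec.model.intercept_).ravel()[0]),
    }
    (outdir / "model.json").write_text(json.dumps(meta, indent=2))
    pd.DataFrame(
        {"gene_id": spec.genes, "mean": spec.mean_, "scale": spec.scale_, "coef": coef}
    ).to_csv(outdir / "standardization.tsv", sep="\t", index=False)


class _FrozenLinearModel:
    """Score-only stand-in for a fitted linear SVM/LR loaded from disk."""

    def __init__(self, coef: np.ndarray, intercept: float):
        self.coef_ = np.asarray(coef, dtype=float)
        self.intercept_ = float(intercept)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p, p])


def load_classifier(indir: str | Path) -> cb.ClassifierSpec:
    """Load a serialized classifier bundle written by the train stage."""
    indir = Path(indir)
    meta = json.loads((indir / "model.json").read_text())
    table = pd.read_csv(indir / "standardization.tsv", sep="\t")
    if table["gene_id"].tolist() != meta["genes"]:
        raise ValueError(f"{indir}: gene order mismatch between model.json and table")
    model = _FrozenLinearModel(table["coef"].to_numpy(), meta["intercept"])
    return cb.ClassifierSpec(
        model_type=meta["model_type"],
        genes=meta["genes"],
        mean_=table["mean"].to_numpy(),
        scale_=table["scale"].to_numpy(),
        model=model,
        threshold=float(meta["threshold"]),
    )
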