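"""End-to-end pipeline: derivation -> training -> independent test.

Workflow (mirrors the signature-development design):

1. **Derivation.**  Two cohorts of matched tumor-normal pairs (nonmetastatic
   vs metastatic primaries) are imputed, the systematic batch bias between
   them is removed with DWD, and SAM at the target FDR derives the gene
   signature.  Class centroids (resected and metastatic) are the per-gene
   means over each cohort's tumors.
2. **Training.**  A training cohort is DWD-adjusted into the common space,
   every sample is scored by its (1 - Pearson r) distance to the resected
   centroid, and the survival-optimal cut-point on that distance is found by
   the log-rank scan.
3. **Test.**  An independent cohort is adjusted the same way and classified
   with the *frozen* training cut-point — never re-optimized — then
   validated with Kaplan-Meier curves, the log-rank test, a Cox model, and
   association tests against clinical covariates.

Adjustments are anchored: the resected derivation cohort defines the frame,
and each later cohort is translated onto it, so the centroid and the frozen
cut-point never change frames between the stage that learns them and the
stage that applies them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .batch_dwd import dwd_adjust, fit_dwd
from .classifier import Centroid, build_centroid, call_samples
from .clinical import chi_square_rxc, fisher_exact_2x2
from .io import read_clinical_table, read_expression_table, write_expression_table
from .preprocess import knn_impute
from .sam import SamResult, sam_two_class
from .survival import CutpointResult, SurvivalRecord, cox_fit, km_estimate, logrank_test, xtile_cutpoint

__all__ = ["PipelineConfig", "PipelineError", "derive", "train", "test", "run_pipeline"]

logger = logging.getLogger(__name__)

RESECTED, METASTATIC = "nonmetastatic", "metastatic"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All file paths and tunables of a pipeline run.

    Numeric defaults are the published analysis parameters: intensity filter
    threshold 10 in at least 70% of experiments, KNN imputation with k = 10,
    SAM at 5% FDR.
    """

    derivation_expression: str | None = None
    derivation_clinical: str | None = None
    training_expression: str | None = None
    training_clinical: str | None = None
    test_expression: str | None = None
    test_clinical: str | None = None
    out_dir: str = "pdacsig_out"
    filter_threshold: float = 10.0
    filter_fraction: float = 0.7
    knn_k: int = 10
    sam_fdr: float = 0.05
    sam_n_perm: int = 1000
    seed: int = 0
    dwd_penalty: float | None = None
    cutpoint_min_group: int = 5
    ties: str = "efron"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def digest(self) -> str:
        """Hash of the analysis parameters (the output location is excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class DerivationResult:
    sam: SamResult
    signature: list
    centroid_resected: Centroid
    centroid_metastatic: Centroid
    adjusted: pd.DataFrame  # all derivation samples, common space
    annotation: pd.DataFrame


@dataclass
class TrainingResult:
    cutpoint: CutpointResult
    calls: pd.DataFrame
    centroid_resected: Centroid
    adjusted_derivation: pd.DataFrame
    adjusted_training: pd.DataFrame


def _impute_if_needed(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    if matrix.isna().to_numpy().any():
        return knn_impute(matrix, k=k)
    return matrix


def _records_for(clinical: pd.DataFrame, sample_ids) -> list[SurvivalRecord]:
    tab = clinical.set_index("sample_id").loc[list(sample_ids)]
    return [
        SurvivalRecord(time=float(row["time_months"]), event=bool(int(row["event"])))
        for _, row in tab.iterrows()
    ]


def derive(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    tumors_a,
    tumors_b,
    config: PipelineConfig,
) -> DerivationResult:
    """Derivation stage: impute, DWD-adjust cohort A vs B, run SAM, build centroids."""
    expr_a = _impute_if_needed(expr_a, config.knn_k)
    expr_b = _impute_if_needed(expr_b, config.knn_k)
    model = fit_dwd(expr_a, expr_b, penalty=config.dwd_penalty)
    adj_a, adj_b = dwd_adjust([expr_a, expr_b], model, target="reference")
    logger.info(
        "derivation DWD: batch mean projections %.3f / %.3f removed",
        model.mean_projections["A"],
        model.mean_projections["B"],
    )

    tumors_a, tumors_b = list(tumors_a), list(tumors_b)
    tumor_expr = pd.concat([adj_a[tumors_a], adj_b[tumors_b]], axis=1)
    labels = [RESECTED] * len(tumors_a) + [METASTATIC] * len(tumors_b)
    sam = sam_two_class(
        tumor_expr,
        labels,
        n_perm=config.sam_n_perm,
        target_fdr=config.sam_fdr,
        seed=config.seed,
    )
    logger.info("SAM selected %d genes at FDR %.0f%%", len(sam.selected), 100 * config.sam_fdr)
    if len(sam.selected) < 3:
        # Pearson correlation to a centroid is undefined over < 3 genes
        raise PipelineError(
            f"derivation: SAM selected only {len(sam.selected)} gene(s) at FDR "
            f"{config.sam_fdr}; at least 3 are needed for the correlation-based "
            "single-sample predictor"
        )

    adjusted = pd.concat([adj_a, adj_b], axis=1)
    annotation = pd.DataFrame(
        {
            "sample_id": list(adj_a.columns) + list(adj_b.columns),
            "batch": ["A"] * adj_a.shape[1] + ["B"] * adj_b.shape[1],
            "outcome": [
                RESECTED if s in set(tumors_a) else "other" for s in adj_a.columns
            ]
            + [METASTATIC if s in set(tumors_b) else "other" for s in adj_b.columns],
        }
    )
    return DerivationResult(
        sam=sam,
        signature=list(sam.selected),
        centroid_resected=build_centroid(adjusted, tumors_a, sam.selected, "resected"),
        centroid_metastatic=build_centroid(adjusted, tumors_b, sam.selected, "metastatic"),
        adjusted=adjusted,
        annotation=annotation,
    )


def train(
    derivation: DerivationResult,
    train_expr: pd.DataFrame,
    train_clinical: pd.DataFrame,
    config: PipelineConfig,
) -> TrainingResult:
    """Training stage: adjust into common space, score distances, find the cut-point."""
    train_expr = _impute_if_needed(train_expr, config.knn_k)
    model = fit_dwd(derivation.adjusted, train_expr, penalty=config.dwd_penalty)
    # the derivation space is the established frame: only the new cohort moves
    adj_deriv, adj_train = dwd_adjust(
        [derivation.adjusted, train_expr], model, target="reference"
    )

    tumors_a = derivation.annotation.query("outcome == @RESECTED")["sample_id"]
    centroid = build_centroid(adj_deriv, tumors_a, derivation.signature, "resected")

    calls = call_samples(adj_train, centroid)  # cut-point not yet known; labels provisional
    records = _records_for(train_clinical, calls["sample_id"])
    cut = xtile_cutpoint(
        calls["distance"].to_numpy(), records, min_group=config.cutpoint_min_group
    )
    calls["risk"] = np.where(calls["distance"] < cut.cutpoint, "low", "high")
    logger.info(
        "training cut-point %.3f (chi2=%.2f, naive p=%.3g, corrected p=%.3g)",
        cut.cutpoint,
        cut.statistic,
        cut.p_naive,
        cut.p_corrected,
    )
    return TrainingResult(
        cutpoint=cut,
        calls=calls,
        centroid_resected=centroid,
        adjusted_derivation=adj_deriv,
        adjusted_training=adj_train,
    )


def _association_tests(calls: pd.DataFrame, clinical: pd.DataFrame) -> dict:
    """Risk-group vs clinical-covariate association tests.

    2-level covariates get the Fisher exact test, >2 levels Pearson
    chi-square; rows with missing values are dropped per variable and
    counted.
    """
    merged = calls.merge(clinical, on="sample_id")
    skip = {"sample_id", "r", "distance", "risk", "time_months", "event"}
    out = {}
    for col in merged.columns:
        if col in skip:
            continue
        sub = merged[["risk", col]].dropna()
        n_dropped = len(merged) - len(sub)
        levels = sub[col].unique()
        if not 2 <= len(levels) <= 10:
            continue
        table = pd.crosstab(sub[col], sub["risk"]).to_numpy()
        if table.shape[0] == 2 and table.shape[1] == 2:
            entry = {"test": "fisher_exact", "p": fisher_exact_2x2(table)}
        else:
            try:
                stat, df, p = chi_square_rxc(table)
            except ValueError:
                continue
            entry = {"test": "chi_square", "p": p, "statistic": stat, "df": df}
        entry["n_dropped"] = n_dropped
        entry["table"] = table.tolist()
        out[col] = entry
    return out


def test(
    training: TrainingResult,
    derivation: DerivationResult,
    test_expr: pd.DataFrame,
    test_clinical: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """Test stage: classify with the frozen cut-point and validate on survival."""
    test_expr = _impute_if_needed(test_expr, config.knn_k)
    pooled = pd.concat(
        [training.adjusted_derivation, training.adjusted_training], axis=1
    )
    model = fit_dwd(pooled, test_expr, penalty=config.dwd_penalty)
    adj_pooled, adj_test = dwd_adjust([pooled, test_expr], model, target="reference")

    n_deriv = training.adjusted_derivation.shape[1]
    tumors_a = derivation.annotation.query("outcome == @RESECTED")["sample_id"]
    centroid = build_centroid(
        adj_pooled.iloc[:, :n_deriv], tumors_a, derivation.signature, "resected"
    )

    frozen_cut = training.cutpoint.cutpoint
    calls = call_samples(adj_test, centroid, cutpoint=frozen_cut)
    records = _records_for(test_clinical, calls["sample_id"])

    high = calls["risk"] == "high"
    rec_high = [r for r, h in zip(records, high) if h]
    rec_low = [r for r, h in zip(records, high) if not h]
    if not rec_high or not rec_low:
        raise PipelineError("test: all samples fell into one risk group")

    km_high, km_low = km_estimate(rec_high), km_estimate(rec_low)
    lr = logrank_test(rec_high, rec_low)

    covariates = pd.DataFrame({"high_risk": high.astype(float).to_numpy()})
    extra = test_clinical.set_index("sample_id").reindex(calls["sample_id"])
    for col in extra.columns:
        if col in ("time_months", "event"):
            continue
        vals = pd.to_numeric(extra[col], errors="coerce")
        if vals.notna().all() and vals.nunique() > 1:
            covariates[col] = vals.to_numpy()
    cox = cox_fit(records, covariates, ties=config.ties)

    def _rates(km):
        return {f"{y}y": km.survival_at(12.0 * y) for y in (1, 2, 3)}

    return {
        "cutpoint": frozen_cut,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
        "median_os_high": km_high.median,
        "median_os_low": km_low.median,
        "survival_rates_high": _rates(km_high),
        "survival_rates_low": _rates(km_low),
        "logrank_p": lr.p_value,
        "logrank_statistic": lr.statistic,
        "cox": {
            "ties": cox.ties,
            "n_used": cox.n_used,
            "n_dropped": cox.n_dropped,
            "n_events": cox.n_events,
            "summary": {
                name: {
                    k: float(v) for k, v in row.items()
                }
                for name, row in cox.summary.iterrows()
            },
        },
        "associations": _association_tests(calls, test_clinical),
        "calls": calls,
        "km_high": km_high,
        "km_low": km_low,
    }


def _split_derivation(expr: pd.DataFrame, clinical: pd.DataFrame):
    ann = clinical.set_index("sample_id").reindex(expr.columns)
    batches = [b for b in ann["batch"].unique()]
    if len(batches) != 2:
        raise PipelineError(f"derivation clinical table must have 2 batches, got {batches}")
    a, b = sorted(batches)
    cols_a = [s for s in expr.columns if ann.loc[s, "batch"] == a]
    cols_b = [s for s in expr.columns if ann.loc[s, "batch"] == b]
    tum_a = [s for s in cols_a if ann.loc[s, "class"] != "normal"]
    tum_b = [s for s in cols_b if ann.loc[s, "class"] != "normal"]
    return expr[cols_a], expr[cols_b], tum_a, tum_b


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run derivation -> training -> test from the configured files.

    Writes all intermediate artifacts plus a JSON and markdown report into
    ``config.out_dir``; reruns with the same config and seed are
    byte-identical.  Without a test cohort the run stops after training and
    says so in the report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_digest": config.digest(), "seed": config.seed, "version": __version__}

    try:
        expr = read_expression_table(config.derivation_expression)
        clin = read_clinical_table(config.derivation_clinical)
        expr_a, expr_b, tumors_a, tumors_b = _split_derivation(expr, clin)
        derivation = derive(expr_a, expr_b, tumors_a, tumors_b, config)
    except Exception as exc:
        raise PipelineError(f"derivation stage failed: {exc}") from exc

    derivation.sam.write_table(out / "sam_table.tsv")
    derivation.centroid_resected.write(out / "centroid_resected.tsv")
    derivation.centroid_metastatic.write(out / "centroid_metastatic.tsv")
    write_expression_table(derivation.adjusted, out / "derivation_adjusted.tsv")
    report["derivation"] = {
        "n_genes": int(derivation.adjusted.shape[0]),
        "n_samples": int(derivation.adjusted.shape[1]),
        "signature": list(map(str, derivation.signature)),
        "sam_s0": derivation.sam.s0,
        "sam_delta": derivation.sam.delta,
        "sam_fdr": derivation.sam.fdr,
    }

    if config.training_expression is None:
        report["status"] = "derivation-only"
        _write_report(report, out)
        return report

    try:
        train_expr = read_expression_table(config.training_expression)
        train_clin = read_clinical_table(config.training_clinical)
        training = train(derivation, train_expr, train_clin, config)
    except Exception as exc:
        _write_report({**report, "status": f"training stage failed: {exc}"}, out)
        raise PipelineError(f"training stage failed: {exc}") from exc

    training.calls.to_csv(out / "training_calls.csv", index=False)
    with open(out / "cutpoint.json", "w") as fh:
        json.dump(
            {
                "cutpoint": training.cutpoint.cutpoint,
                "statistic": training.cutpoint.statistic,
                "p_naive": training.cutpoint.p_naive,
                "p_corrected": training.cutpoint.p_corrected,
            },
            fh,
            sort_keys=True,
        )
    report["training"] = {
        "cutpoint": training.cutpoint.cutpoint,
        "statistic": training.cutpoint.statistic,
        "p_naive": training.cutpoint.p_naive,
        "p_corrected": training.cutpoint.p_corrected,
        "n_low": training.cutpoint.n_low,
        "n_high": training.cutpoint.n_high,
    }

    if config.test_expression is None:
        report["status"] = "no-test-cohort"
        _write_report(report, out)
        return report

    try:
        test_expr = read_expression_table(config.test_expression)
        test_clin = read_clinical_table(config.test_clinical)
        result = test(training, derivation, test_expr, test_clin, config)
    except Exception as exc:
        _write_report({**report, "status": f"test stage failed: {exc}"}, out)
        raise PipelineError(f"test stage failed: {exc}") from exc

    result["calls"].to_csv(out / "test_calls.csv", index=False)
    result.pop("calls")
    result.pop("km_high").to_frame().to_csv(out / "km_test_high.csv", index=False)
    result.pop("km_low").to_frame().to_csv(out / "km_test_low.csv", index=False)
    report["test"] = _jsonable(result)
    report["status"] = "complete"
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    lines = ["# Prognostic signature pipeline report", ""]
    lines.append(f"- status: {report.get('status', 'incomplete')}")
    lines.append(f"- seed: {report['seed']}; config digest: {report['config_digest']}")
    if "derivation" in report:
        d = report["derivation"]
        lines += [
            "",
            "## Derivation",
            f"- {d['n_genes']} genes x {d['n_samples']} samples",
            f"- signature ({len(d['signature'])} genes): {', '.join(d['signature'])}",
            f"- SAM s0={d['sam_s0']:.4g}, delta={d['sam_delta']:.4g}, est. FDR={d['sam_fdr']:.4g}",
        ]
    if "training" in report:
        t = report["training"]
        lines += [
            "",
            "## Training",
            f"- optimal distance cut-point {t['cutpoint']:.4g} "
            f"(log-rank chi2={t['statistic']:.3g})",
            f"- naive p={t['p_naive']:.3g}, corrected p={t['p_corrected']:.3g}",
            f"- groups at cut-point: {t['n_low']} low / {t['n_high']} high",
        ]
    if "test" in report:
        s = report["test"]
        hr = s["cox"]["summary"].get("high_risk", {})
        lines += [
            "",
            "## Independent test",
            f"- frozen cut-point {s['cutpoint']:.4g}: "
            f"{s['n_high']} high / {s['n_low']} low risk",
            f"- median OS high {s['median_os_high']} vs low {s['median_os_low']} months",
            f"- log-rank p = {s['logrank_p']:.4g}",
            f"- Cox HR (high vs low) = {hr.get('hr', float('nan')):.3g} "
            f"[{hr.get('ci_low', float('nan')):.3g}, {hr.get('ci_high', float('nan')):.3g}], "
            f"p = {hr.get('p', float('nan')):.3g}",
        ]
    with open(out / "report.md", "w") as fh:
        fh.write("\n".join(lines) + "\n")
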