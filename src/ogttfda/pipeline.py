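"""End-to-end pipeline: smoothing -> FPCA -> scores -> shapes -> stats.

``run_pipeline`` chains every stage on a cohort (read from file or freshly
simulated), logging participant counts at each step, and returns a bundle
of tidy result tables ready for :func:`ogttfda.cohort.write_results`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import associations, fpca, prediction, shapes, smoothing
from .cohort import CohortReadResult, read_cohort, records_to_frame
from .config import PipelineConfig
from .synthetic import GeneratorParams, generate_cohort

logger = logging.getLogger(__name__)

LAB_TARGETS = ["hba1c", "bmi_percentile", "waist_cm", "sbp", "dbp",
               "total_chol", "ldl", "hdl", "triglycerides"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    """Everything the pipeline computes, as tables plus fitted models."""

    config: PipelineConfig
    cohort: pd.DataFrame
    exclusions: list[tuple[int, str]]
    shapes: pd.DataFrame
    coefficients: pd.DataFrame
    lambdas: dict[str, float]
    models: dict[str, fpca.FPCModel] = field(repr=False)
    scores: pd.DataFrame = None
    variance_explained: pd.DataFrame = None
    spearman: pd.DataFrame = None
    group_tests: pd.DataFrame = None
    adjusted_models: pd.DataFrame = None
    paired_tests: pd.DataFrame = None
    auc: pd.DataFrame = None
    truth: pd.DataFrame = None

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {"cohort": self.cohort, "shapes": self.shapes,
               "coefficients": self.coefficients, "scores": self.scores,
               "variance_explained": self.variance_explained}
        for name in ("spearman", "group_tests", "adjusted_models",
                     "paired_tests", "auc", "truth"):
            t = getattr(self, name)
            if t is not None:
                out[name] = t
        return out


def smooth_cohort(records, config: PipelineConfig):
    """CV-select one lambda per analyte and fit every participant's curves.

    Returns (basis, {analyte: lambda}, coefficient table, curve lists).
    """
    basis = smoothing.build_basis(n_basis=config.n_basis,
                                  quad_step=config.quadrature_step)
    G = np.vstack([r.baseline_profile.glucose for r in records])
    I = np.vstack([r.baseline_profile.insulin for r in records])
    grid = np.asarray(config.lambda_grid, float)
    lam = {"glucose": smoothing.select_lambda(G, basis, grid).lam,
           "insulin": smoothing.select_lambda(I, basis, grid).lam}
    curves = {}
    rows = []
    for analyte, Y in (("glucose", G), ("insulin", I)):
        C = smoothing.fit_coefficients(Y, basis, lam[analyte])
        curves[analyte] = [
            smoothing.SmoothCurve(
                coefficients=C[i], analyte=analyte, lam=lam[analyte],
                residuals=Y[i] - basis.design @ C[i], basis=basis)
            for i in range(len(records))
        ]
        for rec, curve in zip(records, curves[analyte]):
            row = {"id": rec.id, "analyte": analyte,
                   "lambda": lam[analyte], "rss": curve.rss}
            row.update({f"c{k+1}": c for k, c in enumerate(curve.coefficients)})
            rows.append(row)
    return basis, lam, pd.DataFrame(rows), curves


def fit_scores(curves: dict, config: PipelineConfig):
    """FPCA per analyte plus raw and standardized scores."""
    models, score_cols = {}, {}
    ve_rows = []
    for analyte, clist in curves.items():
        model = fpca.fit_fpca(clist, n_components=config.n_fpc)
        models[analyte] = model
        raw = fpca.score_cohort(model, clist)
        std = fpca.standardize_scores(raw)
        score_cols[analyte] = (raw, std)
        for k in range(config.n_fpc):
            ve_rows.append({"analyte": analyte, "component": k + 1,
                            "eigenvalue": model.eigenvalues[k],
                            "variance_explained": model.variance_explained[k]})
    return models, score_cols, pd.DataFrame(ve_rows)


def run_pipeline(config: PipelineConfig | None = None,
                 input: str | CohortReadResult = "synthetic",
                 n: int | None = None,
                 generator_params: GeneratorParams | None = None,
                 ) -> PipelineResult:
    """Execute the full analysis.

    ``input`` is a cohort file path, an already-read ``CohortReadResult``,
    or the string ``"synthetic"`` (simulate ``n`` participants with
    ``generator_params`` or the defaults, seeded from the config seed).
    """
    config = config or PipelineConfig()
    config.validate()

    truth = None
    stage = "load"
    try:
        if isinstance(input, CohortReadResult):
            records, excl = input.records, input.rejects
        elif input == "synthetic":
            params = generator_params or GeneratorParams()
            if n is not None:
                params = GeneratorParams(**{**params.__dict__, "n": n})
            params = GeneratorParams(**{**params.__dict__,
                                        "seed": config.seed})
            cohort = generate_cohort(params)
            records, excl = cohort.records, []
            truth = cohort.truth
        else:
            result = read_cohort(input)
            records, excl = result.records, result.rejects
        if not records:
            raise ValueError("no valid participants")
        logger.info("stage load: %d participants, %d excluded",
                    len(records), len(excl))

        stage = "shape_classification"
        shape_classes = [shapes.classify_shape(r.baseline_profile.glucose,
                                               config.shape_delta)
                         for r in records]
        shape_df = pd.DataFrame({
            "id": [r.id for r in records],
            "shape": [s.label for s in shape_classes],
            "peak_index": [s.peak_index for s in shape_classes],
            "drop": [s.drop for s in shape_classes],
            "rerise": [s.rerise for s in shape_classes],
        })
        logger.info("stage shapes: %s",
                    shape_df["shape"].value_counts().to_dict())

        stage = "smoothing"
        basis, lam, coef_df, curves = smooth_cohort(records, config)
        logger.info("stage smoothing: lambda=%s", lam)

        stage = "fpca"
        models, score_cols, ve_df = fit_scores(curves, config)
        score_df = pd.DataFrame({"id": [r.id for r in records]})
        for analyte, prefix in (("glucose", "glu"), ("insulin", "ins")):
            raw, std = score_cols[analyte]
            for k in range(config.n_fpc):
                score_df[f"{prefix}_fpc{k+1}_raw"] = raw[:, k]
                score_df[f"{prefix}_fpc{k+1}"] = std[:, k]
        logger.info("stage fpca: variance explained %s",
                    {a: float(models[a].variance_explained.sum())
                     for a in models})

        stage = "cross_sectional"
        demo = records_to_frame(records)
        dummies = shapes.shape_dummies(shape_df["shape"])
        features = pd.concat(
            [dummies.add_prefix("shape_"),
             score_df[[c for c in score_df.columns
                       if c.endswith(("fpc1", "fpc2", "fpc3"))]]],
            axis=1).loc[dummies.index]
        target_cols = {}
        for t in (0, 30, 60, 90, 120):
            target_cols[f"glucose_{t}"] = demo[f"glucose_{t}"]
            target_cols[f"insulin_{t}"] = demo[f"insulin_{t}"]
        for lab in LAB_TARGETS:
            target_cols[lab] = demo[lab]
        targets = pd.DataFrame(target_cols)
        spear = associations.spearman_matrix(
            features, targets.loc[features.index],
            alpha=config.bonferroni_alpha, n_comparisons=config.bonferroni_n)
        group = associations.group_difference_tests(
            shape_df.loc[dummies.index, "shape"],
            pd.concat([demo.loc[dummies.index,
                                ["age", "sex", "race", "ethnicity"]],
                       targets.loc[dummies.index, LAB_TARGETS]], axis=1),
            categorical=["sex", "race", "ethnicity"])
        std_cols = [c for c in score_df.columns if not c.endswith("_raw")
                    and c != "id"]
        adjusted = associations.adjusted_fpc_models(
            score_df[std_cols],
            targets[LAB_TARGETS],
            demo[["age", "sex", "race", "ethnicity"]])

        stage = "longitudinal"
        paired = auc = None
        fu_mask = np.array([r.has_followup and
                            (r.followup_interval or 12) >= 6
                            for r in records])
        if fu_mask.sum() >= 10:
            idx = np.nonzero(fu_mask)[0]
            fu = [records[i] for i in idx]
            base_lab = prediction.label_cohort(
                [r.baseline_profile.fpg for r in fu],
                [r.baseline_profile.pg2h for r in fu],
                fpg_gt=config.fpg_gt, pg2h_gt=config.pg2h_gt)
            fu_lab = prediction.label_cohort(
                [r.followup_profile.fpg for r in fu],
                [r.followup_profile.pg2h for r in fu],
                fpg_gt=config.fpg_gt, pg2h_gt=config.pg2h_gt)
            paired = prediction.paired_change_tests(
                pd.DataFrame({
                    "fpg": [r.baseline_profile.fpg for r in fu],
                    "pg2h": [r.baseline_profile.pg2h for r in fu],
                    "dysglycemia": base_lab}),
                pd.DataFrame({
                    "fpg": [r.followup_profile.fpg for r in fu],
                    "pg2h": [r.followup_profile.pg2h for r in fu],
                    "dysglycemia": fu_lab}))
            feats = build_predictor_features(
                demo.iloc[idx].reset_index(drop=True),
                score_df.iloc[idx].reset_index(drop=True),
                shape_df.iloc[idx].reset_index(drop=True))
            keep = feats["shape_valid"].to_numpy()
            if fu_lab[keep].sum() >= 1 and (~fu_lab[keep]).sum() >= 1:
                models_pred = prediction.fit_predictor_models(
                    feats[keep], fu_lab[keep])
                auc = prediction.auc_table(models_pred)
            logger.info("stage longitudinal: %d participants, %d events",
                        int(fu_mask.sum()), int(fu_lab.sum()))
        else:
            logger.info("stage longitudinal: skipped (%d follow-ups)",
                        int(fu_mask.sum()))
    except Exception as exc:  # annotate with the failing stage
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    return PipelineResult(
        config=config, cohort=records_to_frame(records), exclusions=excl,
        shapes=shape_df, coefficients=coef_df, lambdas=lam, models=models,
        scores=score_df, variance_explained=ve_df, spearman=spear,
        group_tests=group, adjusted_models=adjusted, paired_tests=paired,
        auc=auc, truth=truth,
    )


def build_predictor_features(demo: pd.DataFrame, scores: pd.DataFrame,
                             shape_df: pd.DataFrame) -> pd.DataFrame:
    """Assemble the feature table for the seven predictor sets.

    Shape dummies use monophasic as the reference level; rows with an
    inconclusive shape are marked invalid (``shape_valid = False``) and are
    expected to be excluded from model fitting by the caller.
    """
    out = pd.DataFrame({
        "fpg": demo["glucose_0"].to_numpy(float),
        "pg2h": demo["glucose_120"].to_numpy(float),
        "hba1c": demo["hba1c"].to_numpy(float),
    })
    lab = shape_df["shape"].to_numpy()
    out["shape_biphasic"] = (lab == shapes.BIPHASIC).astype(float)
    out["shape_monotonically_increasing"] = (lab == shapes.MONOTONIC).astype(float)
    out["shape_valid"] = lab != shapes.INCONCLUSIVE
    for col in scores.columns:
        if col != "id" and not col.endswith("_raw"):
            out[col] = scores[col].to_numpy(float)
    return out
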