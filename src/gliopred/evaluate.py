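"""Prediction-accuracy metrics and the experiment-grid orchestrator.

Predicted fields are compared against the same-SR noiseless ground truth:
the Dice similarity coefficient scores global volume agreement of the
binarized tumor, Lin's concordance correlation coefficient (CCC) scores
local voxelwise agreement of the continuous fractions, and percent error
scores parameter recovery. Metrics are evaluated within the brain mask; the
CCC is computed on the voxels where truth or prediction exceeds a detection
threshold (0.05 * theta_max by default, the same threshold used to binarize
for Dice and to define the tumor periphery).
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import ScalarField
from .cohort import ModelParameters, VirtualTumorSpec, CALIBRATED_NAMES
from .calibrate import CalibrationConfig, calibrate, predict
from .degrade import ExperimentCondition, condition_grid, degrade
from .study import StudyConfig, ground_truth_course

__all__ = [
    "dice",
    "ccc",
    "percent_error",
    "DegenerateMetricError",
    "run_experiment_grid",
    "summarize",
    "METRIC_COLUMNS",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("dice_tumor", "ccc_tumor", "ccc_vasc",
                  "pe_D_t0", "pe_D_v0", "pe_k_t", "pe_k_v")


class DegenerateMetricError(ValueError):
    """Raised when a metric is undefined on the given evaluation set."""


def _check_common_grid(predicted: ScalarField, truth: ScalarField) -> None:
    if predicted.grid != truth.grid:
        raise ValueError("predicted and truth fields live on different grids")


def dice(predicted: ScalarField, truth: ScalarField, threshold: float,
         mask: np.ndarray | None = None) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|) of the thresholded fields.

    Returns 1.0 (perfect trivial agreement) when both masks are empty; the
    event is logged because it usually signals a degenerate comparison.
    """
    _check_common_grid(predicted, truth)
    a = predicted.values > threshold
    b = truth.values > threshold
    if mask is not None:
        a = a & mask
        b = b & mask
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        logger.debug("dice: both masks empty, returning 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def ccc(predicted: ScalarField, truth: ScalarField, detection_threshold: float,
        mask: np.ndarray | None = None) -> float:
    """Lin's concordance correlation coefficient on detected voxels.

    The evaluation set is the union of voxels where truth or prediction
    exceeds the detection threshold (intersected with ``mask`` if given):

        CCC = 2 cov(p, t) / ( var(p) + var(t) + (mean(p) - mean(t))^2 )

    with population (1/n) moments. Raises
    :class:`DegenerateMetricError` for evaluation sets smaller than two
    voxels or with both fields constant.
    """
    _check_common_grid(predicted, truth)
    select = (predicted.values > detection_threshold) | (truth.values > detection_threshold)
    if mask is not None:
        select = select & mask
    p = predicted.values[select]
    t = truth.values[select]
    if p.size < 2:
        raise DegenerateMetricError(
            f"CCC undefined: only {p.size} voxel(s) exceed the detection threshold"
        )
    var_p = p.var()
    var_t = t.var()
    denom = var_p + var_t + (p.mean() - t.mean()) ** 2
    if denom == 0:
        raise DegenerateMetricError("CCC undefined: constant and identical fields")
    cov = ((p - p.mean()) * (t - t.mean())).mean()
    return float(2.0 * cov / denom)


def percent_error(true_value: float, estimated: float) -> float:
    """Percent error 100 |estimated - true| / |true|; undefined for true = 0."""
    if true_value == 0:
        raise ValueError("percent error undefined for a zero true value")
    return 100.0 * abs(estimated - true_value) / abs(true_value)


def _row_seed(master_seed: int, tumor_idx: int, cond_idx: int, replicate: int):
    """Counter-based per-row seed fan-out; any row is re-runnable in isolation."""
    seq = np.random.SeedSequence(entropy=int(master_seed),
                                 spawn_key=(tumor_idx, cond_idx, replicate))
    noise_seed, guess_seed = (int(s) % (2**31) for s in seq.generate_state(2))
    return noise_seed, guess_seed


def run_experiment_grid(
    cohort: Sequence[VirtualTumorSpec],
    conditions: Sequence[ExperimentCondition] | None = None,
    replicates: int = 5,
    seed: int = 0,
    study: StudyConfig | None = None,
    eval_days: Sequence[int] = (6, 10),
    noise: bool = True,
) -> pd.DataFrame:
    """Run the degradation -> calibration -> prediction -> scoring pipeline.

    For every (tumor, condition, replicate): build the SR-specific noiseless
    ground truth, degrade it per the condition, calibrate the four
    parameters from the degraded days, predict to day 10, and score against
    the same-SR noiseless ground truth at the evaluation days. One row per
    (tumor, condition, replicate, day); failures are recorded with a
    ``failure`` code and the grid continues. Fully reproducible from the
    master seed.
    """
    if study is None:
        study = StudyConfig()
    if conditions is None:
        conditions = condition_grid()
    rows = []
    threshold = study.metric_threshold
    for tumor_idx, spec in enumerate(cohort):
        for cond_idx, cond in enumerate(conditions):
            gt, domain = ground_truth_course(spec.parameters, cond.voxel_volume, study)
            brain = domain.brain_mask
            truth_param = spec.parameters.calibrated_vector()
            for rep in range(replicates):
                noise_seed, guess_seed = _row_seed(seed, tumor_idx, cond_idx, rep)
                cond_rep = replace(cond, replicate_seed=noise_seed)
                base = dict(
                    tumor_id=spec.tumor_id,
                    condition_id=cond.condition_id,
                    snr=cond.snr,
                    voxel_volume=cond.voxel_volume,
                    n_timepoints=len(cond.tr_days),
                    replicate=rep,
                )
                try:
                    observed = degrade(gt, cond_rep, replicate=rep,
                                       clip_max=spec.parameters.theta_max,
                                       noiseless=not noise)
                    calcfg = replace(study.calibration,
                                     true_parameters=spec.parameters,
                                     solver=study.solver)
                    result = calibrate(observed, spec.parameters, domain,
                                       config=calcfg, seed=guess_seed)
                    first_day = observed.days[0]
                    prediction = predict(
                        result,
                        (observed.tumor(first_day), observed.vasculature(first_day)),
                        domain,
                        horizon=study.horizon,
                        solver=study.solver,
                    )
                    est = result.estimated.calibrated_vector()
                    pes = {
                        f"pe_{name}": percent_error(tv, ev)
                        for name, tv, ev in zip(CALIBRATED_NAMES, truth_param, est)
                    }
                    for day in eval_days:
                        row = dict(base, day=day, failure="", notes="",
                                   converged=result.converged,
                                   n_iterations=result.n_iterations,
                                   objective=result.objective, **pes)
                        row["dice_tumor"] = dice(prediction.tumor(day), gt.tumor(day),
                                                 threshold, brain)
                        metric_pairs = (
                            ("ccc_tumor", prediction.tumor(day), gt.tumor(day)),
                            ("ccc_vasc", prediction.vasculature(day),
                             gt.vasculature(day)),
                        )
                        notes = []
                        for name, pred_f, true_f in metric_pairs:
                            try:
                                row[name] = ccc(pred_f, true_f, threshold, brain)
                            except DegenerateMetricError as exc:
                                # e.g. vasculature below the detection
                                # threshold at early days: undefined, not zero
                                row[name] = np.nan
                                notes.append(f"{name}: {exc}")
                        row["notes"] = "; ".join(notes)
                        rows.append(row)
                except Exception as exc:  # keep the grid running
                    logger.warning("row failed (%s, %s, rep %d): %s",
                                   spec.tumor_id, cond.condition_id, rep, exc)
                    for day in eval_days:
                        rows.append(dict(base, day=day, failure=f"{type(exc).__name__}: {exc}"))
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame,
              by: Sequence[str] = ("condition_id", "tumor_id", "day")) -> pd.DataFrame:
    """Median and 25-75% interquartile range per condition cell and metric.

    Quartiles use linear interpolation between order statistics (numpy
    default), recorded in the output metadata columns. Cells with no
    successful replicate are omitted with a warning.
    """
    ok = table[table.get("failure", "") == ""] if "failure" in table else table
    dropped = len(table) - len(ok)
    if dropped:
        logger.warning("summarize: omitting %d failed rows", dropped)
    metrics = [c for c in METRIC_COLUMNS if c in ok.columns]
    records = []
    for keys, group in ok.groupby(list(by)):
        rec = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        rec["n"] = len(group)
        for m in metrics:
            vals = group[m].dropna().to_numpy()
            if vals.size == 0:
                continue
            rec[f"{m}_median"] = float(np.median(vals))
            rec[f"{m}_q25"] = float(np.percentile(vals, 25))
            rec[f"{m}_q75"] = float(np.percentile(vals, 75))
        records.append(rec)
    out = pd.DataFrame(records)
    out.attrs["quartile_convention"] = "linear interpolation between order statistics"
    return out
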