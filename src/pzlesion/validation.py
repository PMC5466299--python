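"""Optimism-corrected AUC with patient-clustered bootstrap inference.

Because each model is fit and evaluated on the same lesions, its
apparent AUC is optimistic.  The correction implemented here refits the
model on bootstrap replicates drawn by resampling *patients* (a drawn
patient contributes all their lesions, so within-patient correlation is
respected), and estimates the optimism as the mean over replicates of

    auc(replicate fit on replicate) - auc(replicate fit on original).

The corrected AUC is the apparent AUC minus that mean.  Confidence
intervals come from the same replicate stream: the distribution of the
replicate apparent AUCs (each replicate fit scored on its own bootstrap
sample, so the spread reflects patient-level sampling variability),
recentred on the corrected estimate (a "basic" bootstrap interval is
available as a switch).
Paired model comparison reuses one replicate stream for both models and
reads a two-sided p-value off the recentred distribution of the paired
AUC differences.

Replicates whose resampled outcome is single-class are skipped and
counted, never redrawn or imputed.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .battery import (
    DegenerateOutcomeError,
    ModelSpec,
    _fit_beta,
    encode_design,
    fit_logistic,
)
from .data_model import Cohort, CsPCaDefinition, LesionRecord
from .features import feature_frame

logger = logging.getLogger("pzlesion.validation")

#: sentinel model name for the reader's Likert score used directly
LIKERT = "Likert"


class ValidationFailure(RuntimeError):
    """Every bootstrap replicate was degenerate; nothing to aggregate."""


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney form with ties counted 1/2.

    Equals P(score+ > score-) + 0.5 * P(score+ = score-) over all
    positive/negative lesion pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateOutcomeError("AUC needs both outcome classes")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def cluster_resample(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    """One patient-level bootstrap replicate of a cohort.

    Draws as many patients as the cohort has, with replacement; each
    drawn patient contributes all their lesions.  Repeat draws of the
    same patient get distinct synthetic cluster ids so downstream
    clustering stays well defined.
    """
    patients = sorted(set(r.patient_id for r in cohort))
    if not patients:
        raise ValueError("cannot resample an empty cohort")
    by_patient: dict[str, list[LesionRecord]] = {p: [] for p in patients}
    for rec in cohort:
        by_patient[rec.patient_id].append(rec)
    records: list[LesionRecord] = []
    draws = rng.integers(0, len(patients), size=len(patients))
    for k, d in enumerate(draws):
        pid = patients[d]
        for rec in by_patient[pid]:
            records.append(dataclasses.replace(rec, patient_id=f"{pid}#{k}"))
    return Cohort(tuple(records), provenance=f"{cohort.provenance} resampled")


@dataclasses.dataclass(frozen=True)
class ValidationResult:
    """Apparent and optimism-corrected AUC for one (model, definition) cell."""

    model_name: str
    definition: str
    seq_variant: str
    apparent_auc: float
    mean_optimism: float
    corrected_auc: float
    ci_low: float
    ci_high: float
    n_boot_used: int
    n_boot_degenerate: int
    seed: int
    fallback_fits: int = 0


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    """Corrected-scale AUC difference between two models on one cohort."""

    model_a: str
    model_b: str
    definition: str
    delta_auc: float
    p_value: float
    ci_low: float
    ci_high: float
    corrected_a: float
    corrected_b: float
    n_boot_used: int
    n_boot_degenerate: int
    seed: int


def analysis_frame(cohort_or_frame: Cohort | pd.DataFrame) -> pd.DataFrame:
    """Single-reader feature frame, canonically ordered.

    Rows are sorted by patient and then by the full feature tuple so the
    bootstrap is exactly invariant to the input lesion order.
    """
    if isinstance(cohort_or_frame, Cohort):
        frame = feature_frame(cohort_or_frame)
    else:
        frame = cohort_or_frame.copy()
    if frame.empty:
        raise ValueError("no evaluable lesions")
    readers = frame["reader_id"].unique()
    if len(readers) > 1:
        raise ValueError(
            f"analyses are single-reader; found readers {sorted(readers)}"
        )
    sort_cols = ["patient_id"] + [c for c in frame.columns if c != "patient_id"]
    return frame.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)


def _labels(frame: pd.DataFrame, definition: CsPCaDefinition) -> np.ndarray:
    y = np.fromiter(
        (definition(gg, epe) for gg, epe in zip(frame["gleason_group"], frame["epe"])),
        dtype=float,
        count=len(frame),
    )
    return y


def _patient_groups(frame: pd.DataFrame) -> list[np.ndarray]:
    codes, _ = pd.factorize(frame["patient_id"], sort=True)
    order = np.argsort(codes, kind="stable")
    boundaries = np.searchsorted(codes[order], np.arange(codes.max() + 2))
    return [order[boundaries[i] : boundaries[i + 1]] for i in range(codes.max() + 1)]


def _percentile_ci(
    dist: np.ndarray, center: float, method: str
) -> tuple[float, float]:
    lo, hi = np.percentile(dist, [2.5, 97.5])
    if method == "percentile":
        shift = center - float(dist.mean())
        return float(lo + shift), float(hi + shift)
    if method == "basic":
        return float(2 * center - hi), float(2 * center - lo)
    raise ValueError(f"unknown CI method {method!r}")


def _score_column(frame: pd.DataFrame, name: str) -> np.ndarray:
    return frame[name].to_numpy(dtype=float)


def validate(
    cohort: Cohort | pd.DataFrame,
    spec: ModelSpec,
    definition: CsPCaDefinition,
    B: int = 1000,
    seed: int = 0,
    min_level_count: int = 3,
    ci_method: str = "percentile",
) -> ValidationResult:
    """Optimism-corrected AUC of one model under one outcome definition.

    With ``B = 0`` the corrected AUC equals the apparent AUC and the
    interval is undefined (NaN).
    """
    frame = analysis_frame(cohort)
    y = _labels(frame, definition)
    design = encode_design(frame, spec, min_level_count=min_level_count)
    X = design.matrix
    fitted = fit_logistic(design, y, spec)
    apparent = auc(fitted.fitted_probabilities, y)

    if B == 0:
        return ValidationResult(
            spec.name, definition.name, spec.seq_variant, apparent,
            0.0, apparent, math.nan, math.nan, 0, 0, seed,
            fallback_fits=int(fitted.fallback),
        )

    rng = np.random.default_rng(seed)
    groups = _patient_groups(frame)
    n_pat = len(groups)
    optimism: list[float] = []
    auc_boot_dist: list[float] = []
    degenerate = 0
    fallbacks = int(fitted.fallback)
    for _ in range(B):
        draws = rng.integers(0, n_pat, size=n_pat)
        rows = np.concatenate([groups[d] for d in draws])
        yb = y[rows]
        if yb.min() == yb.max():
            degenerate += 1
            continue
        Xb = X[rows]
        beta, _, fb = _fit_beta(Xb, yb)
        fallbacks += int(fb)
        auc_boot = auc(expit(Xb @ beta), yb)
        auc_orig = auc(expit(X @ beta), y)
        optimism.append(auc_boot - auc_orig)
        auc_boot_dist.append(auc_boot)
    if not optimism:
        raise ValidationFailure(
            f"all {B} replicates degenerate for {spec.name}/{definition.name}"
        )
    mean_opt = float(np.mean(optimism))
    corrected = apparent - mean_opt
    ci_low, ci_high = _percentile_ci(np.asarray(auc_boot_dist), corrected, ci_method)
    return ValidationResult(
        spec.name, definition.name, spec.seq_variant, apparent, mean_opt,
        corrected, ci_low, ci_high, len(optimism), degenerate, seed,
        fallback_fits=fallbacks,
    )


def likert_baseline(
    cohort: Cohort | pd.DataFrame,
    definition: CsPCaDefinition,
    B: int = 1000,
    seed: int = 0,
    ci_method: str = "percentile",
) -> ValidationResult:
    """AUC of the reader's Likert score used directly as the ranking.

    No model is fit, so the optimism is zero by construction; the
    interval comes from the patient-clustered bootstrap of the AUC
    itself.
    """
    frame = analysis_frame(cohort)
    y = _labels(frame, definition)
    scores = _score_column(frame, "likert")
    apparent = auc(scores, y)
    if B == 0:
        return ValidationResult(
            LIKERT, definition.name, "a", apparent, 0.0, apparent,
            math.nan, math.nan, 0, 0, seed,
        )
    rng = np.random.default_rng(seed)
    groups = _patient_groups(frame)
    n_pat = len(groups)
    dist: list[float] = []
    degenerate = 0
    for _ in range(B):
        draws = rng.integers(0, n_pat, size=n_pat)
        rows = np.concatenate([groups[d] for d in draws])
        yb = y[rows]
        if yb.min() == yb.max():
            degenerate += 1
            continue
        dist.append(auc(scores[rows], yb))
    if not dist:
        raise ValidationFailure("all replicates degenerate for the Likert baseline")
    ci_low, ci_high = _percentile_ci(np.asarray(dist), apparent, ci_method)
    return ValidationResult(
        LIKERT, definition.name, "a", apparent, 0.0, apparent,
        ci_low, ci_high, len(dist), degenerate, seed,
    )


def compare(
    cohort: Cohort | pd.DataFrame,
    spec_a: ModelSpec,
    spec_b: ModelSpec | str,
    definition: CsPCaDefinition,
    B: int = 1000,
    seed: int = 0,
    min_level_count: int = 3,
    ci_method: str = "percentile",
) -> ComparisonResult:
    """Paired bootstrap comparison of two models on the same lesions.

    Both models are refit on every replicate of one shared patient-level
    resampling stream; the paired difference of their replicate-fit AUCs
    on the original cohort drives the interval and the two-sided
    p-value (recentred-null convention, ties at zero counted on both
    sides).  ``spec_b`` may be the string ``"Likert"`` to compare against
    the reader's Likert score (no fit, zero optimism).
    """
    frame = analysis_frame(cohort)
    y = _labels(frame, definition)

    likert_b = isinstance(spec_b, str)
    if likert_b and spec_b != LIKERT:
        raise ValueError(f"unknown baseline {spec_b!r}")

    design_a = encode_design(frame, spec_a, min_level_count=min_level_count)
    apparent_a = auc(
        fit_logistic(design_a, y, spec_a).fitted_probabilities, y
    )
    if likert_b:
        scores_b_full = _score_column(frame, "likert")
        apparent_b = auc(scores_b_full, y)
        name_b = LIKERT
    else:
        design_b = encode_design(frame, spec_b, min_level_count=min_level_count)
        apparent_b = auc(
            fit_logistic(design_b, y, spec_b).fitted_probabilities, y
        )
        name_b = spec_b.name

    rng = np.random.default_rng(seed)
    groups = _patient_groups(frame)
    n_pat = len(groups)
    opt_a: list[float] = []
    opt_b: list[float] = []
    delta_dist: list[float] = []
    degenerate = 0
    for _ in range(B):
        draws = rng.integers(0, n_pat, size=n_pat)
        rows = np.concatenate([groups[d] for d in draws])
        yb = y[rows]
        if yb.min() == yb.max():
            degenerate += 1
            continue
        beta_a, _, _ = _fit_beta(design_a.matrix[rows], yb)
        auc_boot_a = auc(expit(design_a.matrix[rows] @ beta_a), yb)
        auc_orig_a = auc(expit(design_a.matrix @ beta_a), y)
        opt_a.append(auc_boot_a - auc_orig_a)
        if likert_b:
            auc_orig_b = apparent_b
            opt_b.append(0.0)
        else:
            beta_b, _, _ = _fit_beta(design_b.matrix[rows], yb)
            auc_boot_b = auc(expit(design_b.matrix[rows] @ beta_b), yb)
            auc_orig_b = auc(expit(design_b.matrix @ beta_b), y)
            opt_b.append(auc_boot_b - auc_orig_b)
        delta_dist.append(auc_orig_a - auc_orig_b)
    if B > 0 and not delta_dist:
        raise ValidationFailure("all replicates degenerate in comparison")

    corrected_a = apparent_a - (float(np.mean(opt_a)) if opt_a else 0.0)
    corrected_b = apparent_b - (float(np.mean(opt_b)) if opt_b else 0.0)
    point = corrected_a - corrected_b
    if not delta_dist:
        return ComparisonResult(
            spec_a.name, name_b, definition.name, point, math.nan,
            math.nan, math.nan, corrected_a, corrected_b, 0, degenerate, seed,
        )
    d = np.asarray(delta_dist)
    recentred = d - float(d.mean()) + point
    p = min(1.0, 2.0 * min(float((recentred <= 0).mean()),
                           float((recentred >= 0).mean())))
    ci_low, ci_high = np.percentile(recentred, [2.5, 97.5])
    return ComparisonResult(
        spec_a.name, name_b, definition.name, point, p,
        float(ci_low), float(ci_high), corrected_a, corrected_b,
        len(delta_dist), degenerate, seed,
    )
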