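"""The logistic model battery.

The battery is a fixed grid of logistic regressions scored against one
binary outcome (one cancer-significance definition at a time):

* nine univariable models (the three per-sequence scores, the derived
  S_Max and S_Min counts, grouped shape, ECE score, V_Max, PSA density),
  evaluated with all three pulse sequences;
* S_Max alone and three signal-combination models — Signal1 = S_Max +
  S_Min, Signal2 = S_Max* + S_Min* + S_DW (the starred counts exclude
  the diffusion sequence, which is coded separately), Signal3 = the raw
  per-sequence scores;
* Signal1 augmented with every non-empty subset of {Shape, ECE, V_Max,
  dPSA} (15 models).

Every model exists in an "a" variant (T2W + DW + DCE) and a "b" variant
(no dynamic contrast-enhanced imaging); the univariable block is only
defined for variant "a".

Ordinal predictors enter as unordered indicator contrasts against the
lowest observed level (a linear-score coding is available as a switch);
continuous predictors enter untransformed.  Sparse categorical levels
are collapsed toward the reference, and fits that fail or separate fall
back to a lightly ridge-penalized fit, flagged on the result.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .data_model import CsPCaDefinition
from .features import SHAPE_GROUPED_LEVELS

logger = logging.getLogger("pzlesion.battery")

#: ridge strength used by the fallback fit, on standardized columns
RIDGE_ALPHA = 1e-4

#: categorical levels observed fewer times than this are merged toward
#: the reference level before fitting
MIN_LEVEL_COUNT = 3


class DegenerateOutcomeError(ValueError):
    """The outcome has a single class, so nothing can be fit or ranked."""


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A named recipe from the battery: predictors plus sequence-set variant."""

    name: str
    predictors: tuple[str, ...]
    seq_variant: str  # "a" (with DCE) or "b" (without)
    encoding: tuple[tuple[str, str], ...]  # (column, "categorical"|"continuous")
    block: str = "signal1_family"  # univariable | signal | signal1_family

    def encoding_of(self, column: str) -> str:
        return dict(self.encoding)[column]


_COVARIATES = (
    ("Shape", "shape_grouped", "categorical"),
    ("ECE", "ece_score", "categorical"),
    ("Vmax", "v_max", "continuous"),
    ("dPSA", "dpsa", "continuous"),
)


def _spec(name, cols, variant, block):
    encoding = []
    for col in cols:
        kind = "continuous" if col in ("v_max", "dpsa") else "categorical"
        encoding.append((col, kind))
    return ModelSpec(name, tuple(cols), variant, tuple(encoding), block)


def signal_specs(seq_variant: str) -> list[ModelSpec]:
    """S_Max alone plus the Signal1/2/3 combinations for one variant."""
    v = seq_variant
    if v not in ("a", "b"):
        raise ValueError(f"seq_variant must be 'a' or 'b', got {v!r}")
    signal3 = ["s_t2", "s_dw"] + (["s_dce"] if v == "a" else [])
    return [
        _spec("S_Max", [f"s_max_{v}"], v, "signal"),
        _spec("Signal1", [f"s_max_{v}", f"s_min_{v}"], v, "signal"),
        _spec("Signal2", [f"s_max_2{v}", f"s_min_2{v}", "s_dw"], v, "signal"),
        _spec("Signal3", signal3, v, "signal"),
    ]


def signal1_family(seq_variant: str) -> list[ModelSpec]:
    """Signal1 and its 15 covariate augmentations (16 models)."""
    v = seq_variant
    base = [f"s_max_{v}", f"s_min_{v}"]
    out = [_spec("Signal1", base, v, "signal")]
    for k in (1, 2, 3, 4):
        for combo in itertools.combinations(_COVARIATES, k):
            name = "Signal1+" + "+".join(c[0] for c in combo)
            cols = base + [c[1] for c in combo]
            out.append(_spec(name, cols, v, "signal1_family"))
    return out


def univariable_specs() -> list[ModelSpec]:
    """The nine single-predictor models (three-sequence variant only)."""
    singles = [
        ("S_T2", "s_t2"),
        ("S_DW", "s_dw"),
        ("S_DCE", "s_dce"),
        ("S_Max", "s_max_a"),
        ("S_Min", "s_min_a"),
        ("Shape", "shape_grouped"),
        ("ECE", "ece_score"),
        ("V_Max", "v_max"),
        ("dPSA", "dpsa"),
    ]
    return [_spec(name, [col], "a", "univariable") for name, col in singles]


def build_battery(
    definition: CsPCaDefinition | str | None = None, seq_variant: str = "a"
) -> list[ModelSpec]:
    """The full model grid for one sequence-set variant, in fixed order.

    The outcome definition does not change the battery's structure; it is
    accepted so call sites can carry it alongside.  Variant "a" yields
    9 univariable + 4 signal + 15 augmented specs; variant "b" omits the
    univariable block (defined on the full sequence set only).
    """
    specs: list[ModelSpec] = []
    if seq_variant == "a":
        specs.extend(univariable_specs())
    specs.extend(signal_specs(seq_variant))
    specs.extend(s for s in signal1_family(seq_variant) if s.name != "Signal1")
    return specs


def battery_manifest(specs: Sequence[ModelSpec]) -> list[dict]:
    """JSON-serializable description of a battery (join key for results)."""
    return [
        {
            "name": s.name,
            "block": s.block,
            "seq_variant": s.seq_variant,
            "predictors": list(s.predictors),
            "encoding": dict(s.encoding),
        }
        for s in specs
    ]


@dataclasses.dataclass
class Design:
    """An encoded design matrix (intercept first) with its provenance."""

    matrix: np.ndarray
    columns: list[str]
    collapsed: dict[str, list] = dataclasses.field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _ordered_levels(column: str, values: pd.Series) -> list:
    observed = set(values.unique().tolist())
    if column == "shape_grouped":
        return [lv for lv in SHAPE_GROUPED_LEVELS if lv in observed]
    return sorted(observed)


def _collapse_sparse(
    column: str, codes: np.ndarray, levels: list, min_count: int
) -> tuple[np.ndarray, list, list]:
    """Merge levels with < min_count observations toward the reference."""
    collapsed: list = []
    while len(levels) > 1:
        counts = np.bincount(codes, minlength=len(levels))
        sparse = [i for i, c in enumerate(counts) if c < min_count]
        if not sparse:
            break
        i = sparse[-1]  # merge the highest sparse level first
        target = i - 1 if i > 0 else 1
        collapsed.append(levels[i])
        logger.warning(
            "collapsing sparse level %r of %s (n=%d) into %r",
            levels[i], column, counts[i], levels[target],
        )
        codes = np.where(codes == i, target, codes)
        codes = np.where(codes > i, codes - 1, codes)
        levels = levels[:i] + levels[i + 1 :]
    return codes, levels, collapsed


def encode_design(
    frame: pd.DataFrame,
    spec: ModelSpec,
    min_level_count: int = MIN_LEVEL_COUNT,
    ordinal_as_linear: bool = False,
) -> Design:
    """Expand a model's predictors into an intercept-first design matrix.

    Categorical predictors become indicator contrasts against the lowest
    observed level; levels rarer than ``min_level_count`` are merged
    toward the reference (logged).  With ``ordinal_as_linear`` the
    integer-coded predictors enter as single linear columns instead.
    """
    n = len(frame)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["const"]
    collapsed_info: dict[str, list] = {}
    for column in spec.predictors:
        if column not in frame.columns:
            raise KeyError(f"feature column {column!r} missing from frame")
        values = frame[column]
        if spec.encoding_of(column) == "continuous":
            cols.append(values.to_numpy(dtype=float))
            names.append(column)
            continue
        if ordinal_as_linear and column != "shape_grouped":
            cols.append(values.to_numpy(dtype=float))
            names.append(f"{column}_linear")
            continue
        levels = _ordered_levels(column, values)
        index = {lv: i for i, lv in enumerate(levels)}
        codes = values.map(index).to_numpy(dtype=int)
        codes, levels, collapsed = _collapse_sparse(
            column, codes, levels, min_level_count
        )
        if collapsed:
            collapsed_info[column] = collapsed
        for i, lv in enumerate(levels[1:], start=1):
            cols.append((codes == i).astype(float))
            names.append(f"{column}[{lv}]")
    return Design(np.column_stack(cols), names, collapsed_info)


@dataclasses.dataclass
class FittedModel:
    """A fitted battery member: coefficients and in-sample probabilities."""

    spec: ModelSpec | None
    columns: list[str]
    beta: np.ndarray
    fitted_probabilities: np.ndarray
    converged: bool
    fallback: bool

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.columns, self.beta.tolist()))

    def predict(self, design: Design) -> np.ndarray:
        if design.columns != self.columns:
            raise ValueError("design columns do not match the fitted model")
        return expit(design.matrix @ self.beta)


def _ridge_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """L2-penalized fit on standardized columns, mapped back to raw scale."""
    Z = X[:, 1:]
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Zs = (Z - mean) / sd
    clf = LogisticRegression(C=1.0 / RIDGE_ALPHA, solver="lbfgs", max_iter=2000)
    clf.fit(Zs, y)
    beta = np.empty(X.shape[1])
    beta[1:] = clf.coef_[0] / sd
    beta[0] = clf.intercept_[0] - float((clf.coef_[0] * mean / sd).sum())
    return beta


def _fit_beta(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool, bool]:
    """Maximum-likelihood logistic fit with a ridge fallback.

    Returns (beta over all columns of X, converged, fallback).  Columns
    constant within this sample (e.g. a categorical level absent from a
    bootstrap replicate) get coefficient 0, equivalent to merging the
    unseen level into the reference when scoring other data.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome has a single class")
    keep = np.ones(X.shape[1], dtype=bool)
    spans = X.max(axis=0) - X.min(axis=0)
    keep[1:] = spans[1:] > 0
    Xk = X[:, keep]
    beta_k = None
    converged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xk).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        params = np.asarray(res.params, dtype=float)
        if converged and np.all(np.isfinite(params)) and np.abs(params).max() < 30:
            beta_k = params
    except Exception:  # separation, singular matrix, failed line search
        beta_k = None
    fallback = beta_k is None
    if fallback:
        logger.debug("MLE fit failed or separated; using ridge fallback")
        beta_k = _ridge_fit(Xk, y)
    beta = np.zeros(X.shape[1])
    beta[keep] = beta_k
    return beta, converged, fallback


def fit_logistic(
    design: Design, labels: np.ndarray, spec: ModelSpec | None = None
) -> FittedModel:
    """Fit one battery member by maximum likelihood.

    On detected separation or non-convergence the model is refit with a
    small ridge penalty and the ``fallback`` flag is set, so coefficients
    stay finite and every lesion still receives a probability.
    """
    beta, converged, fallback = _fit_beta(design.matrix, np.asarray(labels))
    probs = expit(design.matrix @ beta)
    return FittedModel(spec, list(design.columns), beta, probs, converged, fallback)
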