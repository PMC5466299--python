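"""Synthetic lesion cohorts with the clustering and ordinal structure of
a prospective prostate-MRI / prostatectomy database.

The generator emulates the data structure the analysis assumes, not any
particular patient: lesions clustered within patients (zero-truncated
Poisson counts), a class-conditional cumulative-logit model for each
ordinal signal score (the diffusion-weighted effect largest), lognormal
per-sequence volumes masked by visibility, patient-level lognormal PSA
density, a logistic lesion-level extraprostatic-extension (EPE) model
driven by grade group and lesion size, and a Likert score built from the
same generated features plus independent reader noise.

Defaults are calibrated so that the marginal prevalences land near the
values a prostatectomy cohort would show: clinically significant cancer
(grade group >= 2) around 43-49% of lesions, grade group >= 3 around
22-26%, and histological EPE around 21-26%.

The *null* variant keeps the outcome model (class frequencies and EPE)
but severs every feature-outcome link, so any apparent discrimination a
model shows on a null cohort is pure overfitting — the calibration
fixture for the optimism correction.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq
from scipy.special import expit

from .data_model import Cohort, LesionRecord

_SHAPES = (
    "ill_defined",
    "linear_perpendicular",
    "linear_parallel",
    "triangular",
    "nodular_no_mass_effect",
    "nodular_mass_effect",
)


class ConfigurationError(ValueError):
    """Invalid generator parameters."""


@dataclasses.dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic cohort generator.

    ``class_probs`` is the marginal distribution over pathology classes
    (benign, grade group 1..5).  Ordinal scores follow a cumulative-logit
    model: the latent is ``beta * grade_group`` plus standard-logistic
    noise, cut at ``score_cuts``.  Volumes are lognormal with a
    grade-group trend in the log-mean and an extra per-sequence jitter.
    The Likert latent is a weighted sum of the generated features
    (marked-sequence count, invisibility flag, log lesion volume, ECE
    score, log PSA density) plus Gaussian noise.
    """

    n_patients: int = 250
    lesions_per_patient_mean: float = 1.8
    class_probs: tuple[float, ...] = (0.400, 0.168, 0.214, 0.100, 0.070, 0.048)
    # lesion-level EPE: logit = intercept + gg_slope*gg + vol_slope*log-volume
    epe_intercept: float = -2.8
    epe_gg_slope: float = 1.0
    epe_vol_slope: float = 0.5
    # per-sequence latent class effects; DW carries the most information
    score_betas: tuple[float, float, float] = (0.7, 1.1, 0.8)  # t2, dw, dce
    score_cuts: tuple[float, float, float] = (-1.0, 0.3, 2.2)
    vol_mu0: float = math.log(0.4)
    vol_gg_slope: float = 0.25
    vol_sigma: float = 0.6
    vol_seq_sigma: float = 0.25
    dpsa_mu: float = math.log(0.16)
    dpsa_sigma: float = 0.5
    ece_epe_beta: float = 2.0
    ece_gg_beta: float = 0.4
    ece_cuts: tuple[float, float, float, float] = (0.0, 1.2, 2.2, 3.2)
    shape_probs_benign: tuple[float, ...] = (0.35, 0.15, 0.15, 0.15, 0.15, 0.05)
    shape_probs_cancer: tuple[float, ...] = (0.15, 0.08, 0.07, 0.10, 0.35, 0.25)
    # weights on (s_max over 3 sequences, s_min flag, log v_max,
    # ece - 3, log(dpsa) - dpsa_mu)
    likert_weights: tuple[float, ...] = (1.0, -0.7, 0.5, 0.3, 0.8)
    likert_noise_sd: float = 1.0
    likert_cuts: tuple[float, float, float] = (0.5, 1.8, 3.0)
    reader_id: str = "R1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("class_probs", "shape_probs_benign", "shape_probs_cancer"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-12:
                raise ConfigurationError(f"{name} must sum to 1 (got {p.sum()!r})")
        if len(self.class_probs) != 6:
            raise ConfigurationError("class_probs needs 6 entries (benign, GG1-5)")
        for name in ("vol_sigma", "vol_seq_sigma", "dpsa_sigma", "likert_noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.lesions_per_patient_mean <= 1.0:
            raise ConfigurationError(
                "zero-truncated Poisson mean must exceed 1"
            )
        for cuts in (self.score_cuts, self.ece_cuts, self.likert_cuts):
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ConfigurationError("cutpoints must be strictly increasing")

    def nullified(self) -> "GeneratorParams":
        """Copy with every feature-outcome link removed.

        Class frequencies and the EPE rate are preserved (the EPE model
        keeps its grade-group slope — EPE is part of the outcome), but
        scores, volumes, shape, ECE and hence Likert become independent
        of the pathology class.
        """
        return dataclasses.replace(
            self,
            score_betas=(0.0, 0.0, 0.0),
            vol_gg_slope=0.0,
            epe_vol_slope=0.0,
            ece_epe_beta=0.0,
            ece_gg_beta=0.0,
            shape_probs_cancer=self.shape_probs_benign,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ConfigurationError(f"unknown generator parameter {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def _ztp_rate(mean: float) -> float:
    """Poisson rate whose zero-truncated mean equals ``mean``."""
    return brentq(lambda lam: lam / (1.0 - math.exp(-lam)) - mean, 1e-9, 50.0)


def _draw_ztp(rng: np.random.Generator, lam: float) -> int:
    k = rng.poisson(lam)
    while k == 0:
        k = rng.poisson(lam)
    return int(k)


def _draw_ordinal(rng: np.random.Generator, shift: float, cuts) -> int:
    u = shift + rng.logistic()
    return int(sum(u > c for c in cuts))


def _shape_probs(params: GeneratorParams, gg: int) -> np.ndarray:
    benign = np.asarray(params.shape_probs_benign)
    cancer = np.asarray(params.shape_probs_cancer)
    if gg == 0:
        return benign
    if gg == 1:
        return 0.5 * (benign + cancer)
    return cancer


def _draw_lesion(
    rng: np.random.Generator,
    params: GeneratorParams,
    patient_id: str,
    dpsa: float,
) -> LesionRecord:
    gg = int(rng.choice(6, p=params.class_probs))
    log_vol = params.vol_mu0 + params.vol_gg_slope * gg + rng.normal(0, params.vol_sigma)

    scores = {}
    for _ in range(100):
        scores = {
            seq: _draw_ordinal(rng, beta * gg, params.score_cuts)
            for seq, beta in zip(("t2", "dw", "dce"), params.score_betas)
        }
        if any(scores.values()):
            break
    else:
        scores["dw"] = 1  # a recorded lesion was seen somewhere

    vols = {
        seq: (
            math.exp(log_vol + rng.normal(0, params.vol_seq_sigma))
            if scores[seq] > 0
            else None
        )
        for seq in ("t2", "dw", "dce")
    }

    epe = False
    if gg >= 1:
        logit = (
            params.epe_intercept
            + params.epe_gg_slope * gg
            + params.epe_vol_slope * log_vol
        )
        epe = bool(rng.random() < expit(logit))

    ece = 1 + _draw_ordinal(
        rng,
        params.ece_epe_beta * epe + params.ece_gg_beta * gg,
        params.ece_cuts,
    )
    shape = str(rng.choice(_SHAPES, p=_shape_probs(params, gg)))

    s_max3 = sum(s == 3 for s in scores.values())
    s_min_any = int(any(s == 0 for s in scores.values()))
    v_max = max(v for v in vols.values() if v is not None)
    w = params.likert_weights
    latent = (
        w[0] * s_max3
        + w[1] * s_min_any
        + w[2] * math.log(v_max)
        + w[3] * (ece - 3)
        + w[4] * (math.log(dpsa) - params.dpsa_mu)
        + rng.normal(0, params.likert_noise_sd)
    )
    likert = 2 + sum(latent > c for c in params.likert_cuts)

    return LesionRecord(
        patient_id=patient_id,
        reader_id=params.reader_id,
        s_t2=scores["t2"],
        s_dw=scores["dw"],
        s_dce=scores["dce"],
        vol_t2=vols["t2"],
        vol_dw=vols["dw"],
        vol_dce=vols["dce"],
        shape=shape,
        ece_score=ece,
        likert=likert,
        dpsa=dpsa,
        gleason_group=gg,
        epe=epe,
    )


def generate_cohort(params: GeneratorParams) -> Cohort:
    """Draw a synthetic cohort; identical params (incl. seed) give an
    identical cohort."""
    rng = np.random.default_rng(params.seed)
    lam = _ztp_rate(params.lesions_per_patient_mean)
    records: list[LesionRecord] = []
    for i in range(params.n_patients):
        pid = f"P{i:05d}"
        dpsa = math.exp(rng.normal(params.dpsa_mu, params.dpsa_sigma))
        for _ in range(_draw_ztp(rng, lam)):
            records.append(_draw_lesion(rng, params, pid, dpsa))
    return Cohort(tuple(records), provenance=f"synthetic seed={params.seed}")


def null_cohort(params: GeneratorParams) -> Cohort:
    """A cohort whose features carry no information about the outcome."""
    cohort = generate_cohort(params.nullified())
    return Cohort(cohort.records, provenance=f"synthetic-null seed={params.seed}")


def analytic_prevalence(params: GeneratorParams, definition_name: str) -> float:
    """Marginal outcome probability implied by the generator parameters.

    Definitions A and B are sums of class probabilities; C integrates the
    EPE logistic over the lognormal volume latent (Gauss-Hermite).
    """
    p = np.asarray(params.class_probs)
    if definition_name == "A":
        return float(p[2:].sum())
    if definition_name == "B":
        return float(p[3:].sum())
    if definition_name == "C":
        nodes, weights = hermegauss(40)
        total = 0.0
        for gg in range(2, 6):
            mu = params.vol_mu0 + params.vol_gg_slope * gg
            lv = mu + params.vol_sigma * nodes
            probs = expit(
                params.epe_intercept
                + params.epe_gg_slope * gg
                + params.epe_vol_slope * lv
            )
            total += p[gg] * float((weights * probs).sum() / weights.sum())
        return total
    raise ValueError(f"unknown definition {definition_name!r}")
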