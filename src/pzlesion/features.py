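"""Derived signal features and categorical recodings.

Two count features summarize the per-sequence signal scores over a
chosen sequence set: ``s_max`` counts sequences with a *marked* (3/3)
abnormality, and ``s_min`` flags whether the lesion is invisible (0/3)
on at least one sequence (dichotomized 0 vs >=1, matching the levels
the feature takes in practice).  ``v_max`` is the largest per-sequence
lesion volume.  Shape is recoded to six levels by merging ill-defined
areas with linear lesions perpendicular to the capsule.

Sequence sets
-------------
Variant "a" models use all three pulse sequences; variant "b" models
drop dynamic contrast-enhanced (DCE) imaging.  The Signal2 models code
diffusion-weighted findings separately, so their S_Max/S_Min counts run
over {T2W, DCE} (2a) or {T2W} only (2b).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .data_model import Cohort, LesionRecord

SEQS_A = frozenset({"t2", "dw", "dce"})
SEQS_B = frozenset({"t2", "dw"})
SEQS_SIGNAL2A = frozenset({"t2", "dce"})
SEQS_SIGNAL2B = frozenset({"t2"})

#: canonical tag for each defined sequence set
SEQ_SET_TAGS = {
    SEQS_A: "a",
    SEQS_B: "b",
    SEQS_SIGNAL2A: "2a",
    SEQS_SIGNAL2B: "2b",
}

MERGED_SHAPE = "ill_defined_or_linear_perpendicular"

#: grouped shape levels, reference level first
SHAPE_GROUPED_LEVELS = (
    MERGED_SHAPE,
    "not_visible",
    "linear_parallel",
    "triangular",
    "nodular_no_mass_effect",
    "nodular_mass_effect",
)


class FeatureError(ValueError):
    """A derived feature cannot be computed for a record."""


def compute_smax(record: LesionRecord, seqs: frozenset[str]) -> int:
    """Number of sequences in ``seqs`` showing a marked (3/3) abnormality."""
    return sum(getattr(record, f"s_{seq}") == 3 for seq in seqs)


def compute_smin(record: LesionRecord, seqs: frozenset[str]) -> int:
    """1 if the lesion is invisible on at least one sequence in ``seqs``."""
    return int(any(getattr(record, f"s_{seq}") == 0 for seq in seqs))


def compute_vmax(record: LesionRecord) -> float:
    """Largest of the lesion's volumes over the sequences where it is visible."""
    vols = record.volumes()
    if not vols:
        raise FeatureError("no per-sequence volume present")
    return max(vols.values())


def recode_shape(record: LesionRecord) -> str:
    """Six-level grouped shape (ill-defined merged with linear-perpendicular)."""
    if record.shape in ("ill_defined", "linear_perpendicular"):
        return MERGED_SHAPE
    return record.shape


def feature_frame(cohort: Cohort) -> pd.DataFrame:
    """One row per lesion with every derived feature the model battery uses.

    Columns: pass-through scores and covariates, ``s_max_<tag>`` /
    ``s_min_<tag>`` for each defined sequence set, ``shape_grouped``,
    ``v_max``, plus ``patient_id`` and the pathology outcome needed for
    labelling.  Excluded records are dropped (analysis entry point).
    """
    rows = []
    for rec in cohort.analysis_view():
        row = {
            "patient_id": rec.patient_id,
            "reader_id": rec.reader_id,
            "s_t2": rec.s_t2,
            "s_dw": rec.s_dw,
            "s_dce": rec.s_dce,
            "shape_grouped": recode_shape(rec),
            "v_max": compute_vmax(rec),
            "ece_score": rec.ece_score,
            "dpsa": rec.dpsa,
            "likert": rec.likert,
            "gleason_group": rec.gleason_group,
            "epe": rec.epe,
        }
        for seqs, tag in SEQ_SET_TAGS.items():
            row[f"s_max_{tag}"] = compute_smax(rec, seqs)
            row[f"s_min_{tag}"] = compute_smin(rec, seqs)
        rows.append(row)
    return pd.DataFrame(rows)


def augment_features(
    cohort: Cohort, seqs: frozenset[str], path: str | Path | None = None
) -> pd.DataFrame:
    """Lesion table plus the derived features for one sequence set.

    Feature columns are suffixed with the sequence-set tag (e.g.
    ``s_max_a``).  If ``path`` is given the table is written as CSV.
    """
    tag = SEQ_SET_TAGS.get(seqs)
    if tag is None:
        raise FeatureError(f"undefined sequence set {sorted(seqs)!r}")
    df = cohort.to_frame()
    recs = list(cohort)
    df[f"s_max_{tag}"] = [compute_smax(r, seqs) for r in recs]
    df[f"s_min_{tag}"] = [compute_smin(r, seqs) for r in recs]
    df["shape_grouped"] = [recode_shape(r) for r in recs]
    df["v_max"] = [compute_vmax(r) for r in recs]
    if path is not None:
        out = df.copy()
        out["epe"] = out["epe"].astype(int)
        out["excluded"] = out["excluded"].astype(int)
        out.to_csv(path, index=False, float_format="%.17g")
    return df
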