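"""Domain types for lesion-level prostate multiparametric-MRI records.

The analysis unit is one reader's description of one peripheral-zone
lesion, matched to prostatectomy pathology.  Each record carries the
per-sequence ordinal signal scores and volumes, the subjective shape,
extracapsular-extension (ECE) and Likert scores, patient-level PSA
density, and the pathology outcome (ISUP grade group and lesion-level
histological extraprostatic extension).

Lesions are clustered within patients; the patient is the resampling
unit for all bootstrap inference downstream.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Callable, Iterator, Sequence
from pathlib import Path

import pandas as pd

SEQUENCES = ("t2", "dw", "dce")
READERS = ("R1", "R2")

#: Resolved lesion shape (the T2W shape, falling back to DW then DCE
#: when the lesion is invisible on the earlier sequence; the stored
#: value is already the resolved one).
SHAPE_LEVELS = (
    "not_visible",
    "ill_defined",
    "linear_perpendicular",
    "linear_parallel",
    "triangular",
    "nodular_no_mass_effect",
    "nodular_mass_effect",
)


class SchemaError(ValueError):
    """A lesion table is missing a mandatory column."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class UndefinedPrevalenceError(ValueError):
    """Prevalence requested on an empty set of evaluable lesions."""


@dataclasses.dataclass(frozen=True)
class LesionRecord:
    """One reader's description of one lesion plus its pathology outcome.

    Signal scores use the 4-level scale 0 = not visible, 1 = mild,
    2 = moderate, 3 = marked.  A per-sequence volume (mL) is present
    exactly when the lesion is visible on that sequence.  ``dpsa`` is
    the patient-level PSA density (ng/mL/mL), repeated on every lesion
    of the patient.  ``gleason_group`` is the ISUP grade group with 0
    meaning a benign finding; ``epe`` flags lesion-level histological
    extraprostatic extension.
    """

    patient_id: str
    reader_id: str
    s_t2: int
    s_dw: int
    s_dce: int
    vol_t2: float | None
    vol_dw: float | None
    vol_dce: float | None
    shape: str
    ece_score: int
    likert: int
    dpsa: float
    gleason_group: int
    epe: bool
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.reader_id not in READERS:
            raise ValidationError(f"unknown reader_id {self.reader_id!r}")
        for seq in SEQUENCES:
            s = getattr(self, f"s_{seq}")
            if s not in (0, 1, 2, 3):
                raise ValidationError(f"s_{seq}={s!r} outside the 0-3 scale")
            vol = getattr(self, f"vol_{seq}")
            if s == 0 and vol is not None:
                raise ValidationError(
                    f"vol_{seq} present although the lesion is not visible on {seq}"
                )
            if s > 0 and (vol is None or not math.isfinite(vol) or vol < 0):
                raise ValidationError(
                    f"vol_{seq}={vol!r} must be a non-negative volume when s_{seq} > 0"
                )
        if self.s_t2 == 0 and self.s_dw == 0 and self.s_dce == 0:
            raise ValidationError("lesion invisible on every sequence")
        if self.shape not in SHAPE_LEVELS:
            raise ValidationError(f"unknown shape {self.shape!r}")
        if self.ece_score not in (1, 2, 3, 4, 5):
            raise ValidationError(f"ece_score={self.ece_score!r} outside 1-5")
        if self.likert not in (2, 3, 4, 5):
            # a Likert of 1 is reserved for normal-appearing tissue, so a
            # recorded focal lesion always scores at least 2
            raise ValidationError(f"likert={self.likert!r} outside 2-5")
        if not (math.isfinite(self.dpsa) and self.dpsa > 0):
            raise ValidationError(f"dpsa={self.dpsa!r} must be > 0")
        if self.gleason_group not in (0, 1, 2, 3, 4, 5):
            raise ValidationError(
                f"gleason_group={self.gleason_group!r} outside 0-5"
            )
        if self.epe and self.gleason_group < 1:
            raise ValidationError("a benign finding cannot carry EPE")

    def volumes(self) -> dict[str, float]:
        """Per-sequence volumes for the sequences where the lesion is visible."""
        return {
            seq: getattr(self, f"vol_{seq}")
            for seq in SEQUENCES
            if getattr(self, f"vol_{seq}") is not None
        }


@dataclasses.dataclass(frozen=True)
class CsPCaDefinition:
    """A named rule deciding whether a lesion outcome is clinically significant.

    Definition A: grade group >= 2 (Gleason >= 7).
    Definition B: grade group >= 3 (Gleason >= 7 with primary pattern 4).
    Definition C: grade group >= 2 with histological extraprostatic extension.
    """

    name: str
    rule: Callable[[int, bool], bool]

    def __call__(self, gleason_group: int, epe: bool) -> bool:
        return bool(self.rule(gleason_group, epe))


DEFINITIONS: dict[str, CsPCaDefinition] = {
    "A": CsPCaDefinition("A", lambda gg, epe: gg >= 2),
    "B": CsPCaDefinition("B", lambda gg, epe: gg >= 3),
    "C": CsPCaDefinition("C", lambda gg, epe: gg >= 2 and epe),
}


def label_cspca(record: LesionRecord, definition: CsPCaDefinition) -> bool:
    """Whether ``record``'s pathology outcome meets ``definition``."""
    if record.excluded:
        raise ValidationError("excluded records are not labelled")
    return definition(record.gleason_group, record.epe)


@dataclasses.dataclass(frozen=True)
class Cohort:
    """An ordered collection of lesion records with patient clustering.

    Analyses never pool readers: use :meth:`reader_view` to obtain the
    single-reader stratum, and :meth:`analysis_view` to drop records
    flagged as excluded (exclusions are retained in storage so both the
    pre- and post-exclusion counts stay reportable).
    """

    records: tuple[LesionRecord, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LesionRecord]:
        return iter(self.records)

    @property
    def patients(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.patient_id, None)
        return tuple(seen)

    @property
    def readers(self) -> tuple[str, ...]:
        return tuple(sorted({rec.reader_id for rec in self.records}))

    def reader_view(self, reader_id: str) -> "Cohort":
        return Cohort(
            tuple(r for r in self.records if r.reader_id == reader_id),
            provenance=f"{self.provenance} reader={reader_id}".strip(),
        )

    def analysis_view(self) -> "Cohort":
        return Cohort(
            tuple(r for r in self.records if not r.excluded),
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(rec) for rec in self.records]
        df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
        return df


TABLE_COLUMNS = (
    "patient_id",
    "reader_id",
    "s_t2",
    "s_dw",
    "s_dce",
    "vol_t2",
    "vol_dw",
    "vol_dce",
    "shape",
    "ece_score",
    "likert",
    "dpsa",
    "gleason_group",
    "epe",
    "excluded",
)


def _record_from_row(row: pd.Series, index: int) -> LesionRecord:
    def _vol(name: str) -> float | None:
        v = row[name]
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return float(v)

    try:
        return LesionRecord(
            patient_id=str(row["patient_id"]),
            reader_id=str(row["reader_id"]),
            s_t2=int(row["s_t2"]),
            s_dw=int(row["s_dw"]),
            s_dce=int(row["s_dce"]),
            vol_t2=_vol("vol_t2"),
            vol_dw=_vol("vol_dw"),
            vol_dce=_vol("vol_dce"),
            shape=str(row["shape"]),
            ece_score=int(row["ece_score"]),
            likert=int(row["likert"]),
            dpsa=float(row["dpsa"]),
            gleason_group=int(row["gleason_group"]),
            epe=bool(int(row["epe"])),
            excluded=bool(int(row["excluded"])),
        )
    except ValidationError as exc:
        raise ValidationError(f"row {index}: {exc}") from exc


def read_lesion_table(path: str | Path, provenance: str | None = None) -> Cohort:
    """Read a lesion table CSV into a :class:`Cohort`.

    The header must contain every :data:`TABLE_COLUMNS` name; volumes may
    be empty when the lesion is not visible on that sequence.  Excluded
    records are retained and flagged.  Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "reader_id": str, "shape": str},
        float_precision="round_trip",
    )
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    records = tuple(
        _record_from_row(row, i) for i, (_, row) in enumerate(df.iterrows())
    )
    return Cohort(records, provenance=provenance or f"file:{path.name}")


def write_lesion_table(cohort: Cohort, path: str | Path) -> None:
    """Write the standard lesion-table CSV (volumes empty when absent)."""
    df = cohort.to_frame()
    df["epe"] = df["epe"].astype(int)
    df["excluded"] = df["excluded"].astype(int)
    df.to_csv(path, index=False, float_format="%.17g")


def write_labeled_table(cohort: Cohort, path: str | Path) -> None:
    """Write the lesion table augmented with cspca_a/b/c 0-1 label columns."""
    df = cohort.to_frame()
    df["epe"] = df["epe"].astype(int)
    df["excluded"] = df["excluded"].astype(int)
    for name, definition in DEFINITIONS.items():
        df[f"cspca_{name.lower()}"] = [
            int(definition(r.gleason_group, r.epe)) if not r.excluded else ""
            for r in cohort
        ]
    df.to_csv(path, index=False, float_format="%.17g")


@dataclasses.dataclass(frozen=True)
class Prevalence:
    """A prevalence as an explicit count ratio."""

    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator


def _evaluable(cohort: Cohort, reader: str | None) -> Sequence[LesionRecord]:
    recs = [r for r in cohort if not r.excluded]
    if reader is not None:
        recs = [r for r in recs if r.reader_id == reader]
    return recs


def prevalence(
    cohort: Cohort, reader: str | None, definition: CsPCaDefinition
) -> Prevalence:
    """Fraction of a reader's evaluable lesions that meet ``definition``."""
    recs = _evaluable(cohort, reader)
    if not recs:
        raise UndefinedPrevalenceError(
            f"no evaluable lesions for reader {reader!r}"
        )
    num = sum(label_cspca(r, definition) for r in recs)
    return Prevalence(num, len(recs))


def epe_fraction(cohort: Cohort, reader: str | None) -> Prevalence:
    """Fraction of a reader's evaluable lesions with histological EPE."""
    recs = _evaluable(cohort, reader)
    if not recs:
        raise UndefinedPrevalenceError(
            f"no evaluable lesions for reader {reader!r}"
        )
    return Prevalence(sum(r.epe for r in recs), len(recs))
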