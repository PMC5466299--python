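"""Study orchestration: run the full battery across readers, outcome
definitions and sequence-set variants, and summarize the results.

A run is fully determined by its :class:`RunConfig` (including the
seed): it loads or generates a cohort, validates every battery member
per (reader, definition, variant) cell, compares the best model of each
cell against Signal1 and against the Likert baseline, and emits tidy
CSV/JSON outputs plus median-and-IQR AUC-difference summaries:

* each multivariable model vs Signal1 (variant "a" and variant "b"),
* each multivariable model with vs without DCE imaging.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .battery import ModelSpec, battery_manifest, build_battery, signal1_family
from .data_model import DEFINITIONS, Cohort, read_lesion_table, write_lesion_table
from .synthetic import GeneratorParams, generate_cohort
from .validation import (
    LIKERT,
    ComparisonResult,
    ValidationResult,
    analysis_frame,
    compare,
    likert_baseline,
    validate,
)

logger = logging.getLogger("pzlesion.pipeline")

#: default pairing rule for the with/without-DCE summary: the Signal1
#: family (Signal1 plus its 15 covariate augmentations)
DEFAULT_PAIRING = tuple(s.name for s in signal1_family("a"))


class PairingError(ValueError):
    """A delta summary was asked to pair a model that has no counterpart."""


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a study run."""

    out_dir: str
    cohort_csv: str | None = None
    generator: GeneratorParams | None = None
    readers: tuple[str, ...] | None = None  # None = every reader present
    definitions: tuple[str, ...] = ("A", "B", "C")
    seq_variants: tuple[str, ...] = ("a", "b")
    n_boot: int = 1000
    seed: int = 0
    min_level_count: int = 3
    ci_method: str = "percentile"
    pairing: tuple[str, ...] = DEFAULT_PAIRING
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.cohort_csv is None) == (self.generator is None):
            raise ValueError("exactly one of cohort_csv or generator is required")
        unknown = set(self.definitions) - set(DEFINITIONS)
        if unknown:
            raise ValueError(f"unknown definitions {sorted(unknown)}")
        if set(self.seq_variants) - {"a", "b"}:
            raise ValueError("seq_variants must be a subset of {'a','b'}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        for key in ("readers", "definitions", "seq_variants", "pairing"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if d.get("generator") is not None:
            d["generator"] = GeneratorParams.from_dict(d["generator"])
        for key in ("readers", "definitions", "seq_variants", "pairing"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclasses.dataclass(frozen=True)
class DeltaSummary:
    """Median and interquartile range of paired AUC differences."""

    median: float
    iqr_low: float
    iqr_high: float
    n_pairs: int


def summarize_delta(pairs: Mapping[str, tuple[float, float]]) -> DeltaSummary:
    """Median [IQR] of per-model AUC differences ``first - second``.

    ``pairs`` maps a model name to its two paired AUCs; a missing or
    non-finite member raises :class:`PairingError` naming the model.
    """
    deltas = []
    for name, (a, b) in pairs.items():
        if a is None or b is None or not (np.isfinite(a) and np.isfinite(b)):
            raise PairingError(f"model {name!r} lacks a paired AUC")
        deltas.append(a - b)
    if not deltas:
        raise PairingError("no pairs to summarize")
    arr = np.asarray(deltas)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return DeltaSummary(float(med), float(q1), float(q3), len(deltas))


def cell_seed(base_seed: int, *parts: str) -> int:
    """Stable per-cell bootstrap seed below 2**31."""
    tag = "|".join(parts).encode()
    return (int(base_seed) * 1_000_003 + zlib.crc32(tag)) % (2**31)


def _result_row(reader: str, variant: str, block: str, r: ValidationResult) -> dict:
    return {
        "reader": reader,
        "definition": r.definition,
        "seq_variant": variant,
        "block": block,
        "model": r.model_name,
        "apparent_auc": r.apparent_auc,
        "mean_optimism": r.mean_optimism,
        "corrected_auc": r.corrected_auc,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "n_boot_used": r.n_boot_used,
        "n_boot_degenerate": r.n_boot_degenerate,
        "fallback_fits": r.fallback_fits,
        "seed": r.seed,
    }


def _comparison_row(reader: str, label: str, c: ComparisonResult) -> dict:
    return {
        "reader": reader,
        "definition": c.definition,
        "comparison": label,
        "model_a": c.model_a,
        "model_b": c.model_b,
        "delta_auc": c.delta_auc,
        "ci_low": c.ci_low,
        "ci_high": c.ci_high,
        "p_value": c.p_value,
        "corrected_a": c.corrected_a,
        "corrected_b": c.corrected_b,
        "n_boot_used": c.n_boot_used,
        "seed": c.seed,
    }


def _load_cohort(config: RunConfig, out: Path) -> Cohort:
    if config.cohort_csv is not None:
        return read_lesion_table(config.cohort_csv)
    cohort = generate_cohort(config.generator)
    write_lesion_table(cohort, out / "cohort.csv")
    return cohort


def _corrected_lookup(
    rows: Sequence[dict], reader: str, definition: str
) -> dict[tuple[str, str], float]:
    return {
        (r["model"], r["seq_variant"]): r["corrected_auc"]
        for r in rows
        if r["reader"] == reader and r["definition"] == definition
    }


def run_study(config: RunConfig) -> dict:
    """Execute the full study replica described by ``config``.

    Writes ``validation.csv``, ``comparisons.csv``,
    ``battery_manifest.json``, ``summary.json``, the echoed config and a
    run log into ``config.out_dir``; returns the result tables in
    memory.  Any stage failure aborts with the offending (reader,
    definition, model) cell named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    config.to_file(out / "config.yaml")

    cohort = _load_cohort(config, out)
    readers = config.readers or cohort.readers
    batteries = {v: build_battery(seq_variant=v) for v in config.seq_variants}
    manifest = [m for v in config.seq_variants for m in battery_manifest(batteries[v])]
    (out / "battery_manifest.json").write_text(json.dumps(manifest, indent=2))

    specs_by_key: dict[tuple[str, str], ModelSpec] = {
        (s.name, v): s for v in config.seq_variants for s in batteries[v]
    }

    val_rows: list[dict] = []
    cmp_rows: list[dict] = []
    summary: dict = {}
    for reader in readers:
        frame = analysis_frame(cohort.reader_view(reader))
        for def_name in config.definitions:
            definition = DEFINITIONS[def_name]
            seen: set[tuple[str, str]] = set()
            for variant in config.seq_variants:
                for spec in batteries[variant]:
                    try:
                        res = validate(
                            frame, spec, definition,
                            B=config.n_boot,
                            seed=cell_seed(config.seed, reader, def_name,
                                           variant, spec.name, spec.block),
                            min_level_count=config.min_level_count,
                            ci_method=config.ci_method,
                        )
                    except Exception as exc:
                        raise RuntimeError(
                            f"validation failed at ({reader}, {def_name}, "
                            f"{spec.name}, variant {variant}): {exc}"
                        ) from exc
                    val_rows.append(_result_row(reader, variant, spec.block, res))
                    seen.add((spec.name, variant))

            lik = likert_baseline(
                frame, definition, B=config.n_boot,
                seed=cell_seed(config.seed, reader, def_name, "likert"),
                ci_method=config.ci_method,
            )
            val_rows.append(_result_row(reader, "a", "baseline", lik))

            corrected = _corrected_lookup(val_rows, reader, def_name)
            multivariable = [
                (name, v) for (name, v) in corrected
                if name in config.pairing and (name, v) in seen
            ]
            best_name, best_variant = max(multivariable, key=corrected.get)
            best_spec = specs_by_key[(best_name, best_variant)]
            summary_cell: dict = {
                "best_model": best_name,
                "best_variant": best_variant,
                "best_corrected_auc": corrected[(best_name, best_variant)],
                "likert_auc": lik.corrected_auc,
            }

            for label, other in (
                ("best_vs_Signal1", specs_by_key.get(("Signal1", best_variant))),
                ("best_vs_Likert", LIKERT),
            ):
                if other is None:
                    continue
                cres = compare(
                    frame, best_spec, other, definition,
                    B=config.n_boot,
                    seed=cell_seed(config.seed, reader, def_name, label),
                    min_level_count=config.min_level_count,
                    ci_method=config.ci_method,
                )
                cmp_rows.append(_comparison_row(reader, label, cres))
                summary_cell[label] = {
                    "delta_auc": cres.delta_auc, "p_value": cres.p_value,
                }

            for variant in config.seq_variants:
                ref = corrected.get(("Signal1", variant))
                if ref is None:
                    continue
                pairs = {
                    name: (corrected[(name, variant)], ref)
                    for name in config.pairing
                    if name != "Signal1" and (name, variant) in corrected
                }
                if pairs:
                    ds = summarize_delta(pairs)
                    summary_cell[f"signal1{variant}_vs_multivariable"] = (
                        dataclasses.asdict(ds)
                    )
            if {"a", "b"} <= set(config.seq_variants):
                pairs = {}
                for name in config.pairing:
                    if (name, "a") in corrected and (name, "b") in corrected:
                        pairs[name] = (corrected[(name, "a")], corrected[(name, "b")])
                if pairs:
                    ds = summarize_delta(pairs)
                    summary_cell["with_vs_without_dce"] = dataclasses.asdict(ds)

            summary[f"{reader}/{def_name}"] = summary_cell
            logger.info("finished cell %s/%s", reader, def_name)

    validation_df = pd.DataFrame(val_rows)
    comparisons_df = pd.DataFrame(cmp_rows)
    validation_df.to_csv(out / "validation.csv", index=False)
    comparisons_df.to_csv(out / "comparisons.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return {
        "cohort": cohort,
        "validation": validation_df,
        "comparisons": comparisons_df,
        "summary": summary,
        "manifest": manifest,
    }
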