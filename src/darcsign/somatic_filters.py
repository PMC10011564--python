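"""Bespoke cfDNA somatic and germline small-variant filters.

The somatic caller operates on tumour (plasma cfDNA) / normal (leukocyte)
pileup evidence and a background error model built from a panel of
leukocyte samples: the error rate at a site, for a substituted base, is
the mean VAF of that base across all panel samples.  A candidate passes
only if every rule holds; failed rules are recorded per record so filter
attrition is auditable.

Boundary semantics (each tested): "discard if less than k×" means a pass
requires >= k× (non-strict); depth thresholds are strict (> 30×) in both
samples; the context-dominance test is strictly greater than 80 %.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .types import ValidationError, VariantRecord

#: rule identifiers in evaluation order
RULES = ("vaf", "alt_reads", "depth", "tn_ratio", "error_rate", "end_distance")


@dataclass
class ErrorModel:
    """Position/base-specific background error rates from a leukocyte panel."""

    rates: dict[tuple[str, int, str], float]
    panel_size: int

    def __post_init__(self) -> None:
        if self.panel_size < 1:
            raise ValidationError("panel size must be >= 1")
        for key, r in self.rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValidationError(f"error rate {r} outside [0,1] at {key}")

    def rate(self, chrom: str, pos: int, base: str) -> float:
        """Mean panel VAF of ``base`` at the site; 0 where unmodelled."""
        return self.rates.get((chrom, pos, base), 0.0)


@dataclass(frozen=True)
class FilterConfig:
    min_vaf: float = 0.02
    min_alt_reads: int = 10
    min_depth: int = 30
    tumour_vs_normal_ratio: float = 3.0
    error_multiplier: float = 20.0
    repeat_error_multiplier: float = 40.0
    context_dominance: float = 0.80
    context_window: int = 20
    min_end_distance: float = 6.0
    germline_vaf_low: float = 0.30
    germline_vaf_high: float = 0.70
    germline_min_depth: int = 40

    def __post_init__(self) -> None:
        if self.germline_vaf_low >= self.germline_vaf_high:
            raise ValidationError("germline_vaf_low must be < germline_vaf_high")
        for name in (
            "min_vaf", "min_alt_reads", "min_depth", "tumour_vs_normal_ratio",
            "error_multiplier", "repeat_error_multiplier", "context_dominance",
            "min_end_distance", "germline_min_depth",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class FilterVerdict:
    record: VariantRecord
    failed_rules: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failed_rules


def build_error_model(pileups: pd.DataFrame) -> ErrorModel:
    """Build the background error model from leukocyte pileup counts.

    ``pileups`` columns: sample, chrom, pos, base, alt_count, depth — one
    row per (sample, site, substituted base).  The modelled rate is the
    arithmetic mean of per-sample VAFs across all panel samples carrying
    the site; zero-depth rows are excluded from the mean.
    """
    required = {"sample", "chrom", "pos", "base", "alt_count", "depth"}
    missing = required - set(pileups.columns)
    if missing:
        raise ValidationError(f"pileup table missing columns {sorted(missing)}")
    panel_size = pileups["sample"].nunique()
    if panel_size < 1:
        raise ValidationError("need at least one leukocyte sample")
    usable = pileups[pileups["depth"] > 0].copy()
    n_dropped = len(pileups) - len(usable)
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "build_error_model: excluded %d zero-depth rows", n_dropped
        )
    usable["vaf"] = usable["alt_count"] / usable["depth"]
    grouped = usable.groupby(["chrom", "pos", "base"])["vaf"].mean()
    rates = {
        (str(chrom), int(pos), str(base)): float(v)
        for (chrom, pos, base), v in grouped.items()
    }
    return ErrorModel(rates=rates, panel_size=panel_size)


def context_dominant_base(context: str, threshold: float = 0.80,
                          exclude_index: int | None = None) -> bool:
    """True iff one nucleotide strictly exceeds ``threshold`` of the window.

    ``exclude_index`` drops the variant base itself from the count (the
    centre position of an SNV context); the comparison is strict, so a
    window at exactly the threshold is not dominant.
    """
    if not context:
        raise ValidationError("empty context")
    window = context
    if exclude_index is not None:
        window = context[:exclude_index] + context[exclude_index + 1 :]
        if not window:
            raise ValidationError("context contains only the excluded base")
    counts = Counter(window.upper())
    top = max(counts.values())
    return top / len(window) > threshold


def _substituted_bases(record: VariantRecord) -> list[str]:
    """Bases whose background rate bounds the tumour VAF (ALT for SNVs)."""
    if record.is_snv:
        return [record.alt]
    # indels: use the first differing base of the longer allele
    longer = record.alt if len(record.alt) > len(record.ref) else record.ref
    return [longer[min(len(record.ref), len(record.alt))]] if longer else []


def evaluate_record(record: VariantRecord, error_model: ErrorModel,
                    config: FilterConfig) -> FilterVerdict:
    """Apply every somatic rule to one record, recording all failures."""
    failed: list[str] = []
    vaf = record.tumour_vaf
    if not vaf > config.min_vaf:
        failed.append("vaf")
    if record.tumour_alt < config.min_alt_reads:
        failed.append("alt_reads")
    if not (record.tumour_depth > config.min_depth and record.normal_depth > config.min_depth):
        failed.append("depth")
    if vaf < config.tumour_vs_normal_ratio * record.normal_vaf:
        failed.append("tn_ratio")
    centre = len(record.context) // 2 if record.is_snv else None
    dominant = context_dominant_base(record.context, config.context_dominance, centre) \
        if record.context else False
    multiplier = (
        config.repeat_error_multiplier
        if (record.repeat_adjacent or dominant)
        else config.error_multiplier
    )
    rate = max(
        (error_model.rate(record.chrom, record.pos, b) for b in _substituted_bases(record)),
        default=0.0,
    )
    if vaf < multiplier * rate:
        failed.append("error_rate")
    if record.mean_end_distance < config.min_end_distance:
        failed.append("end_distance")
    return FilterVerdict(record=record, failed_rules=failed)


def call_somatic(records: list[VariantRecord], error_model: ErrorModel,
                 config: FilterConfig | None = None) -> list[FilterVerdict]:
    """Evaluate every candidate; returns verdicts, never exceptions."""
    config = config or FilterConfig()
    return [evaluate_record(r, error_model, config) for r in records]


def call_germline(records: list[VariantRecord],
                  config: FilterConfig | None = None) -> list[VariantRecord]:
    """Keep leukocyte variants with VAF in [0.30, 0.70] and depth >= 40."""
    config = config or FilterConfig()
    return [
        r
        for r in records
        if config.germline_vaf_low <= r.normal_vaf <= config.germline_vaf_high
        and r.normal_depth >= config.germline_min_depth
    ]


def verdicts_to_frame(verdicts: list[FilterVerdict]) -> pd.DataFrame:
    """Tabulate verdicts with one boolean column per rule (True = passed)."""
    rows = []
    for v in verdicts:
        row = {
            "chrom": v.record.chrom,
            "pos": v.record.pos,
            "ref": v.record.ref,
            "alt": v.record.alt,
            "pass": v.passed,
        }
        for rule in RULES:
            row[rule] = rule not in v.failed_rules
        rows.append(row)
    return pd.DataFrame(rows)
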