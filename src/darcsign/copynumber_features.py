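"""Copy-number feature extraction from allele-specific segment tables.

Six feature categories (45 features total under the default schema):

* ``BCper10Mb`` — histogram over 10 Mb windows of the number of 3'
  segment endpoints per window (a chromosome's terminal endpoint is not a
  break and is excluded); count bins {0,1,2,3,4,>=5}.
* ``BCperCA`` — breaks per chromosome arm, ``max(#segments overlapping
  the arm - 1, 0)``; same six count bins.
* ``CN`` — number of segments at each integer total copy state {0..7,>=8}.
* ``CopyFraction`` — length-weighted fraction of the covered genome at
  each copy state {0..7,>=8}.
* ``SegSize`` — segment-length histogram over ten bins with upper edges
  {5 kb, 50 kb, 500 kb, 1 Mb, 3 Mb, 5 Mb, 10 Mb, 20 Mb, 50 Mb, inf}.
* ``CNCP`` — copy-number change points: |total_cn difference| between
  each segment and its 5' neighbour on the same chromosome, binned
  {1,2,3,4,>=5} (a change of 0 is not a change point).

Also provides the genomic-scar comparator scores (HRD-LOH, LST,
telomeric allelic imbalance and their sum), naive burden summaries, and
Cohen's d for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ArmMap, CopySegment, ValidationError

MB = 1_000_000


@dataclass(frozen=True)
class CnFeatureSchema:
    """Named bin edges for the six copy-number feature categories."""

    count_bin_max: int = 5            # BCper10Mb / BCperCA bins 0..4, >=5
    cn_state_max: int = 8             # CN / CopyFraction states 0..7, >=8
    segsize_edges: tuple[int, ...] = (
        5_000, 50_000, 500_000, 1 * MB, 3 * MB, 5 * MB, 10 * MB, 20 * MB, 50 * MB,
    )
    cncp_max: int = 5                 # CNCP bins 1..4, >=5
    window_size: int = 10 * MB
    telomere_tolerance: int = 10_000
    lst_min_segment: int = 10 * MB
    lst_max_gap: int = 3 * MB
    hrd_loh_min_length: int = 15 * MB
    lst_merge_small_interruptions: bool = False

    def __post_init__(self) -> None:
        if list(self.segsize_edges) != sorted(self.segsize_edges):
            raise ValidationError("segsize_edges must be strictly increasing")

    @property
    def bcper10mb_names(self) -> list[str]:
        return [f"BCper10Mb_{i}" for i in range(self.count_bin_max)] + [
            f"BCper10Mb_{self.count_bin_max}+"
        ]

    @property
    def bcperca_names(self) -> list[str]:
        return [f"BCperCA_{i}" for i in range(self.count_bin_max)] + [
            f"BCperCA_{self.count_bin_max}+"
        ]

    @property
    def cn_names(self) -> list[str]:
        return [f"CN_{i}" for i in range(self.cn_state_max)] + [f"CN_{self.cn_state_max}+"]

    @property
    def copyfraction_names(self) -> list[str]:
        return [f"CopyFraction_{i}" for i in range(self.cn_state_max)] + [
            f"CopyFraction_{self.cn_state_max}+"
        ]

    @property
    def segsize_names(self) -> list[str]:
        return [f"SegSize_{i + 1}" for i in range(len(self.segsize_edges) + 1)]

    @property
    def cncp_names(self) -> list[str]:
        return [f"CNCP_{i}" for i in range(1, self.cncp_max)] + [f"CNCP_{self.cncp_max}+"]

    @property
    def feature_names(self) -> list[str]:
        return (
            self.bcper10mb_names + self.bcperca_names + self.cn_names
            + self.copyfraction_names + self.segsize_names + self.cncp_names
        )


DEFAULT_SCHEMA = CnFeatureSchema()
assert len(DEFAULT_SCHEMA.feature_names) == 45


def _sorted_by_chrom(segments: list[CopySegment]) -> dict[str, list[CopySegment]]:
    out: dict[str, list[CopySegment]] = {}
    for seg in segments:
        out.setdefault(seg.chrom, []).append(seg)
    for chrom in out:
        out[chrom].sort(key=lambda s: s.start)
    return out


def _count_histogram(counts: list[int], n_bins_max: int) -> np.ndarray:
    hist = np.zeros(n_bins_max + 1, dtype=int)
    for c in counts:
        hist[min(c, n_bins_max)] += 1
    return hist


def breakpoints_per_10mb(
    segments: list[CopySegment], arm_map: ArmMap, schema: CnFeatureSchema = DEFAULT_SCHEMA
) -> np.ndarray:
    """Histogram of 3' segment-endpoint counts over fixed 10 Mb windows.

    Each chromosome is tiled independently into ``window_size`` windows;
    the final segment's 3' endpoint on each chromosome is excluded (a
    chromosome end is not a break).
    """
    window_counts: list[int] = []
    by_chrom = _sorted_by_chrom(segments)
    for chrom, arms in arm_map.chromosomes.items():
        n_windows = int(np.ceil(arms.length / schema.window_size))
        counts = np.zeros(n_windows, dtype=int)
        segs = by_chrom.get(chrom, [])
        for seg in segs:
            if seg.end > arms.length:
                raise ValidationError(
                    f"segment {chrom}:{seg.start}-{seg.end} beyond chromosome end "
                    f"({arms.length})"
                )
        for seg in segs[:-1]:  # terminal endpoint excluded
            counts[(seg.end - 1) // schema.window_size] += 1
        window_counts.extend(counts.tolist())
    for chrom in by_chrom:
        if chrom not in arm_map:
            raise ValidationError(f"chromosome {chrom} absent from arm map")
    return _count_histogram(window_counts, schema.count_bin_max)


def breaks_per_arm(
    segments: list[CopySegment], arm_map: ArmMap, schema: CnFeatureSchema = DEFAULT_SCHEMA
) -> np.ndarray:
    """Histogram over arms of (#segments overlapping the arm - 1).

    A segment straddling the centromere contributes to both arms.
    """
    by_chrom = _sorted_by_chrom(segments)
    for chrom in by_chrom:
        if chrom not in arm_map:
            raise ValidationError(f"chromosome {chrom} absent from arm map")
    arm_counts: list[int] = []
    for chrom, _arm, start, end in arm_map.arms():
        n = sum(
            1
            for seg in by_chrom.get(chrom, [])
            if seg.start <= end and seg.end >= start
        )
        arm_counts.append(max(n - 1, 0))
    return _count_histogram(arm_counts, schema.count_bin_max)


def cn_state_counts(
    segments: list[CopySegment], schema: CnFeatureSchema = DEFAULT_SCHEMA
) -> np.ndarray:
    """Number of segments at each integer total copy state."""
    return _count_histogram([s.total_cn for s in segments], schema.cn_state_max)


def copy_fraction(
    segments: list[CopySegment], schema: CnFeatureSchema = DEFAULT_SCHEMA
) -> np.ndarray:
    """Length-weighted fraction of the covered genome at each copy state."""
    frac = np.zeros(schema.cn_state_max + 1, dtype=float)
    total = sum(s.length for s in segments)
    if total == 0:
        return frac
    for s in segments:
        frac[min(s.total_cn, schema.cn_state_max)] += s.length
    return frac / total


def segment_size_features(
    segments: list[CopySegment], schema: CnFeatureSchema = DEFAULT_SCHEMA
) -> np.ndarray:
    """Segment-length histogram over the schema's size bins."""
    edges = schema.segsize_edges
    hist = np.zeros(len(edges) + 1, dtype=int)
    for s in segments:
        hist[int(np.searchsorted(edges, s.length))] += 1
    return hist


def cncp_features(
    segments: list[CopySegment], schema: CnFeatureSchema = DEFAULT_SCHEMA
) -> np.ndarray:
    """Copy-number change points between 5'-adjacent segments, binned by |delta|."""
    hist = np.zeros(schema.cncp_max, dtype=int)
    for segs in _sorted_by_chrom(segments).values():
        for prev, cur in zip(segs, segs[1:]):
            delta = abs(cur.total_cn - prev.total_cn)
            if delta >= 1:
                hist[min(delta, schema.cncp_max) - 1] += 1
    return hist


def extract_cn_features(
    segments: list[CopySegment],
    arm_map: ArmMap,
    schema: CnFeatureSchema = DEFAULT_SCHEMA,
) -> pd.Series:
    """All six categories concatenated in schema order with stable names."""
    values = np.concatenate(
        [
            breakpoints_per_10mb(segments, arm_map, schema),
            breaks_per_arm(segments, arm_map, schema),
            cn_state_counts(segments, schema),
            copy_fraction(segments, schema),
            segment_size_features(segments, schema),
            cncp_features(segments, schema),
        ]
    ).astype(float)
    return pd.Series(values, index=schema.feature_names)


# ---------------------------------------------------------------------------
# genomic-scar comparator scores


def _merged_loh_regions(segs: list[CopySegment]) -> list[tuple[int, int]]:
    """Merge directly adjacent LOH segments (gap tolerance 0)."""
    regions: list[tuple[int, int]] = []
    for seg in segs:
        if not seg.is_loh:
            continue
        if regions and seg.start == regions[-1][1] + 1:
            regions[-1] = (regions[-1][0], seg.end)
        else:
            regions.append((seg.start, seg.end))
    return regions


def hrd_loh(segments: list[CopySegment], schema: CnFeatureSchema = DEFAULT_SCHEMA) -> int:
    """LOH regions longer than 15 Mb that do not span the whole chromosome.

    Adjacent LOH segments (minor copy 0, total >= 1) are merged first; a
    merged region covering the full extent of that chromosome's segments
    is excluded.
    """
    count = 0
    for segs in _sorted_by_chrom(segments).values():
        chrom_span = (segs[0].start, segs[-1].end)
        for start, end in _merged_loh_regions(segs):
            if end - start + 1 > schema.hrd_loh_min_length and (start, end) != chrom_span:
                count += 1
    return count


def lst(segments: list[CopySegment], schema: CnFeatureSchema = DEFAULT_SCHEMA) -> int:
    """Large-scale state transitions.

    Within-chromosome adjacent pairs where both segments are >= 10 Mb,
    the gap between them is <= 3 Mb, and the (total, minor) copy state
    differs.  With ``lst_merge_small_interruptions`` set, runs of sub-3 Mb
    segments between identical states are first merged into their
    neighbours (off by default).
    """
    count = 0
    for segs in _sorted_by_chrom(segments).values():
        if schema.lst_merge_small_interruptions:
            segs = _merge_small_interruptions(segs, schema.lst_max_gap)
        for prev, cur in zip(segs, segs[1:]):
            gap = cur.start - prev.end - 1
            if (
                prev.length >= schema.lst_min_segment
                and cur.length >= schema.lst_min_segment
                and gap <= schema.lst_max_gap
                and (prev.total_cn, prev.minor_cn) != (cur.total_cn, cur.minor_cn)
            ):
                count += 1
    return count


def _merge_small_interruptions(segs: list[CopySegment], max_len: int) -> list[CopySegment]:
    """Drop short segments and merge flanking segments of identical state."""
    kept = [s for s in segs if s.length >= max_len]
    merged: list[CopySegment] = []
    for s in kept:
        if merged and (merged[-1].total_cn, merged[-1].major_cn, merged[-1].minor_cn) == (
            s.total_cn, s.major_cn, s.minor_cn,
        ):
            last = merged.pop()
            merged.append(
                CopySegment(s.chrom, last.start, s.end, s.total_cn, s.major_cn, s.minor_cn)
            )
        else:
            merged.append(s)
    return merged


def telomeric_ai(
    segments: list[CopySegment], arm_map: ArmMap, schema: CnFeatureSchema = DEFAULT_SCHEMA
) -> int:
    """Allelic imbalances extending to a telomeric chromosome end.

    A segment with major != minor copy number whose start is within
    ``telomere_tolerance`` of base 1, or whose end is within tolerance of
    the chromosome end, counts once; segments spanning the entire
    chromosome are excluded.
    """
    count = 0
    for chrom, segs in _sorted_by_chrom(segments).items():
        if chrom not in arm_map:
            raise ValidationError(f"chromosome {chrom} absent from arm map")
        length = arm_map[chrom].length
        tol = schema.telomere_tolerance
        for seg in segs:
            if seg.major_cn == seg.minor_cn:
                continue
            at_start = seg.start <= 1 + tol
            at_end = seg.end >= length - tol
            if at_start and at_end:  # whole-chromosome imbalance
                continue
            if at_start or at_end:
                count += 1
    return count


@dataclass(frozen=True)
class ScarScores:
    hrd_loh: int
    lst: int
    telomeric_ai: int

    def __post_init__(self) -> None:
        if min(self.hrd_loh, self.lst, self.telomeric_ai) < 0:
            raise ValidationError("scar scores must be non-negative")

    @property
    def total(self) -> int:
        return self.hrd_loh + self.lst + self.telomeric_ai


def scar_scores(
    segments: list[CopySegment], arm_map: ArmMap, schema: CnFeatureSchema = DEFAULT_SCHEMA
) -> ScarScores:
    return ScarScores(
        hrd_loh=hrd_loh(segments, schema),
        lst=lst(segments, schema),
        telomeric_ai=telomeric_ai(segments, arm_map, schema),
    )


# ---------------------------------------------------------------------------
# naive burden summaries


@dataclass(frozen=True)
class BurdenSummary:
    snv_count: int
    indel_count: int
    mean_ploidy: float
    base_ploidy: int
    altered_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.altered_fraction <= 1.0):
            raise ValidationError("altered_fraction outside [0,1]")
        if self.base_ploidy < 0:
            raise ValidationError("base_ploidy must be >= 0")


def burden_summary(catalog, segments: list[CopySegment]) -> BurdenSummary:
    """Naive per-sample genome-instability summary.

    ``base_ploidy`` is the length-weighted modal integer copy state; the
    altered fraction is the covered-genome fraction whose total copy
    number differs from it.
    """
    total_len = sum(s.length for s in segments)
    if total_len == 0:
        mean_p, base_p, altered = 0.0, 0, 0.0
    else:
        mean_p = sum(s.total_cn * s.length for s in segments) / total_len
        weights: dict[int, int] = {}
        for s in segments:
            weights[s.total_cn] = weights.get(s.total_cn, 0) + s.length
        base_p = max(sorted(weights), key=lambda k: weights[k])
        altered = sum(s.length for s in segments if s.total_cn != base_p) / total_len
    return BurdenSummary(
        snv_count=int(catalog.sbs_counts.sum()),
        indel_count=int(catalog.indel_counts.sum()),
        mean_ploidy=mean_p,
        base_ploidy=base_p,
        altered_fraction=altered,
    )


def cohens_d(group_a, group_b) -> float:
    """Standardised mean difference with the pooled (n-1 weighted) SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("Cohen's d needs at least two values per group")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return 0.0 if a.mean() == b.mean() else float("inf")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))
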