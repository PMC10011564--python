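"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive everywhere inside the package; half-open
external formats (cytoBand.txt) are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


class FormatError(ValueError):
    """An external file does not conform to its declared dialect."""


@dataclass(frozen=True)
class VariantRecord:
    """One candidate small variant with tumour/normal pileup evidence.

    ``context`` carries the reference sequence around the event:

    * SNV: 2*flank+1 bases centred on the variant (41 bp at the default
      20 bp flank), with the reference allele at the centre.
    * Deletion (VCF-anchored ``ref=A+D, alt=A``): ``flank`` bases upstream
      of the deleted tract, the deleted tract itself, then ``flank`` bases
      downstream (40 + len(D) bp).
    * Insertion (``ref=A, alt=A+I``): ``flank`` bases either side of the
      insertion point (40 bp); the inserted sequence is absent from the
      reference and hence from the context.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    tumour_depth: int
    tumour_alt: int
    normal_depth: int
    normal_alt: int
    mean_end_distance: float
    context: str
    repeat_adjacent: bool = False
    flank: int = 20

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.tumour_alt > self.tumour_depth:
            raise ValidationError(
                f"tumour_alt {self.tumour_alt} > tumour_depth {self.tumour_depth}"
            )
        if self.normal_alt > self.normal_depth:
            raise ValidationError(
                f"normal_alt {self.normal_alt} > normal_depth {self.normal_depth}"
            )
        if self.mean_end_distance < 0:
            raise ValidationError("mean_end_distance must be non-negative")
        if self.context:
            expected = self._expected_context_length()
            if expected is not None and len(self.context) != expected:
                raise ValidationError(
                    f"context length {len(self.context)} does not match declared "
                    f"flank {self.flank} (expected {expected}) at {self.chrom}:{self.pos}"
                )

    def _expected_context_length(self) -> int | None:
        if self.is_snv:
            return 2 * self.flank + 1
        r, a = _strip_anchor(self.ref, self.alt)
        if len(r) > 0 and len(a) > 0:  # complex substitution: no fixed rule
            return None
        return 2 * self.flank + len(r)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        if self.is_snv:
            return False
        r, a = _strip_anchor(self.ref, self.alt)
        return (len(r) == 0) != (len(a) == 0)

    @property
    def tumour_vaf(self) -> float:
        return self.tumour_alt / self.tumour_depth if self.tumour_depth else 0.0

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth else 0.0


def _strip_anchor(ref: str, alt: str) -> tuple[str, str]:
    """Remove the shared leading bases of a VCF-style allele pair."""
    k = 0
    while k < len(ref) and k < len(alt) and ref[k] == alt[k]:
        k += 1
    return ref[k:], alt[k:]


@dataclass(frozen=True)
class CopySegment:
    """One allele-specific copy-number segment (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    total_cn: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"start {self.start} > end {self.end} on {self.chrom}")
        if self.minor_cn < 0 or self.major_cn < self.minor_cn:
            raise ValidationError(
                f"need major_cn >= minor_cn >= 0, got A={self.major_cn} B={self.minor_cn} "
                f"at {self.chrom}:{self.start}-{self.end}"
            )
        if self.major_cn + self.minor_cn != self.total_cn:
            raise ValidationError(
                f"major+minor != total ({self.major_cn}+{self.minor_cn} != {self.total_cn}) "
                f"at {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_loh(self) -> bool:
        return self.minor_cn == 0 and self.total_cn >= 1


@dataclass
class SegmentationSolution:
    """Validated segment list plus the caller's purity/ploidy solution."""

    segments: list[CopySegment]
    cellularity: float | None = None
    mean_ploidy: float | None = None

    def __post_init__(self) -> None:
        if self.cellularity is not None and not (0.0 <= self.cellularity <= 1.0):
            raise ValidationError(f"cellularity {self.cellularity} outside [0, 1]")
        if self.mean_ploidy is not None and self.mean_ploidy <= 0:
            raise ValidationError(f"mean_ploidy {self.mean_ploidy} must be > 0")
        validate_segments(self.segments)


def validate_segments(segments: list[CopySegment]) -> None:
    """Check the per-chromosome sorted / non-overlapping invariant."""
    by_chrom: dict[str, list[CopySegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        ordered = sorted(segs, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping segments on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


@dataclass(frozen=True)
class ChromosomeArms:
    """Arm intervals for one chromosome, 1-based inclusive."""

    length: int
    centromere: int
    p: tuple[int, int]
    q: tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.p[0] <= self.p[1] < self.q[0] <= self.q[1]):
            raise ValidationError("arms must be ordered and non-overlapping")
        if not (self.p[1] <= self.centromere <= self.q[0]):
            raise ValidationError("centromere must lie between the p and q arms")
        if self.q[1] != self.length:
            raise ValidationError("q arm must end at the chromosome end")


@dataclass
class ArmMap:
    """Per-chromosome arm definitions (p/q intervals + centromere)."""

    chromosomes: dict[str, ChromosomeArms] = field(default_factory=dict)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __getitem__(self, chrom: str) -> ChromosomeArms:
        return self.chromosomes[chrom]

    def arms(self) -> list[tuple[str, str, int, int]]:
        """All arms as (chrom, arm_name, start, end) in deterministic order."""
        out = []
        for chrom in self.chromosomes:
            c = self.chromosomes[chrom]
            out.append((chrom, "p", c.p[0], c.p[1]))
            out.append((chrom, "q", c.q[0], c.q[1]))
        return out
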