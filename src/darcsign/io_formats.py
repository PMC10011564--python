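"""Readers and writers for every external representation the pipeline touches.

Dialects
--------
* segment TSV: the allele-specific segmentation dialect of the upstream
  purity/ploidy caller (columns ``chromosome / start.pos / end.pos / CNt /
  A / B`` by default, aliases configurable).  Leading ``# key: value``
  comment lines may carry the solution metadata (cellularity, mean ploidy).
* variant tables: a documented plain-TSV dialect, or VCF 4.x via pysam.
* UCSC ``cytoBand.txt`` (0-based half-open, converted on read).
* FASTA via pyfaidx for context retrieval.

All readers validate rather than coerce; rejected rows raise with the
offending line, and acceptance/rejection counts are logged.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd

from .types import (
    ArmMap,
    ChromosomeArms,
    CopySegment,
    FormatError,
    SegmentationSolution,
    ValidationError,
    VariantRecord,
)

log = logging.getLogger(__name__)

#: Default column aliases for the segment dialect (first match wins).
SEGMENT_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "chrom": ("chromosome", "chrom", "chr"),
    "start": ("start.pos", "start", "startpos"),
    "end": ("end.pos", "end", "endpos"),
    "total_cn": ("CNt", "total_cn", "cn_total"),
    "major_cn": ("A", "major_cn", "nMajor"),
    "minor_cn": ("B", "minor_cn", "nMinor"),
}

VARIANT_TSV_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "tumour_depth",
    "tumour_alt",
    "normal_depth",
    "normal_alt",
    "mean_end_distance",
    "context",
    "repeat_adjacent",
)

# Ploidy band inside which a low-cellularity solution is still trusted.
PLOIDY_DIPLOID_BAND = (1.1, 2.9)
MIN_CELLULARITY_NON_DIPLOID = 0.18


def _normalize_chrom(chrom: str, strip_chr_prefix: bool) -> str:
    chrom = str(chrom)
    if strip_chr_prefix and chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


def _read_comment_metadata(path: str | Path) -> dict[str, float]:
    """Parse leading ``# key: value`` lines (cellularity / mean_ploidy)."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                try:
                    meta[key.strip().lower()] = float(value)
                except ValueError:
                    continue
    return meta


def read_segments(
    path: str | Path,
    aliases: dict[str, tuple[str, ...]] | None = None,
    strip_chr_prefix: bool = False,
    cellularity: float | None = None,
    mean_ploidy: float | None = None,
) -> SegmentationSolution:
    """Read an allele-specific segment table into a validated solution.

    Solution metadata is taken from keyword arguments when given, else from
    leading ``# cellularity: x`` / ``# mean_ploidy: y`` comment lines.
    """
    aliases = aliases or SEGMENT_COLUMN_ALIASES
    meta = _read_comment_metadata(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)

    colmap: dict[str, str] = {}
    lowered = {c.lower(): c for c in df.columns}
    for field, names in aliases.items():
        for name in names:
            if name.lower() in lowered:
                colmap[field] = lowered[name.lower()]
                break
        else:
            raise FormatError(
                f"{path}: missing column for {field!r} (tried {', '.join(names)})"
            )

    segments: list[CopySegment] = []
    for idx, row in df.iterrows():
        try:
            start = int(row[colmap["start"]])
            end = int(row[colmap["end"]])
            total = int(row[colmap["total_cn"]])
            major = int(row[colmap["major_cn"]])
            minor = int(row[colmap["minor_cn"]])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path} row {idx + 2}: non-integer value ({exc})")
        if float(row[colmap["total_cn"]]) != total:
            raise ValidationError(f"{path} row {idx + 2}: non-integer copy number")
        segments.append(
            CopySegment(
                chrom=_normalize_chrom(row[colmap["chrom"]], strip_chr_prefix),
                start=start,
                end=end,
                total_cn=total,
                major_cn=major,
                minor_cn=minor,
            )
        )

    # sort, then surface overlaps with the original (1-based data) row numbers
    order = sorted(range(len(segments)), key=lambda i: (segments[i].chrom, segments[i].start))
    for i, j in zip(order, order[1:]):
        a, b = segments[i], segments[j]
        if a.chrom == b.chrom and b.start <= a.end:
            raise ValidationError(
                f"{path}: overlapping segments at data rows {i + 1} and {j + 1} "
                f"({a.chrom}:{a.start}-{a.end} vs {b.chrom}:{b.start}-{b.end})"
            )
    segments = [segments[i] for i in order]
    log.info("read_segments: %d segments from %s", len(segments), path)
    return SegmentationSolution(
        segments=segments,
        cellularity=cellularity if cellularity is not None else meta.get("cellularity"),
        mean_ploidy=mean_ploidy if mean_ploidy is not None else meta.get("mean_ploidy"),
    )


def write_segments(solution: SegmentationSolution, path: str | Path) -> None:
    """Write a solution back out in the default segment dialect."""
    with open(path, "w") as fh:
        if solution.cellularity is not None:
            fh.write(f"# cellularity: {solution.cellularity}\n")
        if solution.mean_ploidy is not None:
            fh.write(f"# mean_ploidy: {solution.mean_ploidy}\n")
        fh.write("chromosome\tstart.pos\tend.pos\tCNt\tA\tB\n")
        for s in solution.segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.total_cn}\t{s.major_cn}\t{s.minor_cn}\n")


def accept_solution(solution: SegmentationSolution) -> bool:
    """Acceptance rule for an upstream purity/ploidy solution.

    Non-diploid mean ploidies (outside [1.1, 2.9]) are only trusted when the
    estimated cellularity exceeds 0.18 — low tumour fraction precludes
    reliable determination of non-diploid status.  Solutions inside the
    diploid band are accepted regardless of cellularity.
    """
    lo, hi = PLOIDY_DIPLOID_BAND
    if solution.mean_ploidy is None:
        raise ValidationError("solution has no mean_ploidy")
    if lo <= solution.mean_ploidy <= hi:
        return True
    if solution.cellularity is None:
        raise ValidationError("non-diploid solution has no cellularity")
    return solution.cellularity > MIN_CELLULARITY_NON_DIPLOID


def read_variants(
    path: str | Path,
    dialect: str = "tabular",
    tumour_sample: str | None = None,
    normal_sample: str | None = None,
    reference=None,
    flank: int = 20,
    strip_chr_prefix: bool = False,
) -> list[VariantRecord]:
    """Read variant records from a tabular file or a VCF.

    For the VCF dialect, tumour/normal columns are identified by sample
    name; per-sample ``DP``/``AD`` fields supply the pileup counts, the
    ``MED`` INFO field (if present) the mean end distance, and contexts are
    resolved from ``reference`` (a pyfaidx.Fasta or path) when not carried
    in a ``CTX`` INFO field.  Records whose context cannot be resolved, and
    symbolic/multi-allelic ALTs, are excluded with a warning.
    """
    if dialect == "tabular":
        return _read_variants_tabular(path, strip_chr_prefix)
    if dialect == "vcf":
        return _read_variants_vcf(
            path, tumour_sample, normal_sample, reference, flank, strip_chr_prefix
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variants_tabular(path: str | Path, strip_chr_prefix: bool) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in VARIANT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing variant columns {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                VariantRecord(
                    chrom=_normalize_chrom(row["chrom"], strip_chr_prefix),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                    tumour_depth=int(row["tumour_depth"]),
                    tumour_alt=int(row["tumour_alt"]),
                    normal_depth=int(row["normal_depth"]),
                    normal_alt=int(row["normal_alt"]),
                    mean_end_distance=float(row["mean_end_distance"]),
                    context=str(row["context"]),
                    repeat_adjacent=str(row["repeat_adjacent"]).lower()
                    in ("1", "true", "t", "yes"),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise FormatError(f"{path} line {idx + 2}: malformed row ({exc})")
    log.info("read_variants: %d records from %s", len(records), path)
    return records


def _read_variants_vcf(
    path, tumour_sample, normal_sample, reference, flank, strip_chr_prefix
) -> list[VariantRecord]:
    import pysam

    if isinstance(reference, (str, Path)):
        from pyfaidx import Fasta

        reference = Fasta(str(reference))

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if tumour_sample is None or normal_sample is None:
        if len(samples) != 2:
            raise FormatError(
                f"{path}: tumour/normal sample names required for a "
                f"{len(samples)}-sample VCF"
            )
        tumour_sample, normal_sample = samples
    records: list[VariantRecord] = []
    excluded = 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1 or rec.alts[0].startswith("<"):
            excluded += 1
            continue
        alt = rec.alts[0]
        t, n = rec.samples[tumour_sample], rec.samples[normal_sample]
        t_ad = t.get("AD")
        n_ad = n.get("AD")
        context = _info_get(rec, "CTX")
        if context is None and reference is not None:
            r_stripped, a_stripped = _strip_pair(rec.ref, alt)
            try:
                if len(rec.ref) == 1 and len(alt) == 1:
                    context = fetch_context(reference, rec.contig, rec.pos, flank)
                else:
                    tract = len(r_stripped)
                    start = rec.pos + len(rec.ref) - tract  # first affected base
                    context = str(
                        reference[rec.contig][start - flank - 1 : start + tract + flank - 1]
                    ).upper()
            except (KeyError, IndexError, ValueError):
                context = None
        if context is None:
            excluded += 1
            continue
        try:
            records.append(
                VariantRecord(
                    chrom=_normalize_chrom(rec.contig, strip_chr_prefix),
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    tumour_depth=int(t.get("DP") or sum(t_ad)),
                    tumour_alt=int(t_ad[1]),
                    normal_depth=int(n.get("DP") or sum(n_ad)),
                    normal_alt=int(n_ad[1]),
                    mean_end_distance=float(_info_get(rec, "MED", 1e9)),
                    context=str(context),
                    repeat_adjacent=bool(_info_get(rec, "REPEAT", False)),
                    flank=flank,
                )
            )
        except (TypeError, ValidationError):
            excluded += 1
    if excluded:
        warnings.warn(f"{path}: excluded {excluded} unsupported/unresolvable VCF records")
        log.info("read_variants(vcf): excluded %d records", excluded)
    return records


def _info_get(rec, key: str, default=None):
    """INFO lookup tolerant of keys missing from the VCF header."""
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def _strip_pair(ref: str, alt: str) -> tuple[str, str]:
    k = 0
    while k < len(ref) and k < len(alt) and ref[k] == alt[k]:
        k += 1
    return ref[k:], alt[k:]


def write_variants(records: list[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.tumour_depth}\t{r.tumour_alt}\t"
                f"{r.normal_depth}\t{r.normal_alt}\t{r.mean_end_distance:g}\t{r.context}\t"
                f"{'true' if r.repeat_adjacent else 'false'}\n"
            )


def read_cytobands(path: str | Path, strip_chr_prefix: bool = False) -> ArmMap:
    """Assemble an arm map from a UCSC-style cytoband file.

    Input is the standard 5-column text (chrom, start, end, band, stain)
    with 0-based half-open coordinates; arms are assembled from the band
    prefix (p*/q*), the centromere from the ``acen`` bands (boundary
    between the p-side and q-side acen bands, else the p/q boundary).
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "band", "stain"],
            dtype={"chrom": str, "band": str, "stain": str},
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty cytoband file")
    if df.empty:
        raise FormatError(f"{path}: empty cytoband file")

    chromosomes: dict[str, ChromosomeArms] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        name = _normalize_chrom(chrom, strip_chr_prefix)
        p = grp[grp["band"].str.startswith("p")]
        q = grp[grp["band"].str.startswith("q")]
        if p.empty or q.empty:
            raise ValidationError(f"{path}: chromosome {chrom} lacks a p or q arm")
        length = int(grp["end"].max())
        p_iv = (int(p["start"].min()) + 1, int(p["end"].max()))
        q_iv = (int(q["start"].min()) + 1, int(q["end"].max()))
        acen = grp[grp["stain"] == "acen"]
        if not acen.empty:
            p_acen = acen[acen["band"].str.startswith("p")]
            centromere = int(p_acen["end"].max()) if not p_acen.empty else int(acen["start"].min())
        else:
            centromere = p_iv[1]
        chromosomes[name] = ChromosomeArms(
            length=length, centromere=centromere, p=p_iv, q=q_iv
        )
    return ArmMap(chromosomes=chromosomes)


def write_cytobands(arm_map: ArmMap, path: str | Path) -> None:
    """Emit a minimal UCSC-style cytoband file (4 bands per chromosome)."""
    with open(path, "w") as fh:
        for chrom, arms in arm_map.chromosomes.items():
            cen = arms.centromere
            fh.write(f"{chrom}\t{arms.p[0] - 1}\t{max(arms.p[0] - 1, cen - 2_000_000)}\tp12\tgneg\n")
            fh.write(f"{chrom}\t{max(arms.p[0] - 1, cen - 2_000_000)}\t{cen}\tp11\tacen\n")
            fh.write(f"{chrom}\t{cen}\t{min(arms.length, cen + 2_000_000)}\tq11\tacen\n")
            fh.write(f"{chrom}\t{min(arms.length, cen + 2_000_000)}\t{arms.length}\tq12\tgneg\n")


def fetch_context(reference, chrom: str, pos: int, flank: int = 20) -> str:
    """Fetch 2*flank+1 uppercase bases centred on ``pos`` (1-based).

    ``reference`` is a pyfaidx.Fasta (or anything mapping chrom to an
    indexable sequence).  An out-of-range window raises; an N-containing
    window is flagged with a warning but returned.
    """
    seq = reference[chrom]
    chrom_len = len(seq)
    if pos - flank < 1 or pos + flank > chrom_len:
        raise ValueError(
            f"context window {chrom}:{pos}±{flank} outside chromosome (len {chrom_len})"
        )
    window = str(seq[pos - flank - 1 : pos + flank]).upper()
    if "N" in window:
        warnings.warn(f"context at {chrom}:{pos} contains N")
    return window


# model persistence lives with the classifier but belongs to this surface too
from .classifier import load_model, save_model  # noqa: E402,F401
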