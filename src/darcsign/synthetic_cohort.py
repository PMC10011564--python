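"""Labelled synthetic samples emulating the DDR-deficiency phenotypes.

Each class generator produces variant records (with their own ±20 bp
contexts) and allele-specific copy-number segments whose feature-space
structure mirrors the documented phenotype:

* **MMRd** — hypermutated: abundant C>T at NpCpG, many 1 bp deletions in
  long cytosine homopolymers (replication slippage), near-diploid genome.
* **CDK12d** — diploid backbone carpeted with focal tandem duplications:
  many sub-5 kb segments with single-copy (occasionally triple-copy)
  steps between neighbours.
* **BRCA2d** — microhomology-flanked and long deletions, a C>G-enriched
  substitution spectrum (A[C>G]G in particular), aneuploid 10–20 Mb
  segmentation with frequent LOH.
* **DDRwt** — an ageing CpG C>T spectrum, low indel burden, large-segment
  aneuploidy and frequent whole-genome doubling.
* **bladder-like** — APOBEC-dominated spectrum with aneuploidy (a
  comparator class, labelled DDRwt).

The copy-number coordinate genome is five synthetic chromosomes
(80–200 Mb) defined by an arm map; variant contexts are generated
directly, so no full-length reference sequence is required.  A small
sequence reference (three ~1 Mb contigs with embedded homopolymers and
tandem repeats) can be written for end-to-end context-fetch testing.

All emitted records satisfy the somatic filter rules by construction; a
configurable fraction of deliberate filter failures supports filter
testing.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import write_cytobands, write_segments, write_variants
from .mutation_features import SBS96_CHANNELS, build_catalog, revcomp
from .profiles import build_profile
from .types import (
    ArmMap,
    ChromosomeArms,
    CopySegment,
    SegmentationSolution,
    VariantRecord,
)

MB = 1_000_000

#: synthetic coordinate genome: name -> (length, centromere)
GENOME = {
    "1": (200 * MB, 100 * MB),
    "2": (160 * MB, 65 * MB),
    "3": (120 * MB, 50 * MB),
    "4": (100 * MB, 45 * MB),
    "5": (80 * MB, 30 * MB),
}


def default_arm_map() -> ArmMap:
    chromosomes = {
        name: ChromosomeArms(length=length, centromere=cen, p=(1, cen), q=(cen + 1, length))
        for name, (length, cen) in GENOME.items()
    }
    return ArmMap(chromosomes=chromosomes)


# ---------------------------------------------------------------------------
# substitution spectrum templates


def _weighted_spectrum(weights: dict[str, float], baseline: float) -> np.ndarray:
    spec = np.full(96, baseline, dtype=float)
    index = {c: i for i, c in enumerate(SBS96_CHANNELS)}
    for channel, w in weights.items():
        spec[index[channel]] += w
    return spec / spec.sum()


def _channels(sub: str, left: str = "ACGT", right: str = "ACGT") -> list[str]:
    ref, alt = sub.split(">")
    return [f"{l}[{ref}>{alt}]{r}" for l in left for r in right]


def ageing_spectrum() -> np.ndarray:
    """Deamination at methylated CpG: C>T with a 3' G."""
    return _weighted_spectrum({c: 12.0 for c in _channels("C>T", right="G")}, baseline=0.5)


def mmr_spectrum() -> np.ndarray:
    """Hypermutator C>T concentrated at NpCpG, like the ageing spectrum.

    The near-identical channel shape (burden aside) is what makes C>T
    features nonspecific for distinguishing MMRd from aged genomes.
    """
    weights = {c: 20.0 for c in _channels("C>T", right="G")}
    weights.update({c: weights.get(c, 0.0) + 1.0 for c in _channels("C>T")})
    weights.update({c: 0.8 for c in _channels("T>C")})
    return _weighted_spectrum(weights, baseline=0.3)


def hrr_spectrum() -> np.ndarray:
    """Flat, C>G-enriched spectrum with a strong A[C>G]G component."""
    weights = {c: 4.0 for c in _channels("C>G")}
    weights["A[C>G]G"] = 14.0
    return _weighted_spectrum(weights, baseline=1.0)


def apobec_spectrum() -> np.ndarray:
    """TCW-focused C>T / C>G."""
    weights = {
        "T[C>T]A": 10.0, "T[C>T]T": 10.0, "T[C>G]A": 8.0, "T[C>G]T": 8.0,
    }
    return _weighted_spectrum(weights, baseline=0.3)


def flat_spectrum() -> np.ndarray:
    return np.full(96, 1.0 / 96)


# ---------------------------------------------------------------------------
# class generators


@dataclass(frozen=True)
class ClassGenerator:
    """Parameters of one phenotype class's sample generator.

    Indel means are expected counts per sample of each indel program;
    segment parameters are per-arm rates.  ``dup_delta_choices`` gives the
    total-copy step (and probability) of a focal tandem duplication.
    """

    name: str
    label: str
    snv_mean: float
    spectrum: np.ndarray
    hpoly_del_c_mean: float = 0.0   # 1 bp C deletions in >=6 bp homopolymers
    hpoly_del_t_mean: float = 0.0
    ins_1bp_mean: float = 0.0
    mh_del_mean: float = 0.0        # 3-5 bp deletions with microhomology
    long_del_mean: float = 0.0      # >=5 bp non-repeat deletions
    rep_del_mean: float = 0.0       # repeat-mediated 2 bp deletions
    arm_event_rate: float = 0.0     # probability an arm is rearranged
    arm_piece_mb: tuple[float, float] = (10.0, 20.0)
    loh_rate: float = 0.0           # probability a rearranged piece is LOH
    dup_rate_per_arm: float = 0.0   # Poisson mean of focal tandem duplications
    dup_len_range: tuple[int, int] = (1_000, 4_000)
    dup_delta_choices: tuple[tuple[int, float], ...] = ((1, 0.85), (3, 0.15))
    wgd_prob: float = 0.0           # whole-genome doubling probability
    burden_dispersion: float = 0.5  # sigma of per-sample lognormal burden factors
    filter_fail_fraction: float = 0.0

    def __post_init__(self) -> None:
        assert abs(self.spectrum.sum() - 1) < 1e-9


def default_generators() -> dict[str, ClassGenerator]:
    """The "strong" profile: clean class separation at realistic burdens."""
    return {
        "MMRd": ClassGenerator(
            name="MMRd", label="MMRd", snv_mean=900, spectrum=mmr_spectrum(),
            hpoly_del_c_mean=130, hpoly_del_t_mean=60, ins_1bp_mean=25,
            long_del_mean=4, rep_del_mean=6,
            arm_event_rate=0.05, loh_rate=0.05,
            # hypermutated, but with a burden range whose low tail meets the
            # aged-DDRwt upper tail: C>T channels alone cannot resolve MMRd,
            # the homopolymer-deletion channel can
            burden_dispersion=0.6,
        ),
        "CDK12d": ClassGenerator(
            name="CDK12d", label="CDK12d", snv_mean=110, spectrum=_mix(
                {"ageing": 0.55, "flat": 0.45}
            ),
            hpoly_del_c_mean=2, hpoly_del_t_mean=2, ins_1bp_mean=3,
            mh_del_mean=1, long_del_mean=1, rep_del_mean=2,
            arm_event_rate=0.0, dup_rate_per_arm=4.0,
        ),
        "BRCA2d": ClassGenerator(
            name="BRCA2d", label="BRCA2d", snv_mean=260, spectrum=_mix(
                {"hrr": 0.7, "ageing": 0.3}
            ),
            hpoly_del_c_mean=4, hpoly_del_t_mean=4, ins_1bp_mean=6,
            mh_del_mean=35, long_del_mean=25, rep_del_mean=5,
            arm_event_rate=0.85, arm_piece_mb=(10.0, 20.0), loh_rate=0.45,
            # scattered focal events (well above 5 kb) as in any rearranged
            # prostate genome, so breakpoint counts alone are not CDK12d-like
            dup_rate_per_arm=0.6, dup_len_range=(20_000, 2_000_000),
            wgd_prob=0.5,
        ),
        "DDRwt": ClassGenerator(
            name="DDRwt", label="DDRwt", snv_mean=130, spectrum=_mix(
                {"ageing": 0.75, "flat": 0.25}
            ),
            hpoly_del_c_mean=1, hpoly_del_t_mean=1, ins_1bp_mean=3,
            mh_del_mean=2, long_del_mean=2, rep_del_mean=2,
            arm_event_rate=0.55, arm_piece_mb=(30.0, 80.0), loh_rate=0.15,
            dup_rate_per_arm=0.4, dup_len_range=(20_000, 2_000_000),
            wgd_prob=0.4,
            # advanced patient age: ageing C>T burden varies widely and its
            # upper tail overlaps hypermutated spectra, which is what makes
            # C>T channels nonspecific for MMRd
            burden_dispersion=1.2,
        ),
        "BLCA_like": ClassGenerator(
            name="BLCA_like", label="DDRwt", snv_mean=420, spectrum=_mix(
                {"apobec": 0.7, "ageing": 0.3}
            ),
            hpoly_del_c_mean=2, hpoly_del_t_mean=2, ins_1bp_mean=4,
            mh_del_mean=3, long_del_mean=3, rep_del_mean=3,
            arm_event_rate=0.6, arm_piece_mb=(25.0, 70.0), loh_rate=0.2,
            dup_rate_per_arm=0.4, dup_len_range=(20_000, 2_000_000),
            wgd_prob=0.3,
        ),
    }


def hard_generators() -> dict[str, ClassGenerator]:
    """Overlapping burdens with attenuated copy-number signal.

    Mimics the degradation of copy-number-driven classes (CDK12d in
    particular) at low tumour fraction: fewer detected focal events and
    weaker arm-level rearrangement, with mutation burdens pulled toward
    the DDRwt range.
    """
    strong = default_generators()
    out = {}
    for name, g in strong.items():
        out[name] = replace(
            g,
            snv_mean=0.55 * g.snv_mean + 0.45 * 100,
            hpoly_del_c_mean=0.5 * g.hpoly_del_c_mean + 1,
            hpoly_del_t_mean=0.5 * g.hpoly_del_t_mean + 1,
            mh_del_mean=0.5 * g.mh_del_mean + 1,
            long_del_mean=0.5 * g.long_del_mean + 1,
            dup_rate_per_arm=0.35 * g.dup_rate_per_arm,
            arm_event_rate=0.6 * g.arm_event_rate,
        )
    return out


def _mix(parts: dict[str, float]) -> np.ndarray:
    templates = {
        "ageing": ageing_spectrum(),
        "mmr": mmr_spectrum(),
        "hrr": hrr_spectrum(),
        "apobec": apobec_spectrum(),
        "flat": flat_spectrum(),
    }
    spec = np.zeros(96)
    for name, w in parts.items():
        spec += w * templates[name]
    return spec / spec.sum()


def zero_rate_generator() -> ClassGenerator:
    """A generator with every rate at zero: no variants, diploid genome."""
    return ClassGenerator(name="empty", label="DDRwt", snv_mean=0.0, spectrum=flat_spectrum())


# ---------------------------------------------------------------------------
# variant construction helpers

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, exclude_first: str = "",
                exclude_last: str = "") -> str:
    seq = "".join(rng.choice(_BASES, size=n))
    if exclude_first and seq and seq[0] in exclude_first:
        pool = [b for b in "ACGT" if b not in exclude_first]
        seq = str(rng.choice(pool)) + seq[1:]
    if exclude_last and seq and seq[-1] in exclude_last:
        pool = [b for b in "ACGT" if b not in exclude_last]
        seq = seq[:-1] + str(rng.choice(pool))
    return seq


def _random_position(rng: np.random.Generator) -> tuple[str, int]:
    names = list(GENOME)
    lengths = np.array([GENOME[n][0] for n in names], dtype=float)
    chrom = names[int(rng.choice(len(names), p=lengths / lengths.sum()))]
    return chrom, int(rng.integers(100, GENOME[chrom][0] - 100))


def _pileup_fields(rng: np.random.Generator) -> dict:
    depth = int(rng.integers(120, 281))
    vaf = float(rng.uniform(0.08, 0.45))
    alt = min(depth, max(10, int(round(vaf * depth))))
    return {
        "tumour_depth": depth,
        "tumour_alt": alt,
        "normal_depth": int(rng.integers(80, 201)),
        "normal_alt": 0,
        "mean_end_distance": float(np.round(rng.uniform(15, 40), 1)),
    }


def _make_snv(rng: np.random.Generator, channel: str) -> VariantRecord:
    left, ref, alt, right = channel[0], channel[2], channel[4], channel[6]
    tri = left + ref + right
    flank_l = _random_seq(rng, 19)
    flank_r = _random_seq(rng, 19)
    context = flank_l + tri + flank_r
    if rng.random() < 0.5:  # emit on the purine strand
        context, ref, alt = revcomp(context), revcomp(ref), revcomp(alt)
    chrom, pos = _random_position(rng)
    return VariantRecord(chrom=chrom, pos=pos, ref=context[20], alt=alt,
                         context=context, **_pileup_fields(rng))


def _make_deletion(rng: np.random.Generator, deleted: str, left20: str,
                   right20: str) -> VariantRecord:
    chrom, pos = _random_position(rng)
    anchor = left20[-1]
    context = left20 + deleted + right20
    return VariantRecord(chrom=chrom, pos=pos, ref=anchor + deleted, alt=anchor,
                         context=context, **_pileup_fields(rng))


def _hpoly_deletion(rng: np.random.Generator, base: str) -> VariantRecord:
    """1 bp deletion inside a >=6 bp homopolymer (channel 1:Del:<base>:5)."""
    run = int(rng.integers(5, 9))
    left = _random_seq(rng, 20, exclude_last=base)
    right = base * run + _random_seq(rng, 20 - run, exclude_first=base)
    return _make_deletion(rng, base, left, right)


def _insertion_1bp(rng: np.random.Generator, base: str = "T") -> VariantRecord:
    run = int(rng.integers(1, 4))
    left = _random_seq(rng, 20, exclude_last=base)
    right = base * run + _random_seq(rng, 20 - run, exclude_first=base)
    chrom, pos = _random_position(rng)
    anchor = left[-1]
    return VariantRecord(chrom=chrom, pos=pos, ref=anchor, alt=anchor + base,
                         context=left + right, **_pileup_fields(rng))


def _microhomology_deletion(rng: np.random.Generator) -> VariantRecord:
    L = int(rng.integers(3, 6))
    while True:
        seq = _random_seq(rng, L)
        if len(set(seq)) > 1:
            break
    mh = int(rng.integers(1, min(L - 1, 3) + 1))
    left = _random_seq(rng, 20, exclude_last=seq[-1])
    tail = _random_seq(rng, 20 - mh, exclude_first=seq[mh] if mh < L else "")
    right = seq[:mh] + tail
    return _make_deletion(rng, seq, left, right)


def _long_deletion(rng: np.random.Generator) -> VariantRecord:
    L = int(rng.integers(5, 12))
    while True:
        seq = _random_seq(rng, L)
        if len(set(seq)) > 1:
            break
    left = _random_seq(rng, 20, exclude_last=seq[-1])
    right = _random_seq(rng, 20, exclude_first=seq[0])
    return _make_deletion(rng, seq, left, right)


def _repeat_deletion(rng: np.random.Generator) -> VariantRecord:
    while True:
        seq = _random_seq(rng, 2)
        if seq[0] != seq[1]:
            break
    copies = int(rng.integers(1, 3))
    left = _random_seq(rng, 20, exclude_last=seq[-1])
    tail = _random_seq(rng, 20 - 2 * copies, exclude_first=seq[0])
    right = seq * copies + tail
    return _make_deletion(rng, seq, left, right)


def _spoil(rng: np.random.Generator, record: VariantRecord) -> VariantRecord:
    """Corrupt one filter rule so the record deliberately fails."""
    choice = rng.integers(0, 3)
    if choice == 0:   # sub-threshold VAF
        return replace(record, tumour_depth=600, tumour_alt=10)
    if choice == 1:   # read-end artifact
        return replace(record, mean_end_distance=3.0)
    return replace(record, normal_depth=25)  # shallow normal


# ---------------------------------------------------------------------------
# segment construction


def _allele_split(rng: np.random.Generator, total: int, loh: bool) -> tuple[int, int]:
    if total == 0:
        return 0, 0
    if loh or total == 1:
        return total, 0
    minor = int(rng.integers(1, total // 2 + 1))
    return total - minor, minor


def _arm_pieces(rng: np.random.Generator, gen: ClassGenerator, start: int, end: int,
                base: int) -> list[tuple[int, int, int, int, int]]:
    """Rearranged arm: contiguous pieces with varied copy states."""
    pieces = []
    pos = start
    lo, hi = gen.arm_piece_mb
    while pos <= end:
        length = int(rng.uniform(lo, hi) * MB)
        stop = min(pos + length - 1, end)
        delta = int(rng.choice([-1, 0, 1, 2], p=[0.3, 0.2, 0.3, 0.2]))
        total = max(0, base + delta)
        loh = bool(rng.random() < gen.loh_rate)
        major, minor = _allele_split(rng, total, loh)
        pieces.append((pos, stop, total, major, minor))
        pos = stop + 1
    return pieces


def _insert_duplications(rng: np.random.Generator, gen: ClassGenerator,
                         pieces: list[tuple[int, int, int, int, int]]) -> list:
    """Split background pieces with focal tandem-duplication spikes."""
    out = []
    for (start, end, total, major, minor) in pieces:
        n_dups = rng.poisson(gen.dup_rate_per_arm) if gen.dup_rate_per_arm else 0
        cuts = []
        for _ in range(n_dups):
            dup_len = int(rng.integers(gen.dup_len_range[0], gen.dup_len_range[1] + 1))
            if end - start < 3 * dup_len + 2:
                continue
            dup_start = int(rng.integers(start + dup_len, end - 2 * dup_len))
            cuts.append((dup_start, dup_start + dup_len - 1))
        cuts.sort()
        pruned = []
        last_end = start - 1
        for s, e in cuts:
            if s > last_end + 1:
                pruned.append((s, e))
                last_end = e
        pos = start
        deltas = [d for d, _ in gen.dup_delta_choices]
        probs = [p for _, p in gen.dup_delta_choices]
        for s, e in pruned:
            if s > pos:
                out.append((pos, s - 1, total, major, minor))
            delta = int(rng.choice(deltas, p=np.asarray(probs) / sum(probs)))
            out.append((s, e, total + delta, major + delta, minor))
            pos = e + 1
        if pos <= end:
            out.append((pos, end, total, major, minor))
    return out


def _sample_segments(rng: np.random.Generator, gen: ClassGenerator) -> list[CopySegment]:
    base = 4 if rng.random() < gen.wgd_prob else 2
    segments: list[CopySegment] = []
    for chrom, (length, cen) in GENOME.items():
        arm_bounds = [(1, cen), (cen + 1, length)]
        rearranged = [rng.random() < gen.arm_event_rate for _ in arm_bounds]
        chrom_pieces = []
        for (start, end), hit in zip(arm_bounds, rearranged):
            if hit:
                pieces = _arm_pieces(rng, gen, start, end, base)
            else:
                major, minor = _allele_split(rng, base, loh=False) if base != 2 else (1, 1)
                if base == 4:
                    major, minor = 2, 2
                pieces = [(start, end, base, major, minor)]
            pieces = _insert_duplications(rng, gen, pieces)
            chrom_pieces.extend(pieces)
        if not any(rearranged) and len(chrom_pieces) == 2 and gen.dup_rate_per_arm == 0:
            # untouched chromosome: one segment spanning it
            (s1, _, t, a, b) = chrom_pieces[0]
            chrom_pieces = [(1, length, t, a, b)]
        for (s, e, t, a, b) in chrom_pieces:
            segments.append(CopySegment(chrom=chrom, start=s, end=e,
                                        total_cn=t, major_cn=a, minor_cn=b))
    return segments


# ---------------------------------------------------------------------------
# sample / cohort simulation


def simulate_sample(
    generator: ClassGenerator, seed: int | np.random.Generator
) -> tuple[list[VariantRecord], list[CopySegment], str]:
    """Generate one sample's variant records and segments for its class."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    variants: list[VariantRecord] = []

    def draw(mean: float) -> int:
        # per-sample, per-program lognormal overdispersion: real burdens vary
        # far beyond Poisson, and no single feature should separate cleanly
        if mean <= 0:
            return 0
        factor = rng.lognormal(0.0, generator.burden_dispersion)
        return int(rng.poisson(mean * factor))

    n_snv = draw(generator.snv_mean)
    channel_counts = rng.multinomial(n_snv, generator.spectrum) if n_snv else np.zeros(96, int)
    for channel, count in zip(SBS96_CHANNELS, channel_counts):
        for _ in range(count):
            variants.append(_make_snv(rng, channel))
    for _ in range(draw(generator.hpoly_del_c_mean)):
        variants.append(_hpoly_deletion(rng, "C"))
    for _ in range(draw(generator.hpoly_del_t_mean)):
        variants.append(_hpoly_deletion(rng, "T"))
    for _ in range(draw(generator.ins_1bp_mean)):
        variants.append(_insertion_1bp(rng))
    for _ in range(draw(generator.mh_del_mean)):
        variants.append(_microhomology_deletion(rng))
    for _ in range(draw(generator.long_del_mean)):
        variants.append(_long_deletion(rng))
    for _ in range(draw(generator.rep_del_mean)):
        variants.append(_repeat_deletion(rng))
    if generator.filter_fail_fraction > 0:
        variants = [
            _spoil(rng, v) if rng.random() < generator.filter_fail_fraction else v
            for v in variants
        ]
    segments = _sample_segments(rng, generator)
    return variants, segments, generator.label


@dataclass
class SimulatedCohort:
    """In-memory cohort: per-sample variants/segments plus the arm map."""

    samples: list[tuple[str, str, list[VariantRecord], list[CopySegment]]]
    arm_map: ArmMap = field(default_factory=default_arm_map)

    def labels(self) -> pd.Series:
        return pd.Series({sid: label for sid, label, _, _ in self.samples}, name="label")

    def feature_matrix(self) -> tuple[pd.DataFrame, pd.Series]:
        """Extract the 224-feature profile for every sample."""
        rows = []
        for sid, _label, variants, segments in self.samples:
            catalog = build_catalog(variants, sid)
            rows.append(build_profile(catalog, segments, self.arm_map))
        X = pd.DataFrame(rows)
        return X, self.labels()


def simulate_cohort(
    n_per_class: int,
    seed: int,
    generators: dict[str, ClassGenerator] | None = None,
    out_dir: str | Path | None = None,
) -> SimulatedCohort:
    """Simulate a labelled cohort; optionally write it in the I/O dialects.

    Per-sample RNG streams are spawned from (seed, class index, sample
    index), so outputs are reproducible per seed and independent of class
    subset ordering.
    """
    if generators is None:
        generators = {
            k: v for k, v in default_generators().items() if k != "BLCA_like"
        }
    samples = []
    for ci, (name, gen) in enumerate(sorted(generators.items())):
        for si in range(n_per_class):
            rng = np.random.default_rng([seed, ci, si])
            variants, segments, label = simulate_sample(gen, rng)
            sid = f"{name}_{si:03d}"
            samples.append((sid, label, variants, segments))
    cohort = SimulatedCohort(samples=samples)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: SimulatedCohort, out_dir: Path) -> None:
    (out_dir / "variants").mkdir(parents=True, exist_ok=True)
    (out_dir / "segments").mkdir(parents=True, exist_ok=True)
    for sid, _label, variants, segments in cohort.samples:
        write_variants(variants, out_dir / "variants" / f"{sid}.tsv")
        total = sum(s.length for s in segments)
        ploidy = sum(s.total_cn * s.length for s in segments) / total if total else 2.0
        write_segments(
            SegmentationSolution(segments=segments, cellularity=0.4, mean_ploidy=ploidy),
            out_dir / "segments" / f"{sid}.tsv",
        )
    cohort.labels().rename_axis("sample").reset_index().to_csv(
        out_dir / "labels.tsv", sep="\t", index=False
    )
    write_cytobands(cohort.arm_map, out_dir / "cytobands.tsv")


# ---------------------------------------------------------------------------
# miniature sequence reference


def write_reference(path: str | Path, seed: int = 0, n_contigs: int = 3,
                    contig_length: int = 1_000_000) -> None:
    """Write a small synthetic FASTA with embedded homopolymers and repeats.

    Synthetic stand-in for a real reference: used only to exercise
    context fetching end to end, never as a biological sequence.
    """
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for i in range(n_contigs):
            seq = list("".join(rng.choice(_BASES, size=contig_length)))
            for _ in range(contig_length // 10_000):  # homopolymer tracts
                start = int(rng.integers(0, contig_length - 30))
                base = str(rng.choice(_BASES))
                run = int(rng.integers(6, 15))
                seq[start : start + run] = base * run
            for _ in range(contig_length // 20_000):  # tandem repeats
                unit = "".join(rng.choice(_BASES, size=int(rng.integers(2, 5))))
                copies = int(rng.integers(3, 8))
                start = int(rng.integers(0, contig_length - len(unit) * copies - 1))
                seq[start : start + len(unit) * copies] = unit * copies
            text = "".join(seq)
            fh.write(f">contig{i + 1}\n")
            for j in range(0, len(text), 80):
                fh.write(text[j : j + 80] + "\n")
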