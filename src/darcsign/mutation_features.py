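"""SBS96 and ID83 mutation channel classification and per-sample catalogs.

SBS96: single-base substitutions keyed by the pyrimidine-strand
substitution (C>A, C>G, C>T, T>A, T>C, T>G) and the two flanking bases;
purine-reference variants are reverse-complemented before assignment.

ID83: small insertions/deletions keyed by length, homopolymer/tandem-repeat
context, and (for non-repeat deletions of >= 2 bp) microhomology with the
adjacent flank.  Channel naming follows the canonical 83-channel scheme,
e.g. ``1:Del:C:5`` = a 1 bp cytosine deletion inside a homopolymer of six
or more C's (counting the deleted base) — the hallmark of replication
slippage under mismatch-repair deficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ValidationError, VariantRecord, _strip_anchor

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _sbs96_channels() -> tuple[str, ...]:
    subs = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
    return tuple(
        f"{l}[{r}>{a}]{t}" for (r, a) in subs for l in "ACGT" for t in "ACGT"
    )


def _id83_channels() -> tuple[str, ...]:
    chans: list[str] = []
    for base in ("C", "T"):
        chans += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in ("C", "T"):
        chans += [f"1:Ins:{base}:{i}" for i in range(6)]
    for length in (2, 3, 4, 5):
        chans += [f"{length}:Del:R:{i}" for i in range(6)]
    for length in (2, 3, 4, 5):
        chans += [f"{length}:Ins:R:{i}" for i in range(6)]
    chans += ["2:Del:M:1"]
    chans += [f"3:Del:M:{i}" for i in (1, 2)]
    chans += [f"4:Del:M:{i}" for i in (1, 2, 3)]
    chans += [f"5:Del:M:{i}" for i in (1, 2, 3, 4, 5)]
    return tuple(chans)


SBS96_CHANNELS: tuple[str, ...] = _sbs96_channels()
ID83_CHANNELS: tuple[str, ...] = _id83_channels()
assert len(SBS96_CHANNELS) == 96 and len(ID83_CHANNELS) == 83


def classify_sbs(ref: str, alt: str, context: str) -> str | None:
    """Assign an SNV to one of the 96 trinucleotide channels.

    ``context`` is the trinucleotide centred on the variant (a longer
    odd-length window is trimmed to its central three bases).  Returns
    None (unclassified) for N-containing contexts.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValidationError(f"not a simple SNV: {ref}>{alt}")
    if len(context) < 3 or len(context) % 2 == 0:
        raise ValidationError(f"context must have odd length >= 3, got {len(context)}")
    mid = len(context) // 2
    tri = context[mid - 1 : mid + 2].upper()
    if tri[1] != ref.upper():
        raise ValidationError(f"context centre {tri[1]} != ref {ref}")
    if any(b not in "ACGT" for b in tri) or alt.upper() not in "ACGT":
        return None
    ref, alt = ref.upper(), alt.upper()
    if ref in "AG":  # purine reference: use the pyrimidine strand
        tri = revcomp(tri)
        ref = tri[1]
        alt = revcomp(alt)
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


def _run_length(seq: str, base: str, reverse: bool = False) -> int:
    """Length of the run of ``base`` at the start (or end) of ``seq``."""
    it = reversed(seq) if reverse else iter(seq)
    n = 0
    for b in it:
        if b != base:
            break
        n += 1
    return n


def _tandem_copies(seq: str, flank: str, reverse: bool = False) -> int:
    """Full adjacent copies of ``seq`` at the start (or end) of ``flank``."""
    L = len(seq)
    n = 0
    if reverse:
        while len(flank) >= (n + 1) * L and \
                flank[len(flank) - (n + 1) * L : len(flank) - n * L] == seq:
            n += 1
    else:
        while flank[n * L : (n + 1) * L] == seq:
            n += 1
    return n


def _overlap_prefix(a: str, b: str, cap: int) -> int:
    """Longest k <= cap with a[:k] == b[:k]."""
    k = 0
    while k < cap and k < len(a) and k < len(b) and a[k] == b[k]:
        k += 1
    return k


def classify_indel(ref: str, alt: str, left_flank: str, right_flank: str) -> str | None:
    """Assign a left-normalized indel to one of the 83 indel channels.

    ``left_flank``/``right_flank`` are the reference sequences immediately
    5' and 3' of the inserted/deleted tract.  Complex substitutions (both
    alleles longer than one base after anchor stripping) return None.
    """
    r, a = _strip_anchor(ref.upper(), alt.upper())
    if len(r) > 0 and len(a) > 0:
        return None  # complex / multi-base substitution
    if len(r) == len(a):
        raise ValidationError(f"not an indel: {ref}>{alt}")
    is_del = len(r) > 0
    seq = r if is_del else a
    if any(b not in "ACGT" for b in seq):
        return None
    L = len(seq)

    if L == 1:
        base = seq
        run = _run_length(left_flank, base, reverse=True) + _run_length(right_flank, base)
        if is_del:
            run += 1  # homopolymer length counts the deleted base
            label = min(run, 6) - 1
            kind = "Del"
        else:
            label = min(run, 5)
            kind = "Ins"
        if base in "AG":
            base = revcomp(base)
        return f"1:{kind}:{base}:{label}"

    size = min(L, 5)
    copies = _tandem_copies(seq, right_flank) + _tandem_copies(seq, left_flank, reverse=True)
    if is_del:
        if copies >= 1:
            return f"{size}:Del:R:{min(copies, 5)}"
        mh = max(
            _overlap_prefix(seq, right_flank, L - 1),
            _overlap_prefix(seq[::-1], left_flank[::-1], L - 1),
        )
        if mh >= 1:
            return f"{size}:Del:M:{min(mh, 5)}"
        return f"{size}:Del:R:0"
    return f"{size}:Ins:R:{min(copies, 5)}"


def _record_flanks(record: VariantRecord) -> tuple[str, str]:
    """Split an indel record's context into (left, right) flank sequences."""
    r, a = _strip_anchor(record.ref.upper(), record.alt.upper())
    tract = len(r)  # deleted bases present in the reference context
    f = record.flank
    return record.context[:f].upper(), record.context[f + tract :].upper()


def classify_record(record: VariantRecord) -> tuple[str | None, str | None]:
    """Classify a record; returns ("sbs"|"indel"|None, channel or None)."""
    if record.is_snv:
        return "sbs", classify_sbs(record.ref, record.alt, record.context)
    if record.is_indel:
        left, right = _record_flanks(record)
        return "indel", classify_indel(record.ref, record.alt, left, right)
    return None, None  # complex substitution


@dataclass
class MutationCatalog:
    """Per-sample counts over the 96 SBS and 83 indel channels."""

    sample_id: str
    sbs_counts: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=int))
    indel_counts: np.ndarray = field(default_factory=lambda: np.zeros(83, dtype=int))
    unclassified: int = 0

    def __post_init__(self) -> None:
        self.sbs_counts = np.asarray(self.sbs_counts, dtype=int)
        self.indel_counts = np.asarray(self.indel_counts, dtype=int)
        if self.sbs_counts.shape != (96,) or self.indel_counts.shape != (83,):
            raise ValidationError("catalog vectors must have lengths 96 and 83")
        if (self.sbs_counts < 0).any() or (self.indel_counts < 0).any():
            raise ValidationError("catalog counts must be non-negative")

    @property
    def n_variants(self) -> int:
        return int(self.sbs_counts.sum() + self.indel_counts.sum() + self.unclassified)

    def sbs_series(self) -> pd.Series:
        return pd.Series(self.sbs_counts, index=list(SBS96_CHANNELS), name=self.sample_id)

    def indel_series(self) -> pd.Series:
        return pd.Series(self.indel_counts, index=list(ID83_CHANNELS), name=self.sample_id)


def build_catalog(records: list[VariantRecord], sample_id: str) -> MutationCatalog:
    """Count passing variants into a per-sample mutation catalog.

    Every input contributes exactly once: to an SBS channel, to an indel
    channel, or to the ``unclassified`` tally (complex substitutions and
    degenerate contexts are never silently dropped).
    """
    sbs_index = {c: i for i, c in enumerate(SBS96_CHANNELS)}
    id_index = {c: i for i, c in enumerate(ID83_CHANNELS)}
    catalog = MutationCatalog(sample_id=sample_id)
    for record in records:
        kind, channel = classify_record(record)
        if kind == "sbs" and channel is not None:
            catalog.sbs_counts[sbs_index[channel]] += 1
        elif kind == "indel" and channel is not None:
            catalog.indel_counts[id_index[channel]] += 1
        else:
            catalog.unclassified += 1
    return catalog


def catalogs_to_frame(catalogs: list[MutationCatalog]) -> pd.DataFrame:
    """Channels (rows, canonical order) x samples matrix, signature-tool layout."""
    cols = {
        c.sample_id: np.concatenate([c.sbs_counts, c.indel_counts]) for c in catalogs
    }
    return pd.DataFrame(cols, index=list(SBS96_CHANNELS) + list(ID83_CHANNELS))
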