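"""Independent brute-force oracles, written without reference to the
package implementations: plain loops, groupby runs and direct definitions.
They are deliberately naive and O(n^2)-ish."""

from itertools import takewhile
from os.path import commonprefix


# --------------------------------------------------------------------------
# SBS96 via explicit complement tables

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_sbs(ref, alt, tri):
    if any(b not in _COMP for b in tri) or alt not in _COMP:
        return None
    if ref in ("A", "G"):
        tri = "".join(_COMP[b] for b in reversed(tri))
        ref = tri[1]
        alt = _COMP[alt]
    return tri[0] + "[" + ref + ">" + alt + "]" + tri[2]


# --------------------------------------------------------------------------
# ID83 from the published decision tree, using takewhile/commonprefix

def _prefix_run(s, base):
    return len(list(takewhile(lambda b: b == base, s)))


def _copies_at_start(s, unit):
    n = 0
    while s.startswith(unit * (n + 1)):
        n += 1
    return n


def oracle_id83(seq, is_del, left, right):
    """seq = inserted/deleted bases; left/right = adjacent reference."""
    L = len(seq)
    if L == 1:
        base = seq
        run = _prefix_run(left[::-1], base) + _prefix_run(right, base)
        if is_del:
            run += 1
            klass = min(run, 6) - 1
            kind = "Del"
        else:
            klass = min(run, 5)
            kind = "Ins"
        pyr = _COMP[base] if base in ("A", "G") else base
        return f"1:{kind}:{pyr}:{klass}"
    size = min(L, 5)
    copies = _copies_at_start(right, seq) + _copies_at_start(left[::-1], seq[::-1])
    if not is_del:
        return f"{size}:Ins:R:{min(copies, 5)}"
    if copies >= 1:
        return f"{size}:Del:R:{min(copies, 5)}"
    mh_r = len(commonprefix([seq[:-1], right]))
    mh_l = len(commonprefix([seq[::-1][: L - 1], left[::-1]]))
    mh = max(mh_r, mh_l)
    if mh >= 1:
        return f"{size}:Del:M:{min(mh, 5)}"
    return f"{size}:Del:R:0"


# --------------------------------------------------------------------------
# copy-number category oracles (operate on (chrom, start, end, t, a, b))

def _per_chrom(rows):
    out = {}
    for row in rows:
        out.setdefault(row[0], []).append(row)
    return {c: sorted(v, key=lambda r: r[1]) for c, v in out.items()}


def oracle_bc10(rows, chrom_lengths, window=10_000_000, nmax=5):
    hist = [0] * (nmax + 1)
    per = _per_chrom(rows)
    for chrom, length in chrom_lengths.items():
        n_win = (length + window - 1) // window
        ends = [r[2] for r in per.get(chrom, [])][:-1]  # last endpoint excluded
        for w in range(n_win):
            lo, hi = w * window + 1, (w + 1) * window
            c = sum(1 for e in ends if lo <= e <= hi)
            hist[min(c, nmax)] += 1
    return hist


def oracle_bcperca(rows, arms, nmax=5):
    """arms: list of (chrom, start, end)."""
    hist = [0] * (nmax + 1)
    for chrom, a_start, a_end in arms:
        n = 0
        for (c, s, e, *_rest) in rows:
            if c == chrom and not (e < a_start or s > a_end):
                n += 1
        hist[min(max(n - 1, 0), nmax)] += 1
    return hist


def oracle_cn_counts(rows, smax=8):
    hist = [0] * (smax + 1)
    for (_c, _s, _e, t, _a, _b) in rows:
        hist[min(t, smax)] += 1
    return hist


def oracle_copy_fraction(rows, smax=8):
    hist = [0.0] * (smax + 1)
    total = sum(e - s + 1 for (_c, s, e, *_r) in rows)
    if total == 0:
        return hist
    for (_c, s, e, t, _a, _b) in rows:
        hist[min(t, smax)] += (e - s + 1) / total
    return hist


def oracle_segsize(rows, edges):
    hist = [0] * (len(edges) + 1)
    for (_c, s, e, *_r) in rows:
        length = e - s + 1
        i = 0
        while i < len(edges) and length > edges[i]:
            i += 1
        hist[i] += 1
    return hist


def oracle_cncp(rows, dmax=5):
    hist = [0] * dmax
    for segs in _per_chrom(rows).values():
        for i in range(1, len(segs)):
            d = abs(segs[i][3] - segs[i - 1][3])
            if d > 0:
                hist[min(d, dmax) - 1] += 1
    return hist


def oracle_hrd_loh(rows, min_len=15_000_000):
    n = 0
    for segs in _per_chrom(rows).values():
        span = (segs[0][1], segs[-1][2])
        loh_flags = [(r, r[5] == 0 and r[3] >= 1) for r in segs]
        # merged runs must be truly adjacent (no gap) per the definition
        merged = []
        for r, is_loh in loh_flags:
            if not is_loh:
                continue
            if merged and r[1] == merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], r[2])
            else:
                merged.append((r[1], r[2]))
        for start, end in merged:
            if end - start + 1 > min_len and (start, end) != span:
                n += 1
    return n


def oracle_lst(rows, min_seg=10_000_000, max_gap=3_000_000):
    n = 0
    for segs in _per_chrom(rows).values():
        for i in range(1, len(segs)):
            a, b = segs[i - 1], segs[i]
            len_a = a[2] - a[1] + 1
            len_b = b[2] - b[1] + 1
            gap = b[1] - a[2] - 1
            if len_a >= min_seg and len_b >= min_seg and gap <= max_gap \
                    and (a[3], a[5]) != (b[3], b[5]):
                n += 1
    return n


def oracle_tai(rows, chrom_lengths, tol=10_000):
    n = 0
    for chrom, segs in _per_chrom(rows).items():
        length = chrom_lengths[chrom]
        for (_c, s, e, _t, a, b) in segs:
            if a == b:
                continue
            lo = s <= 1 + tol
            hi = e >= length - tol
            if lo and hi:
                continue
            if lo or hi:
                n += 1
    return n


# --------------------------------------------------------------------------
# random segment genomes for the oracle-equivalence checks

def random_genome(rng, chrom_lengths, max_segments=12):
    """Random sorted, non-overlapping segments with random copy states."""
    import numpy as np

    rows = []
    for chrom, length in chrom_lengths.items():
        n = int(rng.integers(1, max_segments + 1))
        cuts = np.unique(rng.integers(2, length, size=n - 1)) if n > 1 else []
        bounds = [1] + [int(c) for c in cuts] + [length + 1]
        for i in range(len(bounds) - 1):
            start, end = bounds[i], bounds[i + 1] - 1
            if rng.random() < 0.1:  # leave a gap
                shrink = int((end - start) * rng.uniform(0, 0.3))
                end -= shrink
            total = int(rng.integers(0, 9))
            if total == 0:
                major = minor = 0
            else:
                minor = int(rng.integers(0, total // 2 + 1))
                major = total - minor
            rows.append((chrom, start, end, total, major, minor))
            pos = end + 1
    return rows
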