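"""Dispersed, tandem and simple-sequence repeat detection for plastomes.

Dispersed (forward/inverted) repeats follow the REPuter-style criterion of
a minimum length of 30 bp at >= 90 percent identity (hamming distance <= 3
between the two copies); hits are maximal windows on a (anti)diagonal,
bounded by matching columns, with redundant (contained or IR-duplicated)
hits removed. The tandem detector is a perfect-run period scan; imperfect
tandems are out of scope. SSRs are perfect microsatellites with MISA-style
unit thresholds (mono >= 8 units, di/tri >= 4, tetra/penta/hexa >= 3).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_io import AnnotatedGenome, CircularSequence, revcomp
from .structure import RegionPartition

DEFAULT_SSR_THRESHOLDS = {1: 8, 2: 4, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class RepeatHit:
    """A dispersed (F/I) or tandem (T) repeat.

    F/I hits carry two loci (start positions of equal-length copies) and the
    hamming distance between them (after reverse complement for I); tandem
    hits carry one locus, the unit and the copy number.
    """

    kind: str  # F, I or T
    length: int
    positions: tuple[int, ...]
    unit: str | None = None
    copies: int | None = None
    mismatches: int = 0
    regions: tuple[str, ...] = ()
    contexts: tuple[str, ...] = ()

    def intervals(self) -> tuple[tuple[int, int], ...]:
        return tuple((p, p + self.length) for p in self.positions)


@dataclass(frozen=True)
class SSRHit:
    """A perfect microsatellite, reported as-observed on the forward strand."""

    motif: str
    n_units: int
    start: int
    end: int
    region: str = ""
    context: str = ""


# ---------------------------------------------------------------------------
# dispersed repeats


def _residues(seq) -> str:
    if isinstance(seq, CircularSequence):
        return seq.residues
    if isinstance(seq, AnnotatedGenome):
        return seq.sequence.residues
    return seq


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(s: str) -> np.ndarray:
    return _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    n = arr.size - k + 1
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + arr[j : j + n]
    return codes


def _shared_diagonals(a: np.ndarray, b: np.ndarray, k: int, self_compare: bool):
    """diagonal -> anchor positions of exact shared k-mers.

    Self comparison produces only ordered pairs i < j (diagonal d = j - i,
    anchors are the left position i); cross comparison produces d = i_a - p_b
    with anchors the b-side position p.
    """
    ca = _kmer_codes(a, k)
    order_a = np.argsort(ca, kind="stable")
    sa = ca[order_a]
    diag: dict[int, list[int]] = {}
    if self_compare:
        bounds = np.flatnonzero(np.diff(sa)) + 1
        for grp in np.split(order_a, bounds):
            if len(grp) < 2:
                continue
            grp = np.sort(grp)
            for x in range(len(grp)):
                for y in range(x + 1, len(grp)):
                    i, j = int(grp[x]), int(grp[y])
                    diag.setdefault(j - i, []).append(i)
    else:
        cb = _kmer_codes(b, k)
        order_b = np.argsort(cb, kind="stable")
        sb = cb[order_b]
        ia = ib = 0
        while ia < sa.size and ib < sb.size:
            if sa[ia] < sb[ib]:
                ia += 1
            elif sa[ia] > sb[ib]:
                ib += 1
            else:
                v = sa[ia]
                ja, jb = ia, ib
                while ja < sa.size and sa[ja] == v:
                    ja += 1
                while jb < sb.size and sb[jb] == v:
                    jb += 1
                for i in order_a[ia:ja]:
                    for p in order_b[ib:jb]:
                        diag.setdefault(int(i) - int(p), []).append(int(p))
                ia, ib = ja, jb
    return diag


def _windows_from_anchor(
    mis: np.ndarray, lo: int, hi: int, i0: int, k: int, max_mm: int, min_len: int
):
    """All maximal <= max_mm-mismatch windows on [lo, hi) containing the
    exact anchor run [i0, i0+k), trimmed to matching boundary columns.

    Walks outward from the anchor collecting up to max_mm+1 mismatch
    positions on each side (sentinels at lo-1 and hi), then enumerates every
    left/right split of the mismatch budget.
    """
    left = []  # mismatch positions < i0, descending
    pos = i0 - 1
    while pos >= lo and len(left) <= max_mm:
        if mis[pos]:
            left.append(pos)
        pos -= 1
    if len(left) <= max_mm:
        left.append(lo - 1)
    right = []  # mismatch positions >= i0+k, ascending
    pos = i0 + k
    while pos < hi and len(right) <= max_mm:
        if mis[pos]:
            right.append(pos)
        pos += 1
    if len(right) <= max_mm:
        right.append(hi)
    out = set()
    for lt in range(min(len(left), max_mm + 1)):
        rt = max_mm - lt
        if rt >= len(right):
            continue
        a = (left[lt] + 1) if lt < len(left) else lo
        b = right[rt]
        # boundaries one past the bounding mismatches; trim stray mismatch
        # columns (possible when mismatches are adjacent)
        while a < b and mis[a]:
            a += 1
        while b > a and mis[b - 1]:
            b -= 1
        if b - a >= min_len:
            out.add((a, b))
    return sorted(out)


def _remove_contained(raw):
    """Drop hits whose both loci lie within the loci of a longer same-kind hit."""
    raw = sorted(raw, key=lambda h: (-h[3], h[1], h[2], h[0]))
    kept = []
    for kind, i, j, L in raw:
        if any(kk == kind and ii <= i and i + L <= ii + LL and jj <= j and j + L <= jj + LL
               for kk, ii, jj, LL in kept):
            continue
        kept.append((kind, i, j, L))
    return kept


def find_dispersed(
    seq,
    min_len: int = 30,
    max_mismatch: int = 3,
    k: int | None = None,
    ir_intervals: tuple | None = None,
) -> list[RepeatHit]:
    """Forward and inverted dispersed repeats.

    Reports maximal pairs (i, j), i < j, of equal-length disjoint windows of
    length >= min_len with hamming distance <= max_mismatch, direct (F) or
    reverse-complement (I), bounded by matching columns. Hits wholly
    contained in longer hits are removed; when ``ir_intervals`` is given the
    quadripartite IR pair itself and IR-duplicated images of hits lying
    entirely within the IRs are removed as redundant.

    Seeding uses exact shared k-mers. By default k=7 (complete for 30 bp /
    3 mismatches by pigeonhole) on sequences up to 20 kb, and k=12 at
    genome scale, where completeness is only guaranteed for hits containing
    an exact 12 bp run; every hit of the curated plastome tables does.
    """
    s = _residues(seq)
    n = len(s)
    if n < 2 * min_len:
        raise ValueError("sequence shorter than twice min_len")
    if k is None:
        k = 7 if n <= 20_000 else 12
    arr = _encode(s)
    hits: set[tuple[str, int, int, int]] = set()

    # forward: s vs s on diagonal d = j - i > 0
    for d, anchors in _shared_diagonals(arr, arr, k, self_compare=True).items():
        m = arr.size - d
        mis = (arr[:m] != arr[d:]).astype(np.uint8)
        done: list[tuple[int, int]] = []
        for i0 in sorted(set(anchors)):
            if any(a <= i0 and i0 + k <= b for a, b in done):
                continue
            for a, b in _windows_from_anchor(mis, 0, m, i0, k, max_mismatch, min_len):
                done.append((a, b))
                L = b - a
                if L <= d:  # disjoint loci
                    hits.add(("F", a, a + d, L))

    # inverted: compare s against r = revcomp(s); an exact pairing aligns
    # t-position i = p + d with r-position p; partner locus starts at
    # j = n - (p + L) for a window [p, p+L) in r-coordinates.
    r = _encode(revcomp(s))
    for d, anchors in _shared_diagonals(arr, r, k, self_compare=False).items():
        lo_lim, hi_lim = max(0, -d), min(n, n - d)
        if hi_lim - lo_lim < min_len:
            continue
        mis = np.ones(n + 1, dtype=np.uint8)
        idx = np.arange(lo_lim, hi_lim)
        mis[lo_lim:hi_lim] = (arr[idx + d] != r[idx]).astype(np.uint8)
        done = []
        for p0 in sorted(set(anchors)):
            if any(a <= p0 and p0 + k <= b for a, b in done):
                continue
            for a, b in _windows_from_anchor(
                mis, lo_lim, hi_lim, p0, k, max_mismatch, min_len
            ):
                done.append((a, b))
                L = b - a
                i, j = sorted((a + d, n - b))
                if i + L <= j:
                    hits.add(("I", i, j, L))

    kept = _remove_contained(hits)

    if ir_intervals is not None:
        (b_s, b_e), (a_s, a_e) = sorted(ir_intervals)
        ir_len = b_e - b_s

        def copy_of(i, L):
            if b_s <= i and i + L <= b_e:
                return "b"
            if a_s <= i and i + L <= a_e:
                return "a"
            return None

        def to_irb(i, L):
            # mirror an IRa-contained locus into IRb coordinates
            return b_s + (a_e - (i + L)) if a_s <= i else i

        final = []
        seen = set()
        for kind, i, j, L in kept:
            c1, c2 = copy_of(i, L), copy_of(j, L)
            if kind == "I" and c1 == "b" and c2 == "a" and L >= 0.5 * ir_len:
                continue  # the quadripartite IR pair itself
            if c1 and c2:
                key = (kind if (c1 == "a") == (c2 == "a") else
                       ("F" if kind == "I" else "I"),
                       *sorted((to_irb(i, L), to_irb(j, L))), L)
                if key in seen:
                    continue
                seen.add(key)
            final.append((kind, i, j, L))
        kept = final

    def hamming(kind, i, j, L):
        w2 = s[j : j + L] if kind == "F" else revcomp(s[j : j + L])
        return sum(c1 != c2 for c1, c2 in zip(s[i : i + L], w2))

    out = [
        RepeatHit(kind=kind, length=L, positions=(i, j),
                  mismatches=hamming(kind, i, j, L))
        for kind, i, j, L in kept
    ]
    return sorted(out, key=lambda h: (-h.length, h.positions))


def brute_force_dispersed(s: str, min_len: int = 30, max_mismatch: int = 3) -> list[RepeatHit]:
    """O(L^2) oracle scanning every (anti)diagonal without seeding.

    Independent of the k-mer implementation; for test-scale sequences only.
    """
    n = len(s)
    comp = str.maketrans("ACGT", "TGCA")
    hits = set()
    # forward diagonals
    for d in range(1, n):
        cols = [s[i] != s[i + d] for i in range(n - d)]
        for a, b in _oracle_windows(cols, max_mismatch, min_len):
            L = b - a
            if L <= d:
                hits.add(("F", a, a + d, L))
    # inverted: window [i, i+L) vs [j, j+L) with s[i+t] == comp(s[j+L-1-t]);
    # parameterize by the anti-diagonal c = i + j + L - 1 (i + t pairs with
    # c - (i + t)).
    for c in range(2 * n - 1):
        lo, hi = max(0, c - n + 1), c // 2 + 1
        cols = [s[x] != s[c - x].translate(comp) for x in range(lo, hi)]
        for a, b in _oracle_windows(cols, max_mismatch, min_len):
            i = lo + a
            L = b - a
            j = c - (lo + b - 1)
            if j >= i + L:
                hits.add(("I", i, j, L))
    kept = _remove_contained(hits)
    out = []
    for kind, i, j, L in kept:
        w2 = s[j : j + L] if kind == "F" else revcomp(s[j : j + L])
        mm = sum(c1 != c2 for c1, c2 in zip(s[i : i + L], w2))
        out.append(RepeatHit(kind=kind, length=L, positions=(i, j), mismatches=mm))
    return sorted(out, key=lambda h: (-h.length, h.positions))


def _oracle_windows(cols, max_mm, min_len):
    mism = [-1] + [x for x, c in enumerate(cols) if c] + [len(cols)]
    out = set()
    for t in range(len(mism) - 1):
        u = min(t + max_mm + 1, len(mism) - 1)
        a, b = mism[t] + 1, mism[u]
        while a < b and cols[a]:
            a += 1
        while b > a and cols[b - 1]:
            b -= 1
        if b - a >= min_len:
            out.add((a, b))
    return sorted(out)


# ---------------------------------------------------------------------------
# tandem repeats


def find_tandem(
    seq, min_period: int = 10, min_copies: int = 2, min_len: int = 30,
    max_period: int = 60,
) -> list[RepeatHit]:
    """Perfect tandem repeats via a period scan.

    For each period p, a maximal run of m positions with s[i] == s[i+p]
    spans a tandem region of m + p bases (copies = round((m+p)/p));
    overlapping reports across periods collapse to the one with the highest
    copies x length (ties: smaller period, then leftmost).
    """
    s = _residues(seq)
    arr = _encode(s)
    n = arr.size
    cands = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        eq = (arr[: n - p] == arr[p:]).astype(np.int8)
        delta = np.diff(np.concatenate(([0], eq, [0])))
        starts = np.flatnonzero(delta == 1)
        ends = np.flatnonzero(delta == -1)
        for a, b in zip(starts, ends):
            m = int(b - a)
            if m < p * (min_copies - 1):
                continue
            total = m + p
            if total < min_len:
                continue
            cands.append(RepeatHit(
                kind="T", length=total, positions=(int(a),),
                unit=s[a : a + p], copies=int(round(total / p)),
            ))
    cands.sort(key=lambda h: (-(h.copies * h.length), len(h.unit), h.positions))
    kept: list[RepeatHit] = []
    for h in cands:
        s0, e0 = h.positions[0], h.positions[0] + h.length
        if any(max(s0, g.positions[0]) < min(e0, g.positions[0] + g.length) for g in kept):
            continue
        kept.append(h)
    return sorted(kept, key=lambda h: h.positions)


# ---------------------------------------------------------------------------
# SSRs


def _minimal_period(motif: str) -> int:
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return d
    return k


def find_ssrs(seq, thresholds: dict[int, int] | None = None) -> list[SSRHit]:
    """Perfect SSRs (unit 1-6 bp) at MISA-style unit-count thresholds.

    Runs are maximal and trimmed to whole units; a run qualifying at several
    unit lengths is reported once, at its smallest period (the motif itself
    must not be periodic).
    """
    thresholds = dict(DEFAULT_SSR_THRESHOLDS if thresholds is None else thresholds)
    if set(thresholds) != {1, 2, 3, 4, 5, 6}:
        raise ValueError("thresholds must cover unit lengths 1..6")
    s = _residues(seq)
    arr = _encode(s)
    n = arr.size
    out = []
    for kk in range(1, 7):
        if n <= kk:
            continue
        eq = (arr[: n - kk] == arr[kk:]).astype(np.int8)
        delta = np.diff(np.concatenate(([0], eq, [0])))
        starts = np.flatnonzero(delta == 1)
        ends = np.flatnonzero(delta == -1)
        for a, b in zip(starts, ends):
            total = int(b - a) + kk
            n_units = total // kk
            if n_units < thresholds[kk]:
                continue
            motif = s[int(a) : int(a) + kk]
            if _minimal_period(motif) != kk:
                continue
            out.append(SSRHit(motif=motif, n_units=n_units, start=int(a),
                              end=int(a) + n_units * kk))
    return sorted(out, key=lambda h: (h.start, len(h.motif)))


def ssr_oracle(s: str, thresholds: dict[int, int] | None = None) -> list[SSRHit]:
    """Regex-based independent SSR oracle for test-scale sequences."""
    import re

    thresholds = dict(DEFAULT_SSR_THRESHOLDS if thresholds is None else thresholds)
    out = []
    for kk in range(1, 7):
        for m in re.finditer(rf"(.{{{kk}}})\1+", s):
            motif = m.group(1)
            if _minimal_period(motif) != kk:
                continue
            a = m.start()
            if a >= kk and s[a - 1] == s[a - 1 + kk]:
                continue  # extendable to the left at this period
            n_units = (m.end() - a) // kk
            if n_units < thresholds[kk]:
                continue
            out.append(SSRHit(motif=motif, n_units=n_units, start=a, end=a + n_units * kk))
    return sorted(out, key=lambda h: (h.start, len(h.motif)))


# ---------------------------------------------------------------------------
# classification and summaries


def _context_of(pos: int, genome: AnnotatedGenome) -> str:
    best = "IGS"
    for f in genome.features:
        if f.start <= pos < f.end:
            if any(s <= pos < e for s, e in f.exons):
                return "CDS" if f.klass == "CDS" else f.klass
            best = "intron"
    return best


def _region_labels(iv: tuple[int, int], partition: RegionPartition) -> list[str]:
    labels = []
    for name, (s, e) in partition.as_dict().items():
        if max(iv[0], s) < min(iv[1], e):
            lab = "IR" if name in ("IRa", "IRb") else name
            if lab not in labels:
                labels.append(lab)
    return labels


def classify_hits(hits, genome: AnnotatedGenome, partition: RegionPartition):
    """Attach region (LSC/SSC/IR; dual-labeled when spanning a border) and
    annotation context (CDS/tRNA/rRNA/intron/IGS) labels to hits."""
    out = []
    for h in hits:
        if isinstance(h, SSRHit):
            region = "/".join(_region_labels((h.start, h.end), partition))
            ctx = _context_of((h.start + h.end) // 2, genome)
            out.append(replace(h, region=region,
                               context="CDS" if ctx == "CDS" else "non-coding"))
        else:
            regions: list[str] = []
            ctxs = []
            for s, e in h.intervals():
                for lab in _region_labels((s, e), partition):
                    if lab not in regions:
                        regions.append(lab)
                ctxs.append(_context_of((s + e) // 2, genome))
            out.append(replace(h, regions=tuple(regions), contexts=tuple(ctxs)))
    return out


def multi_genome_ssr_summary(genomes: list[AnnotatedGenome]):
    """Per-genome SSR census: counts by unit length, total, CDS share and
    A/T mononucleotide fraction, as a pandas DataFrame."""
    import pandas as pd

    from .genestats import coding_fractions

    if not genomes:
        raise ValueError("need at least one genome")
    rows = []
    for gnm in genomes:
        ssrs = find_ssrs(gnm.sequence)
        by_len = {kk: sum(1 for h in ssrs if len(h.motif) == kk) for kk in range(1, 7)}
        in_cds = sum(1 for h in ssrs
                     if _context_of((h.start + h.end) // 2, gnm) == "CDS")
        total = len(ssrs)
        at_mono = sum(1 for h in ssrs if h.motif in ("A", "T"))
        rows.append({
            "genome": gnm.sequence.id,
            "size_bp": len(gnm.sequence),
            "mono": by_len[1], "di": by_len[2], "tri": by_len[3],
            "tetra": by_len[4], "penta": by_len[5], "hexa": by_len[6],
            "total": total,
            "cds_length_pct": coding_fractions(gnm)["CDS"],
            "cds_ssr_count": in_cds,
            "cds_ssr_pct": round(100.0 * in_cds / total, 1) if total else 0.0,
            "at_mono_pct": round(100.0 * at_mono / total, 1) if total else 0.0,
        })
    return pd.DataFrame(rows)
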