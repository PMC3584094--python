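"""Quadripartite structure: inverted-repeat detection, LSC/IRb/SSC/IRa
partitioning, per-region base composition, and IR-junction gene truncation.

The two IR copies are required to be exact reverse complements; the detector
finds the maximal pair of disjoint intervals on the circle satisfying that,
by k-mer anchoring against the reverse complement followed by maximal exact
extension.

Canonical linearization: LSC starts at position 0, region order
LSC -> IRb -> SSC -> IRa (IRb is the copy immediately downstream of LSC).
The input strand is preserved; only the rotation is normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import AnnotatedGenome, CircularSequence, GeneFeature, revcomp

_COMP = str.maketrans("ACGTN", "TGCAN")


class NoQuadripartiteStructure(ValueError):
    """No inverted-repeat pair of the required size was found."""


Interval = tuple[int, int]


@dataclass(frozen=True)
class RegionPartition:
    """The four regions on the canonical linearization (0-based half-open)."""

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    genome_length: int

    def __post_init__(self):
        covered = sum(e - s for s, e in (self.lsc, self.irb, self.ssc, self.ira))
        if covered != self.genome_length:
            raise ValueError("partition does not cover the genome")
        if (self.irb[1] - self.irb[0]) != (self.ira[1] - self.ira[0]):
            raise ValueError("IR copies differ in length")
        if (self.lsc[1] - self.lsc[0]) <= (self.ssc[1] - self.ssc[0]):
            raise ValueError("LSC must be longer than SSC")

    @property
    def ir_length(self) -> int:
        return self.irb[1] - self.irb[0]

    def as_dict(self) -> dict[str, Interval]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def region_of(self, pos: int) -> str:
        for name, (s, e) in self.as_dict().items():
            if s <= pos < e:
                return name
        raise IndexError(f"position {pos} outside genome")

    def validate(self, seq: CircularSequence) -> None:
        """Assert the IR reverse-complement identity on an actual sequence."""
        a = seq.fetch(*self.ira)
        b = seq.fetch(*self.irb)
        if a != revcomp(b):
            raise ValueError("IRa is not the exact reverse complement of IRb")


# ---------------------------------------------------------------------------
# Inverted-repeat detection


def _maximal_ir_pairs(t: str, k: int, min_len: int) -> list[tuple[int, int, int]]:
    """Maximal exact inverted pairs (i, j, L) in linear string t, i < j.

    Anchored on shared k-mers between t and revcomp(t), grouped by diagonal,
    then extended to maximal exact matches.
    """
    m = len(t)
    r = t.translate(_COMP)[::-1]
    index: dict[str, list[int]] = {}
    for i in range(m - k + 1):
        index.setdefault(t[i : i + k], []).append(i)
    # diagonal -> sorted anchor positions p (in r coordinates)
    diagonals: dict[int, list[int]] = {}
    for p in range(m - k + 1):
        for i in index.get(r[p : p + k], ()):
            diagonals.setdefault(i - p, []).append(p)
    out = set()
    for d, ps in diagonals.items():
        ps.sort()
        covered_to = -1
        for p in ps:
            if p <= covered_to:
                continue
            i = p + d
            # extend the exact match around (i, p)
            lo_p, hi_p = p, p + k  # [lo_p, hi_p) in r
            while lo_p > 0 and i - (p - lo_p) - 1 >= 0 and t[i - (p - lo_p) - 1] == r[lo_p - 1]:
                lo_p -= 1
            while hi_p < m and i + (hi_p - p) < m and t[i + (hi_p - p)] == r[hi_p]:
                hi_p += 1
            covered_to = hi_p - k
            L = hi_p - lo_p
            if L < min_len:
                continue
            i0 = lo_p + d
            j0 = m - hi_p  # start of the partner interval in t
            a, b = sorted(((i0, i0 + L), (j0, j0 + L)))
            if a[1] <= b[0]:  # disjoint
                out.add((a[0], b[0], L))
    return sorted(out)


def detect_inverted_repeats(
    seq: CircularSequence, min_len: int = 1000, k: int = 25
) -> tuple[Interval, Interval]:
    """Find the maximal pair of disjoint intervals (i1, i2) on the circle with
    sequence(i1) == revcomp(sequence(i2)) and length >= min_len.

    Ties broken by leftmost start. Raises NoQuadripartiteStructure if none.
    """
    if min_len < 100:
        raise ValueError("min_len must be >= 100")
    n = len(seq)
    t = seq.residues + (seq.residues if seq.is_circular else "")
    pairs = _maximal_ir_pairs(t, k, min_len)
    best: tuple[int, int, int] | None = None
    seen = set()
    for i, j, L in pairs:
        if L > n:
            continue
        a, b = (i % n, j % n)
        key = tuple(sorted(((a, L), (b, L))))
        if key in seen:
            continue
        seen.add(key)
        # intervals must be disjoint on the circle
        s1, s2 = sorted((a, b))
        if not (s1 + L <= s2 and s2 + L <= s1 + n):
            continue
        if best is None or (L, -s1, -s2) > (best[2], -best[0], -best[1]):
            best = (s1, s2, L)
    if best is None:
        raise NoQuadripartiteStructure(
            f"no inverted-repeat pair of length >= {min_len} bp found"
        )
    s1, s2, L = best
    return (s1, s1 + L), (s2, s2 + L)


# ---------------------------------------------------------------------------
# Partitioning


def partition_genome(
    seq: CircularSequence, ir_intervals: tuple[Interval, Interval]
) -> tuple[CircularSequence, RegionPartition]:
    """Rotate the circle to the canonical linearization and label regions.

    The longer single-copy gap between the IR copies becomes LSC, the shorter
    SSC; the IR copy immediately downstream of LSC is IRb. The returned
    sequence starts at LSC position 0; the input strand is preserved.
    Idempotent on already-canonical input.
    """
    n = len(seq)
    (s1, e1), (s2, e2) = sorted(ir_intervals)
    L_ir = e1 - s1
    gap_a = (s2 - e1, e1 % n)  # (length, start) of gap after first IR copy
    gap_b = ((s1 - e2) % n, e2 % n)
    if gap_a[0] == 0 or gap_b[0] == 0:
        raise NoQuadripartiteStructure("degenerate zero-length single-copy region")
    (lsc_len, lsc_start), (ssc_len, _) = sorted((gap_a, gap_b), reverse=True)
    if lsc_len == ssc_len:
        raise NoQuadripartiteStructure("single-copy regions have equal length")
    canonical = seq.rotated(lsc_start) if lsc_start % n else seq
    part = RegionPartition(
        lsc=(0, lsc_len),
        irb=(lsc_len, lsc_len + L_ir),
        ssc=(lsc_len + L_ir, lsc_len + L_ir + ssc_len),
        ira=(lsc_len + L_ir + ssc_len, n),
        genome_length=n,
    )
    part.validate(canonical)
    return canonical, part


def canonical_isomer(seq: CircularSequence, min_ir: int = 1000) -> str:
    """Canonical string of a quadripartite circle, invariant to rotation,
    strand, and the relative orientation of the SSC (the two flip-flop
    isomers that short-read data cannot distinguish)."""
    candidates = []
    for s in (seq, seq.reverse_complement()):
        ir = detect_inverted_repeats(s, min_len=min_ir)
        canon, part = partition_genome(s, ir)
        lsc = canon.fetch(*part.lsc)
        irb = canon.fetch(*part.irb)
        ssc = canon.fetch(*part.ssc)
        ira = canon.fetch(*part.ira)
        candidates.append(lsc + irb + ssc + ira)
        candidates.append(lsc + irb + revcomp(ssc) + ira)
    return min(candidates)


# ---------------------------------------------------------------------------
# Base composition


def _round1(x: float) -> float:
    """Round half-up to one decimal (table formatting convention)."""
    import math

    return math.floor(x * 10 + 0.5) / 10


@dataclass(frozen=True)
class BaseComposition:
    """Percent composition of a segment (N residues excluded)."""

    t: float
    c: float
    a: float
    g: float
    gc: float
    length: int

    @classmethod
    def of(cls, segment: str) -> "BaseComposition":
        if not segment:
            raise ValueError("empty segment")
        counts = {b: segment.count(b) for b in "TCAG"}
        denom = sum(counts.values())
        if denom == 0:
            raise ValueError("segment contains no unambiguous residues")
        pct = {b: _round1(100.0 * counts[b] / denom) for b in "TCAG"}
        gc = _round1(100.0 * (counts["G"] + counts["C"]) / denom)
        return cls(pct["T"], pct["C"], pct["A"], pct["G"], gc, len(segment))

    def as_row(self) -> dict[str, float]:
        return {"T": self.t, "C": self.c, "A": self.a, "G": self.g,
                "GC": self.gc, "Length": self.length}


def base_composition(segment: str) -> BaseComposition:
    """Percentages (one decimal, half-up) of T/C/A/G plus GC for a segment."""
    return BaseComposition.of(segment)


def region_composition_table(genome: AnnotatedGenome, partition: RegionPartition):
    """Composition rows for LSC, SSC, IRa, IRb, Total, CDS and the three
    codon positions, as a pandas DataFrame."""
    import pandas as pd

    from .genestats import extract_cds

    seq = genome.sequence
    rows = {}
    for name in ("LSC", "SSC", "IRa", "IRb"):
        rows[name] = base_composition(seq.fetch(*partition.as_dict()[name])).as_row()
    rows["Total"] = base_composition(seq.residues).as_row()
    cds_list = [c for _, c in extract_cds(genome)]
    if cds_list:
        concat = "".join(cds_list)
        rows["CDS"] = base_composition(concat).as_row()
        for pos in range(3):
            sub = "".join(c[pos::3] for c in cds_list)
            rows[f"{pos + 1}{'st' if pos == 0 else 'nd' if pos == 1 else 'rd'} position"] = (
                base_composition(sub).as_row()
            )
    else:
        import warnings

        warnings.warn("no CDS features; CDS composition rows omitted")
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Junction analysis


@dataclass(frozen=True)
class JunctionReport:
    """IR-border gene truncation summary (None = gene not annotated)."""

    psi_ycf1_len: int | None
    psi_rps19_len: int | None
    ycf1_ndhf_overlap: int | None
    trnh_offset_from_ira_lsc: int | None


def _ir_overlap(feature: GeneFeature, partition: RegionPartition) -> tuple[int, str | None]:
    """Bases of the feature envelope inside an IR, and which copy."""
    s, e = feature.span()
    best = (0, None)
    for name in ("IRb", "IRa"):
        rs, re_ = partition.as_dict()[name]
        ov = max(0, min(e, re_) - max(s, rs))
        if ov > best[0]:
            best = (ov, name)
    return best


def _mirror_into_other_copy(
    interval: Interval, copy: str, partition: RegionPartition
) -> Interval:
    """Map an interval inside one IR copy to its image in the other copy."""
    (bs, be), (as_, ae) = partition.irb, partition.ira
    s, e = interval
    if copy == "IRa":
        off_s, off_e = s - as_, e - as_
        return (be - off_e, be - off_s)
    off_s, off_e = s - bs, e - bs
    return (ae - off_e, ae - off_s)


def junction_analysis(
    genome: AnnotatedGenome,
    partition: RegionPartition,
    ycf1: str = "ycf1",
    rps19: str = "rps19",
    ndhf: str = "ndhF",
    trnh: str = "trnH",
) -> JunctionReport:
    """Quantify gene truncation at the IR borders.

    The pseudogene length of a border-spanning gene is the number of its
    bases lying on the IR side of the junction; the ycf1-pseudogene/ndhF
    overlap is the intersection of the pseudogene's mirrored interval with
    the ndhF interval; the trnH offset is the circular distance from the
    IRa/LSC border to the nearest trnH base.
    """
    n = partition.genome_length

    def find(name):
        f = genome.get(name)
        if f is None:
            # tolerate copy-suffixed duplicates (e.g. "ycf1" vs "ycf1-2")
            cands = [g for g in genome.features if g.name.split("::")[0] == name]
            f = cands[0] if cands else None
        return f

    f_ycf1, f_rps19, f_ndhf, f_trnh = (find(x) for x in (ycf1, rps19, ndhf, trnh))

    psi_ycf1 = psi_rps19 = overlap = trnh_off = None
    ycf1_copy = None
    if f_ycf1 is not None:
        psi_ycf1, ycf1_copy = _ir_overlap(f_ycf1, partition)
    if f_rps19 is not None:
        psi_rps19, _ = _ir_overlap(f_rps19, partition)
    if f_ycf1 is not None and f_ndhf is not None and psi_ycf1 and ycf1_copy:
        s, e = f_ycf1.span()
        rs, re_ = partition.as_dict()[ycf1_copy]
        ir_part = (max(s, rs), min(e, re_))
        psi_iv = _mirror_into_other_copy(ir_part, ycf1_copy, partition)
        ns, ne = f_ndhf.span()
        overlap = max(0, min(ne, psi_iv[1]) - max(ns, psi_iv[0]))
    if f_trnh is not None:
        s, e = f_trnh.span()
        if s <= 0 < e or e == n:
            trnh_off = 0
        else:
            trnh_off = min(s % n, (n - e) % n)
    return JunctionReport(psi_ycf1, psi_rps19, overlap, trnh_off)
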