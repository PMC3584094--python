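"""Synthetic quadripartite plastomes with planted ground truth, plus
simulated read sets, so every downstream stage is testable offline.

The generator emits a circular LSC + IRb + SSC + IRa genome in which IRa is
the exact reverse complement of IRb, region GC targets are honored, planted
genes are valid ORFs, and dispersed/tandem/SSR repeats are present verbatim
at recorded coordinates. Defaults mirror a typical Lamiales plastome:
region lengths 82,695 / 25,539 / 17,555 / 25,539 bp (151,328 bp total),
region GC 36.2 / 43.1 / 32.0 percent, a ycf1-like gene crossing the SSC/IRa
border by 1,056 bp (whose IRb mirror overlaps an ndhF-like gene by 32 bp),
an rps19-like gene crossing LSC/IRb by 43 bp, and a trnH-like gene 9 bp
from the IRa/LSC border.

Two read simulators emulate the sequencing chemistry of the assembly
problem: long shotgun reads whose characteristic error mode is +/-1
homopolymer-length indels, and short accurate reads with a low substitution
rate used for correction.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import AnnotatedGenome, CircularSequence, GeneFeature, revcomp
from .genestats import STOP_CODONS
from .structure import RegionPartition

_BASES = b"ACGT"
_COMP = bytes.maketrans(b"ACGT", b"TGCA")
_CTRANS = str.maketrans("ACGT", "TGCA")


def _comp_char(c: str) -> str:
    return c.translate(_CTRANS)

DEFAULT_DISPERSED = (
    # (kind, unit, regions) -- units as printed in the source genome's
    # curated repeat table; one locus per region entry.
    ("F", "AACGATGCGGGTTCGATTCCCGCTACCCGC", ("LSC", "LSC")),
    ("F", "AGCTAAATGATGATGAGCCATATCAGTCAACC", ("LSC", "LSC")),
    ("F", "CCAGAACCGTACGTGAGATTTTCACCTCATACGGCTCCT", ("LSC", "SSC")),
    ("F", "CTACAGAACCGTACATGAGATTTTCACCTCATACGGCTCCT", ("IR", "SSC")),
    ("I", "AACGGAAAGAGAGGGATTCGAACCCTCGGT", ("LSC", "LSC")),
    ("I", "AGGGGAGAGAGAGGGATTCGAACCCTCGAT", ("LSC", "LSC")),
)

DEFAULT_TANDEM = (
    # (unit, copies, region)
    ("ACTATATAGAATATATATAA", 2, "LSC"),
    ("TTAGCTTATCCGAATC", 2, "LSC"),
    ("AATTAATAATAACTAC", 2, "LSC"),
    ("CGCACTCTTAGTCATAA", 2, "LSC"),
    ("TTTTTGTCCAAGTCACTTCTT", 3, "IR"),
    ("TATTGATGAGAGTGACGA", 6, "IR"),
    ("AATAAAAACCTAAAATCCCT", 2, "SSC"),
)

DEFAULT_SSRS = (
    ("A", 10, "LSC"),
    ("T", 11, "LSC"),
    ("A", 8, "SSC"),
    ("AT", 5, "LSC"),
    ("TA", 4, "SSC"),
    ("AAAT", 3, "LSC"),
    ("ATAG", 3, "SSC"),
    ("AATCGG", 3, "LSC"),
)


@dataclass(frozen=True)
class PlastomeSpec:
    """Parameters of a synthetic plastome."""

    lsc_len: int = 82_695
    ssc_len: int = 17_555
    ir_len: int = 25_539
    gc_lsc: float = 0.362
    gc_ssc: float = 0.320
    gc_ir: float = 0.431
    n_cds: int = 40
    n_trna: int = 20
    n_rrna: int = 4
    planted_dispersed: tuple = DEFAULT_DISPERSED
    planted_tandem: tuple = DEFAULT_TANDEM
    planted_ssrs: tuple = DEFAULT_SSRS
    ycf1_ir_len: int = 1_056
    rps19_ir_len: int = 43
    ndhf_overlap: int = 32
    trnh_offset: int = 9
    seed: int = 0

    def __post_init__(self):
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ValueError("region lengths must be positive")
        if self.lsc_len <= self.ssc_len:
            raise ValueError("LSC must be longer than SSC")
        for gc in (self.gc_lsc, self.gc_ssc, self.gc_ir):
            if not 0 < gc < 1:
                raise ValueError("GC fractions must be in (0, 1)")
        if self.ycf1_ir_len % 3:
            raise ValueError("ycf1_ir_len must be a multiple of 3")

    @property
    def genome_length(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len


@dataclass
class RepeatTruth:
    kind: str  # F, I or T
    unit: str
    copies: int
    positions: tuple[int, ...]  # locus starts on the genome
    region: tuple[str, ...]


@dataclass
class SSRTruth:
    motif: str
    n_units: int
    start: int
    region: str


@dataclass
class SyntheticTruth:
    """Everything planted, addressable on the emitted genome."""

    partition: RegionPartition
    gene_cds: dict[str, str]
    repeats: list[RepeatTruth]
    ssrs: list[SSRTruth]
    seed_genes: tuple[str, str] = ("psbA", "ndhI")


@dataclass
class ReadSet:
    reads: list[tuple[str, str]]
    platform: str
    homopolymer_rate: float = 0.0
    sub_rate: float = 0.0
    errors: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)

    def mean_length(self) -> float:
        return float(np.mean([len(s) for _, s in self.reads])) if self.reads else 0.0


class CapacityError(ValueError):
    """A planted item does not fit in its region."""


# ---------------------------------------------------------------------------
# helpers


def _probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> bytes:
    idx = rng.choice(4, size=n, p=_probs(gc))
    return bytes(np.frombuffer(_BASES, dtype=np.uint8)[idx])


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    """n random codons, none a stop, base composition near the GC target."""
    out: list[str] = []
    while len(out) < n:
        chunk = _random_bases(rng, 3 * (n - len(out)), gc).decode()
        for i in range(0, len(chunk), 3):
            c = chunk[i : i + 3]
            if c not in STOP_CODONS:
                out.append(c)
    return out[:n]


def _repair_stops(codons: list[str], locked: set[int], rng, gc: float) -> None:
    """Resample unlocked bases of any internal stop codon (in place)."""
    for ci in range(len(codons) - 1):
        guard = 0
        while codons[ci] in STOP_CODONS:
            free = [k for k in range(3) if 3 * ci + k not in locked]
            if not free:
                raise AssertionError("stop codon with all bases locked")
            k = free[rng.integers(len(free))]
            b = codons[ci]
            codons[ci] = b[:k] + chr(_BASES[rng.choice(4, p=_probs(gc))]) + b[k + 1 :]
            guard += 1
            if guard > 100:
                raise AssertionError("stop repair did not converge")


def _base_not(rng: np.random.Generator, excluded: set[str]) -> str:
    choices = [b for b in "ACGT" if b not in excluded]
    return choices[rng.integers(len(choices))]


class _Allocator:
    """Non-overlapping placement of items inside one region."""

    def __init__(self, lo: int, hi: int, pad: int = 60):
        self.lo, self.hi, self.pad = lo, hi, pad
        self.reserved: list[tuple[int, int]] = []

    def reserve(self, s: int, e: int) -> None:
        for rs, re_ in self.reserved:
            if max(s - self.pad, rs) < min(e + self.pad, re_):
                raise CapacityError(f"interval ({s}, {e}) collides with ({rs}, {re_})")
        self.reserved.append((s, e))

    def place(self, length: int, rng: np.random.Generator) -> int:
        if length + 2 * self.pad > self.hi - self.lo:
            raise CapacityError(f"item of {length} bp exceeds region capacity")
        for _ in range(200):
            s = int(rng.integers(self.lo + self.pad, self.hi - length - self.pad))
            try:
                self.reserve(s, s + length)
            except CapacityError:
                continue
            return s
        # first-fit fallback when the region is too fragmented for rejection
        # sampling
        bounds = sorted(self.reserved)
        cursor = self.lo + self.pad
        for rs, re_ in bounds + [(self.hi - self.pad, self.hi)]:
            if rs - self.pad - cursor >= length:
                self.reserve(cursor, cursor + length)
                return cursor
            cursor = max(cursor, re_ + self.pad)
        raise CapacityError(f"could not place item of {length} bp (region full)")


# ---------------------------------------------------------------------------
# genome construction


def _sample_overlap_zone(rng, o: int, ndhf_len: int, gc: float) -> str:
    """The o bases shared (through the IR mirror) by the ycf1-like gene's IR
    portion and the tail of the minus-strand ndhF-like gene.

    Constraints: the zone ends with the ndhF stop codon; no stop codon fully
    contained in the zone in either gene's reading frame.
    """
    nf_off = (ndhf_len - o) % 3  # offset of first in-frame ndhF codon boundary
    for _ in range(1000):
        zone = list(_random_bases(rng, o, gc).decode())
        stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
        zone[o - 3 :] = list(stop)
        z = "".join(zone)
        ok = True
        # ycf1 frame: codons at zone offsets 0, 3, 6, ... (zone starts at a
        # codon boundary of the ycf1 CDS)
        for i in range(0, o - 2, 3):
            if z[i : i + 3] in STOP_CODONS:
                ok = False
                break
        if ok:
            # ndhF frame: codon boundaries at (3 - nf_off) % 3, step 3
            start = (3 - nf_off) % 3
            for i in range(start, o - 5, 3):  # excludes the final stop
                if z[i : i + 3] in STOP_CODONS:
                    ok = False
                    break
        if ok:
            return z
    raise AssertionError("could not sample junction overlap zone")


def build_plastome(spec: PlastomeSpec) -> tuple[AnnotatedGenome, SyntheticTruth]:
    """Emit an annotated genome and the matching planted truth."""
    n = spec.genome_length
    lsc_e = spec.lsc_len
    irb_s, irb_e = lsc_e, lsc_e + spec.ir_len
    ssc_s, ssc_e = irb_e, irb_e + spec.ssc_len
    ira_s, ira_e = ssc_e, n
    assert ira_e - ira_s == spec.ir_len

    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_bg, rng_gene, rng_rep, rng_ssr, rng_fix, _ = (
        np.random.default_rng(s) for s in streams
    )

    g = bytearray(n)
    g[0:lsc_e] = _random_bases(rng_bg, spec.lsc_len, spec.gc_lsc)
    g[irb_s:irb_e] = _random_bases(rng_bg, spec.ir_len, spec.gc_ir)
    g[ssc_s:ssc_e] = _random_bases(rng_bg, spec.ssc_len, spec.gc_ssc)

    alloc = {
        "LSC": _Allocator(0, lsc_e),
        "IR": _Allocator(irb_s, irb_e),
        "SSC": _Allocator(ssc_s, ssc_e),
    }
    gc_of = {"LSC": spec.gc_lsc, "IR": spec.gc_ir, "SSC": spec.gc_ssc}

    features: list[GeneFeature] = []
    gene_cds: dict[str, str] = {}

    def write_gene(feat: GeneFeature, cds: str) -> None:
        """Write a coding/structural sequence under a feature's exons."""
        if feat.exon_strands is not None:
            parts = []
            pos = 0
            for (s, e), st in zip(feat.exons, feat.exon_strands):
                seg = cds[pos : pos + (e - s)]
                g[s:e] = (seg if st == "+" else revcomp(seg)).encode()
                pos += e - s
        else:
            joined = cds if feat.strand == "+" else revcomp(cds)
            pos = 0
            for s, e in feat.exons:
                g[s:e] = joined[pos : pos + (e - s)].encode()
                pos += e - s
        features.append(feat)
        if feat.klass == "CDS":
            gene_cds[feat.name] = cds

    def make_cds(n_codons: int, gc: float, locked_zone: tuple[int, str] | None = None) -> str:
        """ATG + interior codons + stop; optionally splice a locked zone in."""
        codons = ["ATG"] + _random_codons(rng_gene, n_codons - 2, gc)
        codons.append(STOP_CODONS[rng_gene.integers(len(STOP_CODONS))])
        locked: set[int] = {0, 1, 2}
        locked |= {3 * (n_codons - 1) + k for k in range(3)}
        if locked_zone is not None:
            q0, zone = locked_zone
            s = "".join(codons)
            s = s[:q0] + zone + s[q0 + len(zone) :]
            codons = [s[i : i + 3] for i in range(0, len(s), 3)]
            locked |= set(range(q0, q0 + len(zone)))
        _repair_stops(codons, locked, rng_gene, gc)
        return "".join(codons)

    # --- junction geometry -------------------------------------------------
    o = spec.ndhf_overlap
    ycf1_ir = spec.ycf1_ir_len
    full_size = spec.ssc_len > 4473 + 2500 + 4000  # room for other SSC genes
    ycf1_ssc = 4473 if full_size else max(300, (spec.ssc_len // 12) * 3)
    ycf1_len = ycf1_ssc + ycf1_ir
    ndhf_len = 2235 if full_size else max(150, (spec.ssc_len // 24) * 3)

    zone = _sample_overlap_zone(rng_gene, o, ndhf_len, spec.gc_ssc)

    # ycf1-like: plus strand, crosses SSC -> IRa; its first ycf1_ir bases of
    # IR sequence start at IRa offset 0, so the zone sits at CDS offset
    # ycf1_ssc (a codon boundary).
    ycf1_cds = make_cds(ycf1_len // 3, spec.gc_ssc, locked_zone=(ycf1_ssc, zone))
    ycf1_start = ira_s - ycf1_ssc
    alloc["SSC"].reserve(ycf1_start, ssc_e)
    g[ycf1_start:ira_s] = ycf1_cds[:ycf1_ssc].encode()
    # mirror image of the IR portion, written into the IRb tail (IRa itself
    # is synthesized from IRb at the end)
    alloc["IR"].reserve(irb_e - ycf1_ir, irb_e)
    g[irb_e - ycf1_ir : irb_e] = revcomp(ycf1_cds[ycf1_ssc:]).encode()
    features.append(
        GeneFeature("ycf1", "CDS", "+", ((ycf1_start, ira_s + ycf1_ir),))
    )
    gene_cds["ycf1"] = ycf1_cds

    # ndhF-like: minus strand, overlaps the ycf1 pseudogene (IRb tail) by o
    nf_s = irb_e - o
    nf_e = nf_s + ndhf_len
    ndhf_cds = make_cds(ndhf_len // 3, spec.gc_ssc, locked_zone=(ndhf_len - o, zone))
    alloc["SSC"].reserve(irb_e, nf_e)
    g[irb_e:nf_e] = revcomp(ndhf_cds)[o:].encode()
    features.append(GeneFeature("ndhF", "CDS", "-", ((nf_s, nf_e),)))
    gene_cds["ndhF"] = ndhf_cds
    assert bytes(g[nf_s:irb_e]) == revcomp(ndhf_cds).encode()[:o]

    # rps19-like: plus strand, crosses LSC -> IRb
    rps19_len = 279
    r_s = lsc_e - (rps19_len - spec.rps19_ir_len)
    alloc["LSC"].reserve(r_s, lsc_e)
    alloc["IR"].reserve(irb_s, irb_s + spec.rps19_ir_len)
    write_gene(
        GeneFeature("rps19", "CDS", "+", ((r_s, irb_s + spec.rps19_ir_len),)),
        make_cds(rps19_len // 3, spec.gc_lsc),
    )

    # trnH-like near the IRa/LSC border
    t_s = spec.trnh_offset
    alloc["LSC"].reserve(t_s, t_s + 75)
    features.append(GeneFeature("trnH", "tRNA", "-", ((t_s, t_s + 75),)))

    # seed genes mid-region (assembly entry points)
    psba_len = 1062
    psba_s = (lsc_e - psba_len) // 2
    alloc["LSC"].reserve(psba_s, psba_s + psba_len)
    write_gene(
        GeneFeature("psbA", "CDS", "-", ((psba_s, psba_s + psba_len),)),
        make_cds(psba_len // 3, spec.gc_lsc),
    )
    ndhi_len = 504
    ndhi_s = ssc_s + (spec.ssc_len - ndhi_len) // 3
    alloc["SSC"].reserve(ndhi_s, ndhi_s + ndhi_len)
    write_gene(
        GeneFeature("ndhI", "CDS", "-", ((ndhi_s, ndhi_s + ndhi_len),)),
        make_cds(ndhi_len // 3, spec.gc_ssc),
    )

    # intron-bearing genes: trnK-like (one large intron), clpP-like (two
    # introns, minus strand), rps12-like (trans-spliced: 5' exon in LSC,
    # 3' exons in IRb)
    if spec.lsc_len > 20_000:
        tk_s = alloc["LSC"].place(37 + 2522 + 35, rng_gene)
        features.append(
            GeneFeature("trnK", "tRNA", "+", ((tk_s, tk_s + 37), (tk_s + 2559, tk_s + 2594)))
        )
        cp_s = alloc["LSC"].place(71 + 692 + 292 + 628 + 228, rng_gene)
        ex = ((cp_s, cp_s + 71), (cp_s + 763, cp_s + 1055), (cp_s + 1683, cp_s + 1911))
        write_gene(GeneFeature("clpP", "CDS", "-", ex), make_cds(591 // 3, spec.gc_lsc))
        r12_lsc = alloc["LSC"].place(114, rng_gene)
        r12_ir = alloc["IR"].place(232 + 526 + 26, rng_gene)
        ex12 = ((r12_lsc, r12_lsc + 114), (r12_ir, r12_ir + 232), (r12_ir + 758, r12_ir + 784))
        write_gene(
            GeneFeature("rps12", "CDS", "+", ex12, trans_spliced=True),
            make_cds(372 // 3, spec.gc_lsc),
        )

    # rRNA-like genes in the IR (scaled down on small toy IRs)
    rrna_lengths = (1491, 2810, 103, 121)[: spec.n_rrna]
    if spec.ir_len < 20_000:
        scale = spec.ir_len / 25_539
        rrna_lengths = tuple(max(80, int(L * scale)) for L in rrna_lengths)
    for i, L in enumerate(rrna_lengths):
        s = alloc["IR"].place(L, rng_gene)
        features.append(GeneFeature(f"rrn{i + 1}", "rRNA", "+", ((s, s + L),)))

    # --- planted repeats ----------------------------------------------------
    repeats: list[RepeatTruth] = []

    def harden_pair(p1: int, p2: int, L: int, inverted: bool) -> None:
        """Force mismatch columns flanking a dispersed pair so the maximal
        hit is exactly the planted unit."""
        for i in range(1, 5):
            if not inverted:
                # flanking columns pair position-wise on the same strand
                for a, b in ((p1 - i, p2 - i), (p1 + L - 1 + i, p2 + L - 1 + i)):
                    if g[b] == g[a]:
                        g[b] = ord(_base_not(rng_rep, {chr(g[a])}))
            else:
                # left of locus1 pairs with right of locus2 (and vice versa)
                for a, b in ((p1 - i, p2 + L - 1 + i), (p1 + L - 1 + i, p2 - i)):
                    if chr(g[b]) == _comp_char(chr(g[a])):
                        g[b] = ord(_base_not(rng_rep, {_comp_char(chr(g[a]))}))

    for kind, unit, regions in spec.planted_dispersed:
        L = len(unit)
        p1 = alloc[regions[0]].place(L, rng_rep)
        p2 = alloc[regions[1]].place(L, rng_rep)
        g[p1 : p1 + L] = unit.encode()
        second = unit if kind == "F" else revcomp(unit)
        g[p2 : p2 + L] = second.encode()
        harden_pair(p1, p2, L, inverted=(kind == "I"))
        repeats.append(RepeatTruth(kind, unit, 2, (p1, p2), tuple(regions)))

    for unit, copies, region in spec.planted_tandem:
        p = len(unit)
        total = p * copies
        s = alloc[region].place(total, rng_rep)
        g[s : s + total] = (unit * copies).encode()
        if g[s - 1] == g[s - 1 + p]:
            g[s - 1] = ord(_base_not(rng_rep, {chr(g[s - 1 + p])}))
        if g[s + total] == g[s + total - p]:
            g[s + total] = ord(_base_not(rng_rep, {chr(g[s + total - p])}))
        repeats.append(RepeatTruth("T", unit, copies, (s,), (region,)))

    ssrs: list[SSRTruth] = []
    for motif, n_units, region in spec.planted_ssrs:
        k = len(motif)
        total = k * n_units
        s = alloc[region].place(total, rng_ssr)
        g[s : s + total] = (motif * n_units).encode()
        if g[s - 1] == g[s - 1 + k]:
            g[s - 1] = ord(_base_not(rng_ssr, {chr(g[s - 1 + k])}))
        if g[s + total] == g[s + total - k]:
            g[s + total] = ord(_base_not(rng_ssr, {chr(g[s + total - k])}))
        ssrs.append(SSRTruth(motif, n_units, s, region))


    # generic CDS and tRNA genes
    n_special_cds = len([f for f in features if f.klass == "CDS"])
    shares = {"LSC": 0.7, "SSC": 0.15, "IR": 0.15}
    extra = max(0, spec.n_cds - n_special_cds)
    for i in range(extra):
        region = rng_gene.choice(list(shares), p=list(shares.values()))
        L = int(rng_gene.integers(100, 500)) * 3
        try:
            s = alloc[region].place(L, rng_gene)
        except CapacityError:
            continue
        write_gene(GeneFeature(f"orf{i + 1}", "CDS", "+", ((s, s + L),)),
                   make_cds(L // 3, gc_of[region]))
    n_special_trna = len([f for f in features if f.klass == "tRNA"])
    for i in range(max(0, spec.n_trna - n_special_trna)):
        region = rng_gene.choice(list(shares), p=list(shares.values()))
        try:
            s = alloc[region].place(75, rng_gene)
        except CapacityError:
            continue
        features.append(GeneFeature(f"trnX{i + 1}", "tRNA", "+", ((s, s + 75),)))

    # --- IRa = reverse complement of IRb ------------------------------------
    g[ira_s:ira_e] = bytes(g[irb_s:irb_e]).translate(_COMP)[::-1]

    # prevent chance extension of the IR pair across its borders:
    # column (irb_s - 1) pairs with genome position 0; column (irb_e) pairs
    # with (ira_s - 1). The latter two bases are gene-locked but were chosen
    # compatibly; fix the free ones here.
    if chr(g[0]) == _comp_char(chr(g[irb_s - 1])):
        g[0] = ord(_base_not(rng_fix, {_comp_char(chr(g[irb_s - 1]))}))
    if chr(g[irb_e]) == _comp_char(chr(g[ira_s - 1])):
        # g[irb_e] is ndhF-locked (complement of a free interior base of its
        # CDS); adjust the free ycf1 base at ira_s - 1 instead, avoiding a
        # stop in the ycf1 frame.
        ci = (ycf1_ssc - 1) // 3
        for b in "ACGT":
            cand = ycf1_cds[3 * ci : 3 * ci + 2] + b
            if b != chr(g[ira_s - 1]) and cand not in STOP_CODONS and chr(g[irb_e]) != _comp_char(b):
                g[ira_s - 1] = ord(b)
                ycf1_cds = ycf1_cds[: ycf1_ssc - 1] + b + ycf1_cds[ycf1_ssc:]
                gene_cds["ycf1"] = ycf1_cds
                break

    # duplicate features fully inside IRb into IRa (mirrored, strand flipped)
    def mirror_iv(s: int, e: int) -> tuple[int, int]:
        return (ira_s + (irb_e - e), ira_s + (irb_e - s))

    dup = []
    for f in features:
        if irb_s <= f.start and f.end <= irb_e:
            ex = tuple(sorted(mirror_iv(s, e) for s, e in f.exons))
            dup.append(GeneFeature(f.name + "::2", f.klass, "-" if f.strand == "+" else "+",
                                   ex, trans_spliced=f.trans_spliced))
            if f.klass == "CDS" and f.name in gene_cds:
                gene_cds[f.name + "::2"] = gene_cds[f.name]
        elif f.trans_spliced and any(irb_s <= s and e <= irb_e for s, e in f.exons):
            # trans-spliced: 5' LSC exon is shared; IR exons are duplicated
            ex, st = [], []
            for (s, e), strand in zip(f.exons, [f.strand] * len(f.exons)):
                if irb_s <= s and e <= irb_e:
                    ms, me = mirror_iv(s, e)
                    ex.append((ms, me))
                    st.append("-" if strand == "+" else "+")
                else:
                    ex.append((s, e))
                    st.append(strand)
            dup.append(GeneFeature(f.name + "::2", f.klass, "+", tuple(ex),
                                   trans_spliced=True, exon_strands=tuple(st)))
            if f.klass == "CDS" and f.name in gene_cds:
                gene_cds[f.name + "::2"] = gene_cds[f.name]
    features.extend(dup)
    features.sort(key=lambda f: (f.start, f.name))

    seq = CircularSequence(id=f"synthetic-plastome-{spec.seed}", residues=bytes(g).decode())
    partition = RegionPartition(
        lsc=(0, lsc_e), irb=(irb_s, irb_e), ssc=(ssc_s, ssc_e), ira=(ira_s, ira_e),
        genome_length=n,
    )
    partition.validate(seq)
    genome = AnnotatedGenome(sequence=seq, features=features, partition=partition)
    truth = SyntheticTruth(partition=partition, gene_cds=gene_cds,
                           repeats=repeats, ssrs=ssrs)
    # every planted item must be locatable verbatim
    res = seq.residues
    for r in repeats:
        for idx, p in enumerate(r.positions):
            want = r.unit * r.copies if r.kind == "T" else (
                r.unit if (r.kind == "F" or idx == 0) else revcomp(r.unit))
            assert res[p : p + len(want)] == want
    for srec in ssrs:
        assert res[srec.start : srec.start + len(srec.motif) * srec.n_units] == srec.motif * srec.n_units
    return genome, truth


# ---------------------------------------------------------------------------
# read simulation

_HOMOPOLYMER = re.compile(r"(A{3,}|C{3,}|G{3,}|T{3,})")


def _mutate_homopolymers(read: str, rate: float, rng) -> tuple[str, list[tuple[int, str]]]:
    if rate <= 0:
        return read, []
    out = []
    errors = []
    last = 0
    for m in _HOMOPOLYMER.finditer(read):
        if rng.random() < rate:
            delta = 1 if rng.random() < 0.5 else -1
            out.append(read[last : m.start()])
            run = m.group(0)
            out.append(run[0] * (len(run) + delta))
            errors.append((m.start(), f"hp{delta:+d}"))
            last = m.end()
    out.append(read[last:])
    return "".join(out), errors


def _apply_substitutions(read: str, k: int, rng) -> tuple[str, list[tuple[int, str]]]:
    arr = list(read)
    errors = []
    for pos in rng.choice(len(arr), size=k, replace=False):
        old = arr[pos]
        arr[pos] = _base_not(rng, {old})
        errors.append((int(pos), f"sub{old}"))
    return "".join(arr), errors


def _genome_residues(genome) -> str:
    return genome.sequence.residues if isinstance(genome, AnnotatedGenome) else genome.residues


def simulate_shotgun_reads(
    genome,
    n: int,
    mean_len: int = 384,
    homopolymer_rate: float = 0.02,
    sub_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Long shotgun reads from the circle with homopolymer-length errors.

    Start positions are uniform on the circle, lengths are normal with
    sd = 0.15 x mean truncated to [50, 2 x mean], and each homopolymer run
    of length >= 3 is lengthened or shortened by one base with probability
    ``homopolymer_rate``.
    """
    res = _genome_residues(genome)
    L = len(res)
    if mean_len >= L:
        raise ValueError("mean read length must be below the genome length")
    if n == 0:
        warnings.warn("simulating an empty read set")
        return ReadSet([], "long-shotgun", homopolymer_rate, sub_rate)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    doubled = res + res
    starts = rng.integers(0, L, size=n)
    lens = np.clip(rng.normal(mean_len, 0.15 * mean_len, size=n).round().astype(int), 50, 2 * mean_len)
    flips = rng.random(n) < 0.5
    reads = []
    errors = {}
    for i in range(n):
        s = doubled[starts[i] : starts[i] + lens[i]]
        if flips[i]:
            s = revcomp(s)
        errs = []
        s, hp_errs = _mutate_homopolymers(s, homopolymer_rate, rng)
        errs.extend(hp_errs)
        if sub_rate > 0:
            k = rng.binomial(len(s), sub_rate)
            if k:
                s, sub_errs = _apply_substitutions(s, k, rng)
                errs.extend(sub_errs)
        rid = f"sr{i}"
        reads.append((rid, s))
        if errs:
            errors[rid] = errs
    return ReadSet(reads, "long-shotgun", homopolymer_rate, sub_rate, errors)


def simulate_accurate_pairs(
    genome, n: int, read_len: int = 50, seed: int = 0, sub_rate: float = 0.002
) -> ReadSet:
    """Short accurate reads: substitution-only errors, no indels."""
    if read_len < 25:
        raise ValueError("read_len must be >= 25")
    res = _genome_residues(genome)
    L = len(res)
    if n == 0:
        warnings.warn("simulating an empty read set")
        return ReadSet([], "accurate-pair", 0.0, sub_rate)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    doubled = res + res
    starts = rng.integers(0, L, size=n)
    flips = rng.random(n) < 0.5
    n_subs = rng.binomial(read_len, sub_rate, size=n)
    reads = []
    errors = {}
    for i in range(n):
        s = doubled[starts[i] : starts[i] + read_len]
        if flips[i]:
            s = revcomp(s)
        rid = f"ar{i}"
        if n_subs[i]:
            s, errs = _apply_substitutions(s, n_subs[i], rng)
            errors[rid] = errs
        reads.append((rid, s))
    return ReadSet(reads, "accurate-pair", 0.0, sub_rate, errors)


def reads_for_depth(genome_length: int, depth: float, mean_len: float) -> int:
    """Number of reads giving the requested fold-coverage."""
    return int(round(depth * genome_length / mean_len))


# ---------------------------------------------------------------------------
# truth export


def write_truth_gff(genome: AnnotatedGenome, path) -> None:
    """GFF3 of the planted features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        sid = genome.sequence.id
        fh.write(f"##sequence-region {sid} 1 {len(genome.sequence)}\n")
        for f in genome.features:
            typ = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "pseudogene": "pseudogene"}[f.klass]
            for i, (s, e) in enumerate(f.exons):
                strand = f.exon_strands[i] if f.exon_strands else f.strand
                fh.write(
                    f"{sid}\tplastomekit\t{typ}\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={f.name}.{i + 1};Parent={f.name}\n"
                )


def write_truth_table(truth: SyntheticTruth, path) -> None:
    """Machine-readable TSV of planted repeats and SSRs."""
    with open(path, "w") as fh:
        fh.write("kind\tunit\tcopies\tpositions\tregion\n")
        for r in truth.repeats:
            fh.write(f"{r.kind}\t{r.unit}\t{r.copies}\t{','.join(map(str, r.positions))}\t{','.join(r.region)}\n")
        for s in truth.ssrs:
            fh.write(f"SSR\t{s.motif}\t{s.n_units}\t{s.start}\t{s.region}\n")
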