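"""Greedy seed-and-extend assembly of a circular plastome from long shotgun
reads, with homopolymer correction from an accurate read set.

The strategy mirrors classic two-seed organelle assembly: one seed per
single-copy region is extended read-by-read at both ends (each step appends
the qualifying read with the largest overhang), the two growing contigs are
frozen once they overlap inside the inverted repeats, and the circle is
stitched from the four IR arms. Because no read spans a full ~25 kb IR, the
relative orientation of the two single-copy regions is not identifiable
from read data (the well-known flip-flop isomer ambiguity); comparisons of
assemblies against a reference should therefore use the canonical isomer
form (structure.canonical_isomer).

Homopolymer +/-1 length errors -- the characteristic error mode of the
long-read chemistry -- are corrected afterwards by majority vote of the
run lengths observed in accurate short reads anchored over each run.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from .core_io import CircularSequence, revcomp
from .synthetic_data import ReadSet

_K = 21


class AssemblyError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# seed matching (re-implemented local alignment, not a BLAST wrapper)


@dataclass(frozen=True)
class SeedMatch:
    read_id: str
    identity: float
    columns: int
    read_span: tuple[int, int]
    seed_span: tuple[int, int]
    reverse: bool
    score: float


def _smith_waterman(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """Best local alignment; returns (score, matches, columns, a_span, b_span)."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        ai = a[i - 1]
        row = H[i]
        prev = H[i - 1]
        for j in range(1, m + 1):
            s = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            row[j] = max(0.0, s, prev[j] + gap, row[j - 1] + gap)
    i, j = np.unravel_index(np.argmax(H), H.shape)
    matches = columns = 0
    ei, ej = int(i), int(j)
    score = float(H[i, j])
    while i > 0 and j > 0 and H[i, j] > 0:
        diag = H[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
        if abs(H[i, j] - diag) < 1e-9:
            matches += a[i - 1] == b[j - 1]
            columns += 1
            i, j = i - 1, j - 1
        elif abs(H[i, j] - (H[i - 1, j] + gap)) < 1e-9:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return score, matches, columns, (int(i), ei), (int(j), ej)


def seed_match(
    reads: ReadSet | list[tuple[str, str]],
    seed_seq: str,
    min_identity: float = 0.95,
    min_overlap: int = 30,
) -> list[SeedMatch]:
    """Reads whose best local alignment to the seed (or its reverse
    complement) reaches ``min_identity`` over at least ``min_overlap``
    columns; identity = matches / alignment columns."""
    if len(seed_seq) < 50:
        raise ValueError("seed must be at least 50 bp")
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    read_list = reads.reads if isinstance(reads, ReadSet) else reads
    out = []
    for rid, seq in read_list:
        best = None
        for rev, oriented in ((False, seq), (True, revcomp(seq))):
            score, matches, cols, rs, ss = _smith_waterman(oriented, seed_seq)
            if cols >= min_overlap and cols > 0 and matches / cols >= min_identity:
                cand = SeedMatch(rid, matches / cols, cols, rs, ss, rev, score)
                if best is None or (cand.score, cand.identity) > (best.score, best.identity):
                    best = cand
        if best is not None:
            out.append(best)
    return out


# ---------------------------------------------------------------------------
# assembly state and single-step extension (reference path used by the
# unit-scale operations; the pipeline uses the indexed fast path below)


@dataclass
class AssemblyState:
    """A growing contig with a substitution-level pileup.

    ``origin`` anchors pileup coordinates: column c of the contig is pileup
    key origin + c, so 5' extensions do not shift history.
    """

    contig: str
    origin: int = 0
    pileup: dict[int, Counter] = field(default_factory=dict)
    extension_log: list[tuple[str, str, int]] = field(default_factory=list)

    @classmethod
    def from_seed(cls, seed: str) -> "AssemblyState":
        st = cls(contig=seed)
        st._add_to_pileup(seed, 0)
        return st

    def _add_to_pileup(self, seq: str, start: int) -> None:
        for i, b in enumerate(seq):
            self.pileup.setdefault(start + i, Counter())[b] += 1


def _id_order(rid: str):
    # ties prefer the lexicographically smaller id => invert for max()
    return tuple(-ord(c) for c in rid)


def _best_overlap_read(contig: str, oriented: list[tuple[str, str]],
                       min_identity: float, min_overlap: int):
    """Best 3'-extending read by (overhang, identity, read id); hamming
    identity over the overlap (substitution-level reference path)."""
    best = None
    for rid, seq in oriented:
        max_ov = min(len(seq) - 1, len(contig))
        for ov in range(max_ov, min_overlap - 1, -1):
            tail = contig[-ov:]
            head = seq[:ov]
            matches = sum(a == b for a, b in zip(tail, head))
            if matches / ov >= min_identity:
                cand = (len(seq) - ov, matches / ov, rid, seq, ov)
                if best is None or (cand[0], cand[1], _id_order(cand[2])) > (
                    best[0], best[1], _id_order(best[2])
                ):
                    best = cand
                break  # largest qualifying overlap for this read
    return best


def extend_contig(
    state: AssemblyState,
    reads: ReadSet | list[tuple[str, str]],
    min_identity: float = 0.95,
    min_overlap: int = 30,
) -> AssemblyState:
    """One greedy extension step per contig end.

    Among qualifying reads overlapping a terminus at >= min_identity over
    >= min_overlap bases, the one with the largest overhang is appended
    (ties: higher identity, then lexicographically smaller read id). The
    state is returned unchanged at an end with no qualifying read.
    """
    read_list = reads.reads if isinstance(reads, ReadSet) else reads
    oriented = [(rid, s) for rid, s in read_list] + [
        (rid, revcomp(s)) for rid, s in read_list
    ]
    st = AssemblyState(state.contig, state.origin,
                       {k: Counter(v) for k, v in state.pileup.items()},
                       list(state.extension_log))
    got = _best_overlap_read(st.contig, oriented, min_identity, min_overlap)
    if got:
        overhang, ident, rid, seq, ov = got
        st._add_to_pileup(seq, st.origin + len(st.contig) - ov)
        st.contig += seq[ov:]
        st.extension_log.append(("3'", rid, overhang))
    rc_contig = revcomp(st.contig)
    got = _best_overlap_read(rc_contig, oriented, min_identity, min_overlap)
    if got:
        overhang, ident, rid, seq, ov = got
        st.origin -= overhang
        st.contig = revcomp(rc_contig + seq[ov:])
        st._add_to_pileup(revcomp(seq), st.origin)
        st.extension_log.append(("5'", rid, overhang))
    return st


# ---------------------------------------------------------------------------
# consensus and polymorphism scan


def call_consensus(pileup: dict[int, Counter], min_depth: int = 1) -> str:
    """Per-column plurality base (ties A<C<G<T); low-depth columns emit N."""
    if not pileup:
        raise ValueError("empty pileup")
    lo, hi = min(pileup), max(pileup)
    out = []
    for c in range(lo, hi + 1):
        counts = pileup.get(c)
        if not counts or sum(counts.values()) < min_depth:
            out.append("N")
            continue
        out.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(out)


@dataclass(frozen=True)
class PolymorphicSite:
    position: int
    depth: int
    alleles: dict
    maf: float


def scan_polymorphisms(
    pileup: dict[int, Counter], maf_threshold: float = 0.2, min_depth: int = 10
) -> list[PolymorphicSite]:
    """Sites whose minor-allele fraction reaches the threshold at adequate
    depth (minor allele = second most frequent base)."""
    if not 0 < maf_threshold <= 0.5:
        raise ValueError("maf_threshold must be in (0, 0.5]")
    out = []
    for pos in sorted(pileup):
        counts = pileup[pos]
        depth = sum(counts.values())
        if depth < min_depth or len(counts) < 2:
            continue
        maf = counts.most_common(2)[1][1] / depth
        if maf >= maf_threshold:
            out.append(PolymorphicSite(pos, depth, dict(counts), maf))
    return out


def build_pileup(
    reads: ReadSet | list[tuple[str, str]],
    genome: CircularSequence | str,
    max_mismatch_frac: float = 0.1,
) -> dict[int, Counter]:
    """Substitution-level pileup of reads placed on a (circular) genome.

    Reads are placed by k-mer anchoring and accepted within a hamming
    budget; unplaceable reads are skipped.
    """
    res = genome.residues if isinstance(genome, CircularSequence) else genome
    n = len(res)
    doubled = res + res
    index = _kmer_index(doubled, _K, step=1)
    pileup: dict[int, Counter] = {}
    read_list = reads.reads if isinstance(reads, ReadSet) else reads
    for rid, seq in read_list:
        for oriented in (seq, revcomp(seq)):
            p = _place_read(oriented, doubled, index)
            if p is not None and _mismatch_positions(oriented, doubled, p).size \
                    <= max_mismatch_frac * len(seq):
                for i, b in enumerate(oriented):
                    pileup.setdefault((p + i) % n, Counter())[b] += 1
                break
    return pileup


# ---------------------------------------------------------------------------
# mapping statistics


@dataclass(frozen=True)
class CoverageStats:
    n_mapped: int
    n_total: int
    mean_read_len: float
    genome_length: int

    @property
    def fraction_of_total(self) -> float:
        return 100.0 * self.n_mapped / self.n_total if self.n_total else 0.0

    @property
    def depth(self) -> float:
        return self.n_mapped * self.mean_read_len / self.genome_length


def mapping_stats(
    reads: ReadSet | list[tuple[str, str]],
    genome: CircularSequence | str,
    min_identity: float = 0.95,
) -> CoverageStats:
    """Count reads aligning to the circular genome at >= min_identity
    (edit-distance identity) and derive fold-coverage from the mapped
    reads' mean length."""
    res = genome.residues if isinstance(genome, CircularSequence) else genome
    if not res:
        raise ValueError("empty genome")
    doubled = res + res
    read_list = reads.reads if isinstance(reads, ReadSet) else reads
    mapped_lens = []
    for rid, seq in read_list:
        budget = int((1 - min_identity) * len(seq))
        for oriented in (seq, revcomp(seq)):
            r = edlib.align(oriented, doubled, mode="HW", task="distance", k=budget)
            if r["editDistance"] != -1:
                mapped_lens.append(len(seq))
                break
    n_mapped = len(mapped_lens)
    mean_len = float(np.mean(mapped_lens)) if mapped_lens else 0.0
    return CoverageStats(n_mapped, len(read_list), mean_len, len(res))


# ---------------------------------------------------------------------------
# junction windows


def extract_junction_regions(genome, partition, flank: int) -> dict[str, str]:
    """The four 2 x flank windows centered on the LSC/IRb, IRb/SSC, SSC/IRa
    and IRa/LSC borders, wrapping the circle."""
    if partition is None:
        raise ValueError("genome has no region partition")
    if flank < 1:
        raise ValueError("flank must be >= 1")
    seq = genome.sequence if hasattr(genome, "sequence") else genome
    n = partition.genome_length
    smallest = min(e - s for s, e in partition.as_dict().values())
    if flank > smallest:
        raise ValueError(f"flank {flank} exceeds the smallest region ({smallest} bp)")
    doubled = seq.residues + seq.residues
    cuts = {
        "LSC/IRb": partition.lsc[1],
        "IRb/SSC": partition.irb[1],
        "SSC/IRa": partition.ssc[1],
        "IRa/LSC": partition.ira[1] % n,
    }
    return {name: doubled[(j - flank) % n : (j - flank) % n + 2 * flank]
            for name, j in cuts.items()}


# ---------------------------------------------------------------------------
# indexed fast path: read bank, extension, merge, correction, pipeline


def _kmer_index(s: str, k: int, step: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(0, len(s) - k + 1, step):
        idx[s[i : i + k]].append(i)
    return dict(idx)


# probe offsets covering every index parity for a step-3 target index
_PROBE_OFFSETS = (0, 1, 2, _K, _K + 1, _K + 2)


def _place_read(read: str, doubled: str, index: dict[str, list[int]],
                step: int = 1) -> int | None:
    offsets = (0, _K, 2 * _K) if step == 1 else _PROBE_OFFSETS
    for off in offsets:
        if off + _K > len(read):
            break
        for pos in index.get(read[off : off + _K], ()):
            p = pos - off
            if 0 <= p <= len(doubled) - len(read):
                return p
    return None


def _place_read_all(read: str, doubled: str, index: dict[str, list[int]],
                    step: int = 1) -> list[int]:
    """Every candidate placement of the read (reads from the two identical
    IR copies place ambiguously and must vote at both)."""
    offsets = (0, _K, 2 * _K) if step == 1 else _PROBE_OFFSETS
    for off in offsets:
        if off + _K > len(read):
            break
        hits = index.get(read[off : off + _K])
        if not hits:
            continue
        out = []
        for pos in hits:
            p = pos - off
            if 0 <= p <= len(doubled) - len(read):
                out.append(p)
        if out:
            return out
    return []


def _mismatch_positions(read: str, doubled: str, p: int) -> np.ndarray:
    a = np.frombuffer(read.encode(), dtype=np.uint8)
    b = np.frombuffer(doubled.encode()[p : p + len(read)], dtype=np.uint8)
    if a.size != b.size:
        return np.arange(a.size)
    return np.flatnonzero(a != b)


class _ReadBank:
    """Oriented reads with a sparse k-mer index for terminus queries."""

    def __init__(self, reads: ReadSet | list[tuple[str, str]], step: int = 19):
        read_list = reads.reads if isinstance(reads, ReadSet) else reads
        self.seqs: list[str] = []
        self.ids: list[str] = []
        for rid, seq in read_list:
            self.seqs.append(seq)
            self.ids.append(rid)
            self.seqs.append(revcomp(seq))
            self.ids.append(rid + "'")
        index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ridx, seq in enumerate(self.seqs):
            for pos in range(0, len(seq) - _K + 1, step):
                index[seq[pos : pos + _K]].append((ridx, pos))
        self.index = dict(index)


def _extend_right_fast(
    contig: str,
    bank: _ReadBank,
    min_identity: float,
    min_overlap: int,
    probe_span: int = 260,
    max_eval: int = 60,
) -> tuple[str, str, int] | None:
    """One greedy 3' extension using the read index; returns
    (new_contig, read id, overhang) or None at a fixed point."""
    L = len(contig)
    lo = max(0, L - probe_span)
    cands: dict[tuple[int, int], None] = {}
    for cpos in range(L - _K, lo - 1, -3):
        for ridx, rpos in bank.index.get(contig[cpos : cpos + _K], ()):
            cands[(ridx, cpos - rpos)] = None  # diag = contig pos of read start
    scored = []
    for ridx, diag in cands:
        seq = bank.seqs[ridx]
        ov_est = L - diag
        if ov_est < min_overlap or ov_est >= len(seq):
            continue
        scored.append((len(seq) - ov_est, ridx, ov_est))
    scored.sort(key=lambda t: (-t[0], bank.ids[t[1]]))
    best = None
    for overhang_est, ridx, ov_est in scored[:max_eval]:
        seq = bank.seqs[ridx]
        K = min(ov_est, 150, L)
        r = edlib.align(contig[-K:], seq, mode="HW", task="locations",
                        k=max(2, int((1 - min_identity) * K) + 2))
        if r["editDistance"] == -1:
            continue
        ident = 1 - r["editDistance"] / K
        if ident < min_identity:
            continue
        end = r["locations"][0][1]  # inclusive end of the tail window in read
        overhang = len(seq) - (end + 1)
        if overhang <= 0:
            continue
        cand = (overhang, ident, bank.ids[ridx], seq, end)
        if best is None or (cand[0], cand[1], _id_order(cand[2])) > (
            best[0], best[1], _id_order(best[2])
        ):
            best = cand
    if best is None:
        return None
    overhang, ident, rid, seq, end = best
    # refine the junction with a unique-anchor cut so short-period content
    # at the terminus cannot duplicate or drop a period
    cut = _junction_cut(contig, seq, end + 1)
    if not 0 < cut < len(seq):
        cut = end + 1
    return contig + seq[cut:], rid, len(seq) - cut


_HEAD_INDEX_CACHE: dict[int, tuple[str, dict]] = {}


def _find_overlap(
    x: str, y: str, min_overlap: int, min_identity: float = 0.99,
    head_span: int = 20_000, probe_step: int = 97,
) -> int | None:
    """Length ov such that suffix x[-ov:] aligns prefix y[:ov], or None.

    Diagonal voting on exact 21-mers from the x tail against the y head,
    then identity verification with edlib over (up to) the last 2 kb.
    """
    head = y[: min(len(y), head_span)]
    cached = _HEAD_INDEX_CACHE.get(len(head))
    if cached is not None and cached[0] == head:
        idx = cached[1]
    else:
        idx = _kmer_index(head, _K, step=1)
        _HEAD_INDEX_CACHE[len(head)] = (head, idx)
        if len(_HEAD_INDEX_CACHE) > 8:
            _HEAD_INDEX_CACHE.pop(next(iter(_HEAD_INDEX_CACHE)))
    # a shared k-mer at x position px (back = len(x) - px) and y position py
    # implies ov = len(x) - px + py = back + py, since x[-ov:] ~ y[:ov] maps
    # x position len(x) - ov + t onto y position t
    votes: Counter = Counter()
    span = min(len(x), 6000)
    for back in range(_K, span, probe_step):
        px = len(x) - back
        for py in idx.get(x[px : px + _K], ()):
            votes[back + py] += 1
    if not votes:
        return None
    ov, n_votes = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
    if n_votes < 3:
        return None
    if ov < min_overlap or ov > len(y):
        return None
    w = min(ov, 2000, len(x))
    r = edlib.align(x[-w:], y[max(0, ov - w - 60) : ov + 60], mode="HW",
                    task="distance")
    if r["editDistance"] == -1 or 1 - r["editDistance"] / w < min_identity:
        return None
    return ov


def _skeleton(s: str) -> str:
    """Run-length skeleton: consecutive duplicate bases collapsed."""
    return re.sub(r"(.)\1+", r"\1", s)


def _hamming_at(x: str, y: str, cut: int, m: int = 40) -> int:
    m = min(m, cut, len(x))
    if m == 0:
        return 0
    return sum(a != b for a, b in zip(x[-m:], y[cut - m : cut]))


def _sanity_cut(x: str, y: str, cut: int) -> int:
    """Repair a cut that is shifted by a short period: the contig tail must
    agree with the read just left of the cut. Only overrides cuts whose
    baseline disagreement is gross."""
    base = _hamming_at(x, y, cut)
    if base <= 4:
        return cut
    best = (base, 0)
    # |delta| = 1 shifts are homopolymer ties (benign, later corrected);
    # only short-period (>= 2) mis-cuts are worth overriding, and only on a
    # near-perfect realignment -- anything less is an indel artifact
    for delta in (-2, 2, -3, 3, -4, 4, -5, 5, -6, 6):
        c = cut + delta
        if not 0 < c <= len(y):
            continue
        h = _hamming_at(x, y, c)
        if h < best[0]:
            best = (h, delta)
    return cut + best[1] if best[0] <= 1 else cut


def _junction_cut(x: str, y: str, ov: int) -> int:
    """Position in y just past where x's last base aligns.

    Anchored on the rightmost exact 21-mer shared by the x tail and the y
    overlap region, so cuts are never drifted by short-period ambiguity at
    the junction; falls back to an edlib end-anchored alignment.
    """
    lo = max(0, ov - 600)
    hi = min(len(y), ov + 300)
    window = y[lo:hi]
    # walk back from the x end to a k-mer that is UNIQUE in the junction
    # window (short-period tandems at the junction make nearer anchors
    # ambiguous), then align the remaining x tail from that anchor with a
    # prefix-anchored alignment whose end gives the cut.
    for back in range(0, 400):
        px = len(x) - _K - back
        if px < 0:
            break
        kmer = x[px : px + _K]
        first = window.find(kmer)
        if first == -1 or window.find(kmer, first + 1) != -1:
            continue
        q = x[px:]
        tgt = y[lo + first : min(len(y), lo + first + len(q) + 60)]
        r = edlib.align(q, tgt, mode="SHW", task="locations")
        if r["editDistance"] == -1 or r["editDistance"] > 0.3 * len(q):
            continue
        # tied alignment ends at a homopolymer boundary are resolved by
        # preferring the cut whose spliced junction preserves the local
        # run-length skeleton: the residual error then sits inside a run
        # (fixable by homopolymer correction), never on a flanking base
        cands = [lo + first + e + 1 for (_s, e) in r["locations"]]
        cut = None
        for c in cands:
            if not 0 < c <= len(y):
                continue
            if abs(c - ov) > 8:
                continue
            if cut is None:
                cut = c
            if _skeleton(x[-20:] + y[c : c + 20]) in _skeleton(
                y[max(0, c - 26) : c + 20]
            ):
                cut = c
                break
        if cut is None:
            # an apparently unique anchor can still sit on the wrong copy of
            # a periodic tract when an error masks its twin; back off further
            continue
        return _sanity_cut(x, y, cut)
    w = min(200, len(x), ov + 100)
    target_lo = max(0, ov - w - 100)
    r = edlib.align(x[-w:], y[target_lo : min(len(y), ov + 100)],
                    mode="HW", task="locations")
    return _sanity_cut(x, y, target_lo + r["locations"][0][1] + 1)


def _self_rc_depth(contig: str, cap: int, chunk: int = 500, probe: int = 600) -> int:
    """Depth to which the contig's two ends mirror each other as reverse
    complements (both ends inside the IR).

    The two IR arms generally differ in depth, so the mirror image of the
    tail appears in the head region at an offset; the offset is located
    first with a probe alignment, then the mirrored extent is measured by
    chunk extension along it (with slack for accumulated read errors).
    Returns roughly min(arm depths), 0 when the ends do not mirror.
    """
    L = len(contig)
    W = min(L // 2, cap + 2 * probe + 2000)
    if L < 4 * probe:
        return 0
    budget = int(0.15 * probe)
    r = edlib.align(revcomp(contig[-probe:]), contig[:W], mode="HW",
                    task="locations", k=budget)
    if r["editDistance"] != -1:
        # tail arm is the shallower one; pairing contig[L-1-t] ~
        # comp(contig[off + t])
        off = r["locations"][0][0]

        def chunk_pair(d):
            a = contig[L - d - chunk : L - d]
            b = revcomp(contig[max(0, off + d - 60) : off + d + chunk + 60])
            return a, b
    else:
        r = edlib.align(revcomp(contig[:probe]), contig[L - W :], mode="HW",
                        task="locations", k=budget)
        if r["editDistance"] == -1:
            return 0
        # head arm is the shallower one; pairing contig[t] ~
        # comp(contig[L - 1 - off2 - t])
        off2 = W - (r["locations"][0][1] + 1)

        def chunk_pair(d):
            a = contig[d : d + chunk]
            b = revcomp(contig[max(0, L - off2 - d - chunk - 60) : L - off2 - d + 60])
            return a, b
    d = probe
    while d <= cap:  # allow d to reach/exceed cap so the freeze can fire
        a, b = chunk_pair(d)
        ra = edlib.align(a, b, mode="HW", task="distance")
        if ra["editDistance"] == -1 or 1 - ra["editDistance"] / chunk < 0.9:
            break
        d += chunk
    return d


def merge_and_circularize(
    c1: str, c2: str, min_overlap: int = 1000, min_identity: float = 0.99
) -> tuple[str, tuple[int, int], bool]:
    """Merge two contigs whose ends overlap inside the two IR copies into a
    single circular sequence.

    Tries the second contig in both orientations; both junction overlaps
    must reach ``min_overlap`` at ``min_identity`` identity. Returns
    (circle, (overlap1, overlap2), flipped).
    """
    if min(len(c1), len(c2)) <= min_overlap:
        raise AssemblyError("contigs shorter than the required overlap")
    attempts = []
    for flipped, cc2 in ((False, c2), (True, revcomp(c2))):
        ov1 = _find_overlap(c1, cc2, min_overlap, min_identity)
        ov2 = _find_overlap(cc2, c1, min_overlap, min_identity)
        attempts.append((flipped, ov1, ov2))
        if ov1 and ov2:
            cut1 = _junction_cut(c1, cc2, ov1)
            merged = c1 + cc2[cut1:]
            cut2 = _junction_cut(cc2, c1, ov2)
            return merged[cut2:], (ov1, ov2), flipped
    raise AssemblyError(
        "not circularizable; best candidate overlaps: "
        + ", ".join(f"flip={f} ov1={o1} ov2={o2}" for f, o1, o2 in attempts)
    )


_RUN_RE = re.compile(r"(A{2,}|C{2,}|G{2,}|T{2,})")


def correct_homopolymers(
    contig: str,
    accurate: ReadSet | list[tuple[str, str]],
    min_depth: int = 5,
    majority: float = 0.6,
    min_run: int = 2,
    anchor: int = 10,
    circular: bool = True,
    max_rounds: int = 2,
) -> tuple[str, int]:
    """Rewrite homopolymer runs of the contig to the modal run length
    observed in accurate reads spanning them with ``anchor`` bp on each
    side; non-homopolymer positions are never altered.

    Runs down to length ``min_run`` (default 2) are examined so that a
    true run of three shortened by a sequencing deletion is still seen.
    Returns (corrected sequence, number of rewritten runs).
    """
    if min_depth < 1 or majority <= 0.5:
        raise ValueError("min_depth >= 1 and majority > 0.5 required")
    read_list = accurate.reads if isinstance(accurate, ReadSet) else accurate
    total_rewrites = 0
    rotated = 0
    focus: list[tuple[int, int]] | None = None
    for _ in range(max_rounds):
        rot = 0
        if circular:
            # rotate so position 0 does not split a run (splices stay local);
            # undone before returning
            while rot < len(contig) - 1 and contig[rot] == contig[-1]:
                rot += 1
            if rot:
                contig = contig[rot:] + contig[:rot]
                rotated += rot
                focus = None
        n = len(contig)
        doubled = contig + contig if circular else contig
        runs = [
            (m.start(), m.end(), m.group(0)[0])
            for m in _RUN_RE.finditer(contig)
            if m.end() - m.start() >= min_run
        ]
        if focus is not None and not rot:
            # later rounds only re-examine neighborhoods of prior rewrites
            runs = [r for r in runs
                    if any(fs - 60 <= r[0] <= fe + 60 for fs, fe in focus)]
        if not runs:
            break
        n_base_runs = len(runs)
        # second copy of each run at +n so reads placed across the origin of
        # the doubled sequence still vote
        runs2 = runs + ([(rs + n, re_ + n, b) for rs, re_, b in runs] if circular else [])
        run_starts = np.array([r[0] for r in runs2])
        run_ends = np.array([r[1] for r in runs2])
        index = _kmer_index(doubled, _K, step=3)
        doubled_b = doubled.encode()
        darr = np.frombuffer(doubled_b, dtype=np.uint8)
        votes: dict[int, Counter] = defaultdict(Counter)
        exact_by_len: dict[int, list[int]] = defaultdict(list)

        def vote_mismatch(read: str, p: int, mm_pos: np.ndarray):
            lo = int(np.searchsorted(run_starts, p + anchor, side="left"))
            hi = int(np.searchsorted(run_ends, p + len(read) - anchor, side="right"))
            for ri in range(lo, min(hi, len(runs2))):
                rs, re_, base = runs2[ri]
                if rs < p + anchor or re_ > p + len(read) - anchor:
                    continue
                if mm_pos.size and ((mm_pos >= rs - p - 2) & (mm_pos <= re_ - p + 1)).any():
                    # the read disagrees locally (e.g. a pair of compensating
                    # indels shows up as mismatch columns): vote the run
                    # length the read itself carries there
                    seg = read[max(0, rs - p - 2) : re_ - p + 2]
                    best = 0
                    for m in re.finditer(f"{base}+", seg):
                        best = max(best, m.end() - m.start())
                    if best:
                        votes[ri % n_base_runs][best] += 1
                else:
                    votes[ri % n_base_runs][re_ - rs] += 1

        def vote_aligned(read: str, p: int):
            window_lo = max(0, p - 12)
            window = doubled[window_lo : p + len(read) + 12]
            r = edlib.align(read, window, mode="HW", task="path")
            if r["editDistance"] == -1 or r["editDistance"] > 0.2 * len(read):
                return
            t0 = window_lo + r["locations"][0][0]
            q = t = 0
            tmap = {t0: 0}
            for num, op in re.findall(r"(\d+)([=XIDM])", r["cigar"]):
                num = int(num)
                if op in "=XM":
                    q += num
                    t += num
                elif op == "I":  # present in read only
                    q += num
                else:  # D: present in contig only
                    t += num
                tmap[t0 + t] = q
            keys = sorted(tmap)

            def read_pos(tpos):
                i = int(np.searchsorted(keys, tpos, side="right")) - 1
                return tmap[keys[i]] + (tpos - keys[i])

            t_end = t0 + t
            lo = int(np.searchsorted(run_starts, t0 + anchor, side="left"))
            hi = int(np.searchsorted(run_ends, t_end - anchor, side="right"))
            for ri in range(lo, min(hi, len(runs2))):
                rs, re_, base = runs2[ri]
                if rs < t0 + anchor or re_ > t_end - anchor:
                    continue
                q_lo = max(0, read_pos(rs) - 1)
                q_hi = min(len(read), read_pos(re_) + 1)
                best = 0
                for m in re.finditer(f"{base}+", read[q_lo:q_hi]):
                    best = max(best, m.end() - m.start())
                votes[ri % n_base_runs][best] += 1

        for rid, seq in read_list:
            for oriented in (seq, revcomp(seq)):
                ps = _place_read_all(oriented, doubled, index, step=3)
                if not ps:
                    continue
                rb = oriented.encode()
                # a read matching both IR copies votes at each of them
                for p in sorted({q % n if circular else q for q in ps}):
                    if doubled_b[p : p + len(rb)] == rb:
                        exact_by_len[len(rb)].append(p)
                    else:
                        mm = np.flatnonzero(
                            np.frombuffer(rb, dtype=np.uint8) != darr[p : p + len(rb)]
                        )
                        if mm.size <= 3:
                            vote_mismatch(oriented, p, mm)
                        else:
                            vote_aligned(oriented, p)
                break

        # reads identical to the contig confirm every run they span with
        # full anchors: run ri is confirmed by placements p in
        # [run_end + anchor - read_len, run_start - anchor]
        cur_len = run_ends - run_starts
        for L_r, ps in exact_by_len.items():
            ps_arr = np.sort(np.asarray(ps))
            lo_b = run_ends + anchor - L_r
            hi_b = run_starts - anchor
            cnt = np.searchsorted(ps_arr, hi_b, side="right") - np.searchsorted(
                ps_arr, lo_b, side="left"
            )
            for ri in np.flatnonzero(cnt > 0):
                votes[int(ri) % n_base_runs][int(cur_len[ri])] += int(cnt[ri])

        rewrites = []
        for ri, obs in votes.items():
            rs, re_, base = runs[ri]
            if rs >= n:
                continue
            total = sum(obs.values())
            if total < min_depth:
                continue
            mode, cnt = max(sorted(obs.items()), key=lambda kv: kv[1])
            if cnt / total >= majority and mode != re_ - rs and mode >= 1:
                rewrites.append((rs, re_, base * mode))
        if not rewrites:
            break
        rewrites.sort()
        parts = []
        cur = 0
        shift = 0
        focus = []
        for rs, re_, repl in rewrites:
            parts.append(contig[cur:rs])
            parts.append(repl)
            focus.append((rs + shift, rs + shift + len(repl)))
            shift += len(repl) - (re_ - rs)
            cur = re_
        parts.append(contig[cur:])
        contig = "".join(parts)
        total_rewrites += len(rewrites)
    if rotated:
        contig = contig[-rotated:] + contig[:-rotated]
    return contig, total_rewrites


@dataclass
class AssemblyReport:
    sequence: CircularSequence
    rounds: int
    contig_lengths: tuple[int, int]
    junction_overlaps: tuple[int, int]
    flipped_second_contig: bool
    n_corrected_runs: int = 0


def assemble_plastome(
    shotgun: ReadSet | list[tuple[str, str]],
    accurate: ReadSet | list[tuple[str, str]] | None,
    seed_lsc: str,
    seed_ssc: str,
    min_identity: float = 0.95,
    min_overlap: int = 150,
    merge_overlap: int = 1000,
    ir_cap: int = 15_000,
    max_rounds: int = 3000,
) -> AssemblyReport:
    """Two-seed greedy assembly of a circular quadripartite genome.

    Each seed is extended at both ends until the two contigs overlap inside
    both inverted-repeat copies; a contig whose own two ends become deeply
    reverse-complementary (both ends inside the IR) is frozen at depth
    ``ir_cap`` so an arm never runs through an entire IR. The contigs are
    then merged, circularized and homopolymer-corrected.

    ``min_overlap`` (default 150) exceeds the longest tandem tract of the
    emulated genomes, so a qualifying overlap can never lie entirely within
    a repeated region shorter than the IRs.
    """
    bank = _ReadBank(shotgun)
    contigs = [seed_lsc, seed_ssc]
    frozen = [[False, False], [False, False]]  # [contig][left, right]
    src_depth = [0, 0]
    checked_at = [0, 0]
    result = None
    rounds = 0
    while rounds < max_rounds:
        rounds += 1
        progressed = False
        for ci in range(2):
            if not frozen[ci][1]:
                got = _extend_right_fast(contigs[ci], bank, min_identity, min_overlap)
                if got is None:
                    frozen[ci][1] = True
                else:
                    contigs[ci] = got[0]
                    progressed = True
            if not frozen[ci][0]:
                rc = revcomp(contigs[ci])
                got = _extend_right_fast(rc, bank, min_identity, min_overlap)
                if got is None:
                    frozen[ci][0] = True
                else:
                    contigs[ci] = revcomp(got[0])
                    progressed = True
        # backstop: freeze a contig whose ends mirror each other deeply
        for ci in range(2):
            if not all(frozen[ci]) and len(contigs[ci]) - checked_at[ci] > 1200:
                checked_at[ci] = len(contigs[ci])
                src_depth[ci] = _self_rc_depth(contigs[ci], ir_cap)
                if src_depth[ci] >= ir_cap:
                    frozen[ci] = [True, True]
        # merge only once BOTH junctions exist in one consistent orientation
        # (single cross-orientation overlaps are mirror artifacts of the
        # self-symmetric IR arms and must not freeze anything)
        if rounds % 10 == 0 or not progressed:
            c1, c2 = contigs
            for flipped, cc2 in ((False, c2), (True, revcomp(c2))):
                o1 = _find_overlap(c1, cc2, merge_overlap)
                o2 = _find_overlap(cc2, c1, merge_overlap)
                if o1 is not None and o2 is not None:
                    result = merge_and_circularize(c1, c2, merge_overlap)
                    break
            if result is not None:
                break
        if not progressed and all(all(f) for f in frozen):
            break
    if result is None:
        result = merge_and_circularize(contigs[0], contigs[1], merge_overlap)
    circle, (ov1, ov2), flipped = result
    n_fixed = 0
    if accurate is not None:
        circle, n_fixed = correct_homopolymers(circle, accurate)
    return AssemblyReport(
        sequence=CircularSequence(id="assembly", residues=circle, is_circular=True),
        rounds=rounds,
        contig_lengths=(len(contigs[0]), len(contigs[1])),
        junction_overlaps=(ov1, ov2),
        flipped_second_contig=flipped,
        n_corrected_runs=n_fixed,
    )
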