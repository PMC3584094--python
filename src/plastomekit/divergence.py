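"""Pairwise alignment, Kimura two-parameter distances and per-gene
divergence profiling across taxa.

The K2P model corrects separately for transitions (proportion P) and
transversions (proportion Q) over the ungapped compared sites of a pairwise
alignment:

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Pairwise deletion is used for gaps/ambiguities; a pair is flagged saturated
(d undefined) when 1 - 2P - Q <= 0 or 1 - 2Q <= 0, and saturated pairs are
excluded (with a count) from per-gene means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_PURINES = {"A", "G"}
_VALID = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows of equal length."""

    row1: str
    row2: str
    gene: str = ""
    taxa: tuple[str, str] = ("", "")
    score: float | None = None

    def __post_init__(self):
        if len(self.row1) != len(self.row2):
            raise ValueError("aligned rows differ in length")
        if not any(a != "-" and b != "-" for a, b in zip(self.row1, self.row2)):
            raise ValueError("alignment has no ungapped column")


@dataclass(frozen=True)
class K2PResult:
    p: float
    q: float
    d: float | None
    n: int
    saturated: bool = False


def align_pair(
    s1: str,
    s2: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
    gene: str = "",
    taxa: tuple[str, str] = ("", ""),
) -> PairwiseAlignment:
    """Needleman-Wunsch global alignment with affine gaps (Gotoh).

    The first base of a gap costs ``gap_open``, each further base
    ``gap_extend``. Traceback is deterministic, preferring diagonal over up
    (gap in the second sequence) over left.
    """
    if not s1 or not s2:
        raise ValueError("empty sequence")
    n, m = len(s1), len(s2)
    NEG = -math.inf
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # vertical gap: consumes s1
    Y = np.full((n + 1, m + 1), NEG)  # horizontal gap: consumes s2
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        ci = s1[i - 1]
        for j in range(1, m + 1):
            sub = match if ci == s2[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))  # first max: M > X > Y
    a1, a2 = [], []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            a1.append(s1[i - 1])
            a2.append(s2[j - 1])
            state = int(np.argmax([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]))
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            a1.append(s1[i - 1])
            a2.append("-")
            state = int(np.argmax([M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                                   Y[i - 1, j] + gap_open]))
            i -= 1
        elif state == 2 and j > 0:
            a1.append("-")
            a2.append(s2[j - 1])
            state = [0, 2][int(np.argmax([M[i, j - 1] + gap_open,
                                          Y[i, j - 1] + gap_extend]))]
            j -= 1
        elif i > 0:
            state = 1
        else:
            state = 2
    score = float(max(M[n, m], X[n, m], Y[n, m]))
    return PairwiseAlignment("".join(reversed(a1)), "".join(reversed(a2)),
                             gene=gene, taxa=taxa, score=score)


def k2p(aln: PairwiseAlignment) -> K2PResult:
    """Kimura two-parameter distance with pairwise deletion of gaps."""
    return k2p_from_rows(aln.row1, aln.row2)


def k2p_from_rows(row1: str, row2: str) -> K2PResult:
    n = ts = tv = 0
    for a, b in zip(row1.upper(), row2.upper()):
        if a not in _VALID or b not in _VALID:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("zero compared sites")
    p, q = ts / n, tv / n
    w1, w2 = 1 - 2 * p - q, 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return K2PResult(p, q, None, n, saturated=True)
    return K2PResult(p, q, -0.5 * math.log(w1 * math.sqrt(w2)), n)


@dataclass(frozen=True)
class GeneDivergence:
    gene: str
    mean_d: float | None
    n_pairs: int
    n_saturated: int
    rank: int | None
    len_min: int
    len_max: int

    @property
    def len_range(self) -> int:
        return self.len_max - self.len_min


def gene_profile(alignments: dict[str, dict[str, str]]) -> list[GeneDivergence]:
    """Mean pairwise K2P distance per gene over all unordered taxon pairs.

    ``alignments`` maps gene -> taxon -> gapped row (one multiple alignment
    per gene). Saturated pairs are excluded from the mean but counted;
    genes whose pairs are all saturated get mean None and no rank. Genes
    are ranked 1 = most divergent; the result is permutation-invariant in
    taxon order.
    """
    import warnings

    prelim = []
    for gene, rows in alignments.items():
        taxa = sorted(rows)
        if len(taxa) < 2:
            raise ValueError(f"gene {gene}: need at least two taxa")
        ds = []
        n_sat = 0
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                r = k2p_from_rows(rows[taxa[i]], rows[taxa[j]])
                if r.saturated:
                    n_sat += 1
                else:
                    ds.append(r.d)
        lens = [len(v.replace("-", "")) for v in rows.values()]
        if not ds:
            warnings.warn(f"gene {gene}: all pairs saturated; excluded from ranking")
            prelim.append((gene, None, 0, n_sat, min(lens), max(lens)))
        else:
            prelim.append((gene, float(np.mean(ds)), len(ds), n_sat, min(lens), max(lens)))
    ranked = sorted((g for g in prelim if g[1] is not None), key=lambda t: (-t[1], t[0]))
    rank_of = {g[0]: i + 1 for i, g in enumerate(ranked)}
    return [
        GeneDivergence(gene, mean_d, n_pairs, n_sat, rank_of.get(gene), lmin, lmax)
        for gene, mean_d, n_pairs, n_sat, lmin, lmax in prelim
    ]


def sliding_identity(
    rows: dict[str, str], window: int = 100, step: int = 25, cutoff: float = 0.70
):
    """Windowed all-row column identity track over a multiple alignment.

    A column agrees when every row carries the same unambiguous base (any
    gap counts as disagreement). Returns (midpoints, identities, flagged)
    where flagged marks windows whose identity falls below the cutoff; an
    alignment shorter than the window yields a single whole-length window.
    """
    if window < step:
        raise ValueError("window must be >= step")
    mats = [np.frombuffer(v.encode(), dtype=np.uint8) for v in rows.values()]
    L = mats[0].size
    if any(m.size != L for m in mats):
        raise ValueError("rows have unequal lengths")
    stack = np.vstack(mats)
    agree = np.all(stack == stack[0], axis=0) & (stack[0] != ord("-"))
    if L <= window:
        ident = float(agree.mean())
        return [L / 2.0], [ident], [ident < cutoff]
    mids, idents, flagged = [], [], []
    for a in range(0, L - window + 1, step):
        v = float(agree[a : a + window].mean())
        mids.append(a + window / 2.0)
        idents.append(v)
        flagged.append(v < cutoff)
    return mids, idents, flagged


def length_variation(genes: dict[str, dict[str, str]]) -> dict[str, tuple[int, int, int]]:
    """Ungapped length (min, max, range) per gene across taxa."""
    out = {}
    for gene, rows in genes.items():
        lens = [len(v.replace("-", "")) for v in rows.values()]
        out[gene] = (min(lens), max(lens), max(lens) - min(lens))
    return out


# ---------------------------------------------------------------------------
# known-truth simulation for validation


def _jc_evolve(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a 0..3 coded sequence to expected Jukes-Cantor distance d."""
    p_diff = 0.75 * (1 - math.exp(-4.0 * d / 3.0))
    out = seq.copy()
    hit = rng.random(seq.size) < p_diff
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def simulate_gene_set(
    rates: dict[str, float],
    n_taxa: int = 6,
    length: int = 900,
    seed: int = 0,
) -> dict[str, dict[str, str]]:
    """Star-tree gene alignments with known per-gene expected divergence.

    Each gene evolves from a random ancestor along independent branches of
    length rate/2 under Jukes-Cantor, so the expected pairwise distance
    within a gene equals its rate. Returns gene -> taxon -> row.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    bases = np.array(list("ACGT"))
    out: dict[str, dict[str, str]] = {}
    for gene, rate in rates.items():
        root = rng.integers(0, 4, size=length)
        rows = {}
        for t in range(n_taxa):
            tip = _jc_evolve(root, rate / 2.0, rng)
            rows[f"taxon{t + 1}"] = "".join(bases[tip])
        out[gene] = rows
    return out
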