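"""Pairwise alignment, K2P distances and divergence profiling."""

import itertools
import math
from functools import lru_cache

import numpy as np
import pytest

from plastomekit import divergence as dv
from conftest import random_dna


def nw_oracle(s1, s2, match=1.0, mismatch=-1.0, gap_open=-5.0, gap_extend=-1.0):
    """Exhaustive affine-gap global alignment score by memoized recursion."""

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 = last was match/mismatch, 1 = gap in s2, 2 = gap in s1
        if i == 0 and j == 0:
            return 0.0 if state == 0 else -math.inf
        opts = []
        if i > 0 and j > 0:
            sub = match if s1[i - 1] == s2[j - 1] else mismatch
            if state == 0:
                opts.append(max(best(i - 1, j - 1, k) for k in range(3)) + sub)
        if i > 0 and state == 1:
            opts.append(best(i - 1, j, 1) + gap_extend)
            opts.append(max(best(i - 1, j, 0), best(i - 1, j, 2)) + gap_open)
        if j > 0 and state == 2:
            opts.append(best(i, j - 1, 2) + gap_extend)
            opts.append(max(best(i, j - 1, 0), best(i, j - 1, 1)) + gap_open)
        return max(opts) if opts else -math.inf

    return max(best(len(s1), len(s2), k) for k in range(3))


def test_identical_sequences_align_gapless():
    a = dv.align_pair("ACGTACGT", "ACGTACGT")
    assert a.row1 == a.row2 == "ACGTACGT"
    assert a.score == 8.0


def test_single_gap_alignment():
    a = dv.align_pair("ACGT", "ACT")
    assert "-" in a.row2 and a.row1 == "ACGT"
    assert a.row2.replace("-", "") == "ACT"


@pytest.mark.parametrize("trial", range(12))
def test_alignment_score_equals_exhaustive_oracle(trial):
    rng = np.random.default_rng(3000 + trial)
    s1 = random_dna(rng, int(rng.integers(1, 13)))
    s2 = random_dna(rng, int(rng.integers(1, 13)))
    got = dv.align_pair(s1, s2)
    assert got.score == pytest.approx(nw_oracle(s1, s2))
    # the emitted rows must actually realize the reported score
    score = 0.0
    prev = None
    for a, b in zip(got.row1, got.row2):
        if a != "-" and b != "-":
            score += 1.0 if a == b else -1.0
            prev = None
        else:
            cur = "g1" if a == "-" else "g2"
            score += -1.0 if prev == cur else -5.0
            prev = cur
    assert score == pytest.approx(got.score)


def test_k2p_identical_is_zero():
    r = dv.k2p_from_rows("ACGT" * 10, "ACGT" * 10)
    assert (r.p, r.q, r.d) == (0.0, 0.0, 0.0)


def test_k2p_closed_form_hand_value():
    """10 transitions + 10 transversions per 100 sites: d = -0.5 ln(0.7 sqrt(0.8))."""
    row1 = "A" * 80 + "G" * 10 + "C" * 10
    row2 = "A" * 80 + "A" * 10 + "A" * 10
    r = dv.k2p_from_rows(row1, row2)
    assert (r.p, r.q) == (0.1, 0.1)
    assert r.d == pytest.approx(-0.5 * math.log(0.7 * math.sqrt(0.8)))
    assert round(r.d, 4) == 0.2341


def test_k2p_saturation_flagged_not_raised():
    r = dv.k2p_from_rows("A" * 30 + "G" * 30 + "C" * 40,
                         "G" * 30 + "A" * 30 + "A" * 40)
    assert r.saturated and r.d is None
    with pytest.raises(ValueError):
        dv.k2p_from_rows("---", "AAA")


def test_k2p_pairwise_deletion_of_gaps():
    r = dv.k2p_from_rows("AC--GT", "ACGTGT")
    assert r.n == 4 and r.d == 0.0


def test_k2p_monotone_in_transitions_at_fixed_q():
    ds = []
    for ts in range(0, 25, 5):
        row1 = "A" * 100
        row2 = "G" * ts + "C" * 10 + "A" * (90 - ts)
        ds.append(dv.k2p_from_rows(row1, row2).d)
    assert all(b > a for a, b in zip(ds, ds[1:]))


def test_k2p_consistent_with_jc_generator():
    """With equal transition/transversion rates the estimate matches the
    generating distance within 3 standard errors."""
    rng = np.random.default_rng(8)
    L, d_true = 20_000, 0.12
    root = rng.integers(0, 4, size=L)
    tip = dv._jc_evolve(root, d_true, rng)
    bases = np.array(list("ACGT"))
    r = dv.k2p_from_rows("".join(bases[root]), "".join(bases[tip]))
    se = math.sqrt(d_true / L) * 2  # generous closed-form-free bound
    assert abs(r.d - d_true) < 3 * se


def test_gene_profile_zero_for_identical_taxa():
    rows = {"g": {"t1": "ACGTACGT", "t2": "ACGTACGT"}}
    (p,) = dv.gene_profile(rows)
    assert p.mean_d == 0.0 and p.rank == 1 and p.len_range == 0


def test_gene_profile_mean_matches_closed_form():
    row1 = "A" * 80 + "G" * 10 + "C" * 10
    row2 = "A" * 100
    prof = dv.gene_profile({"g": {"a": row1, "b": row2}})
    assert prof[0].mean_d == pytest.approx(0.2341, abs=5e-5)


def test_gene_profile_permutation_invariant():
    rng = np.random.default_rng(5)
    genes = dv.simulate_gene_set({"g1": 0.05, "g2": 0.15}, n_taxa=5, seed=3)
    prof1 = dv.gene_profile(genes)
    shuffled = {g: dict(reversed(list(rows.items()))) for g, rows in genes.items()}
    prof2 = dv.gene_profile(shuffled)
    assert [(p.gene, p.mean_d, p.rank) for p in prof1] == [
        (p.gene, p.mean_d, p.rank) for p in prof2]


def test_rank_recovery_across_rate_classes():
    """Per-gene mean K2P ranking recovers the generating rate order in at
    least 95% of seeds (three rate classes)."""
    rates = {"slow": 0.02, "mid": 0.08, "fast": 0.20}
    ok = 0
    for seed in range(20):
        prof = dv.gene_profile(dv.simulate_gene_set(rates, n_taxa=4, length=900,
                                                    seed=seed))
        order = [p.gene for p in sorted(prof, key=lambda p: p.rank)]
        ok += order == ["fast", "mid", "slow"]
    assert ok >= 19


def test_sliding_identity_uniform_and_flagged_block():
    rows = {"a": "A" * 400, "b": "A" * 400, "c": "A" * 400}
    mids, idents, flagged = dv.sliding_identity(rows)
    assert all(v == 1.0 for v in idents) and not any(flagged)
    div = {"a": "A" * 150 + "C" * 100 + "A" * 150,
           "b": "A" * 150 + "G" * 100 + "A" * 150,
           "c": "A" * 400}
    mids, idents, flagged = dv.sliding_identity(div, window=100, step=25)
    for m, f in zip(mids, flagged):
        overlaps = m + 50 > 150 and m - 50 < 250
        assert f == (overlaps and (min(250, m + 50) - max(150, m - 50)) > 30)
    # cutoff 0 flags nothing
    _, _, fl0 = dv.sliding_identity(div, cutoff=0.0)
    assert not any(fl0)


def test_sliding_identity_short_alignment_single_window():
    rows = {"a": "ACGT" * 10, "b": "ACGT" * 10}
    mids, idents, flagged = dv.sliding_identity(rows, window=100, step=25)
    assert len(idents) == 1 and idents[0] == 1.0


def test_length_variation_toy_and_large_indel():
    genes = {
        "same": {"a": "AAA", "b": "AAA"},
        "range12": {"a": "A" * 300, "b": "A" * 312},
        "gapped": {"a": "AC-" * 100, "b": "ACG" * 100},
    }
    lv = dv.length_variation(genes)
    assert lv["same"] == (3, 3, 0)
    assert lv["range12"] == (300, 312, 12)
    assert lv["gapped"] == (200, 300, 100)
    big = {"ycf1": {"a": "A" * 3000, "b": "A" * 4300}}
    assert dv.length_variation(big)["ycf1"][2] > 1000
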