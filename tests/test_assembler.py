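"""Greedy seed-and-extend assembly, consensus, correction and mapping."""

import numpy as np
import pytest

from plastomekit import assembler as asm
from plastomekit import structure as st
from plastomekit import synthetic_data as sd
from plastomekit.core_io import revcomp
from conftest import random_dna


def tile_reads(template, read_len=150, step=40, prefix="r"):
    return [(f"{prefix}{i:03d}", template[s : s + read_len])
            for i, s in enumerate(range(0, len(template) - 60, step))]


# -- seed matching -----------------------------------------------------------


def test_seed_match_identity_boundary(rng):
    seed = random_dna(rng, 200)
    exact = seed[50:130]
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    lst = list(exact)
    for p in (5, 20, 40, 60):
        lst[p] = flip[lst[p]]
    four = "".join(lst)  # 4 mismatches over 80 -> identity 0.95
    lst[70] = flip[lst[70]]
    five = "".join(lst)  # 5 mismatches -> 0.9375
    hits = asm.seed_match([("a", four), ("b", five), ("c", revcomp(exact))], seed)
    got = {h.read_id: h for h in hits}
    assert set(got) == {"a", "c"}
    assert got["a"].identity == pytest.approx(0.95)
    assert got["c"].reverse and got["c"].identity == 1.0


def test_seed_match_validates_inputs(rng):
    with pytest.raises(ValueError):
        asm.seed_match([], random_dna(rng, 20))
    with pytest.raises(ValueError):
        asm.seed_match([], random_dna(rng, 100), min_identity=0.0)


# -- greedy extension --------------------------------------------------------


def test_iterated_extension_reconstructs_template(rng):
    template = random_dna(rng, 2000)
    reads = tile_reads(template)
    state = asm.AssemblyState.from_seed(template[950:1050])
    prev = ""
    while state.contig != prev:
        prev = state.contig
        state = asm.extend_contig(state, reads, min_overlap=30)
    assert state.contig == template
    assert all(sum(c.values()) >= 1 for c in state.pileup.values())
    assert all(end in ("3'", "5'") for end, _, _ in state.extension_log)


def test_extension_fixed_point_when_no_read_overlaps(rng):
    template = random_dna(rng, 500)
    state = asm.AssemblyState.from_seed(template[:100])
    foreign = [("x", random_dna(rng, 120))]
    out = asm.extend_contig(state, foreign, min_overlap=30)
    assert out.contig == state.contig


def test_tie_broken_by_identity_then_read_id(rng):
    contig = random_dna(rng, 300)
    tail = contig[-60:]
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    ext = random_dna(rng, 80)
    perfect = tail + ext
    lst = list(tail)
    lst[10] = flip[lst[10]]
    worse = "".join(lst) + ext
    state = asm.AssemblyState.from_seed(contig)
    out = asm.extend_contig(state, [("zz_perfect", perfect), ("aa_worse", worse)],
                            min_overlap=30)
    assert out.extension_log[0][1] == "zz_perfect"
    # equal identity: lexicographically smaller id wins
    state = asm.AssemblyState.from_seed(contig)
    out = asm.extend_contig(state, [("b", perfect), ("a", perfect)], min_overlap=30)
    assert out.extension_log[0][1] == "a"


def test_contig_never_shrinks(rng):
    template = random_dna(rng, 1200)
    reads = tile_reads(template)
    state = asm.AssemblyState.from_seed(template[500:650])
    for _ in range(10):
        nxt = asm.extend_contig(state, reads, min_overlap=30)
        assert len(nxt.contig) >= len(state.contig)
        state = nxt


# -- consensus and polymorphisms --------------------------------------------


def test_consensus_plurality_tie_and_depth():
    from collections import Counter

    pileup = {0: Counter({"A": 5}), 1: Counter({"A": 3, "G": 3}),
              2: Counter({"T": 1}), 3: Counter({"C": 2})}
    assert asm.call_consensus(pileup) == "AATC"
    assert asm.call_consensus(pileup, min_depth=2) == "AANC"
    with pytest.raises(ValueError):
        asm.call_consensus({})


def test_polymorphism_scan_finds_planted_heterozygous_site(rng):
    hap1 = random_dna(rng, 1000)
    pos = 400
    alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[hap1[pos]]
    hap2 = hap1[:pos] + alt + hap1[pos + 1 :]
    reads = []
    for i in range(300):
        src = hap1 if i % 2 else hap2
        s0 = int(rng.integers(0, 950))
        reads.append((f"p{i}", src[s0 : s0 + 50]))
    pile = asm.build_pileup(reads, hap1)
    sites = asm.scan_polymorphisms(pile)
    assert [s.position for s in sites] == [pos]
    assert sites[0].maf <= 0.5
    assert sum(sites[0].alleles.values()) == sites[0].depth


def test_polymorphism_maf_threshold_boundary():
    from collections import Counter

    pile = {5: Counter({"A": 81, "C": 19}), 6: Counter({"A": 80, "C": 20})}
    out = asm.scan_polymorphisms(pile, maf_threshold=0.2, min_depth=10)
    assert [s.position for s in out] == [6]


def test_homogeneous_reads_give_no_sites(rng):
    hap = random_dna(rng, 1000)
    reads = [(f"h{i}", hap[int(rng.integers(0, 950)) :][:50]) for i in range(300)]
    assert asm.scan_polymorphisms(asm.build_pileup(reads, hap)) == []


# -- homopolymer correction ---------------------------------------------------


def _acc_reads(rng, truth, n):
    return [(f"a{i}", truth[int(rng.integers(0, len(truth) - 50)) :][:50])
            for i in range(n)]


@pytest.mark.parametrize("contig_run,truth_run", [("AAAA", "AAAAA"),
                                                  ("GG", "GGG"),
                                                  ("TTTTT", "TTTT")])
def test_run_length_rewritten_to_majority(rng, contig_run, truth_run):
    left, right = random_dna(rng, 500), random_dna(rng, 500)
    base = contig_run[0]
    if left[-1] == base:
        left = left[:-1] + {"A": "C", "G": "C", "T": "C", "C": "G"}[base]
    if right[0] == base:
        right = {"A": "C", "G": "C", "T": "C", "C": "G"}[base] + right[1:]
    truth = left + truth_run + right
    contig = left + contig_run + right
    fixed, n = asm.correct_homopolymers(contig, _acc_reads(rng, truth, 600),
                                        circular=False)
    assert fixed == truth and n == 1


def test_unspanned_run_left_untouched(rng):
    truth = random_dna(rng, 300) + "AAAAA" + random_dna(rng, 300)
    contig = truth[:300] + "AAAA" + truth[305:]
    # accurate reads only from the left flank never span the run
    reads = [(f"a{i}", truth[int(rng.integers(0, 200)) :][:50]) for i in range(200)]
    fixed, n = asm.correct_homopolymers(contig, reads, circular=False)
    assert fixed == contig and n == 0


def test_clean_contig_is_identity(rng):
    truth = random_dna(rng, 1500)
    fixed, n = asm.correct_homopolymers(truth, _acc_reads(rng, truth, 900),
                                        circular=False)
    assert fixed == truth and n == 0


def test_non_homopolymer_columns_never_altered(rng):
    truth = random_dna(rng, 800) + "CCCC" + random_dna(rng, 800)
    contig = truth[:800] + "CCC" + truth[804:]
    fixed, _ = asm.correct_homopolymers(contig, _acc_reads(rng, truth, 900),
                                        circular=False)
    # everything outside the corrected run is untouched
    assert fixed[:800] == contig[:800]
    assert fixed[804:] == contig[803:]


def test_correction_validates_parameters(rng):
    with pytest.raises(ValueError):
        asm.correct_homopolymers("ACGT", [], majority=0.5)


# -- merge / circularize ------------------------------------------------------


def _toy_circle(rng, n=24_000, ir=6_000):
    """LSC + IRb + SSC + IRa toy circle (no genes)."""
    lsc = random_dna(rng, n - 2 * ir - 3_000)
    ssc = random_dna(rng, 3_000)
    irb = random_dna(rng, ir)
    return lsc + irb + ssc + revcomp(irb)


def test_merge_reconstructs_circle_from_overlapping_contigs(rng):
    circle = _toy_circle(rng)
    n = len(circle)
    doubled = circle + circle
    # contig1 covers [20000..n+8000); contig2 covers [6000..16000)
    c1 = doubled[20_000 : n + 8_000]
    c2 = doubled[6_000 : 22_000]  # overlaps c1 by 2 kb at both junctions
    merged, (ov1, ov2), flipped = asm.merge_and_circularize(c1, c2, min_overlap=1_000)
    assert len(merged) == n
    assert merged in doubled
    assert ov1 >= 1_000 and ov2 >= 1_000


def test_merge_succeeds_with_flipped_contig(rng):
    circle = _toy_circle(rng)
    n = len(circle)
    doubled = circle + circle
    c1 = doubled[20_000 : n + 8_000]
    c2 = revcomp(doubled[6_000 : 22_000])
    merged, _, flipped = asm.merge_and_circularize(c1, c2, min_overlap=1_000)
    assert flipped and len(merged) == n and merged in doubled


def test_merge_rejects_insufficient_overlap(rng):
    circle = _toy_circle(rng)
    c1 = circle[:10_000]
    c2 = circle[9_990 : 20_000]  # only 10 bp shared
    with pytest.raises(asm.AssemblyError):
        asm.merge_and_circularize(c1, c2, min_overlap=1_000)


# -- mapping stats and junction windows --------------------------------------


def test_mapping_stats_depth_arithmetic():
    cs = asm.CoverageStats(n_mapped=100, n_total=1_000, mean_read_len=400.0,
                           genome_length=40_000)
    assert cs.depth == 1.0
    assert cs.fraction_of_total == 10.0


def test_mapping_stats_counts_only_matching_reads(rng):
    genome = random_dna(rng, 5_000)
    own = [(f"o{i}", genome[int(rng.integers(0, 4_500)) :][:300]) for i in range(20)]
    foreign = [(f"f{i}", random_dna(rng, 300)) for i in range(20)]
    stats = asm.mapping_stats(own + foreign, genome)
    assert stats.n_mapped == 20
    assert stats.fraction_of_total == 50.0


def test_junction_windows_and_flank_validation(toy_genome):
    genome, truth = toy_genome
    part = truth.partition
    wins = asm.extract_junction_regions(genome, part, flank=5)
    assert set(wins) == {"LSC/IRb", "IRb/SSC", "SSC/IRa", "IRa/LSC"}
    assert all(len(w) == 10 for w in wins.values())
    res = genome.sequence.residues
    assert wins["LSC/IRb"] == res[part.lsc[1] - 5 : part.lsc[1] + 5]
    # the IRa/LSC window wraps the origin
    assert wins["IRa/LSC"] == res[-5:] + res[:5]
    with pytest.raises(ValueError):
        asm.extract_junction_regions(genome, part, flank=10_000)
    with pytest.raises(ValueError):
        asm.extract_junction_regions(genome, None, flank=5)


# -- end to end ---------------------------------------------------------------


def test_pipeline_reconstructs_toy_plastome_exactly(toy_genome):
    genome, truth = toy_genome
    n = len(genome.sequence)
    shot = sd.simulate_shotgun_reads(genome, sd.reads_for_depth(n, 60, 384),
                                     homopolymer_rate=0.02, seed=77)
    acc = sd.simulate_accurate_pairs(genome, sd.reads_for_depth(n, 60, 50), seed=77)
    rep = asm.assemble_plastome(
        shot, acc,
        genome.get("psbA").sequence(genome.sequence),
        genome.get("ndhI").sequence(genome.sequence),
        merge_overlap=800, ir_cap=4_500)
    assert len(rep.sequence) == n
    assert (st.canonical_isomer(rep.sequence, min_ir=2_000)
            == st.canonical_isomer(genome.sequence, min_ir=2_000))
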