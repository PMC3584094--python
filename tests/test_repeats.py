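"""Dispersed/tandem/SSR detection against brute-force oracles and planted
ground truth."""

import numpy as np
import pytest

from plastomekit import repeats as rp
from plastomekit.core_io import revcomp
from conftest import random_dna

UNIT41 = "CTACAGAACCGTACATGAGATTTTCACCTCATACGGCTCCT"
UNIT18 = "TATTGATGAGAGTGACGA"


def plant_pair(rng, kind, unit, total=2000, p1=300, p2=1200):
    """Plant a dispersed pair with mismatching flank columns so the maximal
    hit is exactly the planted unit."""
    comp = dict(zip("ACGT", "TGCA"))
    L = len(unit)
    bg = list(random_dna(rng, total))
    bg[p1 : p1 + L] = unit
    bg[p2 : p2 + L] = unit if kind == "F" else revcomp(unit)
    for i in range(1, 5):
        if kind == "F":
            for a, b in ((p1 - i, p2 - i), (p1 + L - 1 + i, p2 + L - 1 + i)):
                if bg[b] == bg[a]:
                    bg[b] = "ACGT"[("ACGT".index(bg[a]) + 1) % 4]
        else:
            for a, b in ((p1 - i, p2 + L - 1 + i), (p1 + L - 1 + i, p2 - i)):
                if bg[b] == comp[bg[a]]:
                    bg[b] = "ACGT"[("ACGT".index(comp[bg[a]]) + 1) % 4]
    return "".join(bg)


def test_planted_forward_pair_found_at_exact_length(rng):
    s = plant_pair(rng, "F", UNIT41)
    hits = rp.find_dispersed(s)
    assert [(h.kind, h.length, h.positions, h.mismatches) for h in hits] == [
        ("F", 41, (300, 1200), 0)
    ]


def test_planted_inverted_pair_found_at_exact_length(rng):
    s = plant_pair(rng, "I", UNIT41)
    hits = rp.find_dispersed(s)
    assert [(h.kind, h.length, h.positions) for h in hits] == [("I", 41, (300, 1200))]


def test_mismatch_threshold_boundary(rng):
    """Three mismatches qualify at 41 bp; the window is trimmed/bounded by
    matching columns."""
    unit = list(UNIT41)
    for p in (10, 20, 30):
        unit[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[unit[p]]
    s = plant_pair(rng, "F", UNIT41, p1=300, p2=1200)
    s = s[:1200] + "".join(unit) + s[1241:]
    (hit,) = rp.find_dispersed(s)
    assert hit.mismatches == 3 and hit.length == 41


@pytest.mark.parametrize("trial", range(6))
def test_dispersed_equals_brute_force_oracle(trial):
    rng = np.random.default_rng(900 + trial)
    kind = "F" if trial % 2 else "I"
    s = plant_pair(rng, kind, UNIT41, total=1500, p1=200, p2=900)
    impl = {(h.kind, h.positions, h.length, h.mismatches)
            for h in rp.find_dispersed(s)}
    oracle = {(h.kind, h.positions, h.length, h.mismatches)
              for h in rp.brute_force_dispersed(s)}
    assert impl == oracle


def test_random_sequence_has_no_dispersed_hits(rng):
    for _ in range(3):
        assert rp.find_dispersed(random_dna(rng, 5000)) == []


def test_genome_scale_scan_recovers_all_planted_and_drops_ir_pair(default_genome):
    genome, truth = default_genome
    part = truth.partition
    hits = rp.find_dispersed(genome.sequence, ir_intervals=(part.irb, part.ira))
    found = {(h.kind, h.positions) for h in hits}
    for r in truth.repeats:
        if r.kind in "FI":
            assert (r.kind, tuple(sorted(r.positions))) in found
    assert not any(h.length >= 0.5 * part.ir_length for h in hits)


def test_tandem_unit_six_copies(rng):
    s = random_dna(rng, 400) + UNIT18 * 6 + random_dna(rng, 400)
    lst = list(s)
    if lst[399] == lst[399 + 18]:
        lst[399] = "C" if lst[399 + 18] != "C" else "G"
    e = 400 + 108
    if lst[e] == lst[e - 18]:
        lst[e] = "C" if lst[e - 18] != "C" else "G"
    hits = rp.find_tandem("".join(lst))
    assert [(h.length, len(h.unit), h.copies, h.positions) for h in hits] == [
        (108, 18, 6, (400,))
    ]


def test_tandem_three_copies_and_single_copy_ignored(rng):
    unit = "TTTTTGTCCAAGTCACTTCTT"
    s = "GCGC" + random_dna(rng, 300) + unit * 3 + "CACG" + random_dna(rng, 300)
    hits = rp.find_tandem(s)
    assert any(h.length == 63 and h.copies == 3 for h in hits)
    s_single = random_dna(rng, 300) + unit + random_dna(rng, 300)
    assert all(h.copies >= 2 for h in rp.find_tandem(s_single))


def test_tandem_collapses_to_smallest_period(default_genome):
    genome, truth = default_genome
    hits = rp.find_tandem(genome.sequence)
    spans = {(h.positions[0], h.length): h for h in hits}
    for r in truth.repeats:
        if r.kind == "T":
            key = (r.positions[0], len(r.unit) * r.copies)
            assert key in spans
            assert len(spans[key].unit) == len(r.unit)
            assert spans[key].copies == r.copies


def test_ssr_unit_count_thresholds():
    assert [(h.motif, h.n_units) for h in rp.find_ssrs("GG" + "A" * 8 + "CC")] == [("A", 8)]
    assert rp.find_ssrs("GG" + "A" * 7 + "CC") == []
    assert [(h.motif, h.n_units) for h in rp.find_ssrs("GC" + "AT" * 4 + "GC")] == [("AT", 4)]
    assert rp.find_ssrs("GC" + "AT" * 3 + "GC") == []


def test_ssr_periodic_motif_reported_once_at_smallest_period():
    hits = rp.find_ssrs("CCG" + "AT" * 6 + "GCC")
    assert len(hits) == 1 and hits[0].motif == "AT"


def test_ssr_maximality_not_extendable_by_one_unit(default_genome):
    genome, _ = default_genome
    res = genome.sequence.residues
    for h in rp.find_ssrs(genome.sequence):
        k = len(h.motif)
        if h.start >= k:
            # one more unit to the left would extend the repeat
            assert res[h.start - k : h.start] != h.motif
        if h.end + k <= len(res):
            assert res[h.end : h.end + k] != res[h.end - k : h.end]


@pytest.mark.parametrize("trial", range(3))
def test_ssr_finder_equals_regex_oracle(trial):
    rng = np.random.default_rng(40 + trial)
    s = random_dna(rng, 8000, p=[0.31, 0.19, 0.19, 0.31])
    a = {(h.motif, h.n_units, h.start) for h in rp.find_ssrs(s)}
    b = {(h.motif, h.n_units, h.start) for h in rp.ssr_oracle(s)}
    assert a == b


def test_classification_regions_and_contexts(default_genome):
    genome, truth = default_genome
    part = truth.partition
    ssrs = rp.classify_hits(rp.find_ssrs(genome.sequence), genome, part)
    planted = {s.start: s for s in truth.ssrs}
    for h in ssrs:
        if h.start in planted:
            want = planted[h.start].region
            assert h.region == ("IR" if want == "IR" else want)
    # the 41 bp pair planted across IR and SSC gets both labels
    hits = rp.classify_hits(
        rp.find_dispersed(genome.sequence, ir_intervals=(part.irb, part.ira)),
        genome, part)
    cross = [h for h in hits if set(h.regions) == {"IR", "SSC"}]
    assert cross


def test_hit_inside_planted_cds_has_cds_context(toy_genome):
    genome, truth = toy_genome
    part = truth.partition
    # plant-free check via an SSR that the generator placed in an IGS, plus a
    # synthetic query point inside a known CDS
    from plastomekit.repeats import _context_of

    f = genome.get("psbA")
    assert _context_of((f.start + f.end) // 2, genome) == "CDS"


def test_multi_genome_summary_identical_rows(toy_genome):
    genome, _ = toy_genome
    df = rp.multi_genome_ssr_summary([genome, genome])
    assert df.iloc[0].drop("genome").equals(df.iloc[1].drop("genome"))
    assert (df["total"] == df[["mono", "di", "tri", "tetra", "penta", "hexa"]].sum(axis=1)).all()


def test_multi_genome_summary_counts_planted(default_genome):
    genome, truth = default_genome
    df = rp.multi_genome_ssr_summary([genome])
    row = df.iloc[0]
    planted_mono = sum(1 for s in truth.ssrs if len(s.motif) == 1)
    assert row["mono"] >= planted_mono
    assert 0 <= row["at_mono_pct"] <= 100
    with pytest.raises(ValueError):
        rp.multi_genome_ssr_summary([])
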