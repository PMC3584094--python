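"""Codon usage with RSCU, positional base composition, intron/exon
tabulation and coding-fraction summaries for annotated plastomes.

Codon counting uses the literal codons of every (non-pseudo) CDS, including
stop codons; the three stop codons form one synonymous family for RSCU, and
duplicated IR gene copies are counted once per genomic copy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .core_io import AnnotatedGenome, GeneFeature

logger = logging.getLogger(__name__)

_TABLE = unambiguous_dna_by_id[1]  # standard code
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
ALL_CODONS = tuple(sorted(_TABLE.forward_table) + list(STOP_CODONS))


def _families() -> dict[str, tuple[str, ...]]:
    fam: dict[str, list[str]] = {}
    for codon, aa in _TABLE.forward_table.items():
        fam.setdefault(aa, []).append(codon)
    fam["*"] = list(STOP_CODONS)
    return {aa: tuple(sorted(cs)) for aa, cs in fam.items()}


SYNONYMOUS_FAMILIES = _families()
AMINO_ACID_OF = {c: aa for aa, cs in SYNONYMOUS_FAMILIES.items() for c in cs}


class CdsError(ValueError):
    pass


def extract_cds(genome: AnnotatedGenome) -> list[tuple[str, str]]:
    """Spliced coding sequences, 5'->3' on the coding strand, per CDS gene.

    Pseudogenes are excluded; a CDS whose joined length is not divisible by
    three is skipped with a log entry. Trans-spliced genes are assembled in
    annotated exon order across regions.
    """
    out = []
    for f in genome.features:
        if f.klass != "CDS":
            continue
        cds = f.sequence(genome.sequence)
        if len(cds) % 3:
            logger.warning("CDS %s length %d not divisible by 3; skipped", f.name, len(cds))
            continue
        out.append((f.name, cds))
    return out


@dataclass
class CodonUsageTable:
    """Counts (and optionally RSCU) over the 64 codons."""

    counts: dict[str, int]
    ambiguous: int = 0
    rscu: dict[str, float | None] = field(default_factory=dict)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def aa_totals(self) -> dict[str, int]:
        tot: dict[str, int] = {}
        for codon, n in self.counts.items():
            aa = AMINO_ACID_OF[codon]
            tot[aa] = tot.get(aa, 0) + n
        return tot

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "AminoAcid": AMINO_ACID_OF[c],
                "Codon": c.replace("T", "U"),
                "No": self.counts.get(c, 0),
                "RSCU": self.rscu.get(c),
            }
            for c in ALL_CODONS
        ]
        return pd.DataFrame(rows)


def codon_usage(cds_list: list[str]) -> CodonUsageTable:
    """Count all codons (stops included) of in-frame coding sequences."""
    counts = {c: 0 for c in ALL_CODONS}
    ambiguous = 0
    for cds in cds_list:
        if len(cds) % 3:
            raise CdsError(f"sequence length {len(cds)} not divisible by 3")
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if codon in counts:
                counts[codon] += 1
            else:
                ambiguous += 1
    return CodonUsageTable(counts=counts, ambiguous=ambiguous)


def rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill relative synonymous codon usage.

    RSCU_c = N_c * k / sum of family counts, with k the family size; a codon
    in an unobserved family gets None. Single-codon families (Met, Trp) are
    identically 1.
    """
    values: dict[str, float | None] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        fam_total = sum(table.counts.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            values[c] = None if fam_total == 0 else table.counts.get(c, 0) * k / fam_total
    return CodonUsageTable(counts=table.counts, ambiguous=table.ambiguous, rscu=values)


def positional_composition(cds_list: list[str]):
    """Base composition at codon positions 1-3 (three composition rows)."""
    from .structure import base_composition

    rows = []
    for pos in range(3):
        sub = "".join(c[pos::3] for c in cds_list)
        rows.append(base_composition(sub))
    return rows


@dataclass(frozen=True)
class IntronRecord:
    gene: str
    region: str
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int | None, ...]  # None = trans-spliced gap ("-")


def intron_exon_table(
    genome: AnnotatedGenome, max_intron: int = 10_000
) -> list[IntronRecord]:
    """Exon/intron lengths for multi-exon genes, in coding order.

    Introns are the gaps between consecutive exons on the coding strand;
    a trans-spliced gap (negative or implausibly large) is reported as None.
    """
    records = []
    part = genome.partition
    for f in genome.features:
        if len(f.exons) < 2:
            continue
        exons = list(f.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if max(s1, s2) < min(e1, e2) and not f.trans_spliced:
                raise ValueError(f"gene {f.name}: overlapping exons")
        coding = exons[::-1] if (f.strand == "-" and f.exon_strands is None) else exons
        # gap between consecutive coding exons, measured on the genome
        # irrespective of strand/mirroring (later start minus earlier end)
        gaps = []
        for i in range(len(coding) - 1):
            lo, hi = sorted((coding[i], coding[i + 1]))
            gaps.append(hi[0] - lo[1])
        exon_lens = tuple(e - s for s, e in coding)
        introns = tuple(g if 0 < g <= max_intron else None for g in gaps)
        region = ""
        if part is not None:
            mid = (f.start + f.end) // 2
            region = part.region_of(mid % part.genome_length).replace("IRa", "IR").replace("IRb", "IR")
        records.append(IntronRecord(f.name, region, exon_lens, introns))
    return records


def coding_fractions(genome: AnnotatedGenome) -> dict[str, float]:
    """Percent of the genome under CDS, tRNA and rRNA exons (and the rest).

    Overlapping features count once per base with precedence CDS > tRNA >
    rRNA; introns are non-coding.
    """
    n = len(genome.sequence)
    code = np.zeros(n, dtype=np.uint8)  # 0 none, 1 rRNA, 2 tRNA, 3 CDS
    rank = {"rRNA": 1, "tRNA": 2, "CDS": 3}
    for klass in ("rRNA", "tRNA", "CDS"):
        for f in genome.features_of(klass):
            for s, e in f.exons:
                if e <= n:
                    code[s:e] = np.maximum(code[s:e], rank[klass])
                else:  # wraps the origin
                    code[s:] = np.maximum(code[s:], rank[klass])
                    code[: e - n] = np.maximum(code[: e - n], rank[klass])
    counts = np.bincount(code, minlength=4)
    pct = lambda c: round(100.0 * float(c) / n, 1)
    return {
        "CDS": pct(counts[3]),
        "tRNA": pct(counts[2]),
        "rRNA": pct(counts[1]),
        "non-coding": pct(counts[0]),
    }
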