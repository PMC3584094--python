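"""Shared sequence primitives and readers/writers for the standard formats.

Internal coordinates are 0-based half-open throughout; GenBank I/O converts
from/to the 1-based inclusive convention of the flat-file format. Features
wrapping the origin of a circular sequence are represented as an exon pair
split at the origin.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")

FEATURE_CLASSES = ("CDS", "tRNA", "rRNA", "pseudogene")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised for malformed records (bad locations, missing sequence...)."""


@dataclass(frozen=True)
class CircularSequence:
    """A DNA sequence, optionally circular.

    Indexing helpers treat circular sequences as wrapping: ``fetch`` accepts
    an end coordinate past ``len`` and reads through the origin.
    """

    id: str
    residues: str
    is_circular: bool = True

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty sequence")
        if not set(self.residues) <= DNA_ALPHABET:
            bad = sorted(set(self.residues) - DNA_ALPHABET)
            raise ValueError(f"non-DNA residues in {self.id!r}: {bad}")

    def __len__(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int) -> str:
        """Residues in [start, end); wraps the origin when circular."""
        n = len(self.residues)
        if start < 0 or end < start:
            raise IndexError(f"bad interval [{start}, {end})")
        if end <= n:
            return self.residues[start:end]
        if not self.is_circular or end > 2 * n:
            raise IndexError(f"interval [{start}, {end}) outside linear sequence")
        return self.residues[start:] + self.residues[: end - n]

    def reverse_complement(self) -> "CircularSequence":
        return replace(self, residues=revcomp(self.residues))

    def rotated(self, offset: int) -> "CircularSequence":
        """Rotate a circular sequence so old position ``offset`` becomes 0."""
        if not self.is_circular:
            raise ValueError("cannot rotate a linear sequence")
        n = len(self.residues)
        offset %= n
        return replace(self, residues=self.residues[offset:] + self.residues[:offset])


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene with one or more exons.

    ``exons`` are (start, end) half-open intervals in genome coordinates, in
    annotated (file) order; for minus-strand features the coding sequence is
    the reverse complement of the ascending-coordinate join. ``exon_strands``
    is only set for mixed-strand (trans-spliced) locations.
    """

    name: str
    klass: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    trans_spliced: bool = False
    exon_strands: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.klass not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.klass!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"feature {self.name!r} has no exons")
        for s, e in self.exons:
            if e <= s or s < 0:
                raise ValueError(f"feature {self.name!r}: bad exon ({s}, {e})")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    def span(self) -> tuple[int, int]:
        """Envelope (start, end) over all exons."""
        return self.start, self.end

    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def sequence(self, seq: CircularSequence) -> str:
        """Spliced sequence on the coding strand."""
        if self.exon_strands is not None:
            parts = [
                seq.fetch(s, e) if st == "+" else revcomp(seq.fetch(s, e))
                for (s, e), st in zip(self.exons, self.exon_strands)
            ]
            return "".join(parts)
        joined = "".join(seq.fetch(s, e) for s, e in self.exons)
        return joined if self.strand == "+" else revcomp(joined)


@dataclass
class AnnotatedGenome:
    """A (usually circular) genome plus gene features and, optionally, its
    LSC/IRb/SSC/IRa partition (attached by the structure module)."""

    sequence: CircularSequence
    features: list[GeneFeature] = field(default_factory=list)
    partition: "object | None" = None  # structure.RegionPartition

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of(self, klass: str) -> list[GeneFeature]:
        return [f for f in self.features if f.klass == klass]

    def get(self, name: str) -> GeneFeature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None


# ---------------------------------------------------------------------------
# GenBank


_KLASS_FROM_TYPE = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _feature_from_biopython(feat: SeqFeature, length: int) -> GeneFeature | None:
    if feat.type not in _KLASS_FROM_TYPE:
        return None
    quals = feat.qualifiers
    name = (quals.get("gene") or quals.get("locus_tag") or quals.get("product") or ["?"])[0]
    klass = "pseudogene" if "pseudo" in quals or "pseudogene" in quals else _KLASS_FROM_TYPE[feat.type]
    loc = feat.location
    if loc is None:
        raise ParseError(f"feature {name!r}: malformed location")
    parts = loc.parts
    exons = []
    strands = []
    for p in parts:
        s, e = int(p.start), int(p.end)
        if not (0 <= s < e <= length):
            raise ParseError(f"feature {name!r}: exon ({s}, {e}) outside sequence")
        exons.append((s, e))
        strands.append("-" if p.strand == -1 else "+")
    trans = isinstance(loc, CompoundLocation) and loc.operator == "order"
    mixed = len(set(strands)) > 1
    strand = strands[0] if not mixed else "+"
    return GeneFeature(
        name=name,
        klass=klass,
        strand=strand,
        exons=tuple(exons),
        trans_spliced=trans or mixed,
        exon_strands=tuple(strands) if mixed else None,
    )


def parse_genbank(path: str | Path | io.TextIOBase) -> AnnotatedGenome:
    """Read one GenBank flat-file record into an AnnotatedGenome.

    1-based inclusive coordinates become 0-based half-open; join()/
    complement() are honored and order() locations are flagged trans-spliced.
    """
    try:
        record = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise ParseError(str(exc)) from exc
    residues = str(record.seq).upper()
    if not residues or set(residues) == {"N"}:
        raise ParseError(f"record {record.id!r}: missing or empty ORIGIN sequence")
    circular = record.annotations.get("topology", "circular") == "circular"
    seq = CircularSequence(id=record.id, residues=residues, is_circular=circular)
    features = []
    for feat in record.features:
        gf = _feature_from_biopython(feat, len(residues))
        if gf is not None:
            features.append(gf)
    return AnnotatedGenome(sequence=seq, features=features)


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write an AnnotatedGenome as a GenBank flat file (inverse of parse)."""
    _TYPE_FROM_KLASS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "pseudogene": "CDS"}
    record = SeqRecord(
        Seq(genome.sequence.residues),
        id=genome.sequence.id,
        name=genome.sequence.id[:16],
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.sequence.is_circular else "linear",
        },
    )
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.exon_strands is not None:
            locs = [
                SimpleLocation(s, e, -1 if st == "-" else 1)
                for (s, e), st in zip(f.exons, f.exon_strands)
            ]
        else:
            locs = [SimpleLocation(s, e, strand) for s, e in f.exons]
        if len(locs) == 1:
            loc = locs[0]
        else:
            loc = CompoundLocation(locs, operator="order" if f.trans_spliced else "join")
        quals = {"gene": [f.name]}
        if f.klass == "pseudogene":
            quals["pseudo"] = [""]
        record.features.append(SeqFeature(loc, type=_TYPE_FROM_KLASS[f.klass], qualifiers=quals))
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(seqs: Sequence[CircularSequence], path: str | Path, width: int = 70) -> None:
    """Write sequences as wrapped FASTA."""
    if not seqs:
        raise ValueError("empty sequence list")
    with open(path, "w") as fh:
        for s in seqs:
            if not s.id:
                raise ValueError("sequence with empty id")
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_fasta(path: str | Path, is_circular: bool = False) -> list[CircularSequence]:
    return [
        CircularSequence(id=r.id, residues=str(r.seq).upper(), is_circular=is_circular)
        for r in SeqIO.parse(str(path), "fasta")
    ]


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTQ as (id, residues) pairs; qualities are discarded."""
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, res in reads:
            fh.write(f"@{rid}\n{res}\n+\n{'I' * len(res)}\n")


# ---------------------------------------------------------------------------
# Alignments


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned multi-FASTA into a taxon -> gapped-row mapping.

    All rows must have equal length; '-' is the gap character.
    """
    rows: dict[str, str] = {}
    for r in SeqIO.parse(str(path), "fasta"):
        rows[r.id] = str(r.seq).upper()
    if not rows:
        raise ParseError(f"no records in {path}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) > 1:
        offenders = [k for k, v in rows.items() if len(v) != len(next(iter(rows.values())))]
        raise ParseError(f"ragged alignment rows: {offenders}")
    return rows


def write_alignment_fasta(rows: dict[str, str], path: str | Path) -> None:
    if len({len(v) for v in rows.values()}) > 1:
        raise ValueError("rows have unequal lengths")
    with open(path, "w") as fh:
        for k, v in rows.items():
            fh.write(f">{k}\n{v}\n")
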