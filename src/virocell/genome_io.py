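"""Genome and CDS input/output: FASTA, GenBank, codon counting, %GC.

Coordinates are 0-based half-open internally; GenBank's 1-based inclusive
convention is converted at the file boundary only. Stop codons are counted
like any other codon, so every codon table has all 64 cells populated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .codons import CODONS, reverse_complement

IUPAC_DNA = set("ACGTRYSWKMBDHVN")


class GenomeParseError(ValueError):
    """Raised for malformed FASTA/GenBank input."""


@dataclass
class GenomeRecord:
    """A single contig/replicon sequence."""

    genome_id: str
    description: str
    sequence: str
    source_path: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise GenomeParseError(f"{self.genome_id}: empty sequence")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise GenomeParseError(
                f"{self.genome_id}: non-IUPAC DNA character(s) {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CdsFeature:
    """A (possibly multi-interval) coding feature on a genome.

    ``intervals`` are 0-based half-open and ordered 5'->3' in transcript
    orientation: for a minus-strand feature the first interval is the
    genomically last one.
    """

    genome_id: str
    locus_tag: str
    product: str
    intervals: list[tuple[int, int]]
    strand: str  # '+' or '-'
    translation_table: int = 11

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")
        for s, e in self.intervals:
            if not (0 <= s < e):
                raise ValueError(f"{self.locus_tag}: bad interval ({s}, {e})")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class CodonCountTable:
    """Integer counts over all 64 codons for one genome's CDS set."""

    genome_id: str
    counts: dict[str, int]
    n_cds_used: int = 0
    n_codons_skipped: int = 0

    def __post_init__(self) -> None:
        missing = set(CODONS) - set(self.counts)
        if missing:
            raise ValueError(f"codon table missing {len(missing)} codons")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative codon count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into :class:`GenomeRecord` objects.

    Sequences are upper-cased; record order follows the file. Raises
    :class:`GenomeParseError` on empty files or non-IUPAC characters.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise GenomeParseError(f"{path}: record with empty header")
        records.append(
            GenomeRecord(
                genome_id=rec.id,
                description=rec.description,
                sequence=str(rec.seq),
                source_path=str(path),
            )
        )
    if not records:
        raise GenomeParseError(f"{path}: no FASTA records found (empty file?)")
    return records


def read_genbank(
    path: str | Path, skip_report: list[tuple[str, str]] | None = None
) -> tuple[GenomeRecord, list[CdsFeature]]:
    """Read one GenBank flat-file record and its CDS features.

    GenBank 1-based inclusive coordinates become 0-based half-open;
    ``join()`` locations become multiple intervals; ``complement()`` sets
    strand '-'. CDS features extending past the sequence end are skipped
    with a warning (and recorded in ``skip_report`` as (locus_tag, reason)
    rows if a list is supplied).
    """
    path = Path(path)
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise GenomeParseError(f"{path}: no GenBank record found") from None
    genome = GenomeRecord(
        genome_id=rec.id or rec.name,
        description=rec.description,
        sequence=str(rec.seq),
        source_path=str(path),
    )
    features: list[CdsFeature] = []
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        locus = feat.qualifiers.get("locus_tag", ["?"])[0]
        product = feat.qualifiers.get("product", [""])[0]
        table = int(feat.qualifiers.get("transl_table", ["11"])[0])
        parts = feat.location.parts
        intervals = [(int(p.start), int(p.end)) for p in parts]
        if any(e > genome.length or s < 0 for s, e in intervals):
            reason = "interval outside sequence bounds"
            warnings.warn(f"{path.name}:{locus}: skipped CDS ({reason})")
            if skip_report is not None:
                skip_report.append((locus, reason))
            continue
        strand = "-" if feat.location.strand == -1 else "+"
        # transcript orientation: genomic order for +, reversed for -
        intervals.sort()
        if strand == "-":
            intervals = intervals[::-1]
        features.append(
            CdsFeature(
                genome_id=genome.genome_id,
                locus_tag=locus,
                product=product,
                intervals=intervals,
                strand=strand,
                translation_table=table,
            )
        )
    return genome, features


def write_genbank(
    genome: GenomeRecord, features: list[CdsFeature], path: str | Path
) -> Path:
    """Write a genome and its CDS features as a GenBank flat file."""
    path = Path(path)
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.genome_id,
        name=genome.genome_id.split(".")[0].replace("|", "_")[:16],
        description=genome.description,
        annotations={"molecule_type": "DNA", "date": "01-JAN-2000"},
    )
    for cds in features:
        strand = -1 if cds.strand == "-" else 1
        ivals = sorted(cds.intervals)
        locs = [SimpleLocation(s, e, strand) for s, e in ivals]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        rec.features.append(
            SeqFeature(
                loc,
                type="CDS",
                qualifiers={
                    "locus_tag": [cds.locus_tag],
                    "product": [cds.product],
                    "transl_table": [str(cds.translation_table)],
                },
            )
        )
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "genbank")
    return path


def write_skip_report(rows: list[tuple[str, str]], path: str | Path) -> Path:
    """Write skipped-feature rows as a two-column TSV (locus_tag, reason)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("locus_tag\treason\n")
        for locus, reason in rows:
            fh.write(f"{locus}\t{reason}\n")
    return path


def extract_cds_sequence(genome: GenomeRecord, cds: CdsFeature) -> str:
    """Spliced coding sequence read 5'->3' in frame.

    Intervals are concatenated in transcript order; minus-strand pieces are
    reverse-complemented.
    """
    if cds.genome_id != genome.genome_id:
        raise ValueError(
            f"CDS {cds.locus_tag} belongs to {cds.genome_id}, not {genome.genome_id}"
        )
    pieces = []
    for s, e in cds.intervals:
        if e > genome.length:
            raise ValueError(f"{cds.locus_tag}: interval ({s},{e}) out of bounds")
        piece = genome.sequence[s:e]
        pieces.append(reverse_complement(piece) if cds.strand == "-" else piece)
    return "".join(pieces)


def count_codons(
    cds_sequences: list[str], genome_id: str = ""
) -> CodonCountTable:
    """Count codons in frame 0 over a set of coding sequences.

    Codons are read in non-overlapping triplets from position 0. A trailing
    1-2 nt remainder is dropped; any triplet containing a non-ACGT character
    is skipped and tallied in ``n_codons_skipped``. Stop codons count.
    """
    counts = {c: 0 for c in CODONS}
    skipped = 0
    for seq in cds_sequences:
        seq = seq.upper()
        n = len(seq) - len(seq) % 3
        if n < len(seq):
            warnings.warn(
                f"{genome_id}: dropped {len(seq) - n} trailing nt of a CDS"
            )
        for i in range(0, n, 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
            else:
                skipped += 1
    return CodonCountTable(
        genome_id=genome_id,
        counts=counts,
        n_cds_used=len(cds_sequences),
        n_codons_skipped=skipped,
    )


def gc_content(records: list[GenomeRecord]) -> float:
    """Pooled (G+C)/(A+C+G+T) over whole genome sequences.

    Ambiguous bases are excluded from numerator and denominator; multiple
    contigs (e.g. a two-replicon host) are pooled before dividing.
    """
    if not records:
        raise ValueError("gc_content requires at least one record")
    gc = at = 0
    for rec in records:
        gc += rec.sequence.count("G") + rec.sequence.count("C")
        at += rec.sequence.count("A") + rec.sequence.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases; %GC undefined")
    return gc / (gc + at)
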