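"""Sequence/annotation I/O and strand-aware promoter window extraction.

Promoters are the windows immediately upstream of a gene's transcription
start site (TSS); here "upstream" is read strictly, so the TSS base itself
is excluded from the window.  Internal coordinates are 0-based half-open on
the forward genomic strand; GFF3 input is converted from its 1-based
inclusive convention at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes accepted in genome FASTA input.
IUPAC_DNA = set("ACGTRYSWKMBDHVN")

#: Alphabet permitted in extracted promoter sequences.
PROMOTER_ALPHABET = set("ACGTN")


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's TSS on a chromosome, in 1-based genomic coordinates."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 1:
            raise ValueError(f"tss must be >= 1 (1-based), got {self.tss}")


@dataclass(frozen=True)
class PromoterRecord:
    """A TSS-anchored upstream window.

    ``window_start``/``window_end`` are 0-based half-open coordinates on the
    forward genomic strand.  ``sequence`` is reported 5'->3' relative to the
    gene's transcription direction, so minus-strand promoters store the
    reverse complement of the forward-strand slice.
    """

    gene_id: str
    chrom: str
    strand: str
    window_start: int
    window_end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.window_end - self.window_start != len(self.sequence):
            raise ValueError(
                "window length does not match sequence length: "
                f"{self.window_end - self.window_start} vs {len(self.sequence)}"
            )
        bad = set(self.sequence) - PROMOTER_ALPHABET
        if bad:
            raise ValueError(f"promoter sequence contains non-ACGTN bases: {sorted(bad)}")

    @property
    def length(self) -> int:
        return self.window_end - self.window_start

    def fasta_header(self) -> str:
        return f"{self.gene_id}|{self.chrom}|{self.strand}|{self.window_start}-{self.window_end}"


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-)FASTA file into an ordered id -> uppercase sequence map.

    Strict by design: a sequence line before any header, an empty header, a
    non-IUPAC character, or a duplicate record id raise :class:`FastaParseError`
    naming the line number.  Soft-masked (lowercase) bases are uppercased.
    """
    records: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                if name in records:
                    raise FastaParseError(f"line {lineno}: duplicate record id {name!r}")
                records[name] = []
                current = name
            else:
                if current is None:
                    raise FastaParseError(f"line {lineno}: sequence data before any header")
                seq = line.upper()
                bad = set(seq) - IUPAC_DNA
                if bad:
                    raise FastaParseError(
                        f"line {lineno}: non-IUPAC character(s) {sorted(bad)} in record {current!r}"
                    )
                records[current].append(seq)
    return {name: "".join(parts) for name, parts in records.items()}


def write_fasta(records: Mapping[str, str] | Iterable[PromoterRecord], path, width: int = 60) -> None:
    """Write sequences (a mapping or PromoterRecords) to FASTA, wrapped at ``width``."""
    if isinstance(records, Mapping):
        items = list(records.items())
    else:
        items = [(rec.fasta_header(), rec.sequence) for rec in records]
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff_tss(path, feature_types: tuple[str, ...] = ("gene", "mRNA")) -> list[GeneAnnotation]:
    """Extract one TSS annotation per gene from a GFF3 file.

    The TSS is the feature start on '+' and the feature end on '-' (1-based,
    as GFF3 stores them).  When several selected features share a gene id
    (multiple transcripts), the 5'-most TSS in transcription direction is
    kept: the smallest start on '+', the largest end on '-'.

    Raises ``ValueError`` on a missing/invalid strand or non-positive
    coordinates, naming the line number.
    """
    best: dict[str, GeneAnnotation] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {lineno}: expected 9 tab-separated GFF3 fields, got {len(fields)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates {start_s!r}..{end_s!r}")
            if start < 1 or end < 1:
                raise ValueError(f"line {lineno}: non-positive coordinate in {start}..{end}")
            if strand not in ("+", "-"):
                raise ValueError(f"line {lineno}: missing or invalid strand {strand!r}")
            gene_id = _attr_gene_id(attrs) or f"{ftype}:{lineno}"
            tss = start if strand == "+" else end
            prev = best.get(gene_id)
            if prev is None:
                best[gene_id] = GeneAnnotation(gene_id, chrom, strand, tss)
                order.append(gene_id)
            else:
                upstream = tss < prev.tss if strand == "+" else tss > prev.tss
                if upstream:
                    best[gene_id] = GeneAnnotation(gene_id, chrom, strand, tss)
    return [best[g] for g in order]


def _attr_gene_id(attrs: str) -> str | None:
    parsed = {}
    for part in attrs.split(";"):
        part = part.strip()
        if "=" in part:
            key, val = part.split("=", 1)
            parsed[key.strip()] = val.strip()
    for key in ("gene_id", "gene", "ID", "Name"):
        if key in parsed and parsed[key]:
            return parsed[key]
    return None


def extract_promoter(
    genome: Mapping[str, str],
    ann: GeneAnnotation,
    length: int = 2000,
    include_tss: bool = False,
) -> PromoterRecord:
    """Extract the ``length``-base window upstream of ``ann``'s TSS.

    For '+' genes the window is ``[tss-1-length, tss-1)`` in 0-based forward
    coordinates; for '-' genes it is ``[tss, tss+length)`` and the stored
    sequence is the reverse complement, so it always reads 5'->3' in the
    gene's transcription direction.  ``include_tss=True`` shifts the window
    by one base to include the TSS itself.

    Windows overhanging a chromosome end are truncated with a logged
    warning; a window entirely off-chromosome or an unknown chromosome is an
    error.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if ann.chrom not in genome:
        raise KeyError(f"chromosome {ann.chrom!r} not present in genome")
    chrom_seq = genome[ann.chrom].upper()
    chrom_len = len(chrom_seq)
    tss0 = ann.tss - 1  # 0-based position of the TSS base

    if ann.strand == "+":
        end = tss0 + 1 if include_tss else tss0
        start = end - length
    else:
        start = tss0 if include_tss else tss0 + 1
        end = start + length

    clipped_start, clipped_end = max(start, 0), min(end, chrom_len)
    if clipped_start >= clipped_end:
        raise ValueError(
            f"promoter window [{start}, {end}) for {ann.gene_id} lies entirely "
            f"outside chromosome {ann.chrom} (length {chrom_len})"
        )
    if (clipped_start, clipped_end) != (start, end):
        logger.warning(
            "promoter window for %s truncated from [%d, %d) to [%d, %d) at chromosome bounds",
            ann.gene_id, start, end, clipped_start, clipped_end,
        )

    seq = chrom_seq[clipped_start:clipped_end]
    if ann.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return PromoterRecord(ann.gene_id, ann.chrom, ann.strand, clipped_start, clipped_end, seq)


def read_promoter_fasta(path) -> list[PromoterRecord]:
    """Re-read promoters written with :func:`write_fasta` (pipe-delimited headers)."""
    out = []
    for header, seq in read_fasta(path).items():
        gene_id, chrom, strand, window = header.split("|")
        start_s, end_s = window.split("-")
        out.append(PromoterRecord(gene_id, chrom, strand, int(start_s), int(end_s), seq))
    return out
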