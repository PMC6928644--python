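"""Pairwise protein percent identity/similarity with BLOSUM62.

Percent identity counts identical aligned columns; percent similarity
additionally counts columns whose residue pair has a strictly positive
BLOSUM62 score.  Both use the full alignment length (gap columns included)
as the denominator by default — configurable, since reported figures in the
literature rarely state the convention.  Intended for whole FABP proteins
and for their FATTYACIDBP fingerprint motifs (the three-motif PRINTS
signature PR00178 shared by the family), whose coordinates are supplied as
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

#: Denominator conventions for the percentages.
DENOMINATORS = ("alignment", "shorter", "nongap")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional labelled fingerprint motifs
    (label -> (start, end), 0-based half-open)."""

    protein_id: str
    sequence: str
    fingerprint_motifs: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"{self.protein_id}: non-amino-acid character(s) {sorted(bad)}")
        for label, (start, end) in self.fingerprint_motifs.items():
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(
                    f"{self.protein_id}: motif {label} [{start}, {end}) outside sequence bounds"
                )

    def motif_sequence(self, label: str) -> str:
        start, end = self.fingerprint_motifs[label]
        return self.sequence[start:end]


@dataclass(frozen=True)
class PairSimilarity:
    id_a: str
    id_b: str
    aligned_length: int
    pct_identity: float
    pct_similarity: float

    def __post_init__(self) -> None:
        if not 0 <= self.pct_identity <= self.pct_similarity <= 100:
            raise ValueError(
                f"need 0 <= identity ({self.pct_identity}) <= similarity "
                f"({self.pct_similarity}) <= 100"
            )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global Needleman-Wunsch alignment (BLOSUM62, gap open 10 / extend 0.5).

    Returns the two gapped strings.  The aligner enumerates co-optimal
    alignments in a fixed order; the first is taken, making the result
    deterministic.
    """
    for name, seq in (("a", a), ("b", b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(f"sequence {name}: non-amino-acid character(s) {sorted(bad)}")
    alignment = _make_aligner().align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def alignment_score(a: str, b: str) -> float:
    """Optimal global alignment score for the pair (same scoring as
    :func:`align_pair`)."""
    return float(_make_aligner().score(a, b))


def percent_similarity(
    aligned_a: str,
    aligned_b: str,
    id_a: str = "a",
    id_b: str = "b",
    denominator: str = "alignment",
) -> PairSimilarity:
    """Percent identity and BLOSUM62-positive percent similarity of a gapped
    alignment.

    ``denominator`` selects what the counts are divided by: the full
    alignment length including gap columns (default), the shorter ungapped
    sequence length, or the number of non-gap columns.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError(f"aligned lengths differ: {len(aligned_a)} vs {len(aligned_b)}")
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}, got {denominator!r}")
    identical = positive = nongap = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP or y == GAP:
            continue
        nongap += 1
        if x == y:
            identical += 1
            positive += 1
        elif BLOSUM62[x, y] > 0:
            positive += 1
    alen = len(aligned_a)
    if denominator == "alignment":
        denom = alen
    elif denominator == "shorter":
        denom = min(len(aligned_a.replace(GAP, "")), len(aligned_b.replace(GAP, "")))
    else:
        denom = nongap
    if denom == 0:
        pct_id = pct_sim = 0.0
    else:
        pct_id = 100.0 * identical / denom
        pct_sim = 100.0 * positive / denom
    return PairSimilarity(id_a, id_b, alen, pct_id, pct_sim)


def pair_similarity(a: str, b: str, id_a: str = "a", id_b: str = "b", denominator: str = "alignment") -> PairSimilarity:
    """Align two raw sequences and compute their percent identity/similarity."""
    ga, gb = align_pair(a, b)
    return percent_similarity(ga, gb, id_a, id_b, denominator)


def pairwise_matrix(records: dict[str, str], denominator: str = "alignment") -> pd.DataFrame:
    """All-vs-all similarity table (long format) for an id -> sequence map."""
    ids = list(records)
    rows = []
    for i, ia in enumerate(ids):
        for ib in ids[i + 1 :]:
            sim = pair_similarity(records[ia], records[ib], ia, ib, denominator)
            rows.append(
                {
                    "id_a": ia,
                    "id_b": ib,
                    "aligned_length": sim.aligned_length,
                    "pct_identity": sim.pct_identity,
                    "pct_similarity": sim.pct_similarity,
                }
            )
    return pd.DataFrame(rows, columns=["id_a", "id_b", "aligned_length", "pct_identity", "pct_similarity"])


def read_fingerprint_bed(path) -> dict[str, dict[str, tuple[int, int]]]:
    """Read fingerprint motif coordinates from a BED-like TSV
    (protein_id, label, start, end; 0-based half-open)."""
    out: dict[str, dict[str, tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"line {lineno}: expected 4 columns, got {len(fields)}")
            pid, label, start_s, end_s = fields
            motifs = out.setdefault(pid, {})
            if label in motifs:
                raise ValueError(f"line {lineno}: duplicate motif label {label!r} for {pid!r}")
            motifs[label] = (int(start_s), int(end_s))
    return out


def fingerprint_similarity(records: list[ProteinRecord], label: str, denominator: str = "alignment") -> pd.DataFrame:
    """Pairwise similarity of one fingerprint motif across proteins that
    carry it."""
    seqs = {
        rec.protein_id: rec.motif_sequence(label)
        for rec in records
        if label in rec.fingerprint_motifs
    }
    return pairwise_matrix(seqs, denominator)
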