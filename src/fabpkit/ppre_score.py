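"""Bipartite PPRE evaluation: fraction-similarity scoring and PPAR-isoform
selectivity.

A functional PPRE is a composite element, ``5'FR + DR1``: a poorly conserved
5-nt flanking region (consensus ``CAAAC``) immediately upstream of the
conserved direct repeat DR1 (consensus ``AGGTCANAGGTCA``, the AGGTCA
half-site repeated with a 1-nt spacer).  The DR1 carries PPAR/RXR binding;
the 5'FR biases which PPAR isoform binds.

Each candidate element is scored base-by-base against its consensus:

* identical base                      -> 1
* conservative substitution           -> 0.5 (purine<->purine A/G,
                                        pyrimidine<->pyrimidine C/T)
* cross-class substitution            -> 0
* consensus ``N``                     -> 1 against any base

The fraction similar is the summed score divided by the element length.  A
promoter is called PPRE-positive when the DR1 fraction exceeds 0.5; among
positives, a 5'FR fraction above 0.5 predicts PPARalpha selectivity, and at
or below 0.5 PPARgamma.  Both comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass

from fabpkit.promoter_io import PromoterRecord

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

FR5_CONSENSUS = "CAAAC"
DR1_CONSENSUS = "AGGTCANAGGTCA"

ALPHA, GAMMA, NONE = "alpha", "gamma", "none"


@dataclass(frozen=True)
class ConsensusElement:
    """A labelled IUPAC consensus string (FR5 or DR1)."""

    label: str
    consensus: str

    def __post_init__(self) -> None:
        bad = set(self.consensus) - set("ACGTN")
        if bad:
            raise ValueError(f"consensus may only contain ACGTN, got {sorted(bad)}")
        if len(self.consensus) < 1:
            raise ValueError("consensus must be non-empty")

    def __len__(self) -> int:
        return len(self.consensus)


FR5 = ConsensusElement("FR5", FR5_CONSENSUS)
DR1 = ConsensusElement("DR1", DR1_CONSENSUS)


@dataclass(frozen=True)
class PpreEvaluation:
    """Scored bipartite element for one promoter/gene."""

    gene_id: str
    fr5_seq: str
    fr5_score: float
    fr5_fraction: float
    dr1_seq: str
    dr1_score: float
    dr1_fraction: float
    is_ppre: bool
    selectivity: str
    start: int | None = None  # 0-based offset of the 5'FR within the promoter
    strand: str | None = None


def base_pair_score(observed: str, consensus_base: str) -> float:
    """Per-base similarity of an observed base to a consensus base.

    1 for identity or a consensus ``N``; 0.5 for a conservative
    (within-chemical-class) substitution; 0 across classes.
    """
    if observed not in "ACGT" or len(observed) != 1:
        raise ValueError(f"observed base must be one of ACGT, got {observed!r}")
    if consensus_base not in "ACGTN" or len(consensus_base) != 1:
        raise ValueError(f"consensus base must be one of ACGTN, got {consensus_base!r}")
    if consensus_base == "N" or observed == consensus_base:
        return 1.0
    if (observed in PURINES) == (consensus_base in PURINES):
        return 0.5
    return 0.0


def fraction_similar(seq: str, consensus: ConsensusElement | str) -> tuple[float, float]:
    """Summed per-base score and the fraction (score / length) of ``seq``
    against ``consensus``.  Lengths must match; ``seq`` must be unambiguous."""
    cons = consensus.consensus if isinstance(consensus, ConsensusElement) else consensus
    seq = seq.upper()
    if len(seq) != len(cons):
        raise ValueError(f"sequence length {len(seq)} != consensus length {len(cons)}")
    score = sum(base_pair_score(s, c) for s, c in zip(seq, cons))
    return score, score / len(cons)


def format_fraction(fraction: float, decimals: int = 2) -> float:
    """Truncate a fraction toward zero to ``decimals`` places for tabular
    display (e.g. 10/13 = 0.769... -> 0.76).  Classification always uses the
    unrounded value."""
    factor = 10 ** decimals
    return int(fraction * factor + 1e-9) / factor


def classify_selectivity(fr5_fraction: float, dr1_fraction: float) -> str:
    """PPAR-isoform selectivity from the two element fractions.

    DR1 fraction <= 0.5 -> ``none`` (no PPRE).  Otherwise a 5'FR fraction
    > 0.5 predicts ``alpha``, else ``gamma``.  Comparisons are strict, so a
    fraction of exactly 0.5 falls to ``gamma`` (5'FR) or ``none`` (DR1).
    """
    for name, frac in (("fr5", fr5_fraction), ("dr1", dr1_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name}_fraction must be in [0, 1], got {frac}")
    if dr1_fraction <= 0.5:
        return NONE
    return ALPHA if fr5_fraction > 0.5 else GAMMA


def evaluate_elements(
    gene_id: str,
    fr5_seq: str,
    dr1_seq: str,
    start: int | None = None,
    strand: str | None = None,
) -> PpreEvaluation:
    """Score a user-supplied fixed (5'FR, DR1) pair — e.g. published element
    sequences — and classify selectivity."""
    fr5_score, fr5_frac = fraction_similar(fr5_seq, FR5)
    dr1_score, dr1_frac = fraction_similar(dr1_seq, DR1)
    sel = classify_selectivity(fr5_frac, dr1_frac)
    return PpreEvaluation(
        gene_id=gene_id,
        fr5_seq=fr5_seq.upper(),
        fr5_score=fr5_score,
        fr5_fraction=fr5_frac,
        dr1_seq=dr1_seq.upper(),
        dr1_score=dr1_score,
        dr1_fraction=dr1_frac,
        is_ppre=sel != NONE,
        selectivity=sel,
        start=start,
        strand=strand,
    )


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def find_best_ppre(
    promoter: PromoterRecord | str,
    gene_id: str | None = None,
    spacer: int = 0,
) -> PpreEvaluation:
    """Best bipartite PPRE in a promoter by exhaustive sliding-window search.

    An 18-nt window (5-nt 5'FR immediately upstream of the 13-nt DR1, with
    an optional ``spacer`` of 0-2 nt between them) slides across both
    strands.  The returned evaluation maximises the DR1 score; ties break by
    larger 5'FR score, then smaller start, then '+' strand.  Windows with
    ambiguous bases are skipped.
    """
    if isinstance(promoter, PromoterRecord):
        seq, gid = promoter.sequence, promoter.gene_id
    else:
        seq, gid = str(promoter).upper(), gene_id or "seq"
    if not 0 <= spacer <= 2:
        raise ValueError(f"spacer must be in 0..2, got {spacer}")
    win = len(FR5) + spacer + len(DR1)
    if len(seq) < win:
        raise ValueError(f"promoter length {len(seq)} shorter than the {win}-nt bipartite window")

    best: PpreEvaluation | None = None
    best_key: tuple | None = None
    for start in range(len(seq) - win + 1):
        window = seq[start : start + win]
        if set(window) - set("ACGT"):
            continue
        for strand in "+-":
            oriented = window if strand == "+" else _revcomp(window)
            fr5_seq = oriented[: len(FR5)]
            dr1_seq = oriented[len(FR5) + spacer :]
            ev = evaluate_elements(gid, fr5_seq, dr1_seq, start=start, strand=strand)
            key = (ev.dr1_score, ev.fr5_score, -start, strand == "+")
            if best_key is None or key > best_key:
                best, best_key = ev, key
    if best is None:
        raise ValueError("no ambiguity-free window available for PPRE evaluation")
    return best


def evaluations_to_rows(evals: list[PpreEvaluation]) -> list[dict]:
    """TSV-ready rows; fractions truncated to 2 decimals as printed in
    element tables, scores at full precision."""
    return [
        {
            "gene_id": e.gene_id,
            "fr5_seq": e.fr5_seq,
            "fr5_score": e.fr5_score,
            "fr5_fraction": format_fraction(e.fr5_fraction),
            "dr1_seq": e.dr1_seq,
            "dr1_score": e.dr1_score,
            "dr1_fraction": format_fraction(e.dr1_fraction),
            "is_ppre": e.is_ppre,
            "selectivity": e.selectivity,
            "start": e.start,
            "strand": e.strand,
        }
        for e in evals
    ]
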