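"""Position-weight-matrix engine: JASPAR parsing, log-odds scoring, exact
p-values, and double-stranded promoter scanning.

The scanner reproduces what FIMO-class tools do: a count matrix is turned
into a log-odds model against a 0-order background, every window on both
strands of a promoter is scored, and each score is converted to an exact
p-value via the lattice dynamic programme (the distribution of the
discretised score of a random background site).  Scores are in bits
(log base 2).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from fabpkit.promoter_io import PromoterRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G
UNIFORM_BACKGROUND = np.full(4, 0.25)

#: Hard floor (bits per position) substituted for -infinity log-odds entries
#: that arise from a zero count with zero pseudocount.
NEG_INF_FLOOR = -30.0


@dataclass
class WeightMatrix:
    """A TF binding motif: counts plus derived log-odds model.

    ``counts`` is width x 4 (columns A, C, G, T).  The log-odds entry for
    base *b* at position *i* is::

        log2( (counts[i,b] + pseudocount * background[b])
              / (colsum_i + pseudocount) / background[b] )

    Entries that would be -infinity (zero count, zero pseudocount) are
    floored at min(finite entries) - 10 bits, never above
    :data:`NEG_INF_FLOOR`, so every site score stays finite and zero-
    probability sites sort strictly below all attainable ones.
    """

    matrix_id: str
    name: str
    counts: np.ndarray
    pseudocount: float = 0.1
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    log_odds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(f"counts must be width x 4, got shape {self.counts.shape}")
        if self.counts.shape[0] < 1:
            raise ValueError("matrix width must be >= 1")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        colsums = self.counts.sum(axis=1)
        if ((colsums + self.pseudocount) <= 0).any():
            raise ValueError("each column must have positive total count after pseudocount")
        probs = (self.counts + self.pseudocount * self.background) / (
            colsums + self.pseudocount
        )[:, None]
        with np.errstate(divide="ignore"):
            lo = np.log2(probs / self.background)
        finite = lo[np.isfinite(lo)]
        floor = min(NEG_INF_FLOOR, (finite.min() - 10.0) if finite.size else NEG_INF_FLOOR)
        self.log_odds = np.where(np.isfinite(lo), lo, floor)

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def reverse_complement(self) -> "WeightMatrix":
        rc_counts = self.counts[::-1, COMPLEMENT_INDEX]
        return WeightMatrix(self.matrix_id, self.name, rc_counts, self.pseudocount, self.background)

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    """One scoring window on a promoter, with its exact p-value.

    ``q_value`` is the Benjamini-Hochberg FDR over all windows scored in the
    same scan; it is only populated when the scan is run with ``bh=True``.
    """

    gene_id: str
    matrix_id: str
    start: int  # 0-based offset within the promoter
    strand: str  # relative to the promoter sequence
    site: str
    score: float  # bits
    p_value: float
    q_value: float | None = None


def read_jaspar(path_or_text, pseudocount: float = 0.1, background: np.ndarray | None = None) -> list[WeightMatrix]:
    """Parse JASPAR count-matrix text into :class:`WeightMatrix` objects.

    Accepts both the bracketed dialect (``A  [ 4 19  0 ]``) and the bare
    matrix dialect (four whitespace-separated count rows, in A, C, G, T
    order) — mixed freely between records.  Raises ``ValueError`` on ragged
    rows or negative counts.
    """
    try:
        text = open(path_or_text).read()
    except (OSError, TypeError):
        text = str(path_or_text)
    if background is None:
        background = UNIFORM_BACKGROUND.copy()

    matrices: list[WeightMatrix] = []
    header: tuple[str, str] | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise ValueError(f"matrix {header[0]!r}: expected 4 count rows, got {len(rows)}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"matrix {header[0]!r}: count rows of unequal length {sorted(lengths)}")
        counts = np.array(rows, dtype=float).T  # rows are per-base, columns per-position
        if (counts < 0).any():
            raise ValueError(f"matrix {header[0]!r}: negative counts")
        matrices.append(WeightMatrix(header[0], header[1], counts, pseudocount, background))
        header, rows = None, []

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split(None, 1)
            if not parts:
                raise ValueError("empty JASPAR header line")
            header = (parts[0], parts[1].strip() if len(parts) > 1 else parts[0])
            continue
        if header is None:
            raise ValueError("count row before any '>' header")
        body = re.sub(r"^[ACGTacgt]\s*", "", line)
        body = body.replace("[", " ").replace("]", " ")
        try:
            rows.append([float(x) for x in body.split()])
        except ValueError:
            raise ValueError(f"unparseable count row: {raw!r}")
    flush()
    return matrices


def estimate_background(sequences: Iterable[str]) -> np.ndarray:
    """0-order background from base frequencies over a set of sequences (N ignored)."""
    counts = np.zeros(4)
    for seq in sequences:
        for base in seq.upper():
            idx = BASE_INDEX.get(base)
            if idx is not None:
                counts[idx] += 1
    if counts.sum() == 0:
        return UNIFORM_BACKGROUND.copy()
    return counts / counts.sum()


def score_site(wm: WeightMatrix, site: str) -> float:
    """Log-odds score (bits) of a concrete site of the matrix's width.

    Ambiguous bases are an error: sites come from scans of concrete
    sequence, and N-containing windows are skipped upstream.
    """
    site = site.upper()
    if len(site) != wm.width:
        raise ValueError(f"site length {len(site)} != matrix width {wm.width}")
    total = 0.0
    for i, base in enumerate(site):
        idx = BASE_INDEX.get(base)
        if idx is None:
            raise ValueError(f"ambiguous or invalid base {base!r} at position {i}")
        total += wm.log_odds[i, idx]
    return total


class ScoreDistribution:
    """Exact distribution of the discretised site score under the background.

    Per-position log-odds are rounded onto an integer lattice with
    ``granularity`` bins per bit and convolved across positions by dynamic
    programming — the same construction FIMO-class scanners use.  The
    default granularity is chosen so the attainable score range spans at
    least 1000 bins.
    """

    def __init__(self, wm: WeightMatrix, granularity: float | None = None):
        if granularity is None:
            span = float(wm.log_odds.max(axis=1).sum() - wm.log_odds.min(axis=1).sum())
            granularity = max(1.0, 1000.0 / span) if span > 0 else 1.0
        if granularity < 1:
            raise ValueError("granularity must be >= 1 bin per bit")
        self.granularity = float(granularity)
        self.wm = wm
        q = np.rint(wm.log_odds * self.granularity).astype(np.int64)
        self._q = q
        lo = int(q.min(axis=1).sum())
        hi = int(q.max(axis=1).sum())
        probs = np.zeros(hi - lo + 1)
        # DP over positions: start as a point mass, convolve with the four
        # per-position outcomes weighted by the background.
        offset_min = 0
        dist = np.array([1.0])
        for i in range(wm.width):
            row = q[i]
            new_min = offset_min + int(row.min())
            new_len = len(dist) + int(row.max() - row.min())
            new = np.zeros(new_len)
            for b in range(4):
                shift = offset_min + int(row[b]) - new_min
                new[shift : shift + len(dist)] += wm.background[b] * dist
            dist, offset_min = new, new_min
        probs[offset_min - lo : offset_min - lo + len(dist)] = dist
        self._lo = lo
        self.probabilities = probs
        # tail[i] = P(score_bin >= lo + i)
        self._tail = np.cumsum(probs[::-1])[::-1]

    def site_bin(self, site: str) -> int:
        """Integer lattice score of a concrete site (sum of rounded entries)."""
        return int(sum(self._q[i, BASE_INDEX[b]] for i, b in enumerate(site.upper())))

    def pvalue_of_bin(self, score_bin: int) -> float:
        idx = score_bin - self._lo
        if idx < 0:
            return 1.0
        if idx >= len(self._tail):
            return 0.0
        return float(self._tail[idx])

    def pvalue(self, score_bits: float) -> float:
        """Tail probability P(background site score >= ``score_bits``)."""
        return self.pvalue_of_bin(int(np.rint(score_bits * self.granularity)))

    def as_dict(self) -> dict[float, float]:
        """Mapping of score-bin centre (bits) -> probability, zero bins omitted."""
        return {
            (self._lo + i) / self.granularity: float(p)
            for i, p in enumerate(self.probabilities)
            if p > 0
        }


def score_distribution(wm: WeightMatrix, granularity: float | None = None) -> ScoreDistribution:
    """Build the exact background score distribution for ``wm``."""
    return ScoreDistribution(wm, granularity)


def scan_promoter(
    wm: WeightMatrix,
    promoter: PromoterRecord | str,
    p_threshold: float = 1e-4,
    gene_id: str | None = None,
    distribution: ScoreDistribution | None = None,
    bh: bool = False,
) -> list[MotifHit]:
    """All windows on both strands of ``promoter`` with p-value <= threshold.

    Minus-strand hits score the reverse complement of the window but report
    the promoter-forward start offset.  Windows containing non-ACGT bases
    are skipped.  Hits are sorted by start, '+' before '-'.

    With ``bh=True`` each reported hit additionally carries a
    Benjamini-Hochberg q-value computed over every window scored in this
    scan (both strands); filtering stays on the raw p-value.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    if isinstance(promoter, PromoterRecord):
        seq, gid = promoter.sequence, promoter.gene_id
    else:
        seq, gid = str(promoter).upper(), gene_id or "seq"
    w = wm.width
    if len(seq) < w:
        logger.warning("promoter %s (length %d) shorter than matrix width %d", gid, len(seq), w)
        return []
    dist = distribution if distribution is not None else ScoreDistribution(wm)
    rc_wm = wm.reverse_complement()
    # The reverse-complement matrix's log-odds entries are a permutation of
    # the forward ones, so its lattice scores live on the same distribution;
    # reuse dist's tail with the rc matrix's own rounded entries.
    rc_qmat = np.rint(rc_wm.log_odds * dist.granularity).astype(np.int64)

    scored: list[tuple[int, str, str, float, float]] = []  # start, strand, site, score, p
    for start in range(len(seq) - w + 1):
        window = seq[start : start + w]
        idx = [BASE_INDEX.get(b) for b in window]
        if any(i is None for i in idx):
            continue
        for strand in "+-":
            if strand == "+":
                sbin = int(sum(dist._q[i, b] for i, b in enumerate(idx)))
                lo = wm.log_odds
            else:
                sbin = int(sum(rc_qmat[i, b] for i, b in enumerate(idx)))
                lo = rc_wm.log_odds
            score = float(sum(lo[i, b] for i, b in enumerate(idx)))
            p = dist.pvalue_of_bin(sbin)
            site = window if strand == "+" else _revcomp(window)
            scored.append((start, strand, site, score, p))

    qvals: list[float | None]
    if bh and scored:
        from scipy.stats import false_discovery_control

        qvals = list(false_discovery_control([s[4] for s in scored], method="bh"))
    else:
        qvals = [None] * len(scored)

    return [
        MotifHit(gid, wm.matrix_id, start, strand, site, score, p, q)
        for (start, strand, site, score, p), q in zip(scored, qvals)
        if p <= p_threshold
    ]


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def hits_to_rows(hits: Sequence[MotifHit], width: int) -> list[dict]:
    """TSV-ready rows (1-based start/end in the report) for a set of hits."""
    return [
        {
            "gene_id": h.gene_id,
            "matrix_id": h.matrix_id,
            "start": h.start + 1,
            "end": h.start + width,
            "strand": h.strand,
            "site": h.site,
            "score_bits": round(h.score, 4),
            "p_value": h.p_value,
        }
        for h in hits
    ]
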