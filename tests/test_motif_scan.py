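"""PWM engine: parsing, log-odds scoring, exact p-values, scanning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fabpkit.motif_scan import (
    BASES,
    WeightMatrix,
    estimate_background,
    read_jaspar,
    scan_promoter,
    score_distribution,
    score_site,
)

_RC = str.maketrans("ACGT", "TGCA")


def random_count_matrix(rng: np.random.Generator, width: int) -> WeightMatrix:
    """A random strictly-positive count matrix (no -inf log-odds)."""
    counts = rng.integers(1, 50, size=(width, 4)).astype(float)
    return WeightMatrix(f"RND{width}", "random", counts, pseudocount=0.1)


def revcomp(s):
    return s.translate(_RC)[::-1]


BRACKETED = """\
>MA0000.1 toy
A [ 4 19 0 ]
C [16  0 20]
G [ 0  1  0]
T [ 0  0  0]
"""

BARE = """\
>MX0002 bare
4 19 0
16 0 20
0 1 0
0 0 0
"""


class TestReadJaspar:
    def test_minimal_one_column_matrix(self):
        (wm,) = read_jaspar(">M1 one\nA [4]\nC [0]\nG [0]\nT [0]\n")
        assert wm.width == 1
        assert wm.counts[0].tolist() == [4.0, 0.0, 0.0, 0.0]

    @pytest.mark.parametrize("text", [BRACKETED, BARE])
    def test_both_dialects_parse_identically(self, text):
        (wm,) = read_jaspar(text)
        assert wm.width == 3
        assert wm.counts[:, 0].tolist() == [4.0, 19.0, 0.0]  # A row -> first column
        assert wm.counts[:, 1].tolist() == [16.0, 0.0, 20.0]

    def test_two_matrices_order_preserved(self):
        mats = read_jaspar(BRACKETED + "\n" + BARE)
        assert [m.matrix_id for m in mats] == ["MA0000.1", "MX0002"]

    def test_ragged_rows_error(self):
        with pytest.raises(ValueError, match="unequal length"):
            read_jaspar(">M1 bad\nA [1 2 3]\nC [1 2 3]\nG [1 2 3]\nT [1 2]\n")

    def test_negative_counts_error(self):
        with pytest.raises(ValueError, match="negative"):
            read_jaspar(">M1 bad\nA [1 -2]\nC [1 2]\nG [1 2]\nT [1 2]\n")


class TestScoreSite:
    def test_uniform_matrix_scores_zero_everywhere(self):
        wm = WeightMatrix("M", "flat", np.full((3, 4), 5.0), pseudocount=0.0)
        for site in ("AAA", "CGT", "TTT"):
            assert score_site(wm, site) == pytest.approx(0.0)

    def test_a_only_matrix_closed_form(self):
        wm = WeightMatrix("M", "aa", np.array([[1, 0, 0, 0], [1, 0, 0, 0]], float), pseudocount=0.0)
        assert score_site(wm, "AA") == pytest.approx(4.0)  # 2 * log2(4)

    def test_zero_probability_site_large_negative(self):
        wm = WeightMatrix("M", "aa", np.array([[1, 0, 0, 0], [1, 0, 0, 0]], float), pseudocount=0.0)
        assert score_site(wm, "CC") <= -30.0
        assert np.isfinite(score_site(wm, "CC"))

    def test_ambiguous_base_is_error(self, consensus_matrix):
        with pytest.raises(ValueError, match="ambiguous"):
            score_site(consensus_matrix, "ACGTNCGTAC")

    def test_wrong_length_is_error(self, consensus_matrix):
        with pytest.raises(ValueError, match="width"):
            score_site(consensus_matrix, "ACGT")


def enumerate_tail(wm: WeightMatrix, site_bin, threshold_bin: int) -> float:
    """Independent oracle: tail mass at a lattice threshold by summing the
    background probability of every one of the 4^w sites explicitly (no
    convolution)."""
    total = 0.0
    for site in itertools.product(BASES, repeat=wm.width):
        if site_bin("".join(site)) >= threshold_bin:
            total += float(np.prod([wm.background[BASES.index(b)] for b in site]))
    return total


class TestScoreDistribution:
    def test_width_one_uniform_four_equal_bins(self):
        wm = WeightMatrix("M", "w1", np.array([[8, 4, 2, 1]], float), pseudocount=0.0)
        dist = score_distribution(wm)
        assert sum(dist.as_dict().values()) == pytest.approx(1.0, abs=1e-9)
        assert sorted(dist.as_dict().values()) == pytest.approx([0.25] * 4)

    def test_pvalue_of_unique_optimum_is_quarter_power_width(self, consensus_matrix):
        dist = score_distribution(consensus_matrix)
        assert dist.pvalue(consensus_matrix.max_score()) == pytest.approx(
            0.25 ** consensus_matrix.width, rel=1e-9
        )

    def test_probabilities_sum_to_one(self, consensus_matrix):
        dist = score_distribution(consensus_matrix)
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=20, deadline=None)
    @given(width=st.integers(1, 5), seed=st.integers(0, 2**31 - 1))
    def test_dp_matches_enumeration(self, width, seed):
        """DP tail p-values equal brute-force enumeration over all 4^w sites."""
        rng = np.random.default_rng(seed)
        wm = random_count_matrix(rng, width)
        dist = score_distribution(wm)
        # evaluate at the exact lattice score of a few random sites
        for _ in range(5):
            site = "".join(rng.choice(list(BASES), size=width))
            sbin = dist.site_bin(site)
            brute = enumerate_tail(wm, dist.site_bin, sbin)
            assert dist.pvalue_of_bin(sbin) == pytest.approx(brute, rel=1e-9, abs=1e-12)

    def test_pvalue_monotone_in_score(self, consensus_matrix):
        dist = score_distribution(consensus_matrix)
        scores = np.linspace(-20, consensus_matrix.max_score(), 50)
        pvals = [dist.pvalue(s) for s in scores]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))


class TestScanPromoter:
    def test_planted_consensus_recovered(self, consensus_matrix):
        rng = np.random.default_rng(5)
        background = "".join(rng.choice(list(BASES), size=200))
        cons = consensus_matrix.consensus()
        seq = background[:80] + cons + background[80:]
        hits = scan_promoter(consensus_matrix, seq, 1e-4, gene_id="g")
        assert any(h.start == 80 and h.strand == "+" and h.site == cons for h in hits)

    def test_threshold_one_returns_every_window(self, consensus_matrix):
        seq = "ACGT" * 10  # 40 nt, no N
        hits = scan_promoter(consensus_matrix, seq, 1.0, gene_id="g")
        w = consensus_matrix.width
        assert len(hits) == 2 * (len(seq) - w + 1)

    def test_all_n_promoter_empty(self, consensus_matrix):
        assert scan_promoter(consensus_matrix, "N" * 50, 0.5, gene_id="g") == []

    def test_promoter_shorter_than_width_warns_empty(self, consensus_matrix, caplog):
        assert scan_promoter(consensus_matrix, "ACG", 0.5, gene_id="g") == []
        assert any("shorter" in r.message for r in caplog.records)

    def test_monotonicity_lower_threshold_never_adds_hits(self, consensus_matrix):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list(BASES), size=300))
        loose = {(h.start, h.strand) for h in scan_promoter(consensus_matrix, seq, 1e-2, gene_id="g")}
        tight = {(h.start, h.strand) for h in scan_promoter(consensus_matrix, seq, 1e-4, gene_id="g")}
        assert tight <= loose

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_strand_symmetry(self, seed):
        """Scanning a sequence equals scanning its revcomp with strands
        swapped and coordinates mirrored."""
        rng = np.random.default_rng(seed)
        wm = random_count_matrix(rng, int(rng.integers(3, 8)))
        seq = "".join(rng.choice(list(BASES), size=60))
        w = wm.width
        fwd = scan_promoter(wm, seq, 0.05, gene_id="g")
        rev = scan_promoter(wm, revcomp(seq), 0.05, gene_id="g")
        mirrored = {
            (len(seq) - h.start - w, "+-"[h.strand == "+"], h.site, round(h.p_value, 12))
            for h in rev
        }
        assert {(h.start, h.strand, h.site, round(h.p_value, 12)) for h in fwd} == mirrored


def test_estimate_background_counts_frequencies():
    bg = estimate_background(["AACC", "GGNN"])
    assert bg.tolist() == pytest.approx([2 / 6, 2 / 6, 2 / 6, 0.0])


def test_bh_qvalues_attached_and_no_smaller_than_p(consensus_matrix):
    rng = np.random.default_rng(23)
    cons = consensus_matrix.consensus()
    seq = "".join(rng.choice(list(BASES), size=120)) + cons
    hits = scan_promoter(consensus_matrix, seq, 1e-3, gene_id="g", bh=True)
    assert hits, "planted consensus should be reported"
    for h in hits:
        assert h.q_value is not None
        assert h.q_value >= h.p_value - 1e-15
    # default scan leaves q_value unset
    plain = scan_promoter(consensus_matrix, seq, 1e-3, gene_id="g")
    assert all(h.q_value is None for h in plain)
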