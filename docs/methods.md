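# Methods

`fabpkit` links promoter sequence to expression behaviour for the chicken
fatty acid-binding protein (FABP) gene family: it extracts promoters,
scans them for nuclear-receptor motifs, scores candidate bipartite PPREs
with a fraction-similarity rule, quantifies qPCR experiments by the
comparative-threshold-cycle method, and joins the motif predictions to
observed agonist responses. This note records the models, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Promoter extraction

Promoters are the `length` bases (default 2000) strictly upstream of a
gene's transcription start site (TSS): the TSS base itself is excluded,
since "upstream of the TSS" is read literally. `include_tss=True` shifts
the window by one base for the other convention. Internally all
coordinates are 0-based half-open on the forward strand; GFF3 input
(1-based inclusive) is converted at the boundary. For a `+` gene with TSS
at 1-based position *t* the window is `[t-1-length, t-1)`; for a `-` gene
it is `[t, t+length)` and the stored sequence is reverse-complemented, so
promoter sequences always read 5'→3' in the direction of transcription.

Windows overhanging a chromosome end are truncated with a logged warning
(a window entirely off-chromosome is an error). When several transcripts
share a gene id, the 5'-most TSS in transcription direction is used — a
deterministic rule chosen because annotation sets rarely say which
transcript a published promoter analysis used. Soft-masked (lowercase)
bases are uppercased, not filtered.

## PWM scanning and exact p-values

Count matrices in JASPAR text format (both the bracketed `A [ 4 19 0 ]`
dialect and bare four-row matrices) are converted to log-odds models in
bits:

    log_odds[i][b] = log2( (counts[i][b] + κ·q_b) / (Σ_b counts[i][b] + κ) / q_b )

with pseudocount κ = 0.1 (distributed by background) and a uniform
background q = (¼,¼,¼,¼) by default; a 0-order background can instead be
estimated from the scanned promoter set. The pseudocount default is a
small positive value that avoids −∞ log-odds; when κ = 0 is requested,
−∞ entries are floored at min(finite entries) − 10 bits (never above
−30 bits/position) so every site score stays finite and zero-probability
sites sort strictly below all attainable ones.

Score p-values are exact, not sampled: per-position log-odds are rounded
onto an integer lattice and convolved across positions by dynamic
programming, giving the distribution of the discretised score of a random
background site. The default lattice resolution makes the attainable
score range span at least 1000 bins, tying the discretisation error of a
p-value to below 0.1% of the score range. Site p-values are looked up at
the site's own lattice score (the sum of its rounded per-position
entries), which makes the p-value exactly monotone in the lattice score
and lets the test suite demand bit-for-bit equality between the DP tail
and brute-force enumeration over all 4^w sites.

Scanning evaluates every window on both strands; minus-strand windows are
scored through the reverse-complement matrix (whose log-odds entries are
a permutation of the forward ones under a complement-symmetric
background, so the same score distribution applies) and report the
promoter-forward start. Windows containing ambiguous bases are skipped.
The default reporting threshold is p ≤ 1e-4, the conventional default of
FIMO-class scanners. Overlapping hits are all reported and no
multiple-testing correction is applied by default (putative-site scans
are usually reported uncorrected); a Benjamini–Hochberg flag exists for
users who want q-values.

Note a structural consequence of exact p-values: a width-w motif's best
attainable p-value is 0.25^w under the uniform background, so perfect
consensus sites of motifs narrower than 7 bp cannot pass p ≤ 1e-4. The
planted-site recovery guarantees in the test suite therefore use motifs
of DR1-like width (≥ 10 bp).

## Bipartite PPRE scoring and PPAR-isoform selectivity

A functional PPRE is modelled as a 5-nt 5' flanking region (5'FR,
consensus `CAAAC`) immediately upstream of the 13-nt direct repeat DR1
(consensus `AGGTCANAGGTCA` — the AGGTCA half-site repeated with a 1-nt
spacer). Each candidate element is scored base-by-base against its
consensus: 1 for identity, 0.5 for a conservative substitution
(purine↔purine A/G or pyrimidine↔pyrimidine C/T), 0 across classes, and 1
for any base against a consensus `N`. The *fraction similar* is the
summed score divided by element length (5 or 13).

The N-scores-1 rule is the only choice in {0, 0.5, 1} that reproduces the
published score table for this family (e.g. a DR1 score of 9.5/13 for the
FABP1 element); this was confirmed by brute force over the alternatives.
Three published DR1 cells (FABP5, FABP7, FABP10) are each 0.5 higher than
the stated rule yields on the printed sequences; no consistent variant of
the rule reproduces all 14 cells simultaneously, so the implementation
follows the stated rule and `validate_reported_elements()` flags the three
discrepant cells in its report rather than absorbing them. The
classification is insensitive to the ±0.5 because all the affected DR1
fractions exceed 0.5 either way.

Classification: DR1 fraction > 0.5 ⇒ the promoter carries a putative PPRE;
among positives, 5'FR fraction > 0.5 predicts PPARα selectivity, otherwise
PPARγ. Both comparisons are strict, so a fraction of exactly 0.5 falls to
γ (5'FR) or to no-PPRE (DR1). The rule only emits α/γ; PPARβ selectivity
is not modelled.

`find_best_ppre` slides the 18-nt bipartite window (5'FR directly abutting
DR1; a 0–2 nt spacer is configurable but defaults to 0, mirroring the
composite consensus `CAAAACAGGTCANAGGTCA`) across both strands and returns
the window maximising the DR1 score, with ties broken by larger 5'FR
score, then smaller start, then `+` strand. An exhaustive brute-force
maximisation serves as the oracle in tests. Fixed, user-supplied element
pairs (e.g. published sequences) can be scored directly via
`evaluate_elements`.

Display convention: tabular output truncates fractions toward zero at two
decimals (10/13 → 0.76), matching how such tables are conventionally
printed; classification always uses the unrounded values.

## Protein percent identity and similarity

Pairs of protein sequences are globally aligned (Needleman–Wunsch through
Biopython's `PairwiseAligner`) with BLOSUM62, gap open 10 and gap extend
0.5. Percent identity is the fraction of identical aligned columns;
percent similarity additionally counts columns whose residue pair has a
strictly positive BLOSUM62 score. The default denominator is the full
alignment length including gap columns; `shorter` and `nongap`
alternatives are available because published percentages rarely state the
convention. The same machinery applies to the FATTYACIDBP fingerprint
motifs (the three-motif PRINTS signature PR00178 shared by all FABPs),
whose coordinates are inputs, supplied as a BED-like TSV — fingerprint
*detection* is out of scope.

### Optional external validation

Quantities that derive from the real chicken genome and proteome — the
nine-member family size, protein lengths of 115–134 aa, the reported
full-protein pairwise similarity band of 25.37–39.37%, and divergence-time
estimates — cannot be recomputed without downloading those sequences, so
the package ships no such data and the test suite does not assert them.
Users with the chicken FABP protein set can run `pairwise_matrix` on it
and check that the full-protein similarities fall in the reported
25.37–39.37% band; this is a documented optional external validation, not
a shipped test. The reported molecular-weight range for these proteins
(128.6–157.5 kDa for 115–134 aa chains) is physically impossible by an
order of magnitude, so molecular-weight computation was deliberately
excluded rather than reproducing a likely typo.

## qPCR relative quantification

The Livak comparative-threshold-cycle model with amplification efficiency
fixed at 2 per cycle:

    ΔCt_s  = Ct_target,s − Ct_reference,s          (per sample s)
    ΔΔCt   = mean(ΔCt, treatment) − mean(ΔCt, control)
    fold   = 2^−ΔΔCt

Technical replicates are arithmetically averaged per (sample, gene)
before any statistics so that biological n drives the degrees of freedom;
a replicate spread above 1 cycle triggers a warning naming the sample and
gene. Samples lacking a reference-gene measurement are dropped with a
warning. The calibrator is the control-group mean ΔCt (per-group
calibration), the standard Livak formulation. Significance is a
two-sided two-sample t-test on the per-sample ΔCt values — Student's
pooled-variance test by default, Welch by flag — and a gene is called
`up`/`down` when p < α (default 0.05) with fold above/below 1, otherwise
`unchanged`. When both arms have zero variance the t-statistic is
undefined; the implementation returns p = 1 for equal means and p = 0
otherwise. No multiple-testing correction is applied across genes by
default (matching the per-gene p < 0.05 reporting convention of the
experiments this emulates); a Benjamini–Hochberg option exists.

Two structural invariants are tested: ΔΔCt antisymmetry (swapping the
arms inverts the fold change) and invariance under a per-sample global Ct
shift (reference-gene normalisation removes sample-level efficiency
offsets).

### Concordance with agonist responses

The concordance stage joins the per-gene PPRE selectivity prediction with
a table of qualitative agonist responses (gene × agonist → up / down /
unchanged, with an optional concentration column so dose-dependent
reversals can be encoded). A prediction is *concordant* when the
predicted isoform's agonist (α → PPARα agonist, γ → PPARγ agonist) is
among the agonists that elicited a non-unchanged response; a PPRE-negative
gene is concordant when nothing responds. Genes present on only one side
of the join are listed separately rather than judged.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes, seeded and
reproducible (every generator is a pure function of its config, seed
included):

* **Promoters/genomes** — i.i.d. background sequence at a configurable GC
  content (default 0.41, a typical avian promoter neighbourhood), with
  elements planted at recorded offsets and strands. To plant an element at
  a target similarity fraction, consensus positions are mutated (a
  cross-class substitution lowers the fraction by 1/L, a class-preserving
  one by 0.5/L); the achieved fraction is verified with the production
  scorer before anything is written, and targets are snapped to the
  nearest reachable 0.5/L lattice point so rounded published fractions
  (0.73 for 9.5/13) are accepted. Unreachable targets (below the floor set
  by `N` positions) are an error.
* **Ct tables** — per sample, control ΔCt ~ Normal(baseline_ct −
  reference_ct, noise_sd) with the treatment arm shifted by −(planted
  log2 fold change); technical replicates add Normal(0, tech_sd) cycles to
  each measured Ct. Defaults: baseline 25, reference 18, biological noise
  0.3 cycles, technical noise 0.1 cycles, 3 technical replicates, 8
  samples per arm — the design scale of the liver staging experiment this
  emulates.

Deliberately not modelled: repeat structure, CpG islands or any
higher-order sequence composition; qPCR plate effects, efficiency
differences between genes, or non-Gaussian Ct noise. Passing tests on
this synthetic data therefore demonstrate correctness of the scoring and
inference machinery under the stated noise model, not robustness to real
promoter composition or real qPCR artefacts.

## Numerical choices and degenerate inputs

* PWM lattice: ≥ 1000 bins over the attainable score range; p-values exact
  on the lattice (tests assert equality to 1e-9 relative against
  enumeration).
* Fractions: classification on unrounded values; display truncated at two
  decimals.
* Tie-breaks: PPRE search prefers larger DR1 score, then larger 5'FR
  score, then smaller start, then `+` strand; TSS selection prefers the
  5'-most transcript; alignment takes the aligner's first co-optimal
  alignment, which is deterministic.
* Degenerate inputs: all-N promoters scan to empty; promoters shorter than
  the matrix width warn and return empty; promoters shorter than the 18-nt
  bipartite window are an error; zero-variance t-tests are handled as
  above; an empty response table yields a predictions-only concordance
  report.

## Calibration of the expression stage

At the default study conditions (n = 8 per arm, ΔCt noise 0.3 cycles,
3 technical replicates), 200 seeded replicates show: per-gene
false-positive rate on planted-null genes within the exact binomial 95%
band of α = 0.05; planted ±1.5 log2 fold changes recovered with absolute
bias below 0.1. One caveat worth stating precisely: recovering a full
8-gene up/down/unchanged profile *exactly* requires zero false positives
across all null genes, so with three null genes the expected exact-match
rate is bounded by 0.95³ ≈ 86% — a multiplicity fact inherent to per-gene
testing at α = 0.05, observed at 171/200 (85.5%) in the shipped
calibration test. Per-gene accuracy is the right headline figure; the
joint-profile rate is reported for transparency.

## Known limitations

* The PPRE rule is sequence-similarity only; no thermodynamics, no PWM
  affinity for the bipartite element, and no PPARβ selectivity.
* Background models above order 0 (dinucleotide composition) are not
  supported in the scanner.
* Promoter extraction assumes the annotation's TSS is correct; no
  CAGE-style TSS refinement.
* The ΔΔCt model fixes amplification efficiency at 2; standard-curve
  efficiency correction is out of scope.
* Multiple sequence alignment is not provided; protein similarity is
  strictly pairwise.
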