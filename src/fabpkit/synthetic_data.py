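"""Seeded generators for every input the pipeline consumes.

Two families of generators:

* sequence-side — i.i.d. background promoters/chromosomes at a chosen GC
  content with regulatory elements planted at recorded positions, strands
  and similarity-to-consensus fractions, plus toy gene models (GFF3) and
  consensus-derived count matrices;
* expression-side — Ct tables with planted per-gene log2 fold changes,
  Gaussian biological noise on dCt, and Gaussian technical-replicate noise.

Every generator is a pure function of its config, seed included; no global
random state is touched.  Truth tables accompany the sequence outputs so
downstream scanners/scorers can be checked against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fabpkit.ppre_score import ConsensusElement, fraction_similar
from fabpkit.promoter_io import GeneAnnotation

BASES = "ACGT"
PURINES, PYRIMIDINES = "AG", "CT"
_RC = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class PlantSpec:
    """One element to plant: either a literal ``element`` string, or a
    ``consensus`` to be degraded to ``target_fraction`` similarity."""

    gene_id: str
    element: str | None = None
    consensus: str | None = None
    target_fraction: float | None = None
    strand: str = "+"
    offset: int = 0

    def __post_init__(self) -> None:
        if (self.element is None) == (self.consensus is None):
            raise ValueError("give exactly one of element or consensus")
        if self.consensus is not None and self.target_fraction is None:
            raise ValueError("target_fraction required with a consensus")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class PromoterSimConfig:
    n_promoters: int
    length: int = 2000
    gc_content: float = 0.41  # typical avian promoter neighbourhood
    planted_elements: list[PlantSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        for spec in self.planted_elements:
            elen = len(spec.element or spec.consensus)
            if not 0 <= spec.offset <= self.length - elen:
                raise ValueError(
                    f"planted element for {spec.gene_id} at offset {spec.offset} "
                    f"does not fit in a {self.length}-nt promoter"
                )


def random_sequence(rng: np.random.Generator, length: int, gc_content: float = 0.5) -> str:
    probs = np.array([
        (1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2,
    ])
    return "".join(rng.choice(list(BASES), size=length, p=probs))


def mutate_to_fraction(
    consensus: str, target_fraction: float, rng: np.random.Generator
) -> tuple[str, float]:
    """Degrade a consensus to an exact similarity fraction under the per-base
    1 / 0.5 / 0 rule.

    A cross-class substitution removes 1/L from the fraction and a
    class-preserving substitution 0.5/L, so achievable fractions live on a
    0.5/L lattice; the target is snapped to the nearest lattice point (a
    rounded fraction like 0.73 for 9.5/13 is accepted).  ``N`` consensus
    positions score 1 against every base and are filled with a random base.
    Raises ``ValueError`` before emitting anything if the target is
    unreachable.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError(f"target_fraction must be in [0, 1], got {target_fraction}")
    L = len(consensus)
    deficit = round((L - target_fraction * L) * 2) / 2
    mutable = [i for i, c in enumerate(consensus) if c != "N"]
    n_full = int(deficit)
    n_half = int(round((deficit - n_full) * 2))
    if n_full + n_half > len(mutable):
        raise ValueError(
            f"target_fraction {target_fraction} unreachable: needs {n_full + n_half} "
            f"substitutions but only {len(mutable)} non-N positions"
        )
    positions = rng.permutation(mutable)[: n_full + n_half]
    seq = list(consensus)
    for i, pos in enumerate(positions):
        base = consensus[pos]
        same_class = PURINES if base in PURINES else PYRIMIDINES
        cross_class = PYRIMIDINES if base in PURINES else PURINES
        if i < n_full:
            seq[pos] = rng.choice(list(cross_class))
        else:
            seq[pos] = same_class.replace(base, "")
    for i, c in enumerate(seq):
        if c == "N":
            seq[i] = rng.choice(list(BASES))
    out = "".join(seq)
    _, achieved = fraction_similar(out, ConsensusElement("sim", consensus))
    if abs(achieved - (L - deficit) / L) > 1e-9:  # defensive; should not happen
        raise AssertionError(f"achieved {achieved}, wanted {(L - deficit) / L}")
    return out, achieved


def gen_promoters(cfg: PromoterSimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Synthetic promoters plus the truth table of planted elements.

    Returns (gene_id -> sequence, truth DataFrame with columns gene_id,
    element, start, strand, achieved_fraction).  Elements planted on '-' are
    written as the reverse complement of the element so that scanning the
    minus strand recovers them.
    """
    rng = np.random.default_rng(cfg.seed)
    planted_by_gene: dict[str, list[PlantSpec]] = {}
    for spec in cfg.planted_elements:
        planted_by_gene.setdefault(spec.gene_id, []).append(spec)

    promoters: dict[str, str] = {}
    truth_rows = []
    gene_ids = list(planted_by_gene)
    gene_ids += [f"bg_{i}" for i in range(len(gene_ids), cfg.n_promoters)]
    for gene_id in gene_ids[: max(cfg.n_promoters, len(planted_by_gene))]:
        seq = list(random_sequence(rng, cfg.length, cfg.gc_content))
        for spec in planted_by_gene.get(gene_id, []):
            if spec.element is not None:
                element, achieved = spec.element.upper(), None
            else:
                element, achieved = mutate_to_fraction(
                    spec.consensus.upper(), spec.target_fraction, rng
                )
            insert = element if spec.strand == "+" else element.translate(_RC)[::-1]
            seq[spec.offset : spec.offset + len(insert)] = insert
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "element": element,
                    "start": spec.offset,
                    "strand": spec.strand,
                    "achieved_fraction": achieved,
                }
            )
        promoters[gene_id] = "".join(seq)
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "element", "start", "strand", "achieved_fraction"]
    )
    return promoters, truth


def gen_genome(
    n_genes: int,
    chrom_length: int = 6000,
    promoter_length: int = 2000,
    gc_content: float = 0.41,
    seed: int = 0,
) -> tuple[dict[str, str], list[GeneAnnotation]]:
    """A toy multi-chromosome genome with one gene per chromosome,
    alternating strands, each with room for a full upstream promoter."""
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    annotations: list[GeneAnnotation] = []
    for i in range(n_genes):
        chrom = f"chr{i + 1}"
        genome[chrom] = random_sequence(rng, chrom_length, gc_content)
        strand = "+" if i % 2 == 0 else "-"
        # leave >= promoter_length upstream of the TSS on either strand
        tss = promoter_length + 1 if strand == "+" else chrom_length - promoter_length
        annotations.append(GeneAnnotation(f"gene{i + 1}", chrom, strand, tss))
    return genome, annotations


def annotations_to_gff(annotations: list[GeneAnnotation], gene_span: int = 1000) -> str:
    """Render annotations as GFF3 text (gene features of ``gene_span`` bases
    downstream of each TSS)."""
    lines = ["##gff-version 3"]
    for ann in annotations:
        if ann.strand == "+":
            start, end = ann.tss, ann.tss + gene_span - 1
        else:
            start, end = max(1, ann.tss - gene_span + 1), ann.tss
        lines.append(
            "\t".join(
                [ann.chrom, "fabpkit_sim", "gene", str(start), str(end), ".",
                 ann.strand, ".", f"ID={ann.gene_id}"]
            )
        )
    return "\n".join(lines) + "\n"


def consensus_to_counts(consensus: str, total: int = 100, minority: int = 1) -> np.ndarray:
    """A high-information width x 4 count matrix from a consensus string
    (``N`` -> uniform column), for synthetic JASPAR fixtures."""
    counts = np.full((len(consensus), 4), minority, dtype=float)
    for i, base in enumerate(consensus.upper()):
        if base == "N":
            counts[i] = total / 4
        else:
            counts[i, BASES.index(base)] = total - 3 * minority
    return counts


def counts_to_jaspar(matrix_id: str, name: str, counts: np.ndarray) -> str:
    """Render a count matrix as bracketed JASPAR text."""
    lines = [f">{matrix_id} {name}"]
    for b, base in enumerate(BASES):
        row = " ".join(f"{counts[i, b]:g}" for i in range(counts.shape[0]))
        lines.append(f"{base} [ {row} ]")
    return "\n".join(lines) + "\n"


@dataclass
class CtSimConfig:
    """Design of a simulated qPCR experiment.

    ``genes`` maps gene -> planted log2 fold change (treatment vs control);
    the realised treatment dCt is shifted by minus that amount.  ``noise_sd``
    is the biological between-sample dCt standard deviation in cycles and
    ``tech_sd`` the technical replicate standard deviation.
    """

    genes: dict[str, float]
    n_control: int = 8
    n_treatment: int = 8
    treatment_group: str = "treatment"
    control_group: str = "control"
    baseline_ct: float = 25.0
    reference_ct: float = 18.0
    reference_gene: str = "beta_actin"
    noise_sd: float = 0.3
    tech_sd: float = 0.1
    tech_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_treatment < 2:
            raise ValueError("need >= 2 samples per arm")
        if self.noise_sd < 0 or self.tech_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.tech_reps < 1:
            raise ValueError("tech_reps must be >= 1")


def gen_ct_table(cfg: CtSimConfig) -> pd.DataFrame:
    """Simulate a Ct table (sample_id, group, gene, ct), one row per
    technical replicate, reference-gene rows included for every sample.

    Control dCt ~ Normal(baseline_ct - reference_ct, noise_sd); treatment
    dCt is shifted by -(planted log2 fold change).  Technical replicates add
    Normal(0, tech_sd) to each measured Ct.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    arms = [(cfg.control_group, cfg.n_control, 0.0), (cfg.treatment_group, cfg.n_treatment, 1.0)]
    for group, n, treated in arms:
        for s in range(n):
            sample_id = f"{group}_{s + 1}"
            ref_ct = cfg.reference_ct
            for rep in range(cfg.tech_reps):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "gene": cfg.reference_gene,
                        "ct": ref_ct + rng.normal(0.0, cfg.tech_sd),
                    }
                )
            for gene, log2fc in cfg.genes.items():
                dct = rng.normal(cfg.baseline_ct - cfg.reference_ct, cfg.noise_sd)
                dct -= treated * log2fc
                gene_ct = ref_ct + dct
                for rep in range(cfg.tech_reps):
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "group": group,
                            "gene": gene,
                            "ct": gene_ct + rng.normal(0.0, cfg.tech_sd),
                        }
                    )
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])
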