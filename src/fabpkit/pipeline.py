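"""Orchestrate promoters -> motif scan -> PPRE scoring -> expression calls
-> concordance into one configured, logged run.

A run is driven by a :class:`RunConfig` (usually loaded from YAML).  Each
stage writes a TSV into the output directory and contributes counts to a
JSON summary that also records the package version and a hash of the
config, so two runs with identical config and seed produce identical
summaries.  Stages whose inputs are absent are skipped with a notice;
stages whose outputs already exist are skipped unless ``force`` is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from fabpkit import __version__
from fabpkit.expression import concordance, expression_calls, stage_profile
from fabpkit.motif_scan import hits_to_rows, read_jaspar, scan_promoter
from fabpkit.ppre_score import evaluate_elements, evaluations_to_rows, find_best_ppre
from fabpkit.promoter_io import (
    extract_promoter,
    read_fasta,
    read_gff_tss,
    read_promoter_fasta,
    write_fasta,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run.

    Sequence input is either (``genome_fasta`` + ``gff``) or a ready-made
    ``promoter_fasta``; ``elements_tsv`` (gene_id, fr5_seq, dr1_seq) scores
    fixed published elements instead of scanning promoters.  Expression
    input (``ct_table``) and the agonist ``response_table`` are optional —
    the corresponding stages are skipped when absent.
    """

    outdir: str = "fabpkit_run"
    genome_fasta: str | None = None
    gff: str | None = None
    promoter_fasta: str | None = None
    elements_tsv: str | None = None
    matrices: str | None = None
    ct_table: str | None = None
    response_table: str | None = None
    promoter_length: int = 2000
    p_threshold: float = 1e-4
    alpha: float = 0.05
    treatment_group: str = "treatment"
    control_group: str = "control"
    reference_gene: str = "beta_actin"
    seed: int = 0
    force: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("genome_fasta", "gff", "promoter_fasta", "elements_tsv",
                     "matrices", "ct_table", "response_table"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "force"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("promoters")
def stage_promoters(cfg: RunConfig, outdir: Path) -> list:
    out = outdir / "promoters.fasta"
    if cfg.promoter_fasta:
        promoters = read_promoter_fasta(cfg.promoter_fasta)
    elif cfg.genome_fasta and cfg.gff:
        genome = read_fasta(cfg.genome_fasta)
        annotations = read_gff_tss(cfg.gff)
        promoters = [extract_promoter(genome, ann, cfg.promoter_length) for ann in annotations]
    else:
        return []
    if cfg.force or not out.exists():
        write_fasta(promoters, out)
    return promoters


@_stage("scan")
def stage_scan(cfg: RunConfig, promoters: list, outdir: Path) -> pd.DataFrame:
    matrices = read_jaspar(cfg.matrices)
    rows = []
    for wm in matrices:
        for promoter in promoters:
            rows.extend(hits_to_rows(scan_promoter(wm, promoter, cfg.p_threshold), wm.width))
    hits = pd.DataFrame(
        rows,
        columns=["gene_id", "matrix_id", "start", "end", "strand", "site", "score_bits", "p_value"],
    )
    hits.to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
    return hits


@_stage("ppre")
def stage_ppre(cfg: RunConfig, promoters: list, outdir: Path) -> list:
    if cfg.elements_tsv:
        table = pd.read_csv(cfg.elements_tsv, sep="\t")
        evals = [
            evaluate_elements(row.gene_id, row.fr5_seq, row.dr1_seq)
            for row in table.itertuples()
        ]
    else:
        evals = [find_best_ppre(p) for p in promoters]
    pd.DataFrame(evaluations_to_rows(evals)).to_csv(outdir / "ppre.tsv", sep="\t", index=False)
    return evals


@_stage("qpcr")
def stage_qpcr(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    ct = pd.read_csv(cfg.ct_table, sep="\t")
    calls = expression_calls(
        ct,
        treatment=cfg.treatment_group,
        control=cfg.control_group,
        reference=cfg.reference_gene,
        alpha=cfg.alpha,
    )
    profile = stage_profile(calls)
    profile.to_csv(outdir / "expression_calls.tsv", sep="\t", index=False)
    return profile


@_stage("concordance")
def stage_concordance(cfg: RunConfig, evals: list, outdir: Path) -> pd.DataFrame:
    responses = pd.read_csv(cfg.response_table, sep="\t")
    report = concordance(evals, responses)
    report.table.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    return report.table


def run_all(cfg: RunConfig) -> dict:
    """Execute all configured stages in dependency order and write the JSON
    summary.  Returns the summary dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "fabpkit_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }

    promoters = stage_promoters(cfg, outdir)
    if promoters:
        summary["stages"]["promoters"] = {"n_promoters": len(promoters)}
    else:
        logger.info("no sequence input configured; promoter stage skipped")

    if cfg.matrices and promoters:
        hits = stage_scan(cfg, promoters, outdir)
        summary["stages"]["scan"] = {
            "n_hits": int(len(hits)),
            "by_matrix": {k: int(v) for k, v in hits.groupby("matrix_id").size().items()},
        }
    elif cfg.matrices:
        logger.info("matrices configured but no promoters; scan stage skipped")

    evals = []
    if cfg.elements_tsv or promoters:
        evals = stage_ppre(cfg, promoters, outdir)
        by_sel: dict[str, int] = {}
        for ev in evals:
            by_sel[ev.selectivity] = by_sel.get(ev.selectivity, 0) + 1
        summary["stages"]["ppre"] = {
            "n_evaluated": len(evals),
            "n_ppre": sum(ev.is_ppre for ev in evals),
            "by_selectivity": by_sel,
        }

    if cfg.ct_table:
        profile = stage_qpcr(cfg, outdir)
        summary["stages"]["qpcr"] = {
            "n_genes": int(len(profile)),
            "calls": {k: int(v) for k, v in profile.groupby("call").size().items()},
        }
    else:
        logger.info("no Ct table configured; expression stage skipped")

    if cfg.response_table and evals:
        table = stage_concordance(cfg, evals, outdir)
        judged = table["concordant"].dropna()
        summary["stages"]["concordance"] = {
            "n_genes": int(len(table)),
            "n_concordant": int(judged.sum()),
            "n_discordant": int((~judged.astype(bool)).sum()),
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
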