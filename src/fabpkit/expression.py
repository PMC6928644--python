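"""qPCR relative quantification (2^-ddCt), significance calls, and the
concordance of motif predictions with agonist responses.

The Livak comparative-threshold-cycle method: per sample,
dCt = Ct(target) - Ct(reference gene); per contrast,
ddCt = mean(dCt, treatment) - mean(dCt, control); the relative expression is
2^-ddCt (amplification efficiency fixed at 2 per cycle).  Significance is a
two-sided two-sample t-test on the per-sample dCt values (Student's pooled-
variance test by default, Welch by flag).  A gene is called ``up`` when
p < alpha and the fold change exceeds 1, ``down`` when p < alpha and the
fold change is below 1, otherwise ``unchanged``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CT_COLUMNS = ["sample_id", "group", "gene", "ct"]
DEFAULT_REFERENCE = "beta_actin"
UP, DOWN, UNCHANGED = "up", "down", "unchanged"


@dataclass(frozen=True)
class ExpressionCall:
    """Per-gene ddCt result for one treatment-vs-control contrast."""

    gene: str
    group_vs_control: str
    delta_delta_ct: float
    fold_change: float
    p_value: float
    call: str
    n_treatment: int
    n_control: int


def _validate_ct(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s) {missing}; need {CT_COLUMNS}")
    if not np.isfinite(ct["ct"]).all():
        raise ValueError("Ct values must be finite")
    return ct


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct TSV (sample_id, group, gene, ct; one row per technical
    replicate)."""
    return _validate_ct(pd.read_csv(path, sep="\t"))


def collapse_technical(ct: pd.DataFrame, spread_warn: float = 1.0) -> pd.DataFrame:
    """Average technical replicates to one Ct per (sample, gene).

    Logs a warning naming any (sample, gene) whose replicate spread
    (max - min) exceeds ``spread_warn`` cycles.
    """
    ct = _validate_ct(ct)
    grouped = ct.groupby(["sample_id", "group", "gene"], sort=False)["ct"]
    spread = grouped.agg(lambda x: x.max() - x.min())
    for (sample, _group, gene), value in spread.items():
        if value > spread_warn:
            logger.warning(
                "technical replicate spread %.2f cycles for sample %s, gene %s "
                "exceeds %.1f", value, sample, gene, spread_warn,
            )
    collapsed = grouped.mean().reset_index()
    n_reps = int(len(ct) / max(len(collapsed), 1))
    logger.info("collapsed %d rows to %d (~%d technical replicates)", len(ct), len(collapsed), n_reps)
    return collapsed


def delta_ct(ct: pd.DataFrame, gene: str, reference: str = DEFAULT_REFERENCE) -> pd.DataFrame:
    """Per-sample dCt = Ct(gene) - Ct(reference).

    Input must already be collapsed to one Ct per (sample, gene).  Samples
    lacking a reference measurement are dropped with a warning.  Returns a
    DataFrame (sample_id, group, delta_ct).
    """
    ct = _validate_ct(ct)
    target = ct[ct["gene"] == gene].set_index("sample_id")
    ref = ct[ct["gene"] == reference].set_index("sample_id")["ct"]
    if target.empty:
        raise ValueError(f"gene {gene!r} not present in Ct table")
    missing = target.index.difference(ref.index)
    if len(missing):
        logger.warning(
            "%d sample(s) lack a %s reference measurement and were dropped: %s",
            len(missing), reference, ", ".join(map(str, missing)),
        )
        target = target.drop(index=missing)
    out = target.reset_index()[["sample_id", "group"]]
    out["delta_ct"] = (target["ct"] - ref.reindex(target.index)).to_numpy()
    return out


def fold_change_call(
    treat_dct: np.ndarray,
    control_dct: np.ndarray,
    alpha: float = 0.05,
    equal_var: bool = True,
    gene: str = "",
    group_vs_control: str = "",
) -> ExpressionCall:
    """ddCt fold change and up/down/unchanged call for one contrast.

    ddCt = mean(treatment dCt) - mean(control dCt); fold = 2^-ddCt.  The
    p-value is a two-sided two-sample t-test on the dCt values.  When both
    arms have zero variance the t-test is degenerate: p is 1 for equal
    means, 0 otherwise.
    """
    treat = np.asarray(treat_dct, dtype=float)
    control = np.asarray(control_dct, dtype=float)
    if len(treat) < 2 or len(control) < 2:
        raise ValueError("need >= 2 samples per arm for a t-test")
    ddct = float(treat.mean() - control.mean())
    fold = float(2.0 ** (-ddct))
    if treat.std(ddof=1) == 0.0 and control.std(ddof=1) == 0.0:
        p_value = 1.0 if treat.mean() == control.mean() else 0.0
    else:
        p_value = float(stats.ttest_ind(treat, control, equal_var=equal_var).pvalue)
    if p_value < alpha:
        call = UP if fold > 1.0 else DOWN if fold < 1.0 else UNCHANGED
    else:
        call = UNCHANGED
    return ExpressionCall(gene, group_vs_control, ddct, fold, p_value, call, len(treat), len(control))


def expression_calls(
    ct: pd.DataFrame,
    treatment: str,
    control: str,
    genes: list[str] | None = None,
    reference: str = DEFAULT_REFERENCE,
    alpha: float = 0.05,
    equal_var: bool = True,
    collapse: bool = True,
    p_adjust: str = "none",
) -> list[ExpressionCall]:
    """Full per-gene ddCt analysis of a Ct table for one treatment-vs-control
    contrast.

    ``p_adjust="bh"`` applies Benjamini-Hochberg correction across the genes
    before calling significance (off by default, matching per-gene p < alpha
    reporting).
    """
    if p_adjust not in ("none", "bh"):
        raise ValueError(f"p_adjust must be 'none' or 'bh', got {p_adjust!r}")
    ct = _validate_ct(ct)
    if collapse:
        ct = collapse_technical(ct)
    if genes is None:
        genes = [g for g in ct["gene"].unique() if g != reference]
    calls = []
    for gene in genes:
        dct = delta_ct(ct, gene, reference)
        treat = dct.loc[dct["group"] == treatment, "delta_ct"].to_numpy()
        ctrl = dct.loc[dct["group"] == control, "delta_ct"].to_numpy()
        calls.append(
            fold_change_call(
                treat, ctrl, alpha=alpha, equal_var=equal_var,
                gene=gene, group_vs_control=f"{treatment}_vs_{control}",
            )
        )
    if p_adjust == "bh" and calls:
        adjusted = stats.false_discovery_control([c.p_value for c in calls], method="bh")
        calls = [
            replace(
                c,
                p_value=float(q),
                call=(UP if c.fold_change > 1.0 else DOWN) if q < alpha and c.fold_change != 1.0 else UNCHANGED,
            )
            for c, q in zip(calls, adjusted)
        ]
    return calls


def stage_profile(calls: list[ExpressionCall], genes: list[str] | None = None) -> pd.DataFrame:
    """Tabulate the up/down/unchanged pattern across genes (one call per
    gene)."""
    by_gene = {c.gene: c for c in calls}
    if len(by_gene) != len(calls):
        raise ValueError("stage_profile expects one call per gene")
    order = genes if genes is not None else list(by_gene)
    rows = [
        {
            "gene": g,
            "call": by_gene[g].call,
            "fold_change": by_gene[g].fold_change,
            "p_value": by_gene[g].p_value,
        }
        for g in order
        if g in by_gene
    ]
    return pd.DataFrame(rows, columns=["gene", "call", "fold_change", "p_value"])


#: Selectivity label -> the agonist class expected to drive a response.
SELECTIVITY_TO_AGONIST = {"alpha": "PPARa", "gamma": "PPARg"}


@dataclass
class ConcordanceReport:
    """Join of PPRE selectivity predictions with observed agonist responses."""

    table: pd.DataFrame
    missing_predictions: list[str]
    missing_responses: list[str]


def concordance(ppre_evaluations, responses: pd.DataFrame) -> ConcordanceReport:
    """Per-gene agreement between predicted PPAR selectivity and agonist
    responses.

    ``responses`` needs columns (gene, agonist, call) and may carry a
    concentration column.  A gene is *concordant* when its predicted isoform
    (alpha -> PPARa, gamma -> PPARg) is among the agonists with a
    non-unchanged response; a prediction with no response at all, or a
    response not matching the predicted isoform, is discordant.  Genes
    present on only one side are listed separately, not judged.
    """
    needed = {"gene", "agonist", "call"}
    if not responses.empty and not needed.issubset(responses.columns):
        raise ValueError(f"response table needs columns {sorted(needed)}")
    predictions = {ev.gene_id: ev for ev in ppre_evaluations}
    response_genes = set(responses["gene"]) if not responses.empty else set()

    rows = []
    for gene, ev in predictions.items():
        gene_resp = (
            responses[responses["gene"] == gene] if gene in response_genes else pd.DataFrame(columns=list(needed))
        )
        responding = sorted(set(gene_resp.loc[gene_resp["call"] != UNCHANGED, "agonist"]))
        expected = SELECTIVITY_TO_AGONIST.get(ev.selectivity)
        if gene not in response_genes:
            concordant = None
        elif not ev.is_ppre:
            concordant = len(responding) == 0
        else:
            concordant = expected in responding
        rows.append(
            {
                "gene": gene,
                "selectivity": ev.selectivity,
                "is_ppre": ev.is_ppre,
                "expected_agonist": expected,
                "responding_agonists": ",".join(responding),
                "concordant": concordant,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene", "selectivity", "is_ppre", "expected_agonist", "responding_agonists", "concordant"],
    )
    return ConcordanceReport(
        table=table,
        missing_predictions=sorted(response_genes - set(predictions)),
        missing_responses=sorted(set(predictions) - response_genes),
    )
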