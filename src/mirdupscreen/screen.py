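"""The candidate-gene funnel.

Starting from an up-regulated miRNA duplex, the screen intersects each arm's
predicted seed-site targets with the genes down-regulated in tumors
(log2FC strictly below -2.0 by default) to build the candidate table, then
applies two survival filters gene by gene on the tumor cohort:

1. Kaplan-Meier filter — median split of the gene's expression, follow-up
   truncated at the horizon (60 months = 5 years), log-rank p < alpha AND
   the low-expression arm must be the one with worse survival;
2. Cox filter — a multivariate proportional-hazards model per gene
   (expression group + stage + grade + age); the gene survives if the
   expression term's Wald p < alpha, i.e. it is an independent prognostic
   factor.

Genes targeted by both arms appear in both candidate partitions; the
screen applies no multiple-testing correction by default (raw p < 0.05),
with an optional Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CandidateGene, CandidateTable, ClinicalTable
from .seed_sites import TargetPrediction
from .signature import FoldChangeTable
from .survival_stats import (
    CoxResult,
    cox_fit,
    km_estimate,
    logrank_test,
    median_split,
    truncate_follow_up,
)

logger = logging.getLogger("mirdupscreen")

DOWN_THRESHOLD_DEFAULT = -2.0
ALPHA_DEFAULT = 0.05
HORIZON_DEFAULT = 60.0  # months: 5-year analysis


def downregulated_genes(
    fc: FoldChangeTable, threshold: float = DOWN_THRESHOLD_DEFAULT
) -> set[str]:
    """Genes with log2 fold change strictly below ``threshold``."""
    frame = fc.frame
    return set(frame.index[frame["log2fc"] < threshold])


def build_candidate_table(
    pred5p: TargetPrediction,
    pred3p: TargetPrediction,
    down: set[str],
    fc: FoldChangeTable,
    gene_names: Mapping[str, str] | None = None,
    entrez_ids: Mapping[str, int] | None = None,
) -> CandidateTable:
    """Intersect per-arm predicted targets with the down-regulated set.

    A gene targeted by both arms appears in BOTH partitions, carrying the
    arm-specific site count; every candidate must have a fold change.
    """
    gene_names = gene_names or {}
    entrez_ids = entrez_ids or {}
    rows: list[CandidateGene] = []
    for arm, pred in (("5p", pred5p), ("3p", pred3p)):
        for gene in sorted(pred.genes & down):
            if gene not in fc.frame.index:
                raise ValueError(f"candidate gene {gene!r} missing from fold-change table")
            rows.append(
                CandidateGene(
                    entrez_id=entrez_ids.get(gene),
                    symbol=gene,
                    name=gene_names.get(gene, ""),
                    log2fc=fc.log2fc(gene),
                    total_sites=pred.total_sites(gene),
                    arm=arm,
                )
            )
    return CandidateTable(rows)


def _endpoint_columns(endpoint: str) -> tuple[str, str]:
    if endpoint.lower() == "os":
        return "time", "event"
    if endpoint.lower() == "dfs":
        return "dfs_time", "dfs_event"
    raise ValueError(f"endpoint must be 'os' or 'dfs', got {endpoint!r}")


def km_screen(
    candidates: CandidateTable | Sequence[str],
    clinical: ClinicalTable,
    alpha: float = ALPHA_DEFAULT,
    horizon: float = HORIZON_DEFAULT,
    endpoint: str = "os",
    bh_correct: bool = False,
) -> dict[str, float]:
    """Kaplan-Meier median-split filter.

    Returns {gene: log-rank p} for genes where the LOW-expression group has
    the worse Kaplan-Meier estimate at the horizon and p < alpha. A cohort
    with zero events yields p = 1 for every gene (nothing retained).
    """
    genes = candidates.symbols() if isinstance(candidates, CandidateTable) else list(candidates)
    time_col, event_col = _endpoint_columns(endpoint)
    if time_col not in clinical.data.columns:
        raise ValueError(f"clinical table has no {time_col!r} column for endpoint {endpoint!r}")
    times, events = truncate_follow_up(
        clinical.data[time_col].to_numpy(float),
        clinical.data[event_col].to_numpy(int),
        horizon,
    )
    missing = [g for g in genes if g not in clinical.expression_columns]
    if missing:
        raise ValueError(f"genes without expression columns: {missing}")

    pvals: dict[str, float] = {}
    worse_low: dict[str, bool] = {}
    for gene in genes:
        labels = median_split(clinical.expression(gene))
        low = labels == "low"
        if events.sum() == 0:
            pvals[gene] = 1.0
            worse_low[gene] = False
            continue
        _, p = logrank_test((times[low], events[low]), (times[~low], events[~low]))
        s_low = km_estimate(times[low], events[low]).survival_at(horizon)
        s_high = km_estimate(times[~low], events[~low]).survival_at(horizon)
        pvals[gene] = p
        worse_low[gene] = s_low < s_high
    padj = _bh_adjust(pvals) if bh_correct else pvals
    return {g: pvals[g] for g in genes if padj[g] < alpha and worse_low[g]}


def cox_screen(
    km_survivors: Iterable[str],
    clinical: ClinicalTable,
    alpha: float = ALPHA_DEFAULT,
    horizon: float = HORIZON_DEFAULT,
    endpoint: str = "os",
    adjust_for: Sequence[str] = ("stage", "grade", "age"),
    bh_correct: bool = False,
) -> dict[str, CoxResult]:
    """Multivariate Cox filter: one model per gene.

    The model is expression group (low = 1 vs high = 0, median split) plus
    the adjustment covariates; a gene is retained iff the expression term's
    Wald p < alpha.
    """
    time_col, event_col = _endpoint_columns(endpoint)
    results: dict[str, CoxResult] = {}
    pvals: dict[str, float] = {}
    times, events = truncate_follow_up(
        clinical.data[time_col].to_numpy(float),
        clinical.data[event_col].to_numpy(int),
        horizon,
    )
    for gene in km_survivors:
        labels = median_split(clinical.expression(gene))
        df = pd.DataFrame(
            {
                "time": times,
                "event": events,
                "expression_low": (labels == "low").astype(float),
            }
        )
        for cov in adjust_for:
            df[cov] = clinical.data[cov].to_numpy(float)
        res = cox_fit(df, ["expression_low", *adjust_for])
        results[gene] = res
        pvals[gene] = res["expression_low"]["p"]
    padj = _bh_adjust(pvals) if bh_correct else pvals
    return {g: results[g] for g in results if padj[g] < alpha}


def _bh_adjust(pvals: Mapping[str, float]) -> dict[str, float]:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    genes = list(pvals)
    p = np.array([pvals[g] for g in genes], dtype=float)
    m = p.size
    if m == 0:
        return {}
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return dict(zip(genes, adj))


@dataclass
class ScreenReport:
    """Stage-by-stage record of one screen run (the funnel)."""

    up_mirnas: list[str]
    duplex_precursors: list[str]
    n_predicted_per_arm: dict[str, int]
    n_downregulated: int
    candidates: CandidateTable
    km_survivors: dict[str, float]
    cox_survivors: dict[str, CoxResult]
    final_genes: list[str]
    params: dict = field(default_factory=dict)

    def funnel_counts(self) -> dict[str, int]:
        return {
            "n_upregulated_mirnas": len(self.up_mirnas),
            "n_duplex_precursors": len(self.duplex_precursors),
            "n_predicted_5p": self.n_predicted_per_arm.get("5p", 0),
            "n_predicted_3p": self.n_predicted_per_arm.get("3p", 0),
            "n_downregulated": self.n_downregulated,
            "n_candidates_5p": len(self.candidates.partition("5p")),
            "n_candidates_3p": len(self.candidates.partition("3p")),
            "n_km_survivors": len(self.km_survivors),
            "n_final": len(self.final_genes),
        }

    def to_tables(self) -> dict[str, pd.DataFrame]:
        from .survival_stats import forest_summary

        cand = pd.DataFrame(
            [
                {
                    "arm": r.arm,
                    "symbol": r.symbol,
                    "log2fc": r.log2fc,
                    "total_sites": r.total_sites,
                }
                for r in self.candidates.rows
            ],
            columns=["arm", "symbol", "log2fc", "total_sites"],
        )
        km = pd.DataFrame(
            sorted(self.km_survivors.items()), columns=["gene", "logrank_p"]
        )
        forest = forest_summary(self.cox_survivors)
        final = pd.DataFrame({"gene": self.final_genes})
        funnel = pd.DataFrame(
            list(self.funnel_counts().items()), columns=["stage", "count"]
        )
        return {
            "candidates": cand,
            "km_survivors": km,
            "cox_forest": forest,
            "final_genes": final,
            "funnel": funnel,
        }


def screen_pipeline(
    counts,
    mirna_5p,
    mirna_3p,
    utrs,
    expression: pd.DataFrame,
    clinical: ClinicalTable,
    up_threshold: float = 1.5,
    down_threshold: float = DOWN_THRESHOLD_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    horizon: float = HORIZON_DEFAULT,
    endpoint: str = "os",
    pseudocount: float = 0.5,
    bh_correct: bool = False,
) -> ScreenReport:
    """Run the whole funnel on in-memory inputs.

    ``counts`` is the miRNA :class:`CountMatrix`; ``mirna_5p``/``mirna_3p``
    are :class:`MatureMiRNA` with sequences; ``utrs`` the 3'-UTR records;
    ``expression`` a genes x samples linear-scale matrix sharing the count
    matrix's sample ids; ``clinical`` the tumor cohort with per-gene
    expression columns.
    """
    from .seed_sites import predict_targets
    from .signature import (
        detect_duplex_upregulated,
        log2_fold_change,
        normalize_cpm,
        select_upregulated,
    )

    cpm = normalize_cpm(counts)
    mirna_fc = log2_fold_change(cpm, counts.group_of, pseudocount)
    up = select_upregulated(mirna_fc, up_threshold)
    duplexes = detect_duplex_upregulated(up)
    logger.info("signature: %d up-regulated miRNAs, %d duplex precursors", len(up), len(duplexes))

    pred5p = predict_targets(utrs, mirna_5p)
    pred3p = predict_targets(utrs, mirna_3p)

    gene_fc = log2_fold_change(expression, counts.group_of, pseudocount)
    down = downregulated_genes(gene_fc, down_threshold)
    candidates = build_candidate_table(pred5p, pred3p, down, gene_fc)
    logger.info(
        "funnel: %d/%d predicted (5p/3p), %d down-regulated, %d/%d candidates (5p/3p)",
        len(pred5p), len(pred3p), len(down),
        len(candidates.partition("5p")), len(candidates.partition("3p")),
    )

    km = km_screen(candidates, clinical, alpha, horizon, endpoint, bh_correct)
    cox = cox_screen(sorted(km), clinical, alpha, horizon, endpoint, bh_correct=bh_correct)
    final = sorted(cox)
    logger.info("survival: %d KM survivors, %d final genes", len(km), len(final))

    report = ScreenReport(
        up_mirnas=up,
        duplex_precursors=duplexes,
        n_predicted_per_arm={"5p": len(pred5p), "3p": len(pred3p)},
        n_downregulated=len(down),
        candidates=candidates,
        km_survivors=km,
        cox_survivors=cox,
        final_genes=final,
        params={
            "up_threshold": up_threshold,
            "down_threshold": down_threshold,
            "alpha": alpha,
            "horizon": horizon,
            "endpoint": endpoint,
            "pseudocount": pseudocount,
            "bh_correct": bh_correct,
        },
    )
    # funnel monotonicity is a structural guarantee; verify on every run
    assert len(report.final_genes) <= len(report.km_survivors)
    assert set(report.final_genes) <= set(report.km_survivors)
    assert set(report.km_survivors) <= set(report.candidates.symbols())
    assert set(report.candidates.symbols()) <= (pred5p.genes | pred3p.genes)
    return report


def run_screen(
    counts_path,
    annotation_path,
    mirna_fasta,
    mirna_5p_name: str,
    mirna_3p_name: str,
    utr_fasta,
    expression_path,
    clinical_path,
    out_dir,
    **kwargs,
) -> ScreenReport:
    """Path-based wrapper: read inputs, run the funnel, write the report."""
    from .io_formats import read_clinical_table, read_count_matrix, read_fasta, write_results
    from .signature import MatureMiRNA

    counts = read_count_matrix(counts_path, annotation_path)
    matures = {r.id: r for r in read_fasta(mirna_fasta)}
    for name in (mirna_5p_name, mirna_3p_name):
        if name not in matures:
            raise ValueError(f"mature miRNA {name!r} not in {mirna_fasta}")
    mirna_5p = MatureMiRNA.from_name(mirna_5p_name, matures[mirna_5p_name])
    mirna_3p = MatureMiRNA.from_name(mirna_3p_name, matures[mirna_3p_name])
    utrs = read_fasta(utr_fasta)
    expression = pd.read_csv(expression_path, sep="\t", comment="#", index_col=0)
    clinical = read_clinical_table(clinical_path)
    report = screen_pipeline(counts, mirna_5p, mirna_3p, utrs, expression, clinical, **kwargs)
    write_results(report.to_tables(), out_dir)
    return report
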