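"""Tumor mutation burden, frequently mutated gene selection, mutation-PBM
association and mutation-stratified survival.

TMB is the per-sample count of nonsynonymous somatic events; the
nonsynonymous vocabulary follows the standard MAF convention.  The gene
universe for "frequently mutated" selection is restricted to a
user-supplied whitelist (e.g. a COSMIC Cancer gene list), with a minimum
carrier count and a top-N truncation.  Mutation-stratified survival splits
the PBM score at the global cohort median, not per stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ClinicalTable, MutationTable
from .stats import GroupComparisonResult, bh_adjust, wilcoxon_rank_sum
from .survival import cox_fit, km_logrank, median_split

logger = logging.getLogger(__name__)

#: MAF variant classifications counted as nonsynonymous.
NONSYNONYMOUS = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

#: Recognised synonymous / non-coding classifications (excluded from TMB
#: silently; anything outside both sets is "unknown").
SYNONYMOUS_OR_NONCODING = frozenset(
    {
        "Silent",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Intron",
        "IGR",
        "RNA",
        "Targeted_Region",
    }
)


@dataclass(frozen=True)
class MutationSummary:
    tmb: pd.Series  # per sample, integer count of nonsynonymous events
    carriers: dict  # gene -> frozenset of carrier sample ids

    def carrier_count(self, gene: str) -> int:
        return len(self.carriers.get(gene, ()))


def compute_tmb(mutations: MutationTable, samples, strict: bool = False) -> pd.Series:
    """Per-sample count of nonsynonymous mutation records.

    Samples with no records get 0.  Records with a classification outside
    the declared vocabulary are excluded with a log message (``strict=True``
    raises instead).
    """
    df = mutations.data
    known = NONSYNONYMOUS | SYNONYMOUS_OR_NONCODING
    unknown = set(df["variant_classification"]) - known
    if unknown:
        if strict:
            raise ValueError(f"unknown variant classifications: {sorted(unknown)}")
        logger.warning(
            "excluding %d records with unknown classifications: %s",
            int(df["variant_classification"].isin(unknown).sum()),
            sorted(unknown),
        )
    nonsyn = df[df["variant_classification"].isin(NONSYNONYMOUS)]
    counts = nonsyn.groupby("sample_id").size()
    return counts.reindex(list(samples), fill_value=0).astype(int).rename("tmb")


def summarize_mutations(
    mutations: MutationTable, samples, strict: bool = False
) -> MutationSummary:
    """TMB plus per-gene carrier sets (nonsynonymous events only)."""
    tmb = compute_tmb(mutations, samples, strict=strict)
    df = mutations.data
    nonsyn = df[df["variant_classification"].isin(NONSYNONYMOUS)]
    sample_set = set(samples)
    carriers = {
        gene: frozenset(set(sub["sample_id"]) & sample_set)
        for gene, sub in nonsyn.groupby("gene")
    }
    return MutationSummary(tmb=tmb, carriers=carriers)


def tmb_pbm_association(tmb: pd.Series, pbm: pd.Series) -> GroupComparisonResult:
    """Median-split the cohort on TMB (ties to low) and compare PBM scores
    between TMB-high and TMB-low with a Wilcoxon rank-sum test."""
    if not tmb.index.equals(pbm.index):
        if set(tmb.index) != set(pbm.index):
            raise ValueError("TMB and PBM sample ids do not match")
        pbm = pbm.loc[tmb.index]
    groups = median_split(tmb.astype(float))
    high = pbm[groups == "high"].to_numpy()
    low = pbm[groups == "low"].to_numpy()
    if len(high) < 2 or len(low) < 2:
        raise ValueError("degenerate TMB split (< 2 samples on a side)")
    return wilcoxon_rank_sum(high, low, mode="approx")


def select_frequent_genes(
    summary: MutationSummary,
    gene_whitelist,
    min_carriers: int = 30,
    top_n: int = 10,
) -> list[str]:
    """Whitelisted genes with >= ``min_carriers`` carriers, sorted by
    descending carrier count (name on ties), truncated to ``top_n``."""
    whitelist = set(gene_whitelist)
    if not whitelist:
        raise ValueError("gene whitelist is empty")
    eligible = [
        (gene, summary.carrier_count(gene))
        for gene in whitelist
        if summary.carrier_count(gene) >= min_carriers
    ]
    eligible.sort(key=lambda gc: (-gc[1], gc[0]))
    return [g for g, _ in eligible[:top_n]]


def mutation_pbm_association(
    summary: MutationSummary, pbm: pd.Series, genes
) -> pd.DataFrame:
    """Wilcoxon carrier-versus-wild-type PBM comparison per gene with BH
    adjustment across the tested genes.

    Genes with fewer than 2 carriers or 2 wild-type samples are skipped
    with a log message.  Columns: n_carriers, n_wildtype, statistic, p,
    direction, p_adj.
    """
    rows = []
    for gene in genes:
        carriers = summary.carriers.get(gene, frozenset())
        carrier_ids = [s for s in pbm.index if s in carriers]
        wt_ids = [s for s in pbm.index if s not in carriers]
        if len(carrier_ids) < 2 or len(wt_ids) < 2:
            logger.warning("gene %s skipped (carriers=%d)", gene, len(carrier_ids))
            continue
        res = wilcoxon_rank_sum(
            pbm.loc[carrier_ids].to_numpy(), pbm.loc[wt_ids].to_numpy(), mode="approx"
        )
        rows.append(
            {
                "gene": gene,
                "n_carriers": len(carrier_ids),
                "n_wildtype": len(wt_ids),
                "statistic": res.statistic,
                "p": res.p_value,
                "direction": res.direction,
            }
        )
    out = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["n_carriers", "n_wildtype", "statistic", "p", "direction"]
    )
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def stratified_survival(
    summary: MutationSummary,
    pbm: pd.Series,
    clinical: ClinicalTable,
    gene: str,
    time_col: str = "os_time",
    event_col: str = "os_event",
) -> dict:
    """PBM-high/low survival within mutation strata of one gene.

    The high/low split uses the GLOBAL median PBM of all patients; within
    each stratum (carrier; wild-type) a Kaplan-Meier/log-rank comparison
    and a Cox hazard ratio for the high group are reported.  Empty strata
    are omitted with a log message.
    """
    aligned = clinical.data.loc[pbm.index]
    groups = median_split(pbm)
    carriers = summary.carriers.get(gene, frozenset())
    is_carrier = pd.Series([s in carriers for s in pbm.index], index=pbm.index)
    report: dict = {"gene": gene, "global_median_pbm": float(np.median(pbm))}
    for name, mask in (("mutated", is_carrier), ("wild_type", ~is_carrier)):
        sub = aligned[mask]
        if len(sub) == 0 or sub[event_col].sum() == 0:
            logger.warning("stratum %s for %s omitted (no samples or events)", name, gene)
            continue
        g = groups[mask]
        if g.nunique() < 2:
            logger.warning("stratum %s for %s omitted (single PBM group)", name, gene)
            continue
        km = km_logrank(sub[time_col].to_numpy(), sub[event_col].to_numpy(), g.to_numpy())
        cox = cox_fit(
            sub[time_col].to_numpy(),
            sub[event_col].to_numpy(),
            pd.DataFrame({"pbm_high": (g == "high").astype(float).to_numpy()}),
        )
        report[name] = {
            "n": int(len(sub)),
            "logrank_chi_square": km.chi_square,
            "logrank_p": km.p_value,
            "hr_high_vs_low": cox.hr("pbm_high") if cox.converged else np.nan,
            "cox_converged": cox.converged,
        }
    return report
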