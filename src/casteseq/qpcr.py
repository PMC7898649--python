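"""qRT-PCR analysis: plate calibration, reference-gene stability, relative
quantification and caste comparisons.

Cq values arrive as a long table (plate_id, well, gene_id, sample_id, Cq,
is_IPC).  An inter-plate calibrator (IPC) on every plate removes between-
plate offsets.  Candidate reference genes are ranked by the geNorm
stability measure M (mean standard deviation of pairwise log2 expression
ratios with the other candidates, with iterative exclusion of the least
stable gene) alongside the BestKeeper per-gene Cq standard deviation.
Targets are quantified relative to the geometric mean of the chosen
references with per-gene amplification efficiencies, and caste differences
within a stage are tested with exact Mann-Whitney U tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .overlap import CongruenceRecord

#: geNorm pairwise-variation cutoff below which adding a reference gene
#: is considered unnecessary.
V_THRESHOLD = 0.15
DEFAULT_EFFICIENCY = 2.0
SIG_LEVEL = 0.05

PLATE_COLUMNS = ["plate_id", "well", "gene_id", "sample_id", "Cq", "is_IPC"]


def calibrate_plates(plates: pd.DataFrame) -> pd.DataFrame:
    """Remove between-plate offsets using the inter-plate calibrator wells.

    Each plate's mean IPC Cq is compared with the grand mean of IPC Cq
    across plates, and the difference is subtracted from every well on the
    plate.  Within-plate Cq differences are preserved exactly; after
    calibration the per-plate IPC means coincide.  A single plate is
    returned unchanged.  A plate without an IPC well is an error.
    """
    missing = [c for c in PLATE_COLUMNS if c not in plates.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    ipc = plates[plates["is_IPC"].astype(bool)]
    plate_ids = plates["plate_id"].unique()
    no_ipc = [p for p in plate_ids if p not in set(ipc["plate_id"])]
    if no_ipc:
        raise ValueError(f"plates without an inter-plate calibrator: {no_ipc}")
    if len(plate_ids) == 1:
        return plates.copy()
    ipc_mean = ipc.groupby("plate_id")["Cq"].mean()
    shift = ipc_mean - ipc_mean.mean()
    out = plates.copy()
    out["Cq"] = out["Cq"] - out["plate_id"].map(shift)
    return out


def _cq_wide(calibrated: pd.DataFrame) -> pd.DataFrame:
    """Genes x samples Cq table (IPC wells excluded, replicate wells averaged)."""
    sub = calibrated[~calibrated["is_IPC"].astype(bool)]
    return sub.pivot_table(index="gene_id", columns="sample_id", values="Cq", aggfunc="mean")


def relative_quantities(
    cq: pd.DataFrame, efficiencies: dict[str, float] | None = None
) -> pd.DataFrame:
    """Efficiency-corrected relative quantities RQ(g, s) = E_g^(mean_s Cq_g - Cq_g,s).

    The calibrator is the per-gene mean Cq over all samples, so RQ is
    invariant to adding a constant to all of one gene's Cq values.
    """
    efficiencies = efficiencies or {}
    e = np.array([float(efficiencies.get(g, DEFAULT_EFFICIENCY)) for g in cq.index])
    if (e <= 1.0).any() or (e > 2.2).any():
        raise ValueError("amplification efficiencies must lie in (1, 2.2]")
    delta = cq.mean(axis=1).to_numpy()[:, None] - cq.to_numpy()
    rq = np.power(e[:, None], delta)
    return pd.DataFrame(rq, index=cq.index, columns=cq.columns)


# -- reference-gene stability --------------------------------------------------


@dataclass
class StabilityReport:
    m_values: dict[str, float]
    exclusion_order: list[str]  # least stable first
    pairwise_variation: dict[str, float]  # "V2/3" -> value
    bestkeeper_sd: dict[str, float]
    recommended_references: list[str]


def _genorm_m(log_rq: pd.DataFrame) -> pd.Series:
    """geNorm M per gene: mean SD of pairwise log2 ratios with other genes."""
    genes = list(log_rq.index)
    vals = log_rq.to_numpy()
    m = {}
    for i, g in enumerate(genes):
        sds = [
            np.std(vals[i] - vals[j], ddof=1)
            for j in range(len(genes))
            if j != i
        ]
        m[g] = float(np.mean(sds)) if sds else 0.0
    return pd.Series(m)


def genorm_stability(
    calibrated: pd.DataFrame,
    candidates: list[str],
    efficiencies: dict[str, float] | None = None,
) -> StabilityReport:
    """Rank candidate reference genes by expression stability.

    Computes geNorm M for every candidate, iteratively excludes the
    highest-M gene down to the final pair, derives the pairwise variations
    V(n/n+1) from normalization factors of the best n vs n+1 genes, and
    recommends the smallest n >= 2 with V(n/n+1) < 0.15 (falling back to
    all candidates when no V passes).  BestKeeper SD is the per-gene
    standard deviation of calibrated Cq.  Needs >= 3 candidates and >= 2
    samples.
    """
    if len(candidates) < 3:
        raise ValueError("geNorm needs at least 3 candidate reference genes")
    cq = _cq_wide(calibrated).loc[candidates]
    if cq.isna().any().any():
        raise ValueError("candidate reference genes must have Cq in every sample")
    if cq.shape[1] < 2:
        raise ValueError("geNorm needs at least 2 samples")
    rq = relative_quantities(cq, efficiencies)
    log_rq = np.log2(rq)

    m_all = _genorm_m(log_rq)

    # iterative exclusion: repeatedly drop the least stable gene
    remaining = list(candidates)
    exclusion: list[str] = []
    while len(remaining) > 2:
        m = _genorm_m(log_rq.loc[remaining])
        worst = m.sort_values(ascending=False, kind="mergesort").index[0]
        exclusion.append(str(worst))
        remaining.remove(worst)
    # ranking from most to least stable: final pair first
    ranked = remaining + exclusion[::-1]

    # pairwise variation V(n/n+1) from normalization factors of top-n genes
    pairwise: dict[str, float] = {}
    for n in range(2, len(candidates)):
        top_n = ranked[:n]
        top_n1 = ranked[: n + 1]
        nf_n = log_rq.loc[top_n].mean(axis=0)  # log2 of geometric-mean NF
        nf_n1 = log_rq.loc[top_n1].mean(axis=0)
        v = float(np.std(nf_n - nf_n1, ddof=1))
        pairwise[f"V{n}/{n + 1}"] = v

    n_rec = len(candidates)
    for n in range(2, len(candidates)):
        if pairwise[f"V{n}/{n + 1}"] < V_THRESHOLD:
            n_rec = n
            break
    n_rec = max(2, n_rec)

    bestkeeper = cq.std(axis=1, ddof=1)
    return StabilityReport(
        m_values={g: float(m_all[g]) for g in candidates},
        exclusion_order=exclusion,
        pairwise_variation=pairwise,
        bestkeeper_sd={g: float(bestkeeper[g]) for g in candidates},
        recommended_references=ranked[:n_rec],
    )


# -- relative quantification of targets ---------------------------------------


def relative_quantify(
    calibrated: pd.DataFrame,
    targets: list[str],
    references: list[str],
    efficiencies: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Reference-normalized expression ratios for target genes.

    ratio(g, s) = RQ_g,s / NF(s), with NF(s) the geometric mean of the
    reference genes' relative quantities in sample s.  At least two
    reference genes are required.  Samples missing a reference Cq are
    dropped with a warning.
    """
    if len(references) < 2:
        raise ValueError("at least two reference genes are required")
    cq = _cq_wide(calibrated)
    missing_genes = [g for g in list(targets) + list(references) if g not in cq.index]
    if missing_genes:
        raise KeyError(f"genes absent from the Cq table: {missing_genes}")
    ref_cq = cq.loc[references]
    bad_samples = list(ref_cq.columns[ref_cq.isna().any(axis=0)])
    if bad_samples:
        warnings.warn(
            f"dropping samples with missing reference Cq: {bad_samples}", stacklevel=2
        )
        cq = cq.drop(columns=bad_samples)
    rq = relative_quantities(cq.loc[list(dict.fromkeys(list(targets) + list(references)))], efficiencies)
    nf = np.exp(np.log(rq.loc[references]).mean(axis=0))  # geometric mean
    ratios = rq.loc[targets].div(nf, axis=1)
    out = ratios.reset_index().melt(id_vars="gene_id", var_name="sample_id", value_name="ratio")
    return out


# -- caste comparisons ---------------------------------------------------------


def caste_rank_test(
    ratios: pd.DataFrame,
    metadata: pd.DataFrame,
    stage: str,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U test of Q vs W expression ratios per gene.

    Exact p-values when the two groups are tie-free; with ties the normal
    approximation (tie-corrected, mid-ranks) is used and flagged in the
    ``method`` column.  Both castes need >= 3 samples at the stage.
    """
    meta = metadata.loc[metadata["stage"] == stage]
    rows = []
    for gene, sub in ratios.groupby("gene_id"):
        sub = sub.set_index("sample_id")["ratio"]
        q = sub[[s for s in sub.index if s in meta.index and meta.loc[s, "caste"] == "Q"]]
        w = sub[[s for s in sub.index if s in meta.index and meta.loc[s, "caste"] == "W"]]
        if len(q) < 3 or len(w) < 3:
            raise ValueError(f"gene {gene}: need >=3 samples per caste at stage {stage}")
        has_ties = len(np.unique(np.concatenate([q, w]))) < len(q) + len(w)
        method = "asymptotic" if has_ties else "exact"
        res = stats.mannwhitneyu(q, w, alternative="two-sided", method=method)
        rows.append(
            {
                "gene_id": gene,
                "stage": stage,
                "U": float(res.statistic),
                "p": float(res.pvalue),
                "method": method,
                "median_Q": float(np.median(q)),
                "median_W": float(np.median(w)),
            }
        )
    return pd.DataFrame(rows)


def platform_congruence(
    pcr_tests: pd.DataFrame,
    de_calls_by_stage: dict[str, pd.DataFrame],
    genes: list[str],
    alpha: float = SIG_LEVEL,
) -> list[CongruenceRecord]:
    """Score mRNA-seq vs qRT-PCR agreement per gene and stage.

    The sequencing side calls sig_up_Q / sig_up_W when the gene is an HDEG
    in that stage (direction from the call table), else not_sig.  The qPCR
    side calls significance at Mann-Whitney p < ``alpha`` with direction
    from the caste with the higher median ratio.  Genes absent from one
    platform are recorded as missing and excluded from the binomial total.
    """
    records = []
    for stage, calls in de_calls_by_stage.items():
        calls_idx = calls.set_index("feature_id")
        tests = pcr_tests[pcr_tests["stage"] == stage].set_index("gene_id")
        for gene in genes:
            if gene not in calls_idx.index or gene not in tests.index:
                records.append(
                    CongruenceRecord(gene_id=gene, stage=stage,
                                     seq_result="missing", pcr_result="missing")
                )
                continue
            row = calls_idx.loc[gene]
            if bool(row["is_hdeg"]) and row["direction"] in ("Q", "W"):
                seq_result = f"sig_up_{row['direction']}"
            else:
                seq_result = "not_sig"
            t = tests.loc[gene]
            if t["p"] < alpha:
                pcr_result = "sig_up_Q" if t["median_Q"] > t["median_W"] else "sig_up_W"
            else:
                pcr_result = "not_sig"
            records.append(
                CongruenceRecord(gene_id=gene, stage=stage,
                                 seq_result=seq_result, pcr_result=pcr_result)
            )
    return records
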