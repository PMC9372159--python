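"""Expression QC, TPM, differential expression stand-in and dosage tests.

The transcriptome side of the analysis: library QC (a gene counts as
expressed at >= 5 reads; libraries expressing < 1000 genes are dropped),
TPM normalisation, a self-contained differential-expression stand-in
(Welch test on log2(TPM+1), BH-adjusted; the original analyses used
limma-voom — an adapter hook accepts externally computed DE tables),
50-gene rolling fold-change tracks along a chromosome, cytoband rank-sum
enrichment, and the 12p dosage permutation: the mean log2 fold-change of
the genes on the target arm is compared with 100,000 same-size gene draws
from segments within +/- 0.5 of the sample's overall ploidy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionStudy:
    """Gene x biopsy counts with gene annotation and biopsy metadata.

    ``counts``: integer frame indexed by gene, columns are biopsies.
    ``annotation``: frame with gene, chrom, start, end, cytoband, biotype,
    exclusion_set (empty string = not excluded) and length (bases).
    ``metadata``: frame indexed by biopsy with at least ``histology`` and
    ``is_normal_tubule``.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame
    metadata: pd.DataFrame
    _tpm_cache: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not set(self.counts.index).issubset(set(self.annotation["gene"])):
            raise ValueError("counts contain genes absent from the annotation")
        if (self.annotation["length"] <= 0).any():
            raise ValueError("gene lengths must be positive")

    def gene_lengths(self) -> pd.Series:
        return self.annotation.set_index("gene").loc[self.counts.index, "length"]

    def tpm(self) -> pd.DataFrame:
        if self._tpm_cache is None:
            self._tpm_cache = tpm(self.counts, self.gene_lengths())
        return self._tpm_cache


def qc_libraries(
    counts: pd.DataFrame,
    expressed_min_reads: int = 5,
    min_features: int = 1000,
) -> list:
    """Libraries passing the expressed-feature QC.

    A feature is expressed in a library if it received at least
    ``expressed_min_reads`` reads; libraries expressing fewer than
    ``min_features`` features (strictly fewer — a library at exactly 1000
    is retained) are removed.
    """
    if counts.shape[1] == 0:
        return []
    n_expressed = (counts >= expressed_min_reads).sum(axis=0)
    return list(counts.columns[n_expressed >= min_features])


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalised rates scaled to 1e6 per library."""
    lengths = lengths.loc[counts.index]
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"libraries with zero total rate: {bad}")
    return rate.div(totals, axis=1) * 1e6


@dataclass
class DEResult:
    """Per-gene differential expression summary."""

    table: pd.DataFrame     # gene-indexed: log2fc, pvalue, qvalue
    group_a: list
    group_b: list
    blocking: str | None = None


def differential_expression(
    expr: ExpressionStudy,
    group_a: list,
    group_b: list,
    blocking: str | None = None,
    min_expressed_reads: int = 5,
    min_expressed_libraries: int = 2,
) -> DEResult:
    """Differential expression between two biopsy groups (stand-in routine).

    log2FC = log2((mean TPM_a + 1) / (mean TPM_b + 1)); p-values from a
    two-sided Welch test on log2(TPM + 1), BH-adjusted across genes.  With
    ``blocking`` set to a metadata column (typically ``histology``), the
    log2FC is the unweighted mean of per-block log2FCs over blocks
    represented in group_a, so histologies contribute equally regardless of
    how many libraries each supplied.  Genes expressed (>= 5
    reads) in fewer than ``min_expressed_libraries`` of the used libraries
    are filtered out, mirroring the minimum-expression filtering of
    standard DE pipelines.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 libraries per group")
    used = list(group_a) + list(group_b)
    counts = expr.counts[used]
    expressed = (counts >= min_expressed_reads).sum(axis=1) >= min_expressed_libraries
    tpm_all = expr.tpm()[used].loc[expressed]
    log_tpm = np.log2(tpm_all + 1)

    a = tpm_all[list(group_a)]
    b = tpm_all[list(group_b)]

    if blocking is None:
        log2fc = np.log2((a.mean(axis=1) + 1) / (b.mean(axis=1) + 1))
        la, lb = log_tpm[list(group_a)], log_tpm[list(group_b)]
    else:
        blocks = expr.metadata.loc[used, blocking]
        fcs = []
        for blk in sorted(blocks.loc[list(group_a)].unique()):
            ga = [s for s in group_a if blocks[s] == blk]
            fcs.append(np.log2((tpm_all[ga].mean(axis=1) + 1) / (b.mean(axis=1) + 1)))
        log2fc = pd.concat(fcs, axis=1).mean(axis=1)
        la, lb = log_tpm[list(group_a)], log_tpm[list(group_b)]

    with np.errstate(invalid="ignore"):
        tstat, pval = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    pval = np.where(np.isnan(pval), 1.0, pval)
    qval = multipletests(pval, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pval, "qvalue": qval}, index=tpm_all.index
    )
    return DEResult(table, list(group_a), list(group_b), blocking)


DE_SIG_LOG2FC = 2.0
DE_SIG_ADJ_P = 0.01


def significant_genes(de: DEResult, min_abs_log2fc: float = DE_SIG_LOG2FC,
                      max_adj_p: float = DE_SIG_ADJ_P) -> pd.DataFrame:
    """Genes passing the |log2FC| > 2 and adjusted p < 0.01 cut-offs."""
    t = de.table
    return t[(t["log2fc"].abs() > min_abs_log2fc) & (t["qvalue"] < max_adj_p)]


def rolling_logfc(
    de: DEResult,
    annotation: pd.DataFrame,
    chrom: str,
    window: int = 50,
) -> pd.DataFrame:
    """Centred 50-gene rolling average of log2FC along one chromosome.

    Genes are ordered by start coordinate; each window of ``window``
    consecutive genes contributes one point at the median position of its
    genes.  Track length is n_genes - window + 1; with fewer genes than
    ``window`` the track is empty.
    """
    ann = annotation[annotation["chrom"].astype(str) == str(chrom)]
    ann = ann[ann["gene"].isin(de.table.index)].sort_values("start")
    n = len(ann)
    if n < window:
        return pd.DataFrame(columns=["chrom", "centre_pos", "mean_log2fc"])
    fc = de.table.loc[ann["gene"], "log2fc"].to_numpy()
    pos = ann["start"].to_numpy(dtype=float)
    means = np.convolve(fc, np.ones(window) / window, mode="valid")
    centres = [float(np.median(pos[i:i + window])) for i in range(n - window + 1)]
    return pd.DataFrame({"chrom": chrom, "centre_pos": centres, "mean_log2fc": means})


def cytoband_enrichment(
    de: DEResult,
    annotation: pd.DataFrame,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Per-cytoband enrichment of log2 fold-changes (competitive rank-sum).

    Each band's genes are compared against all other retained genes with a
    two-sided Mann-Whitney test; BH across bands.  Bands with fewer than
    ``min_genes`` retained genes are skipped (listed with NaN p).  Gene-to-
    band assignment uses the annotation's cytoband column.
    """
    ann = annotation[annotation["gene"].isin(de.table.index)]
    fc = de.table["log2fc"]
    rows = []
    for band, grp in ann.groupby("cytoband"):
        in_band = fc.loc[grp["gene"]]
        if len(in_band) < min_genes:
            rows.append({"cytoband": band, "n_genes": len(in_band),
                         "direction": "", "pvalue": np.nan})
            continue
        out_band = fc.drop(grp["gene"])
        stat, p = stats.mannwhitneyu(in_band, out_band, alternative="two-sided")
        rows.append({
            "cytoband": band, "n_genes": len(in_band),
            "direction": "+" if in_band.median() > out_band.median() else "-",
            "pvalue": float(p),
        })
    out = pd.DataFrame(rows)
    tested = out["pvalue"].notna()
    out["qvalue"] = np.nan
    if tested.any():
        out.loc[tested, "qvalue"] = multipletests(out.loc[tested, "pvalue"], method="fdr_bh")[1]
    return out


def near_baseline_genes(
    annotation: pd.DataFrame,
    segments: pd.DataFrame,
    ploidy: float,
    near_baseline: float = 0.5,
) -> list:
    """Genes on segments whose total copy number is within +/-0.5 of ploidy.

    Gene-to-segment assignment uses the gene start coordinate.
    """
    hits = []
    segs = segments.assign(total_cn=segments["major"] + segments["minor"])
    segs = segs[(segs["total_cn"] - ploidy).abs() <= near_baseline]
    for _, seg in segs.iterrows():
        sel = annotation[
            (annotation["chrom"].astype(str) == str(seg["chrom"]))
            & (annotation["start"] >= seg["start"])
            & (annotation["start"] <= seg["end"])
        ]
        hits.extend(sel["gene"].tolist())
    return sorted(set(hits))


def dosage_permutation(
    de: DEResult,
    target_genes: list,
    pool_genes: list,
    n_draws: int = 100_000,
    seed: int | None = None,
    replace: bool = False,
) -> dict:
    """One-sided permutation test of a gene set's mean log2 fold-change.

    The observed statistic is the mean log2FC of the target genes retained
    in the DE table (the 12p genes in the motivating analysis).  The null
    distribution is built from ``n_draws`` random same-size gene sets drawn
    without replacement from the near-baseline-ploidy pool;
    p = (1 + #{null >= observed}) / (n_draws + 1).
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    fc = de.table["log2fc"]
    target = [g for g in target_genes if g in fc.index]
    # the pool is taken as given (near-baseline genes); any overlap with the
    # target is kept so that a target drawn from the pool itself is exactly
    # exchangeable with the null draws
    pool = [g for g in pool_genes if g in fc.index]
    k = len(target)
    if k == 0:
        raise ValueError("no target genes retained in the DE table")
    if len(pool) < k:
        raise ValueError(f"near-baseline pool ({len(pool)} genes) smaller than target ({k})")
    observed = float(fc.loc[target].mean())
    pool_fc = fc.loc[pool].to_numpy()
    rng = np.random.default_rng(seed)
    if replace:
        draws = rng.choice(pool_fc, size=(n_draws, k), replace=True).mean(axis=1)
    else:
        draws = np.empty(n_draws)
        for i in range(n_draws):
            draws[i] = pool_fc[rng.choice(pool_fc.size, size=k, replace=False)].mean()
    exceed = int((draws >= observed).sum())
    return {
        "observed_mean_log2fc": observed,
        "p_value": (1 + exceed) / (n_draws + 1),
        "n_target": k,
        "n_pool": len(pool),
    }
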