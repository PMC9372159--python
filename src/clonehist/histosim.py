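"""Histology-vs-clone similarity scores and permutation tests.

Within a tumour, every pair of microdissections gets a genetic similarity
(shared mutation-cluster content relative to average burden) and a
transcriptomic similarity (Pearson correlation of log2 TPM).  Pairs are
labelled intra- or inter-histology and the difference in median scores is
tested by swapping the pair labels: 1000 random swaps by default, or an
exhaustive enumeration when the label-assignment space is small (for a
4-genome/2-histology tumour the space has C(6,2) = 15 assignments).

The chromothripsis variance test asks whether one tumour's intra-histology
correlations are more dispersed than random same-size subsets of the
cohort's pooled correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


@dataclass
class SimilarityMatrix:
    """Pairwise similarity scores between a tumour's biopsies."""

    scores: pd.DataFrame      # square, symmetric, index == columns == biopsies
    histology: dict           # biopsy -> histology label

    def __post_init__(self) -> None:
        if not self.scores.index.equals(self.scores.columns):
            raise ValueError("score matrix must be square with matching labels")

    def pairs(self) -> pd.DataFrame:
        """Long-form upper-triangle pairs with intra/inter labels (diagonal excluded)."""
        rows = []
        names = list(self.scores.index)
        for a, b in combinations(names, 2):
            rows.append({
                "a": a, "b": b,
                "score": float(self.scores.loc[a, b]),
                "intra": self.histology[a] == self.histology[b],
            })
        return pd.DataFrame(rows)


def genetic_similarity(tree, presence_ccf: float = 0.1, histology: dict | None = None) -> SimilarityMatrix:
    """Genetic similarity from a clone tree's cluster table.

    ``score(a, b)`` is the substitution count summed over clusters present
    (CCF > ``presence_ccf``) in both biopsies, divided by the mean of the
    two biopsies' total present burdens.  A biopsy with no present cluster
    yields NaN scores.
    """
    tab = tree.clusters if hasattr(tree, "clusters") else tree
    ccf_cols = [c for c in tab.columns if c.startswith("ccf_")]
    biopsies = [c[4:] for c in ccf_cols]
    n_subs = tab["n_subs"].to_numpy(dtype=float)
    present = tab[ccf_cols].to_numpy(dtype=float) > presence_ccf
    burden = present.T @ n_subs  # per-biopsy total present substitutions
    B = len(biopsies)
    mat = np.full((B, B), np.nan)
    for i in range(B):
        for j in range(B):
            if burden[i] == 0 or burden[j] == 0:
                continue
            shared = float(n_subs[present[:, i] & present[:, j]].sum())
            mat[i, j] = shared / ((burden[i] + burden[j]) / 2)
    scores = pd.DataFrame(mat, index=biopsies, columns=biopsies)
    if histology is None:
        histology = {b: "unknown" for b in biopsies}
    return SimilarityMatrix(scores, histology)


def transcriptomic_similarity(expr, histology: dict | None = None) -> SimilarityMatrix:
    """Pearson correlation of log2(TPM + 1) between biopsies.

    Restricted to protein-coding genes outside the exclusion sets
    (haemoglobin, immunoglobulin, cycling, housekeeping).  ``expr`` is an
    :class:`~clonehist.dosagexpr.ExpressionStudy`.
    """
    annot = expr.annotation
    keep = (annot["biotype"] == "protein_coding") & (annot["exclusion_set"] == "")
    genes = annot.loc[keep, "gene"]
    if len(genes) < 2:
        raise ValueError("fewer than 2 retained genes; similarity undefined")
    tpm = expr.tpm().loc[genes]
    log_tpm = np.log2(tpm + 1)
    corr = np.corrcoef(log_tpm.to_numpy().T)
    scores = pd.DataFrame(corr, index=tpm.columns, columns=tpm.columns)
    if histology is None:
        histology = dict(zip(expr.metadata.index, expr.metadata["histology"]))
    return SimilarityMatrix(scores, histology)


@dataclass
class SwapTestResult:
    observed: float       # median(intra) - median(inter)
    p_value: float
    mode: str             # "sampled" or "exhaustive"
    n_assignments: int


def label_swap_test(
    sim: SimilarityMatrix | pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> SwapTestResult:
    """One-sided label-swap permutation test of intra vs inter similarity.

    The statistic is median(intra) - median(inter) over the pairwise
    comparisons.  The null permutes which pairs carry the "intra" label,
    keeping the intra count.  When the number of distinct assignments
    C(n_pairs, n_intra) is <= ``n_perm`` the space is enumerated
    exhaustively and p = (1 + #{alternatives >= observed}) / #assignments;
    otherwise p = (1 + #{null >= observed}) / (n_perm + 1).  Ties count as
    exceedances.
    """
    pairs = sim.pairs() if isinstance(sim, SimilarityMatrix) else sim
    pairs = pairs.dropna(subset=["score"])
    scores = pairs["score"].to_numpy(dtype=float)
    intra = pairs["intra"].to_numpy(dtype=bool)
    n_intra = int(intra.sum())
    n_pairs = intra.size
    if n_intra == 0 or n_intra == n_pairs:
        raise ValueError("need at least one intra- and one inter-histology pair")
    observed = float(np.median(scores[intra]) - np.median(scores[~intra]))

    n_assign = comb(n_pairs, n_intra)
    if n_assign <= n_perm:
        exceed = 0
        for combo in combinations(range(n_pairs), n_intra):
            mask = np.zeros(n_pairs, dtype=bool)
            mask[list(combo)] = True
            if np.array_equal(mask, intra):
                continue  # the observed assignment is not an alternative
            stat = np.median(scores[mask]) - np.median(scores[~mask])
            if stat >= observed:
                exceed += 1
        return SwapTestResult(observed, (1 + exceed) / n_assign, "exhaustive", n_assign)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        mask = np.zeros(n_pairs, dtype=bool)
        mask[rng.choice(n_pairs, size=n_intra, replace=False)] = True
        stat = np.median(scores[mask]) - np.median(scores[~mask])
        if stat >= observed:
            exceed += 1
    return SwapTestResult(observed, (1 + exceed) / (n_perm + 1), "sampled", n_assign)


def chromothripsis_variance_test(
    pooled_correlations: np.ndarray,
    focal_correlations: np.ndarray,
    n_iter: int = 1000,
    seed: int | None = None,
) -> dict:
    """Is the focal tumour's transcriptional heterogeneity excessive?

    Compares the variance of the focal tumour's intra-histology
    correlations against variances of ``n_iter`` random same-size subsets
    of the pooled cohort correlations.  One-sided: large variance means
    heterogeneity.  If the pool admits fewer than ``n_iter`` distinct
    subsets they are enumerated exhaustively.
    """
    pool = np.asarray(pooled_correlations, dtype=float)
    focal = np.asarray(focal_correlations, dtype=float)
    k = focal.size
    if k < 2:
        raise ValueError("need at least 2 focal correlations")
    if pool.size < k:
        raise ValueError("pool smaller than the focal correlation set")
    observed = float(np.var(focal, ddof=1))
    n_subsets = comb(pool.size, k)
    if n_subsets <= n_iter:
        null = np.array([
            np.var(pool[list(c)], ddof=1) for c in combinations(range(pool.size), k)
        ])
        mode = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        null = np.array([
            np.var(pool[rng.choice(pool.size, size=k, replace=False)], ddof=1)
            for _ in range(n_iter)
        ])
        mode = "sampled"
    p = float((null >= observed).mean())
    return {"observed_variance": observed, "p_value": p, "mode": mode, "n_null": null.size}
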