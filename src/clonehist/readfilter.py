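"""Post-caller variant filtering, pileup rescue and the panel error model.

Laser-capture microbiopsies are sequenced at modest depth (15-48x), so a
variant genuinely present in one biopsy is often supported by only a handful
of reads in its neighbours.  The rescue strategy is: (i) hard quality
filters on the primary calls, (ii) a patient-level pileup of every called
site across all of the patient's samples with removal of universally
low-coverage loci, and (iii) a site-specific beta-binomial error test
against an unmatched panel of normal samples, with Benjamini-Hochberg
correction and presence declared at adjusted p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

# ---------------------------------------------------------------------------
# sample profile and reads per chromosome copy

@dataclass
class SampleProfile:
    """Purity/ploidy summary of one sequenced sample.

    Attributes
    ----------
    purity : float
        Tumour cell fraction rho, in (0, 1].
    ploidy : float
        Ploidy psi weighted by subclonality (Battenberg-style).
    tumour_coverage : float
        Mean sequencing coverage C of the sample.
    homozygous_fraction : float
        Length-weighted fraction h of the genome with minor allele 0,
        weighted by subclonality; used by the WGD classifier.
    """

    purity: float
    ploidy: float
    tumour_coverage: float = 0.0
    homozygous_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be positive, got {self.ploidy}")
        if self.tumour_coverage < 0:
            raise ValueError("tumour_coverage must be >= 0")
        if not (0 <= self.homozygous_fraction <= 1):
            raise ValueError("homozygous_fraction must be in [0, 1]")


def reads_per_copy(profile: SampleProfile) -> float:
    """Average reads per chromosome copy.

    ``rho / (rho*psi + 2*(1-rho)) * C``: the sample's coverage split over
    the tumour's chromosome copies after accounting for the diploid
    admixed normal cells.  Tree building requires >= 5, copy-number timing
    >= 7 reads per copy.
    """
    rho, psi, cov = profile.purity, profile.ploidy, profile.tumour_coverage
    return rho / (rho * psi + (1 - rho) * 2) * cov


TREE_MIN_READS_PER_COPY = 5.0
TIMING_MIN_READS_PER_COPY = 7.0


# ---------------------------------------------------------------------------
# hard filters

@dataclass
class VariantReadSummary:
    """Read-level summary statistics for one candidate variant in one sample."""

    alt: int
    total: int
    median_alignment_score: float | None = None
    clipped_fraction: float | None = None
    low_mapq_reads: int | None = None
    ambiguous_reads: int | None = None
    normal_vaf: float | None = None
    panel_vaf: float | None = None
    quality: float | None = None  # caller quality score; required for indels

    def __post_init__(self) -> None:
        if self.alt > self.total:
            raise ValueError("alt reads exceed total reads")
        for name in ("clipped_fraction", "normal_vaf", "panel_vaf"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


#: failure reason codes emitted by :func:`apply_hard_filters`
REASON_CODES = (
    "ALIGN_SCORE",   # median alignment score < 140 (substitutions)
    "CLIPPED",       # half or more supporting reads clipped (substitutions)
    "QUAL_SCORE",    # caller quality < 300 (indels)
    "MIN_ALT_READS", # < 4 alt reads (bulk substitutions) / < 5 (indels)
    "MIN_COVERAGE",  # total coverage < 10 (bulk)
    "GERMLINE_VAF",  # normal or panel VAF >= 0.2
    "AMBIG_READS",   # unknown+ambiguous reads strictly exceed variant reads
    "LOW_MAPQ",      # half or more reads with mapping quality < 20
)

_SUB_ALIGN_MIN = 140.0
_INDEL_QUAL_MIN = 300.0
_GERMLINE_VAF_MAX = 0.2
_BULK_SUB_MIN_ALT = 4
_INDEL_MIN_ALT = 5
_BULK_MIN_COV = 10


def _require(summary: VariantReadSummary, name: str) -> float:
    value = getattr(summary, name)
    if value is None:
        raise ValueError(f"hard filter requires field '{name}' for this variant class")
    return value


def apply_hard_filters(
    summaries: list[VariantReadSummary] | pd.DataFrame,
    variant_class: str = "substitution",
    mode: str = "microdissection",
) -> pd.DataFrame:
    """Apply the conjunctive post-caller hard filters.

    Parameters
    ----------
    summaries
        One :class:`VariantReadSummary` per candidate variant (or a frame
        with the same columns).
    variant_class
        ``"substitution"`` or ``"indel"``; the classes carry different
        quality rules (alignment score >= 140 vs quality score >= 300,
        minimum alt reads 4-bulk vs 5).
    mode
        ``"microdissection"`` or ``"bulk"``; bulk adds the >= 4 alt reads /
        >= 10x coverage requirements for substitutions and the >= 10x
        coverage requirement for indels.

    Returns
    -------
    DataFrame with boolean ``passed`` and a semicolon-joined ``reasons``
    column.  Rules are conjunctive, so the outcome is independent of the
    order in which they are evaluated.
    """
    if variant_class not in ("substitution", "indel"):
        raise ValueError(f"unknown variant_class {variant_class!r}")
    if mode not in ("microdissection", "bulk"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(summaries, pd.DataFrame):
        summaries = [
            VariantReadSummary(**{k: (None if pd.isna(v) else v) for k, v in row.items()})
            for row in summaries.to_dict("records")
        ]

    rows = []
    for s in summaries:
        reasons = []
        if variant_class == "substitution":
            if _require(s, "median_alignment_score") < _SUB_ALIGN_MIN:
                reasons.append("ALIGN_SCORE")
            if _require(s, "clipped_fraction") >= 0.5:
                reasons.append("CLIPPED")
            if mode == "bulk":
                if s.alt < _BULK_SUB_MIN_ALT:
                    reasons.append("MIN_ALT_READS")
                if s.total < _BULK_MIN_COV:
                    reasons.append("MIN_COVERAGE")
        else:
            if _require(s, "quality") < _INDEL_QUAL_MIN:
                reasons.append("QUAL_SCORE")
            if s.alt < _INDEL_MIN_ALT:
                reasons.append("MIN_ALT_READS")
            if mode == "bulk" and s.total < _BULK_MIN_COV:
                reasons.append("MIN_COVERAGE")
        for vaf_field in ("normal_vaf", "panel_vaf"):
            v = getattr(s, vaf_field)
            if v is not None and v >= _GERMLINE_VAF_MAX:
                reasons.append("GERMLINE_VAF")
                break
        # exclusion requires ambiguous reads to STRICTLY exceed variant reads
        if s.ambiguous_reads is not None and s.ambiguous_reads > s.alt:
            reasons.append("AMBIG_READS")
        if s.low_mapq_reads is not None and s.total > 0 and s.low_mapq_reads >= s.total / 2:
            reasons.append("LOW_MAPQ")
        rows.append({"passed": not reasons, "reasons": ";".join(reasons)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pileup rescue

def pileup_rescue(total_reads: np.ndarray | pd.DataFrame, mean_cov_max_fail: float = 10.0) -> np.ndarray:
    """Drop pileup sites with universally low coverage across a patient.

    ``total_reads`` is a sites x samples matrix of read totals (already
    restricted to reads meeting base quality >= 25 and mapping quality
    >= 30).  Sites whose mean coverage across the patient's samples is
    <= ``mean_cov_max_fail`` (inclusive) are removed as probable mapping
    artefacts.  Returns a boolean retention mask over sites.
    """
    totals = np.asarray(total_reads, dtype=float)
    if totals.size == 0:
        return np.zeros(totals.shape[0] if totals.ndim else 0, dtype=bool)
    if totals.ndim != 2:
        raise ValueError("expected a sites x samples matrix")
    return totals.mean(axis=1) > mean_cov_max_fail


# ---------------------------------------------------------------------------
# beta-binomial panel error model

@dataclass
class PanelCounts:
    """Per-site alt/total read counts from an unmatched normal panel."""

    alt: np.ndarray    # sites x samples
    total: np.ndarray  # sites x samples

    def __post_init__(self) -> None:
        self.alt = np.asarray(self.alt)
        self.total = np.asarray(self.total)
        if self.alt.shape != self.total.shape:
            raise ValueError("alt/total shape mismatch")
        if np.any(self.alt > self.total):
            raise ValueError("alt exceeds total in panel")


@dataclass
class PanelErrorModel:
    """Site-specific error rates with one global overdispersion.

    ``mu`` holds the pseudocount-regularised pooled error fraction per site;
    ``rho`` is a single method-of-moments beta-binomial overdispersion shared
    by all sites (per-site overdispersion fits are unstable at panel depth).
    """

    mu: np.ndarray
    rho: float
    pseudocounts: tuple[float, float] = (0.5, 0.5)
    untestable: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if np.any((self.mu < 0) | (self.mu >= 0.5)):
            raise ValueError("per-site error rates must lie in [0, 0.5)")
        if not (0 < self.rho < 1):
            raise ValueError("overdispersion must lie in (0, 1)")
        if self.untestable.size == 0:
            self.untestable = np.zeros(self.mu.shape, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mu": self.mu, "untestable": self.untestable}).assign(rho=self.rho)


MIN_RHO = 1e-6


def fit_panel_error(panel: PanelCounts, pseudocounts: tuple[float, float] = (0.5, 0.5)) -> PanelErrorModel:
    """Fit the panel error model.

    Per-site mean: ``mu_i = (sum alt_i + a) / (sum total_i + a + b)`` with
    pseudocounts ``(a, b)`` so a perfectly clean panel still has a non-zero
    tail.  Overdispersion: method of moments pooled over all site/sample
    cells, ``E[(x - n mu)^2] = n mu (1-mu) (1 + (n-1) rho)``, clipped to
    ``[1e-6, 1)``; a binomial panel therefore lands at the lower bound.
    Sites with zero panel depth are flagged untestable.
    """
    if panel.alt.ndim != 2 or panel.alt.shape[1] < 2:
        raise ValueError("panel must have >= 2 samples per site")
    a, b = pseudocounts
    if a <= 0 or b <= 0:
        raise ValueError("pseudocounts must be positive")
    depth = panel.total.sum(axis=1).astype(float)
    alt = panel.alt.sum(axis=1).astype(float)
    untestable = depth == 0
    mu = (alt + a) / (depth + a + b)
    mu = np.clip(mu, 0.0, 0.5 - 1e-12)

    n = panel.total.astype(float)
    x = panel.alt.astype(float)
    with np.errstate(invalid="ignore"):
        resid_sq = (x - n * mu[:, None]) ** 2
    var_bin = n * (mu * (1 - mu))[:, None]
    weight = n * (n - 1) * (mu * (1 - mu))[:, None]
    mask = n > 0
    num = float((resid_sq[mask] - var_bin[mask]).sum())
    den = float(weight[mask].sum())
    rho = num / den if den > 0 else MIN_RHO
    rho = float(np.clip(rho, MIN_RHO, 1 - 1e-9))
    return PanelErrorModel(mu=mu, rho=rho, pseudocounts=(a, b), untestable=untestable)


def betabinom_pvalues(alt: np.ndarray, total: np.ndarray, model: PanelErrorModel) -> np.ndarray:
    """One-sided upper-tail beta-binomial p-values, P[X >= alt].

    ``alt``/``total`` are sites x samples; row i uses the panel's ``mu[i]``
    and the shared overdispersion.  ``alt = 0`` gives p = 1 by construction.
    """
    alt = np.asarray(alt)
    total = np.asarray(total)
    if np.any(alt > total):
        raise ValueError("alt exceeds total")
    mu = model.mu[:, None] if alt.ndim == 2 else model.mu
    rho = model.rho
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    # sf(k-1) = P[X >= k]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.betabinom.sf(alt - 1, np.maximum(total, 0), a, b)
    p = np.asarray(p, dtype=float)
    p[np.asarray(total) == 0] = 1.0
    return np.clip(p, 0.0, 1.0)


def betabinom_rescue(
    alt: np.ndarray,
    total: np.ndarray,
    model: PanelErrorModel,
    alpha: float = 0.001,
    pool: str = "patient",
) -> pd.DataFrame | dict:
    """Call per-(site, sample) variant presence against the panel error model.

    Benjamini-Hochberg correction is applied across all tests in the patient
    (``pool="patient"``, sites x samples jointly — the default) or within
    each sample (``pool="per_sample"``).  A variant is considered real where
    the adjusted p-value is < ``alpha``.

    Returns a dict with ``pvalues``, ``qvalues`` and boolean ``present``
    arrays of the input shape.
    """
    p = betabinom_pvalues(alt, total, model)
    q = np.empty_like(p)
    if pool == "patient":
        q.flat[:] = multipletests(p.ravel(), method="fdr_bh")[1]
    elif pool == "per_sample":
        if p.ndim != 2:
            raise ValueError("per_sample pooling needs a sites x samples matrix")
        for j in range(p.shape[1]):
            q[:, j] = multipletests(p[:, j], method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown pool {pool!r}")
    present = q < alpha
    if model.untestable.any():
        untest = model.untestable
        present[untest] = False
    return {"pvalues": p, "qvalues": q, "present": present}


# ---------------------------------------------------------------------------
# callable length and burden

def _merged_length(intervals: pd.DataFrame) -> "list[tuple[str, int, int]]":
    merged = []
    for chrom, grp in intervals.groupby("chrom", sort=False):
        last = None
        for start, end in sorted(zip(grp["start"], grp["end"])):
            if last is not None and start <= last[2]:
                last = (chrom, last[1], max(last[2], end))
                merged[-1] = last
            else:
                last = (chrom, start, end)
                merged.append(last)
    return merged


def callable_length(depth_track: pd.DataFrame, masked_regions: pd.DataFrame | None = None,
                    min_depth: int = 4) -> int:
    """Callable genome length in bases.

    ``depth_track`` is a BED-graph-like frame (chrom, start, end, depth;
    0-based half-open).  Bases need depth >= ``min_depth`` and must not fall
    in ``masked_regions`` (chrom, start, end).
    """
    covered = depth_track.loc[depth_track["depth"] >= min_depth, ["chrom", "start", "end"]]
    cov = _merged_length(covered)
    total = sum(e - s for _, s, e in cov)
    if masked_regions is None or len(masked_regions) == 0:
        return total
    masked = _merged_length(masked_regions[["chrom", "start", "end"]])
    overlap = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in masked:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, s, e in cov:
        for ms, me in by_chrom.get(chrom, ()):
            overlap += max(0, min(e, me) - max(s, ms))
    return total - overlap


def mutation_burden(
    n_substitutions: int,
    n_indels: int,
    depth_track: pd.DataFrame,
    masked_regions: pd.DataFrame | None = None,
) -> dict:
    """Substitution and indel burden per callable megabase.

    The callable length is the number of bases with >= 4 reads minus the
    caller-masked regions.  With zero callable length the burdens are
    undefined and reported as NaN.
    """
    length = callable_length(depth_track, masked_regions)
    if length <= 0:
        return {"callable_mb": 0.0, "subs_per_mb": float("nan"), "indels_per_mb": float("nan")}
    mb = length / 1e6
    return {
        "callable_mb": mb,
        "subs_per_mb": n_substitutions / mb,
        "indels_per_mb": n_indels / mb,
    }
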