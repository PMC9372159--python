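"""Timing clonal copy-number gains in mutation time.

A clonal gain splits a segment's substitutions into two multiplicity
classes: mutations that preceded the gain sit on every duplicated copy
(multiplicity 2) while later mutations sit on a single copy (multiplicity
1).  Counting the two classes therefore times the gain on the [0, 1] axis
of accumulated clonal substitutions ("mutation time").  Only the
allele-specific states 2+0, 2+1 and 2+2 are timeable; for these the
maximum-likelihood inversions are

    t = 2*n2 / (2*n2 + n1)      (2+0 and 2+2)
    t = 3*n2 / (2*n2 + n1)      (2+1)

The pre-duplication substitution burden sums multiplicity-2 mutations over
confidently timed segments, corrects for the pre-duplication minor-allele
mutations that 2+0 and 2+1 segments cannot reveal,

    adjusted = n_pre + n_pre * (n_total[2+1, 2+0] / n_total[2+2, 2+1, 2+0]),

and extrapolates to the genome by covered length.  Whole-genome duplication
is declared by the PCAWG-style rule ploidy >= 2.9 - 2 * homozygous
fraction, and the genome-wide burden converts to primordial-germ-cell
divisions by doubling the published 0.5-0.7 substitutions per haploid
genome per division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .readfilter import SampleProfile

TIMEABLE_STATES = ("2+0", "2+1", "2+2")

#: autosomal bases of GRCh37, the default extrapolation denominator
GENOME_LENGTH_AUTOSOMES = 2_875_001_522


# ---------------------------------------------------------------------------
# multiplicity assignment

def expected_vaf(multiplicity, purity, total_cn, ccf=1.0):
    """Expected VAF of a mutation: ``m * rho * CCF / (rho*CNt + 2*(1-rho))``."""
    m = np.asarray(multiplicity, dtype=float)
    rho = np.asarray(purity, dtype=float)
    cnt = np.asarray(total_cn, dtype=float)
    return m * rho * np.asarray(ccf, dtype=float) / (rho * cnt + 2 * (1 - rho))


def assign_multiplicity(alt, total, purity, total_cn) -> np.ndarray:
    """Hard maximum-likelihood multiplicity (1 or 2) per clonal mutation.

    Compares the binomial likelihood of the observed alt count under the
    expected VAFs of multiplicity 1 and 2; ties go to multiplicity 1.
    Mutations with zero depth are unassigned (0).
    """
    alt = np.atleast_1d(np.asarray(alt, dtype=float))
    total = np.atleast_1d(np.asarray(total, dtype=float))
    purity = np.broadcast_to(np.asarray(purity, dtype=float), alt.shape)
    cnt = np.broadcast_to(np.asarray(total_cn, dtype=float), alt.shape)
    if np.any(alt > total):
        raise ValueError("alt exceeds total")
    v1 = np.clip(expected_vaf(1, purity, cnt), 1e-12, 1 - 1e-12)
    v2 = np.clip(expected_vaf(2, purity, cnt), 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore"):
        ll1 = alt * np.log(v1) + (total - alt) * np.log1p(-v1)
        ll2 = alt * np.log(v2) + (total - alt) * np.log1p(-v2)
    out = np.where(ll2 > ll1, 2, 1)
    out = np.where(total == 0, 0, out)
    return out


def _mixture_em(ll1, ll2, tol=1e-8, max_iter=500):
    """EM for the mixing weight pi = P(multiplicity 2); returns (pi, loglik)."""
    pi = 0.5
    for _ in range(max_iter):
        log_w2 = np.log(pi) + ll2
        log_w1 = np.log1p(-pi) + ll1
        m = np.maximum(log_w1, log_w2)
        e1, e2 = np.exp(log_w1 - m), np.exp(log_w2 - m)
        r2 = e2 / (e1 + e2)
        pi_new = float(np.clip(r2.mean(), 1e-9, 1 - 1e-9))
        if abs(pi_new - pi) < tol:
            pi = pi_new
            break
        pi = pi_new
    log_w2 = np.log(pi) + ll2
    log_w1 = np.log1p(-pi) + ll1
    m = np.maximum(log_w1, log_w2)
    ll = float((m + np.log(np.exp(log_w1 - m) + np.exp(log_w2 - m))).sum())
    return pi, ll


def _component_logliks(alt, total, purity, cnt, ccf):
    v1 = np.clip(expected_vaf(1, purity, cnt, ccf), 1e-12, 1 - 1e-12)
    v2 = np.clip(expected_vaf(2, purity, cnt, ccf), 1e-12, 1 - 1e-12)
    ll1 = alt * np.log(v1) + (total - alt) * np.log1p(-v1)
    ll2 = alt * np.log(v2) + (total - alt) * np.log1p(-v2)
    return ll1, ll2


def soft_multiplicity_counts(alt, total, purity, total_cn, ccf=1.0, tol=1e-8, max_iter=500):
    """Mixture-estimated (n1, n2) for one segment's clonal mutations.

    Hard maximum-likelihood assignment systematically inflates the
    multiplicity-2 count when the class is rare (the many multiplicity-1
    mutations leak across the decision boundary at moderate depth), so for
    burden estimation the mixing fraction is instead estimated by EM on the
    two-component binomial mixture with known component VAFs.  ``ccf``
    scales both component VAFs by the clonal cancer cell fraction (see
    :func:`fit_clonal_scale`).  Returns expected counts ``(n1, n2)``
    summing to the number of assigned mutations.
    """
    alt = np.atleast_1d(np.asarray(alt, dtype=float))
    total = np.atleast_1d(np.asarray(total, dtype=float))
    purity = np.broadcast_to(np.asarray(purity, dtype=float), alt.shape)
    cnt = np.broadcast_to(np.asarray(total_cn, dtype=float), alt.shape)
    keep = total > 0
    alt, total, purity, cnt = alt[keep], total[keep], purity[keep], cnt[keep]
    n = alt.size
    if n == 0:
        return 0.0, 0.0
    ll1, ll2 = _component_logliks(alt, total, purity, cnt, ccf)
    pi, _ = _mixture_em(ll1, ll2, tol=tol, max_iter=max_iter)
    return float(n * (1 - pi)), float(n * pi)


def fit_clonal_scale(per_segment, purity, grid=None):
    """Shared clonal CCF scale for one sample's timeable mutations.

    Even "clonal" substitutions sit slightly below CCF 1 in a
    near-monoclonal microbiopsy; using unscaled component VAFs then biases
    the multiplicity split.  This profiles the mixture likelihood over a
    common scale applied to both component VAFs, with each segment's
    mixing weight free — the same role the clonal-cluster location plays
    in mutation-timing packages.

    Parameters
    ----------
    per_segment : list of (alt, total, total_cn) arrays, one per segment.
    purity : float
    grid : optional array of candidate scales (default 0.85..1.05).
    """
    if grid is None:
        grid = np.arange(0.85, 1.0501, 0.005)
    best_s, best_ll = 1.0, -np.inf
    prepared = []
    for alt, total, cnt in per_segment:
        alt = np.atleast_1d(np.asarray(alt, dtype=float))
        total = np.atleast_1d(np.asarray(total, dtype=float))
        cnt_arr = np.broadcast_to(np.asarray(cnt, dtype=float), alt.shape)
        keep = total > 0
        if keep.any():
            prepared.append((alt[keep], total[keep], cnt_arr[keep]))
    if not prepared:
        return 1.0
    for s in grid:
        ll = 0.0
        for alt, total, cnt in prepared:
            ll1, ll2 = _component_logliks(alt, total, purity, cnt, s)
            _, seg_ll = _mixture_em(ll1, ll2, tol=1e-6, max_iter=200)
            ll += seg_ll
        if ll > best_ll:
            best_ll, best_s = ll, float(s)
    return best_s


# ---------------------------------------------------------------------------
# segment timing

@dataclass
class TimedSegment:
    """One copy-number segment with its mutation-time estimate."""

    chrom: str
    start: int
    end: int
    major: int
    minor: int
    n_mult1: float
    n_mult2: float
    time: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    eligible: bool = False

    @property
    def state(self) -> str:
        return f"{self.major}+{self.minor}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1  # 1-based inclusive


def _time_formula(n1: np.ndarray, n2: np.ndarray, state: str) -> np.ndarray:
    denom = 2.0 * n2 + n1
    with np.errstate(divide="ignore", invalid="ignore"):
        if state == "2+1":
            t = 3.0 * n2 / denom
        else:  # 2+0 and 2+2
            t = 2.0 * n2 / denom
    return np.clip(t, 0.0, 1.0)


def segment_time(
    n_mult1: float,
    n_mult2: float,
    state: str,
    n_boot: int = 200,
    ci_width_max: float = 0.5,
    seed: int | None = None,
) -> dict:
    """Time one gained segment from its multiplicity counts.

    Returns the point estimate, a 95% percentile CI from ``n_boot``
    multinomial bootstrap resamples of the (n1, n2) split, and the
    eligibility flag (CI width < ``ci_width_max``; wider segments are
    excluded from burden estimation as low-confidence).
    """
    if state not in TIMEABLE_STATES:
        raise ValueError(f"state {state!r} is not timeable; expected one of {TIMEABLE_STATES}")
    n1, n2 = float(n_mult1), float(n_mult2)
    if n1 < 0 or n2 < 0 or n1 + n2 < 1:
        raise ValueError("need at least one mutation with non-negative counts")
    t_hat = float(_time_formula(np.array(n1), np.array(n2), state))
    total = n1 + n2
    rng = np.random.default_rng(seed)
    draws_n2 = rng.binomial(int(round(total)), n2 / total, size=n_boot).astype(float)
    draws_n1 = total - draws_n2
    t_boot = _time_formula(draws_n1, draws_n2, state)
    lo, hi = np.percentile(t_boot, [2.5, 97.5])
    # the point estimate can fall marginally outside the percentile interval
    lo, hi = min(lo, t_hat), max(hi, t_hat)
    return {
        "time": t_hat,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "eligible": bool(hi - lo < ci_width_max),
    }


def time_segments(
    segments: pd.DataFrame,
    n_boot: int = 200,
    ci_width_max: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Vectorised :func:`segment_time` over a segment table.

    ``segments`` needs columns chrom, start, end, major, minor, n_mult1,
    n_mult2.  Non-timeable states get NaN times and eligible=False.
    """
    rng = np.random.default_rng(seed)
    out = segments.copy()
    out["state"] = out["major"].astype(int).astype(str) + "+" + out["minor"].astype(int).astype(str)
    times, lows, highs, elig = [], [], [], []
    for _, row in out.iterrows():
        if row["state"] not in TIMEABLE_STATES or row["n_mult1"] + row["n_mult2"] < 1:
            times.append(np.nan); lows.append(np.nan); highs.append(np.nan); elig.append(False)
            continue
        res = segment_time(
            row["n_mult1"], row["n_mult2"], row["state"],
            n_boot=n_boot, ci_width_max=ci_width_max,
            seed=int(rng.integers(2**31 - 1)),
        )
        times.append(res["time"]); lows.append(res["ci_low"])
        highs.append(res["ci_high"]); elig.append(res["eligible"])
    out["time"] = times
    out["ci_low"] = lows
    out["ci_high"] = highs
    out["eligible"] = elig
    return out


# ---------------------------------------------------------------------------
# pre-duplication burden

@dataclass
class TimingEstimate:
    """Copy-number-adjusted pre-duplication burden for one sample."""

    num_pre_dup_subs: float
    num_total_subs_21_20: float
    num_total_subs_22_21_20: float
    cn_adjusted_burden: float
    covered_bases: int
    genome_wide_burden: float


def pre_dup_burden(
    timed: pd.DataFrame,
    genome_length: int = GENOME_LENGTH_AUTOSOMES,
) -> TimingEstimate | None:
    """Genome-wide pre-duplication substitution burden.

    Sums multiplicity-2 substitutions over eligible 2+0/2+1/2+2 segments,
    applies the copy-number-configuration adjustment (pre-duplication
    mutations on the minor allele of 2+0/2+1 segments are invisible), and
    extrapolates by covered length.  Returns ``None`` when no segment is
    eligible.
    """
    if "state" not in timed.columns:
        timed = timed.assign(
            state=timed["major"].astype(int).astype(str) + "+" + timed["minor"].astype(int).astype(str)
        )
    elig = timed[timed["eligible"] & timed["state"].isin(TIMEABLE_STATES)]
    if len(elig) == 0:
        return None
    n_pre = float(elig["n_mult2"].sum())
    totals = elig["n_mult1"] + elig["n_mult2"]
    in_21_20 = elig["state"].isin(("2+1", "2+0"))
    n_21_20 = float(totals[in_21_20].sum())
    n_all = float(totals.sum())
    adjusted = n_pre + n_pre * (n_21_20 / n_all) if n_all > 0 else n_pre
    covered = int((elig["end"] - elig["start"] + 1).sum())
    genome_wide = adjusted * genome_length / covered if covered > 0 else float("nan")
    return TimingEstimate(
        num_pre_dup_subs=n_pre,
        num_total_subs_21_20=n_21_20,
        num_total_subs_22_21_20=n_all,
        cn_adjusted_burden=adjusted,
        covered_bases=covered,
        genome_wide_burden=genome_wide,
    )


# ---------------------------------------------------------------------------
# WGD classification and cell divisions

def classify_wgd(profile: SampleProfile) -> bool:
    """Whole-genome duplication call: ``ploidy >= 2.9 - 2 * homozygous_fraction``."""
    return profile.ploidy >= 2.9 - 2.0 * profile.homozygous_fraction


def cell_divisions(
    genome_wide_burden: float,
    rate_per_haploid: tuple[float, float] = (0.5, 0.7),
) -> dict:
    """Convert a pre-duplication burden to primordial-germ-cell divisions.

    The published 0.5-0.7 substitutions per haploid genome per division is
    doubled to a per-diploid-genome rate; the point estimate divides by
    twice the midpoint and is rounded to the nearest integer.
    """
    lo_rate, hi_rate = rate_per_haploid
    if lo_rate <= 0 or hi_rate <= 0:
        raise ValueError("substitution rates must be positive")
    if genome_wide_burden < 0:
        raise ValueError("burden must be non-negative")
    mid = (lo_rate + hi_rate) / 2
    point = genome_wide_burden / (2 * mid)
    return {
        "divisions": int(round(point)),
        "point": point,
        "range": (genome_wide_burden / (2 * hi_rate), genome_wide_burden / (2 * lo_rate)),
    }


# ---------------------------------------------------------------------------
# burden-vs-age asymptotic regression

@dataclass
class AgeCurve:
    """Asymptotic regression ``burden = a + b * exp(c * age)`` (c < 0 for decay)."""

    a: float
    b: float
    c: float
    degenerate: bool = False

    def predict(self, ages) -> np.ndarray:
        return self.a + self.b * np.exp(self.c * np.asarray(ages, dtype=float))


def _profile_rss(c: float, ages: np.ndarray, burdens: np.ndarray):
    X = np.column_stack([np.ones_like(ages), np.exp(c * ages)])
    coef, *_ = np.linalg.lstsq(X, burdens, rcond=None)
    resid = burdens - X @ coef
    return float(resid @ resid), coef


def fit_age_curve(ages, burdens) -> AgeCurve:
    """Least-squares fit of ``a + b * exp(c * age)``.

    For fixed rate constant c the model is linear in (a, b), so the fit
    profiles the residual sum of squares over c on a log-spaced grid and
    polishes the best grid point with bounded scalar minimisation.  The fit
    is deterministic.  Constant burdens give the degenerate solution
    ``a = mean, b = 0``.
    """
    ages = np.asarray(ages, dtype=float)
    burdens = np.asarray(burdens, dtype=float)
    if ages.size < 4:
        raise ValueError("need at least 4 points")
    if np.unique(ages).size < 3:
        raise ValueError("need at least 3 distinct ages")
    if np.allclose(burdens, burdens[0]):
        return AgeCurve(a=float(burdens.mean()), b=0.0, c=0.0, degenerate=True)

    grid = -np.logspace(-4, 1, 60)  # decay constants from -1e-4 to -10
    rss = np.array([_profile_rss(c, ages, burdens)[0] for c in grid])
    best = int(np.argmin(rss))
    lo = grid[min(best + 1, len(grid) - 1)]
    hi = grid[max(best - 1, 0)]
    if lo == hi:
        c_opt = grid[best]
    else:
        res = optimize.minimize_scalar(
            lambda c: _profile_rss(c, ages, burdens)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        c_opt = float(res.x)
    _, coef = _profile_rss(c_opt, ages, burdens)
    return AgeCurve(a=float(coef[0]), b=float(coef[1]), c=c_opt)


# ---------------------------------------------------------------------------
# focal driver heuristics

def classify_focal_events(
    segments: pd.DataFrame,
    average_ploidy: float,
    gene_annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Focal amplification/deletion heuristics over a segment table.

    Amplification: segment span < 1 Mb and a minimum of 5 intact copies
    when ploidy < 2.7, 9 otherwise.  Deletion:
    same span cut-off with total CN of 0 or < ploidy - 2.7.  Segments of
    1-10 Mb carrying the copy minimum are tiered ``gain`` rather than
    ``amplification``.  Genes overlapping qualifying segments are listed
    when an annotation table (gene, chrom, start, end) is supplied.
    """
    min_gain = 5 if average_ploidy < 2.7 else 9
    rows = []
    for _, seg in segments.iterrows():
        span = seg["end"] - seg["start"] + 1
        total_cn = seg["major"] + seg["minor"]
        call = None
        if span < 1e6 and total_cn >= min_gain:
            call = "amplification"
        elif 1e6 <= span <= 10e6 and total_cn >= min_gain:
            call = "gain"
        elif span < 1e6 and (total_cn == 0 or total_cn < average_ploidy - 2.7):
            call = "deletion"
        if call is None:
            continue
        genes = ""
        if gene_annotations is not None:
            hit = gene_annotations[
                (gene_annotations["chrom"] == seg["chrom"])
                & (gene_annotations["end"] >= seg["start"])
                & (gene_annotations["start"] <= seg["end"])
            ]
            genes = ",".join(hit["gene"])
        rows.append({
            "chrom": seg["chrom"], "start": seg["start"], "end": seg["end"],
            "total_cn": total_cn, "call": call, "genes": genes,
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "total_cn", "call", "genes"])
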