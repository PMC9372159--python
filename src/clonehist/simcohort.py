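"""Synthetic multi-region germ-cell-tumour cohorts with known ground truth.

The simulator emulates the statistical structure of a microdissection
cohort: near-monoclonal biopsies (major-clone CCF ~= 0.96), a truncal
whole-genome duplication at a configurable mutation time (early for the
postpubertal regime, late for the prepubertal one), allele-specific
copy-number segments drawn from post-WGD configurations (2+2, 2+1, 2+0,
3+2 and 1+1 equivalents), subclone clusters shared across spatially
patched biopsies of mixed histology, sequencing depth in the 15-48x range,
histology-specific expression programs with a 12p dosage effect, and
trinucleotide channels drawn from a signature mixture that includes an
A[C>G]G-peaked component.

The generative model for read counts is the same one the inference
modules invert: a mutation of multiplicity m and cancer cell fraction CCF
on a segment of total copy number CNt in a biopsy of purity rho has
expected VAF ``m * rho * CCF / (rho * CNt + 2 * (1 - rho))``; alt reads
are binomial at that VAF with Poisson totals scaled by the local copy
number.  Truncal mutations before the WGD time sit on duplicated alleles
with multiplicity 2 (or are lost with the deleted allele of 2+0
segments); later mutations have multiplicity 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .readfilter import PanelCounts, SampleProfile
from .sigfit import CHANNELS, toy_catalogue

#: simplified karyotype: 22 autosomes of ~130 Mb, two arms each (p 40%, q 60%)
CHROM_LENGTH = 130_000_000
ARM_SPLIT = 0.4

DEFAULT_SEGMENT_STATES = {"2+2": 0.40, "2+1": 0.25, "2+0": 0.15, "3+2": 0.10, "1+1": 0.10}
DEFAULT_SIGNATURE_MIX = {"SBS5like": 0.65, "SBS1like": 0.25, "SBS18like": 0.10}

MAJOR_CLONE_CCF = 0.96


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``mutation_rate`` is the expected number of truncal substitutions per
    chromosome copy per unit of mutation time; the expected truncal total
    is ``rate * (2 * wgd_time + mean_cn * (1 - wgd_time))`` because the
    genome is diploid before the duplication and carries ``mean_cn`` copies
    afterwards.  ``wgd_time`` is the mutation-time fraction in [0, 1) at
    which the duplication occurs (small for postpubertal tumours, large
    for prepubertal ones).
    """

    n_patients: int = 1
    ages: tuple = (27,)
    wgd_time: tuple = (0.1,)
    n_biopsies: int = 4
    histologies: tuple = ("embryonal carcinoma", "yolk sac tumour", "teratoma")
    depth: float = 30.0
    purity: float = 0.95
    n_clusters: int = 3
    mutation_rate: float = 1000.0
    subclone_mutations: float = 150.0
    subclone_ccf: float = MAJOR_CLONE_CCF
    signature_mix: dict = field(default_factory=lambda: dict(DEFAULT_SIGNATURE_MIX))
    segment_states: dict = field(default_factory=lambda: dict(DEFAULT_SEGMENT_STATES))
    dosage_arm: str = "12p"
    dosage_multiplier: float = 1.8
    n_genes: int = 2000
    n_normal_tubules: int = 4
    histology_program_size: int = 400
    histology_fold: float = 3.0
    expression_dispersion: float = 0.2
    library_size: float = 300_000.0
    normal_error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_biopsies < 1:
            raise ValueError("n_biopsies must be >= 1")
        if len(self.ages) != self.n_patients:
            raise ValueError("ages must have one entry per patient")
        if len(self.wgd_time) != self.n_patients:
            raise ValueError("wgd_time must have one entry per patient")
        for t in self.wgd_time:
            if not (0 <= t < 1):
                raise ValueError("wgd_time entries must lie in [0, 1)")
        if not (0 < self.purity <= 1):
            raise ValueError("purity must lie in (0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        total = sum(self.signature_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("signature_mix weights must sum to 1")

    def patient_ids(self) -> list:
        return [f"PD{1000 + i}" for i in range(self.n_patients)]


@dataclass
class GroundTruth:
    """Everything the simulator knows that inference must recover."""

    mutations: pd.DataFrame      # patient, chrom, pos, cluster, time, pre_dup, lost, multiplicity, state, channel
    tree_edges: pd.DataFrame     # patient, child, parent
    cluster_ccfs: pd.DataFrame   # patient, cluster, biopsy, ccf
    expression: pd.DataFrame     # gene, histology, log2fc, on_dosage_arm
    profiles: dict               # biopsy -> SampleProfile

    def pre_dup_count(self, patient: str) -> int:
        """Planted genome-wide pre-duplication substitutions (lost ones included)."""
        m = self.mutations
        return int(((m["patient"] == patient) & m["pre_dup"]).sum())


@dataclass
class SimulatedCohort:
    calls: pd.DataFrame          # per-mutation per-biopsy read counts (wide)
    segments: pd.DataFrame       # sample, chrom, start, end, major, minor, frac
    expression: "object"         # dosagexpr.ExpressionStudy
    truth: GroundTruth
    config: CohortConfig


def _arm_table() -> pd.DataFrame:
    rows = []
    for c in range(1, 23):
        split = int(CHROM_LENGTH * ARM_SPLIT)
        rows.append({"chrom": str(c), "arm": f"{c}p", "start": 1, "end": split})
        rows.append({"chrom": str(c), "arm": f"{c}q", "start": split + 1, "end": CHROM_LENGTH})
    return pd.DataFrame(rows)


def _draw_segments(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    arms = _arm_table()
    states = list(cfg.segment_states)
    weights = np.array([cfg.segment_states[s] for s in states], dtype=float)
    weights /= weights.sum()
    chosen = rng.choice(len(states), size=len(arms), p=weights)
    segs = arms.copy()
    segs["state"] = [states[i] for i in chosen]
    if cfg.dosage_arm in set(segs["arm"]):
        # the dosage arm is constitutively gained (isochromosome-like)
        segs.loc[segs["arm"] == cfg.dosage_arm, "state"] = "3+2"
    segs["major"] = segs["state"].str.split("+").str[0].astype(int)
    segs["minor"] = segs["state"].str.split("+").str[1].astype(int)
    segs["total_cn"] = segs["major"] + segs["minor"]
    segs["length"] = segs["end"] - segs["start"] + 1
    return segs


def _random_tree(n_clusters: int, rng: np.random.Generator) -> dict:
    """Random rooted topology over subclone ids 1..n (0 is the trunk)."""
    parent = {}
    for k in range(1, n_clusters + 1):
        # bias towards shallow trees: half the subclones hang off the trunk
        choices = [0] + list(range(1, k))
        w = np.ones(len(choices))
        w[0] = max(1.0, len(choices) - 1)
        parent[k] = int(rng.choice(choices, p=w / w.sum()))
    return parent


def _cluster_ccfs(cfg: CohortConfig, parent: dict, rng: np.random.Generator) -> np.ndarray:
    """CCF per cluster (rows, 0=trunk) per biopsy: near-monoclonal patches.

    Each biopsy is a patch dominated by one subclone; every cluster on the
    path trunk -> major clone carries the major-clone CCF, others are
    absent.  Subclones cycle through biopsies so each is the major clone
    somewhere (patched spatial structure without explicit geometry).
    """
    n_nodes = cfg.n_clusters + 1
    ccf = np.zeros((n_nodes, cfg.n_biopsies))
    majors = []
    nodes = list(range(1, n_nodes)) or [0]
    for b in range(cfg.n_biopsies):
        majors.append(nodes[b % len(nodes)])
    for b, major in enumerate(majors):
        node = major
        while True:
            ccf[node, b] = cfg.subclone_ccf if node != 0 else MAJOR_CLONE_CCF
            if node == 0:
                break
            node = parent[node]
    ccf[0, :] = MAJOR_CLONE_CCF
    return ccf


_PYR = {"C": ("A", "G", "T"), "T": ("A", "C", "G")}


def _channel_bases(channel: str) -> tuple[str, str]:
    # "A[C>G]T" -> ref C, alt G
    return channel[2], channel[4]


def _simulate_patient_mutations(cfg, patient, t_w, segs, parent, ccf, rng, sig_probs):
    """Draw mutations for one patient; returns (calls rows, truth rows)."""
    mean_cn = float((segs["total_cn"] * segs["length"]).sum() / segs["length"].sum())
    expected_trunk = cfg.mutation_rate * (2 * t_w + mean_cn * (1 - t_w))
    n_trunk = rng.poisson(expected_trunk)
    n_sub = rng.poisson(cfg.subclone_mutations, size=cfg.n_clusters)

    lengths = segs["length"].to_numpy(dtype=float)
    cn = segs["total_cn"].to_numpy(dtype=float)
    p_len = lengths / lengths.sum()
    p_cn = lengths * cn / (lengths * cn).sum()

    rows = []
    p_pre = 2 * t_w / (2 * t_w + mean_cn * (1 - t_w)) if n_trunk else 0.0
    pre_flags = rng.random(n_trunk) < p_pre
    for pre in pre_flags:
        seg_i = int(rng.choice(len(segs), p=p_len if pre else p_cn))
        state = segs.loc[seg_i, "state"]
        time = rng.uniform(0, t_w) if pre else rng.uniform(t_w, 1.0)
        lost = False
        if pre:
            allele_major = rng.random() < 0.5
            if state == "2+2":
                mult = 2
            elif state == "2+1":
                mult = 2 if allele_major else 1
            elif state == "2+0":
                mult = 2 if allele_major else 0
                lost = not allele_major
            elif state == "3+2":
                mult = 3 if allele_major else 2
            else:  # 1+1 equivalent after post-WGD losses
                mult = 1
        else:
            mult = 1
        rows.append((seg_i, 0, time, bool(pre), lost, mult))
    for k in range(cfg.n_clusters):
        for _ in range(n_sub[k]):
            seg_i = int(rng.choice(len(segs), p=p_cn))
            rows.append((seg_i, k + 1, rng.uniform(t_w, 1.0), False, False, 1))

    n = len(rows)
    channels = rng.choice(len(CHANNELS), size=n, p=sig_probs)
    calls = []
    truths = []
    seg_starts = segs["start"].to_numpy()
    seg_ends = segs["end"].to_numpy()
    seg_chrom = segs["chrom"].to_numpy()
    psi = cfg.purity * mean_cn + 2 * (1 - cfg.purity)
    biopsies = [f"{patient}_b{j}" for j in range(cfg.n_biopsies)]
    for (seg_i, cluster, time, pre, lost, mult), ch_i in zip(rows, channels):
        pos = int(rng.integers(seg_starts[seg_i], seg_ends[seg_i] + 1))
        channel = CHANNELS[ch_i]
        ref, alt_base = _channel_bases(channel)
        cnt = float(cn[seg_i])
        rec = {
            "patient": patient, "chrom": seg_chrom[seg_i], "pos": pos,
            "ref": ref, "alt": alt_base, "channel": channel,
            "total_cn": int(cnt), "state": segs.loc[seg_i, "state"],
        }
        local = cfg.purity * cnt + 2 * (1 - cfg.purity)
        for b, name in enumerate(biopsies):
            f = ccf[cluster, b]
            vaf = mult * cfg.purity * f / local if mult > 0 else 0.0
            tot = rng.poisson(cfg.depth * local / psi)
            a = rng.binomial(tot, min(vaf, 1.0)) if tot > 0 else 0
            rec[f"alt_{name}"] = int(a)
            rec[f"tot_{name}"] = int(tot)
        tot_n = rng.poisson(cfg.depth)
        rec["alt_normal"] = int(rng.binomial(tot_n, cfg.normal_error_rate)) if tot_n else 0
        rec["tot_normal"] = int(tot_n)
        calls.append(rec)
        truths.append({
            "patient": patient, "chrom": seg_chrom[seg_i], "pos": pos,
            "cluster": cluster, "time": time, "pre_dup": pre, "lost": lost,
            "multiplicity": mult, "state": segs.loc[seg_i, "state"], "channel": channel,
        })
    return calls, truths, biopsies, mean_cn


def _simulate_expression(cfg: CohortConfig, rng: np.random.Generator,
                         biopsy_meta: pd.DataFrame, arm_of_gene, genes: pd.DataFrame):
    from .dosagexpr import ExpressionStudy

    n_genes = len(genes)
    base = rng.lognormal(mean=1.0, sigma=1.2, size=n_genes)
    histologies = sorted(set(biopsy_meta["histology"]))
    programs = {}
    for h in histologies:
        chosen = rng.choice(n_genes, size=min(cfg.histology_program_size, n_genes), replace=False)
        programs[h] = set(chosen.tolist())
    fold_rows = []
    counts = {}
    shape = 1.0 / cfg.expression_dispersion
    on_dosage = (arm_of_gene == cfg.dosage_arm).to_numpy()
    for biopsy, meta in biopsy_meta.iterrows():
        mean = base.copy()
        prog = programs[meta["histology"]]
        idx = np.fromiter(prog, dtype=int)
        mean[idx] *= cfg.histology_fold
        if not meta["is_normal_tubule"]:
            mean[on_dosage] *= cfg.dosage_multiplier
        rel = mean / mean.sum()
        lam = cfg.library_size * rel * rng.gamma(shape, 1.0 / shape, size=n_genes)
        counts[biopsy] = rng.poisson(lam)
    for h in histologies:
        flags = np.zeros(n_genes, dtype=bool)
        flags[np.fromiter(programs[h], dtype=int)] = True
        fold_rows.append(pd.DataFrame({
            "gene": genes["gene"], "histology": h,
            "log2fc": np.where(flags, np.log2(cfg.histology_fold), 0.0),
            "on_dosage_arm": on_dosage,
        }))
    counts_df = pd.DataFrame(counts, index=genes["gene"])
    study = ExpressionStudy(counts_df, genes, biopsy_meta)
    return study, pd.concat(fold_rows, ignore_index=True)


def _gene_annotation(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    arms = _arm_table()
    arm_idx = rng.integers(0, len(arms), size=cfg.n_genes)
    starts = []
    for i in arm_idx:
        a = arms.iloc[int(i)]
        starts.append(int(rng.integers(a["start"], a["end"] - 10_000)))
    lengths = np.maximum(200, rng.lognormal(7.5, 0.6, size=cfg.n_genes)).astype(int)
    biotype = np.where(rng.random(cfg.n_genes) < 0.9, "protein_coding", "lincRNA")
    exclusion = np.where(rng.random(cfg.n_genes) < 0.05, "housekeeping", "")
    genes = pd.DataFrame({
        "gene": [f"G{i:05d}" for i in range(cfg.n_genes)],
        "chrom": arms.iloc[arm_idx]["chrom"].to_numpy(),
        "start": starts,
        "end": np.array(starts) + lengths,
        "strand": np.where(rng.random(cfg.n_genes) < 0.5, "+", "-"),
        "cytoband": arms.iloc[arm_idx]["arm"].to_numpy(),
        "biotype": biotype,
        "exclusion_set": exclusion,
        "length": lengths,
    })
    return genes


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort (DNA calls, segments, RNA, truth).

    Identical config and seed give identical output.  See the module
    docstring for the generative model.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    catalogue = toy_catalogue()
    missing = set(cfg.signature_mix) - set(catalogue.names)
    if missing:
        raise ValueError(f"signature_mix names not in the bundled catalogue: {sorted(missing)}")
    sig_probs = np.zeros(96)
    for name, w in cfg.signature_mix.items():
        sig_probs += w * catalogue.signatures[name].to_numpy()
    sig_probs = sig_probs / sig_probs.sum()

    all_calls, all_truth, all_segments = [], [], []
    edges, ccf_rows = [], []
    profiles: dict[str, SampleProfile] = {}
    biopsy_meta_rows = []

    for p_i, patient in enumerate(cfg.patient_ids()):
        prng = np.random.default_rng(rng.integers(2**31 - 1))
        segs = _draw_segments(cfg, prng)
        parent = _random_tree(cfg.n_clusters, prng)
        ccf = _cluster_ccfs(cfg, parent, prng)
        calls, truths, biopsies, mean_cn = _simulate_patient_mutations(
            cfg, patient, cfg.wgd_time[p_i], segs, parent, ccf, prng, sig_probs
        )
        all_calls.extend(calls)
        all_truth.extend(truths)
        hom_frac = float(segs.loc[segs["minor"] == 0, "length"].sum() / segs["length"].sum())
        for b, name in enumerate(biopsies):
            seg_out = segs[["chrom", "start", "end", "major", "minor"]].copy()
            seg_out.insert(0, "sample", name)
            seg_out["frac"] = 1.0
            all_segments.append(seg_out)
            profiles[name] = SampleProfile(
                purity=cfg.purity, ploidy=mean_cn,
                tumour_coverage=cfg.depth, homozygous_fraction=hom_frac,
            )
            hist = cfg.histologies[b % len(cfg.histologies)]
            biopsy_meta_rows.append({
                "biopsy": name, "patient": patient, "histology": hist,
                "is_normal_tubule": False,
            })
        edges.append({"patient": patient, "child": 0, "parent": -1})
        for child, par in parent.items():
            edges.append({"patient": patient, "child": child, "parent": par})
        for k in range(cfg.n_clusters + 1):
            for b, name in enumerate(biopsies):
                ccf_rows.append({"patient": patient, "cluster": k, "biopsy": name,
                                 "ccf": float(ccf[k, b])})

    for j in range(cfg.n_normal_tubules):
        biopsy_meta_rows.append({
            "biopsy": f"NT_b{j}", "patient": "normal", "histology": "seminiferous tubule",
            "is_normal_tubule": True,
        })

    call_cols = ["patient", "chrom", "pos", "ref", "alt", "channel", "total_cn", "state"]
    calls_df = pd.DataFrame(all_calls)
    if len(calls_df):
        count_cols = [c for c in calls_df.columns if c.startswith(("alt_", "tot_"))]
        calls_df = calls_df[call_cols + count_cols]
        calls_df = calls_df.fillna({c: 0 for c in count_cols})
        for c in count_cols:
            calls_df[c] = calls_df[c].astype(int)
    else:
        calls_df = pd.DataFrame(columns=call_cols)
    truth_df = pd.DataFrame(all_truth, columns=[
        "patient", "chrom", "pos", "cluster", "time", "pre_dup", "lost",
        "multiplicity", "state", "channel",
    ])

    meta = pd.DataFrame(biopsy_meta_rows).set_index("biopsy")
    genes = _gene_annotation(cfg, np.random.default_rng(rng.integers(2**31 - 1)))
    study, fold_df = _simulate_expression(
        cfg, np.random.default_rng(rng.integers(2**31 - 1)), meta,
        genes["cytoband"], genes,
    )

    truth = GroundTruth(
        mutations=truth_df,
        tree_edges=pd.DataFrame(edges, columns=["patient", "child", "parent"]),
        cluster_ccfs=pd.DataFrame(ccf_rows, columns=["patient", "cluster", "biopsy", "ccf"]),
        expression=fold_df,
        profiles=profiles,
    )
    segments_df = (pd.concat(all_segments, ignore_index=True)
                   if all_segments else
                   pd.DataFrame(columns=["sample", "chrom", "start", "end", "major", "minor", "frac"]))
    return SimulatedCohort(calls_df, segments_df, study, truth, cfg)


def simulate_panel(
    n_samples: int = 250,
    depth: float = 30.0,
    error_rate: float = 1e-3,
    n_sites: int = 1000,
    seed: int = 0,
    overdispersion: float = 1e-2,
) -> PanelCounts:
    """Unmatched normal panel: beta-binomial alt counts at Poisson depths.

    ``error_rate`` is the per-site mean alt fraction, ``overdispersion``
    the beta-binomial rho.  ``error_rate = 0`` gives an all-zero panel.
    """
    if n_samples < 2:
        raise ValueError("panel needs n_samples >= 2")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    total = rng.poisson(depth, size=(n_sites, n_samples))
    if error_rate == 0:
        alt = np.zeros_like(total)
    else:
        a = error_rate * (1 - overdispersion) / overdispersion
        b = (1 - error_rate) * (1 - overdispersion) / overdispersion
        p = rng.beta(a, b, size=total.shape)
        alt = rng.binomial(total, p)
    return PanelCounts(alt=alt, total=total)
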