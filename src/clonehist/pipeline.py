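"""End-to-end orchestration of the analysis stages on cohort data.

The pipeline chains the stages in dependency order — simulate (or load),
variant rescue, clone tree, copy-number timing, similarity tests, dosage
expression, signatures — with a single global seed that is hashed per
stage so any stage can be reproduced in isolation.  Every output TSV
carries a provenance header (# version, seed, config hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, clonetree, dosagexpr, gaintiming, histosim, readfilter, sigfit
from .io import write_fixtures
from .simcohort import CohortConfig, simulate_cohort, simulate_panel

log = logging.getLogger("clonehist")

STAGES = ("simulate", "filter", "tree", "time", "similarity", "dosage", "signatures")


@dataclass
class RunConfig:
    """Pipeline configuration.

    Threshold defaults equal the published analysis values: alignment
    score >= 140, BH-adjusted p < 0.001 for presence, CCF > 0.1 presence,
    cluster filters < 1% / < 20 substitutions, CI width < 0.5 timing
    eligibility, WGD rule 2.9 - 2h, near-baseline +/- 0.5, 50-gene rolling
    window, 100,000 dosage draws, 1000 label swaps, >= 5 reads expressed,
    < 1000 expressed features library exclusion.
    """

    out_dir: str = "clonehist_out"
    seed: int = 0
    stages: tuple = STAGES
    sim: CohortConfig | None = None
    # thresholds (paper defaults)
    rescue_alpha: float = 0.001
    presence_ccf: float = 0.1
    cluster_min_fraction: float = 0.01
    cluster_min_count: int = 20
    ci_width_max: float = 0.5
    near_baseline: float = 0.5
    rolling_window: int = 50
    dosage_draws: int = 100_000
    n_perm: int = 1000
    expressed_min_reads: int = 5
    min_features: int = 1000
    # scale knobs
    gibbs_iters: int = 600
    gibbs_burnin: int = 150
    n_boot: int = 200
    panel_samples: int = 60
    panel_sites: int = 200

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # a location, not an analysis parameter
        if self.sim is not None:
            payload["sim"] = dataclasses.asdict(self.sim)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (zlib.crc32(stage.encode()) ^ (seed & 0x7FFFFFFF)) % (2**31 - 1)


def _provenance(cfg: RunConfig) -> str:
    return (f"# clonehist v{__version__} seed={cfg.seed} "
            f"config={cfg.config_hash()}\n")


def _write(cfg: RunConfig, name: str, frame: pd.DataFrame, index: bool = False) -> str:
    path = os.path.join(cfg.out_dir, name)
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        frame.to_csv(fh, sep="\t", index=index)
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages; returns a report dict of stage outputs.

    A stage failure is recorded and halts its downstream dependents while
    independent stages still run; partial results are reported.
    """
    cfg = config
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {"outputs": {}, "errors": {}, "summary": {}}

    sim_cfg = cfg.sim or CohortConfig(seed=stage_seed(cfg.seed, "simulate"))
    cohort = simulate_cohort(sim_cfg)
    panel = simulate_panel(
        n_samples=cfg.panel_samples, n_sites=cfg.panel_sites,
        seed=stage_seed(cfg.seed, "panel"),
    )
    if "simulate" in cfg.stages:
        paths = write_fixtures(cohort, os.path.join(cfg.out_dir, "fixtures"), panel=panel)
        report["outputs"]["simulate"] = paths
        log.info("simulated %d mutations across %d patients",
                 len(cohort.calls), cohort.config.n_patients)

    presence = None
    if "filter" in cfg.stages:
        try:
            presence = _stage_filter(cfg, cohort, panel, report)
        except Exception as exc:  # pragma: no cover - defensive
            report["errors"]["filter"] = str(exc)

    trees = {}
    if "tree" in cfg.stages and "filter" not in report["errors"]:
        try:
            trees = _stage_tree(cfg, cohort, report)
        except Exception as exc:
            report["errors"]["tree"] = f"{type(exc).__name__}: {exc}"
    if "time" in cfg.stages:
        try:
            _stage_time(cfg, cohort, report)
        except Exception as exc:
            report["errors"]["time"] = f"{type(exc).__name__}: {exc}"
    if "similarity" in cfg.stages and trees:
        try:
            _stage_similarity(cfg, cohort, trees, report)
        except Exception as exc:
            report["errors"]["similarity"] = f"{type(exc).__name__}: {exc}"
    if "dosage" in cfg.stages:
        try:
            _stage_dosage(cfg, cohort, report)
        except Exception as exc:
            report["errors"]["dosage"] = f"{type(exc).__name__}: {exc}"
    if "signatures" in cfg.stages:
        try:
            _stage_signatures(cfg, cohort, report)
        except Exception as exc:
            report["errors"]["signatures"] = f"{type(exc).__name__}: {exc}"
    return report


def _count_cols(calls: pd.DataFrame, patient: str, n_biopsies: int):
    biopsies = [f"{patient}_b{j}" for j in range(n_biopsies)]
    alt = calls[[f"alt_{b}" for b in biopsies]].to_numpy()
    tot = calls[[f"tot_{b}" for b in biopsies]].to_numpy()
    return biopsies, alt, tot


def _stage_filter(cfg: RunConfig, cohort, panel, report) -> dict:
    model = readfilter.fit_panel_error(panel)
    out = {}
    rows = []
    for patient in cohort.config.patient_ids():
        sub = cohort.calls[cohort.calls["patient"] == patient]
        if len(sub) == 0:
            continue
        biopsies, alt, tot = _count_cols(sub, patient, cohort.config.n_biopsies)
        keep = readfilter.pileup_rescue(tot)
        # site error rates for cohort loci: use the panel's pooled baseline
        mu = np.full(int(keep.sum()), float(np.median(model.mu)))
        site_model = readfilter.PanelErrorModel(mu=mu, rho=model.rho)
        res = readfilter.betabinom_rescue(
            alt[keep], tot[keep], site_model, alpha=cfg.rescue_alpha
        )
        n_present = int(res["present"].any(axis=1).sum())
        rows.append({"patient": patient, "n_input": len(sub),
                     "n_after_pileup": int(keep.sum()), "n_present": n_present})
        out[patient] = {"keep": keep, "present": res["present"]}
        log.info("%s: %d sites in, %d past pileup, %d called present",
                 patient, len(sub), int(keep.sum()), n_present)
    report["outputs"]["filter"] = _write(cfg, "filter_report.tsv", pd.DataFrame(rows))
    return out


def _multiplicities(sub: pd.DataFrame, alt, tot, purity) -> np.ndarray:
    # reads pooled across biopsies: the clonal copy state is shared, and the
    # pooled depth makes the multiplicity call far more reliable than any
    # single low-depth biopsy could
    cnt = sub["total_cn"].to_numpy()
    pooled = gaintiming.assign_multiplicity(
        alt.sum(axis=1), tot.sum(axis=1), purity, cnt
    )
    return np.broadcast_to(np.maximum(pooled, 1)[:, None], alt.shape)


def _stage_tree(cfg: RunConfig, cohort, report) -> dict:
    trees = {}
    rows = []
    for patient in cohort.config.patient_ids():
        sub = cohort.calls[cohort.calls["patient"] == patient]
        if len(sub) == 0:
            continue
        biopsies, alt, tot = _count_cols(sub, patient, cohort.config.n_biopsies)
        purity = np.full(len(biopsies), cohort.config.purity)
        mult = _multiplicities(sub, alt, tot, cohort.config.purity)
        cnt = np.broadcast_to(sub["total_cn"].to_numpy()[:, None], alt.shape)
        res = clonetree.cluster_ccf(
            alt, tot, purity, cnt, mult,
            iters=cfg.gibbs_iters, burnin=cfg.gibbs_burnin,
            seed=stage_seed(cfg.seed, f"tree:{patient}"),
            biopsies=biopsies, chrom=sub["chrom"].to_numpy(),
        )
        kept, _ = clonetree.filter_clusters(
            res.clusters, res.assignments,
            min_fraction=cfg.cluster_min_fraction, min_count=cfg.cluster_min_count,
        )
        tree = clonetree.build_tree(kept, presence_ccf=cfg.presence_ccf)
        violators = tree.flagged_small_violators()
        if violators:
            kept, _ = clonetree.filter_clusters(kept, violating=violators,
                                                min_fraction=0, min_count=0)
            tree = clonetree.build_tree(kept, presence_ccf=cfg.presence_ccf)
        trees[patient] = tree
        prop = clonetree.trunk_proportion(tree) if not tree.is_forest else np.nan
        rows.append({"patient": patient, "n_clusters": len(kept),
                     "trunk_subs": tree.n_subs(tree.trunk) if not tree.is_forest else 0,
                     "trunk_proportion": prop})
        with open(os.path.join(cfg.out_dir, f"{patient}.nwk"), "w") as fh:
            if not tree.is_forest:
                fh.write(tree.to_newick() + "\n")
    report["outputs"]["tree"] = _write(cfg, "tree_report.tsv", pd.DataFrame(rows))
    return trees


def _stage_time(cfg: RunConfig, cohort, report) -> None:
    rows = []
    ages, burdens = [], []
    for p_i, patient in enumerate(cohort.config.patient_ids()):
        sub = cohort.calls[cohort.calls["patient"] == patient]
        if len(sub) == 0:
            continue
        biopsies, alt, tot = _count_cols(sub, patient, cohort.config.n_biopsies)
        profile = cohort.truth.profiles[biopsies[0]]
        if readfilter.reads_per_copy(profile) < readfilter.TIMING_MIN_READS_PER_COPY:
            log.info("%s below timing coverage eligibility", patient)
        est = timing_from_calls(
            sub, alt[:, 0], tot[:, 0], cohort.segments, biopsies[0],
            purity=profile.purity, n_boot=cfg.n_boot,
            ci_width_max=cfg.ci_width_max,
            seed=stage_seed(cfg.seed, f"time:{patient}"),
        )
        if est is None:
            continue
        conv = gaintiming.cell_divisions(est.genome_wide_burden)
        rows.append({
            "patient": patient, "age": cohort.config.ages[p_i],
            "wgd": gaintiming.classify_wgd(profile),
            "pre_dup_raw": est.num_pre_dup_subs,
            "cn_adjusted": est.cn_adjusted_burden,
            "genome_wide": est.genome_wide_burden,
            "divisions": conv["divisions"],
        })
        ages.append(cohort.config.ages[p_i])
        burdens.append(est.genome_wide_burden)
    report["outputs"]["time"] = _write(cfg, "timing_report.tsv", pd.DataFrame(rows))
    if len(ages) >= 4 and len(set(ages)) >= 3:
        curve = gaintiming.fit_age_curve(ages, burdens)
        report["summary"]["age_curve"] = (curve.a, curve.b, curve.c)


def timing_from_calls(
    calls: pd.DataFrame,
    alt: np.ndarray,
    tot: np.ndarray,
    segments: pd.DataFrame,
    sample: str,
    purity: float,
    n_boot: int = 200,
    ci_width_max: float = 0.5,
    seed: int | None = None,
    genome_length: int | None = None,
    soft: bool = True,
):
    """Per-segment multiplicity counts -> timed segments -> burden estimate.

    Aggregates one biopsy's clonal substitutions per copy-number segment,
    estimates the (n1, n2) multiplicity split (EM mixture by default, hard
    maximum-likelihood assignment with ``soft=False``), times each 2+0 /
    2+1 / 2+2 segment and returns the :class:`~clonehist.gaintiming.TimingEstimate`.
    """
    segs = segments[segments["sample"] == sample]
    seg_data = []
    for _, seg in segs.iterrows():
        in_seg = (
            (calls["chrom"].astype(str) == str(seg["chrom"]))
            & (calls["pos"] >= seg["start"])
            & (calls["pos"] <= seg["end"])
        ).to_numpy()
        # only substitutions actually supported in this sample are timed
        # (cohort-level call sets carry sites private to other biopsies)
        in_seg &= alt > 0
        if in_seg.sum() == 0:
            continue
        seg_data.append((seg, alt[in_seg], tot[in_seg]))
    ccf_scale = 1.0
    if soft and seg_data:
        timeable = [
            (a, t, seg["major"] + seg["minor"])
            for seg, a, t in seg_data
            if f"{int(seg['major'])}+{int(seg['minor'])}" in gaintiming.TIMEABLE_STATES
        ]
        if timeable:
            ccf_scale = gaintiming.fit_clonal_scale(timeable, purity)
    seg_rows = []
    for seg, a, t in seg_data:
        cnt = seg["major"] + seg["minor"]
        if soft:
            n1, n2 = gaintiming.soft_multiplicity_counts(a, t, purity, cnt, ccf=ccf_scale)
        else:
            m = gaintiming.assign_multiplicity(a, t, purity, cnt)
            n1, n2 = float((m == 1).sum()), float((m == 2).sum())
        seg_rows.append({
            "chrom": seg["chrom"], "start": seg["start"], "end": seg["end"],
            "major": seg["major"], "minor": seg["minor"],
            "n_mult1": n1, "n_mult2": n2,
        })
    if not seg_rows:
        return None
    timed = gaintiming.time_segments(
        pd.DataFrame(seg_rows), n_boot=n_boot, ci_width_max=ci_width_max, seed=seed
    )
    kwargs = {}
    if genome_length is not None:
        kwargs["genome_length"] = genome_length
    return gaintiming.pre_dup_burden(timed, **kwargs)


def _stage_similarity(cfg: RunConfig, cohort, trees, report) -> None:
    meta = cohort.expression.metadata
    rows = []
    for patient, tree in trees.items():
        if tree.is_forest:
            continue
        hist = {b: meta.loc[b, "histology"] for b in tree.biopsies if b in meta.index}
        if len(set(hist.values())) < 2:
            continue
        sim = histosim.genetic_similarity(tree, presence_ccf=cfg.presence_ccf, histology=hist)
        try:
            res = histosim.label_swap_test(
                sim, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, f"sim:{patient}")
            )
        except ValueError:
            continue
        rows.append({"patient": patient, "modality": "genetic",
                     "observed": res.observed, "p": res.p_value, "mode": res.mode})
    report["outputs"]["similarity"] = _write(cfg, "similarity_report.tsv", pd.DataFrame(rows))


def _stage_dosage(cfg: RunConfig, cohort, report) -> None:
    expr = cohort.expression
    kept = dosagexpr.qc_libraries(
        expr.counts, expressed_min_reads=cfg.expressed_min_reads,
        min_features=cfg.min_features,
    )
    meta = expr.metadata.loc[kept]
    tumours = list(meta.index[~meta["is_normal_tubule"]])
    normals = list(meta.index[meta["is_normal_tubule"]])
    if len(tumours) < 2 or len(normals) < 2:
        raise ValueError("dosage stage needs >= 2 tumour and >= 2 normal libraries after QC")
    de = dosagexpr.differential_expression(expr, tumours, normals, blocking="histology")
    arm = cohort.config.dosage_arm
    annot = expr.annotation
    target = annot.loc[annot["cytoband"] == arm, "gene"].tolist()
    first = cohort.config.patient_ids()[0]
    segs = cohort.segments[cohort.segments["sample"] == f"{first}_b0"]
    ploidy = cohort.truth.profiles[f"{first}_b0"].ploidy
    pool = dosagexpr.near_baseline_genes(annot, segs, ploidy, cfg.near_baseline)
    res = dosagexpr.dosage_permutation(
        de, target, pool, n_draws=cfg.dosage_draws,
        seed=stage_seed(cfg.seed, "dosage"),
    )
    report["summary"]["dosage"] = res
    track = dosagexpr.rolling_logfc(de, annot, chrom="12", window=cfg.rolling_window)
    report["outputs"]["dosage"] = _write(cfg, "dosage_track.tsv", track)
    _write(cfg, "de_table.tsv", de.table, index=True)


def _stage_signatures(cfg: RunConfig, cohort, report) -> None:
    catalogue = sigfit.toy_catalogue()
    rows = []
    for patient in cohort.config.patient_ids():
        sub = cohort.calls[cohort.calls["patient"] == patient]
        # unique substitutions across the patient's biopsies (no double counting)
        sub = sub.drop_duplicates(subset=["chrom", "pos"])
        if len(sub) == 0:
            continue
        spectrum = sigfit.tabulate_96(sub)
        res = sigfit.em_attribution(spectrum, catalogue)
        for name, w in res.exposures.items():
            rows.append({"patient": patient, "signature": name, "exposure": w})
    report["outputs"]["signatures"] = _write(cfg, "signature_exposures.tsv", pd.DataFrame(rows))
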