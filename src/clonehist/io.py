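"""Reading and writing the package's tabular and VCF-subset formats.

All tables are TSV.  Per-patient substitution calls travel as a VCF v4.2
subset carrying per-sample allelic depths (FORMAT/AD, ref and alt); the
trinucleotide channel, local total copy number and copy state ride along
in INFO.  Segment tables use 1-based inclusive coordinates with columns
sample, chrom, start, end, major, minor, frac.
"""

from __future__ import annotations

import os

import pandas as pd

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=CH,Number=1,Type=String,Description="96-channel trinucleotide context label">
##INFO=<ID=CN,Number=1,Type=Integer,Description="Local total copy number">
##INFO=<ID=CS,Number=1,Type=String,Description="Allele-specific copy state major+minor">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
"""


def write_vcf(calls: pd.DataFrame, path: str, samples: list[str]) -> None:
    """Write one patient's calls as a VCF subset with AD per sample.

    ``calls`` must carry chrom, pos, ref, alt, channel, total_cn, state and
    ``alt_<sample>`` / ``tot_<sample>`` count columns for every name in
    ``samples`` (plus the matched ``normal``).
    """
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        ordered = calls.sort_values(["chrom", "pos"], key=_chrom_key)
        for _, row in ordered.iterrows():
            info = f"CH={row['channel']};CN={int(row['total_cn'])};CS={row['state']}"
            fields = [
                str(row["chrom"]), str(int(row["pos"])), ".", row["ref"], row["alt"],
                ".", "PASS", info, "AD",
            ]
            for s in samples:
                alt = int(row[f"alt_{s}"])
                tot = int(row[f"tot_{s}"])
                fields.append(f"{tot - alt},{alt}")
            fh.write("\t".join(fields) + "\n")


def _chrom_key(col: pd.Series) -> pd.Series:
    if col.name == "chrom":
        return col.map(lambda c: int(c) if str(c).isdigit() else 1000)
    return col


def read_vcf(path: str) -> pd.DataFrame:
    """Read a VCF subset written by :func:`write_vcf` back into the wide
    calls layout (alt_/tot_ columns per sample)."""
    import pysam

    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    rows = []
    for rec in vf:
        row = {
            "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alts[0],
            "channel": rec.info.get("CH"), "total_cn": rec.info.get("CN"),
            "state": rec.info.get("CS"),
        }
        for s in samples:
            ad = rec.samples[s]["AD"]
            row[f"alt_{s}"] = int(ad[1])
            row[f"tot_{s}"] = int(ad[0]) + int(ad[1])
        rows.append(row)
    cols = ["chrom", "pos", "ref", "alt", "channel", "total_cn", "state"]
    cols += [f"{k}_{s}" for s in samples for k in ("alt", "tot")]
    return pd.DataFrame(rows, columns=cols)


def write_fixtures(cohort, directory: str, panel=None) -> dict:
    """Write a simulated cohort (and optional panel) to ``directory``.

    One VCF per patient, one segment TSV per biopsy, cohort-level
    expression and ground-truth TSVs.  Returns a mapping from artefact
    name to path.  Reading the files back reproduces the in-memory values
    exactly.
    """
    os.makedirs(directory, exist_ok=True)
    if not os.access(directory, os.W_OK):
        raise OSError(f"directory not writable: {directory}")
    paths: dict[str, str] = {}
    cfg = cohort.config
    for patient in cfg.patient_ids():
        sub = cohort.calls[cohort.calls["patient"] == patient] if len(cohort.calls) else cohort.calls
        samples = [f"{patient}_b{j}" for j in range(cfg.n_biopsies)] + ["normal"]
        path = os.path.join(directory, f"{patient}.vcf")
        write_vcf(sub, path, samples)
        paths[f"vcf:{patient}"] = path
    seg_dir = os.path.join(directory, "segments")
    os.makedirs(seg_dir, exist_ok=True)
    for sample, grp in cohort.segments.groupby("sample"):
        path = os.path.join(seg_dir, f"{sample}.tsv")
        grp.to_csv(path, sep="\t", index=False)
        paths[f"segments:{sample}"] = path

    expr = cohort.expression
    for name, frame in {
        "expression_counts": expr.counts,
        "gene_annotation": expr.annotation,
        "biopsy_metadata": expr.metadata,
        "truth_mutations": cohort.truth.mutations,
        "truth_tree": cohort.truth.tree_edges,
        "truth_ccfs": cohort.truth.cluster_ccfs,
        "truth_expression": cohort.truth.expression,
    }.items():
        path = os.path.join(directory, f"{name}.tsv")
        index = name == "expression_counts"
        frame.to_csv(path, sep="\t", index=index, index_label="gene" if index else None)
        paths[name] = path

    if panel is not None:
        alt = pd.DataFrame(panel.alt, columns=[f"alt_s{j}" for j in range(panel.alt.shape[1])])
        tot = pd.DataFrame(panel.total, columns=[f"tot_s{j}" for j in range(panel.total.shape[1])])
        path = os.path.join(directory, "panel.tsv")
        pd.concat([alt, tot], axis=1).to_csv(path, sep="\t", index=False)
        paths["panel"] = path
    return paths


def read_panel(path: str):
    from .readfilter import PanelCounts

    df = pd.read_csv(path, sep="\t")
    alt_cols = [c for c in df.columns if c.startswith("alt_")]
    tot_cols = [c for c in df.columns if c.startswith("tot_")]
    return PanelCounts(alt=df[alt_cols].to_numpy(), total=df[tot_cols].to_numpy())


def read_segments(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
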