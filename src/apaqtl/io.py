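"""Readers and writers for the pipeline's on-disk formats.

Conventions: bedgraph and BED are 0-based half-open, VCF is 1-based.  All
tabular outputs are TSV for desk-scale inspectability.  VCF is written as
plain text v4.2 with a DS (dosage) FORMAT field and read back through
cyvcf2; missing DS entries are masked as NaN.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import PduiMatrix
from .simulate import GenotypeMatrix

__all__ = [
    "write_bedgraph", "read_bedgraph",
    "write_bed12", "read_bed12",
    "write_vcf", "read_vcf",
    "write_sumstats", "read_sumstats",
    "write_pdui", "read_pdui",
    "write_ld_matrix", "read_ld_matrix",
    "write_ground_truth",
]


# ---------------------------------------------------------------------------
# bedgraph


def write_bedgraph(path: str | Path, chrom: str, start: int,
                   coverage: np.ndarray) -> None:
    """Write a per-base track as run-length-collapsed bedgraph (0-based half-open)."""
    cov = np.asarray(coverage)
    change = np.flatnonzero(np.diff(cov)) + 1
    bounds = np.concatenate([[0], change, [cov.size]])
    with open(path, "w") as fh:
        for a, b in zip(bounds[:-1], bounds[1:]):
            fh.write(f"{chrom}\t{start + a}\t{start + b}\t{cov[a]:g}\n")


def read_bedgraph(path: str | Path, chrom: str, start: int,
                  length: int) -> np.ndarray:
    """Expand a bedgraph back to a per-base track over [start, start+length)."""
    cov = np.zeros(length)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{ln}: malformed bedgraph record")
            c, a, b, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if c != chrom:
                continue
            lo, hi = max(a - start, 0), min(b - start, length)
            if lo < hi:
                cov[lo:hi] = v
    return cov


# ---------------------------------------------------------------------------
# BED12 gene models


def write_bed12(path: str | Path, genes: pd.DataFrame) -> None:
    """Write gene models (gene, chrom, utr_start, utr_end, strand) as BED12."""
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            s, e = int(g["utr_start"]), int(g["utr_end"])
            fh.write("\t".join(map(str, [
                g["chrom"], s, e, g["gene"], 0, g["strand"],
                s, e, "0,0,0", 1, e - s, 0])) + "\n")


def read_bed12(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: expected 12 BED fields, got {len(f)}")
            rows.append({"gene": f[3], "chrom": f[0], "utr_start": int(f[1]),
                         "utr_end": int(f[2]), "strand": f[5]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF with DS dosages


def write_vcf(path: str | Path, genotypes: GenotypeMatrix) -> None:
    """Plain-text VCF v4.2 with GT and DS FORMAT fields."""
    dos = genotypes.dosages
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("##contig=<ID=chr1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        for j, (_, s) in enumerate(genotypes.snps.iterrows()):
            cells = "\t".join(f"{gt_map[int(d)]}:{int(d)}" for d in dos[:, j])
            fh.write(f"{s['chrom']}\t{s['pos']}\t{s['snp']}\t{s['ref']}\t"
                     f"{s['alt']}\t.\tPASS\t.\tGT:DS\t{cells}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read dosages back via cyvcf2; missing DS becomes NaN."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            d = np.full(len(samples), np.nan)
        else:
            d = ds.astype(float).ravel()
            d[d < 0] = np.nan
        rows.append(d)
        meta.append({"snp": var.ID, "chrom": var.CHROM, "pos": var.POS,
                     "ref": var.REF, "alt": var.ALT[0]})
    dos = np.array(rows).T if rows else np.empty((len(samples), 0))
    snps = pd.DataFrame(meta)
    if len(snps):
        f = np.nanmean(dos, axis=0) / 2.0
        snps["maf"] = np.minimum(f, 1 - f)
    pop = np.array(["POP1"] * len(samples))
    return GenotypeMatrix(dos, snps, samples, pop)


# ---------------------------------------------------------------------------
# TSVs


def write_sumstats(path: str | Path, sumstats: pd.DataFrame) -> None:
    sumstats.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"snp", "beta", "se", "p", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing summary-stat columns {sorted(missing)}")
    return df


def write_pdui(path: str | Path, pdui: PduiMatrix, genes: pd.DataFrame | None = None) -> None:
    """DaPars2-style wide TSV: transcript annotation columns then one PDUI per sample."""
    out = pdui.values.copy()
    out.insert(0, "proximal_offset", pdui.proximal_offsets)
    if genes is not None:
        ann = genes.set_index("gene")
        locus = (ann["chrom"].astype(str) + ":" + ann["utr_start"].astype(str)
                 + "-" + ann["utr_end"].astype(str))
        out.insert(0, "locus", locus.reindex(out.index))
    out.index.name = "transcript"
    out.to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")


def read_pdui(path: str | Path) -> PduiMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    offsets = df.pop("proximal_offset").astype(int)
    if "locus" in df.columns:
        df = df.drop(columns=["locus"])
    meancov = pd.DataFrame(np.inf, index=df.index, columns=df.columns)
    return PduiMatrix(df, meancov, offsets)


def write_ld_matrix(path: str | Path, ld: pd.DataFrame) -> None:
    ld.to_csv(path, sep="\t", float_format="%.10g")


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_ground_truth(path: str | Path, truth) -> None:
    """JSON dump of the planted truth (genes table + per-condition effects)."""
    payload = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in truth.config.__dict__.items()},
        "genes": truth.genes.to_dict(orient="records"),
        "effects": truth.effects.to_dict(orient="index"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=lambda o: o.item()
                  if isinstance(o, np.generic) else str(o))
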