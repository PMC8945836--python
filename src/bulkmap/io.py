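"""Readers and writers for the interchange formats used by the pipeline.

Internal coordinates are 1-based throughout; the BED writer converts to
0-based half-open at the boundary. VCF is version 4.2 with per-pool allele
depths (AD) in two sample columns.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .bsaseq import Region, SnpSite, WindowStat
from .finemap import MarkerPanel
from .genecand import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "write_pool_vcf",
    "read_vcf_pools",
    "write_genotype_matrix",
    "read_genotype_matrix",
    "write_phenotypes",
    "read_phenotypes",
    "write_marker_panel",
    "read_marker_panel",
    "write_window_stats",
    "write_regions_bed",
    "read_gff_genes",
    "read_cds_fasta",
    "read_count_matrix",
    "write_json_report",
]


def write_pool_vcf(
    path: str | Path,
    sites: Sequence[SnpSite],
    g_sample: str = "G",
    y_sample: str = "Y",
    extra_header: Sequence[str] = (),
) -> None:
    """Write pooled allele depths as a two-sample VCF 4.2 with AD."""
    chroms: dict[str, int] = {}
    for s in sites:
        chroms[s.chrom] = max(chroms.get(s.chrom, 0), s.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bulkmap\n")
        for line in extra_header:
            fh.write(f"##{line}\n")
        for chrom, maxpos in chroms.items():
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{g_sample}\t{y_sample}\n"
        )
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tAD\t"
                f"{s.g_ref},{s.g_alt}\t{s.y_ref},{s.y_alt}\n"
            )


def read_vcf_pools(
    path: str | Path, g_sample: str = "G", y_sample: str = "Y"
) -> tuple[list[SnpSite], int]:
    """Read biallelic SNVs with per-pool AD; returns (sites, n_skipped).

    Multi-allelic records and non-SNV alleles are skipped with a logged
    count; a missing sample or AD field raises.
    """
    sites: list[SnpSite] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for name in (g_sample, y_sample):
            if name not in vcf.header.samples:
                raise ValueError(f"sample {name!r} missing from VCF")
        if "AD" not in vcf.header.formats:
            raise ValueError("FORMAT field AD missing from VCF header")
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                skipped += 1
                continue
            try:
                g_ad = rec.samples[g_sample]["AD"]
                y_ad = rec.samples[y_sample]["AD"]
            except KeyError:
                raise ValueError("record lacks AD for a pool sample") from None
            sites.append(
                SnpSite(
                    rec.chrom,
                    rec.pos,
                    rec.ref,
                    alts[0],
                    int(g_ad[0]),
                    int(g_ad[1]),
                    int(y_ad[0]),
                    int(y_ad[1]),
                )
            )
    if skipped:
        logger.info("skipped %d non-biallelic/non-SNV records", skipped)
    return sites, skipped


def write_genotype_matrix(path: str | Path, genotypes: pd.DataFrame) -> None:
    genotypes.to_csv(path, sep="\t", index_label="individual")


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("individual")
    bad = set(np.unique(df.values)) - {"A", "H", "B", "NN"}
    if bad:
        raise ValueError(f"invalid genotype calls: {sorted(bad)}")
    return df


def write_phenotypes(path: str | Path, phenos: pd.DataFrame) -> None:
    phenos.to_csv(path, sep="\t", index_label="id")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index("id")
    if not {"spad", "class"} <= set(df.columns):
        raise ValueError("phenotype table needs 'spad' and 'class' columns")
    return df


def write_marker_panel(path: str | Path, panel: MarkerPanel) -> None:
    pd.DataFrame(
        {"name": panel.names, "chrom": panel.chrom, "pos": panel.positions}
    ).to_csv(path, sep="\t", index=False)


def read_marker_panel(path: str | Path) -> MarkerPanel:
    df = pd.read_csv(path, sep="\t")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("marker panel must be on a single chromosome")
    return MarkerPanel(
        tuple(df["name"].astype(str)), str(chroms[0]), tuple(df["pos"])
    )


def write_window_stats(path: str | Path, windows: Sequence[WindowStat]) -> None:
    pd.DataFrame(
        [
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_snps": w.n_snps,
                "idx_g": w.idx_g,
                "idx_y": w.idx_y,
                "delta": w.delta,
                "band_lo": w.band_lo,
                "band_hi": w.band_hi,
                "truncated": w.truncated,
            }
            for w in windows
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_regions_bed(path: str | Path, regions: Sequence[Region]) -> None:
    # BED is 0-based half-open; internal coordinates are 1-based with
    # exclusive ends, so start shifts by one and end carries over.
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end - 1}\t"
                f"delta={r.mean_delta:.4f}\n"
            )


def read_gff_genes(
    path: str | Path, expression_flags: Mapping[str, tuple[bool, bool]] | None = None
) -> list[GeneModel]:
    """Parse gene models (gene + CDS features) from a GFF3 file."""
    genes: dict[str, dict] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError("malformed GFF3 line")
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID")
                if not gid:
                    raise ValueError("gene feature without ID attribute")
                genes[gid] = {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                    "annotation": attr.get("Note", ""),
                }
            elif ftype == "CDS":
                parent = attr.get("Parent", attr.get("ID", ""))
                gid = parent.split(".")[0]
                cds.setdefault(gid, []).append((int(start), int(end)))
    out = []
    for gid, g in genes.items():
        exp_wt, exp_mut = (expression_flags or {}).get(gid, (True, True))
        out.append(
            GeneModel(
                id=gid,
                chrom=g["chrom"],
                start=g["start"],
                end=g["end"],
                strand=g["strand"],
                cds_segments=tuple(sorted(cds.get(gid, []))),
                annotation=g["annotation"],
                expressed_wt=exp_wt,
                expressed_mut=exp_mut,
            )
        )
    return out


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_count_matrix(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """TSV count matrix whose header row carries 'sample:GROUP' labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    groups = {}
    renames = {}
    for col in df.columns:
        if ":" not in col:
            raise ValueError("count-matrix columns must be 'sample:GROUP'")
        sample, group = col.rsplit(":", 1)
        renames[col] = sample
        groups[sample] = group
    return df.rename(columns=renames), groups


def write_json_report(path: str | Path, report: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
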