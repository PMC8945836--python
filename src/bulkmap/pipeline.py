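"""End-to-end pipeline: simulate → scan → fine-map → triage → validate.

Every stage draws randomness from a child seed derived deterministically
from the global seed, so a rerun of the same configuration produces a
byte-identical report.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bsaseq, finemap, genecand, markerval, simpop
from .config import PipelineConfig
from .io import (
    write_genotype_matrix,
    write_json_report,
    write_marker_panel,
    write_phenotypes,
    write_pool_vcf,
    write_regions_bed,
    write_window_stats,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

# stable offsets for deriving per-stage child seeds from the global seed
_STAGE_SEEDS = {
    "simulate": 11,
    "bulks": 23,
    "depth_g": 37,
    "depth_y": 41,
    "band": 53,
    "fixture": 67,
    "genes": 79,
}


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, _STAGE_SEEDS[stage]]).generate_state(1)[0])


def _genotype_calls(
    pop: list[simpop.F2Individual],
    gmap: simpop.GeneticMap,
    marker_bp: np.ndarray,
    ids: list[str],
) -> pd.DataFrame:
    bps = gmap.positions_bp
    idx = np.searchsorted(bps, marker_bp)
    by_id = {ind.id: ind for ind in pop}
    sym = np.array(["A", "H", "B"])
    rows = [sym[by_id[i].dosage[idx]] for i in ids]
    return pd.DataFrame(
        rows, index=ids, columns=[f"M{k + 1}" for k in range(marker_bp.size)]
    )


def run_pipeline(cfg: PipelineConfig, write_outputs: bool = True) -> dict:
    """Run all stages on a simulated population; returns the report dict."""
    outdir = Path(cfg.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"seed": cfg.seed, "stages": {}}

    # --- simulate -----------------------------------------------------
    gmap = simpop.GeneticMap.uniform(
        cfg.chrom, cfg.chrom_len, cfg.site_spacing, cfg.cm_per_mb
    )
    model = simpop.PhenoModel(cfg.mu_wt, cfg.mu_het, cfg.mu_mut, cfg.sigma)
    sim_seed = _stage_seed(cfg.seed, "simulate")
    pop = simpop.simulate_f2(cfg.n_f2, gmap, cfg.causal_bp, model, sim_seed)
    report["stages"]["simulate"] = {
        "seed": sim_seed,
        "n_f2": cfg.n_f2,
        "n_loci": len(gmap),
        "causal_bp": cfg.causal_bp,
        "class_counts": {
            c: sum(1 for p in pop if p.pheno_class == c)
            for c in ("WT", "HET", "MUT")
        },
    }

    spec = simpop.BulkSpec(cfg.bulk_size, cfg.coverage_g, cfg.coverage_y)
    bulk_seed = _stage_seed(cfg.seed, "bulks")
    g_ids, y_ids = simpop.build_bulks(pop, spec, bulk_seed)
    positions = gmap.positions_bp
    g_counts = simpop.sample_pool_depths(
        g_ids, pop, gmap, positions, spec.coverage_g, _stage_seed(cfg.seed, "depth_g")
    )
    y_counts = simpop.sample_pool_depths(
        y_ids, pop, gmap, positions, spec.coverage_y, _stage_seed(cfg.seed, "depth_y")
    )
    sites = simpop.pool_sites(gmap, g_counts, y_counts)
    report["stages"]["bulks"] = {
        "seed": bulk_seed,
        "n_per_bulk": spec.n_per_bulk,
        "n_sites": len(sites),
    }

    # --- scan ---------------------------------------------------------
    scan_cfg = bsaseq.ScanConfig(
        cfg.window_bp, cfg.step_bp, cfg.alpha, cfg.min_depth,
        cfg.n_null_reps, cfg.bulk_size,
    )
    band_seed = _stage_seed(cfg.seed, "band")
    windows = bsaseq.scan_with_band(sites, scan_cfg, cfg.chrom_len, band_seed)
    regions = bsaseq.call_regions(windows)
    report["stages"]["scan"] = {
        "seed": band_seed,
        "n_windows": len(windows),
        "regions": [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "mean_delta": round(r.mean_delta, 4),
            }
            for r in regions
        ],
    }
    if not regions:
        report["error"] = "scan: no region exceeded the confidence band"
        if write_outputs:
            _write_all(outdir, cfg, sites, windows, regions, report=report)
        return report
    region = max(regions, key=lambda r: r.mean_delta)

    # --- fine mapping -------------------------------------------------
    # iterative rounds: markers evenly spaced over the current interval
    # (snapped to panel loci), narrowed each round as in marker-by-marker
    # map-based cloning
    mut_ids = [p.id for p in pop if p.pheno_class == "MUT"]
    phenos = {p.id: p.pheno_class for p in pop}
    left_bp, right_bp = int(region.start), int(region.end - 1)
    rounds_report = []
    panel = None
    genotypes = None
    import warnings as _warnings

    for rnd in range(cfg.finemap_rounds):
        marker_bp = np.unique(
            positions[
                np.searchsorted(
                    positions,
                    np.linspace(left_bp, right_bp, cfg.n_markers),
                ).clip(max=positions.size - 1)
            ]
        )
        if marker_bp.size < 2:
            break
        panel = finemap.MarkerPanel(
            tuple(f"M{k + 1}" for k in range(marker_bp.size)),
            cfg.chrom,
            tuple(int(b) for b in marker_bp),
        )
        genotypes = _genotype_calls(pop, gmap, marker_bp, mut_ids)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            narrowed = finemap.narrow_interval(panel, genotypes, phenos)
        new_left = (
            panel.position_of(narrowed.left_flank)
            if narrowed.left_flank
            else left_bp
        )
        new_right = (
            panel.position_of(narrowed.right_flank)
            if narrowed.right_flank
            else right_bp
        )
        if narrowed.fallback:
            # no cosegregating marker: widen by one marker on each side
            names = list(panel.names)
            li = names.index(narrowed.left_flank)
            ri = names.index(narrowed.right_flank)
            if li > 0:
                new_left = panel.positions[li - 1]
            if ri < len(names) - 1:
                new_right = panel.positions[ri + 1]
        left_bp, right_bp = int(new_left), int(new_right)
        rounds_report.append(
            {
                "round": rnd + 1,
                "markers": {n: int(p) for n, p in zip(panel.names, panel.positions)},
                "recombinant_counts": dict(narrowed.counts),
                "cosegregating": sorted(narrowed.cosegregating),
                "left_flank": narrowed.left_flank,
                "right_flank": narrowed.right_flank,
                "fallback": narrowed.fallback,
                "interval": [left_bp, right_bp],
            }
        )
    report["stages"]["finemap"] = {
        "n_mut": len(mut_ids),
        "rounds": rounds_report,
        "interval": [left_bp, right_bp],
    }

    # --- candidate triage --------------------------------------------
    genes, effects, causal_gene = _interval_genes(
        cfg, int(left_bp), int(right_bp), _stage_seed(cfg.seed, "genes")
    )
    result = genecand.triage(genes, effects)
    report["stages"]["triage"] = {
        "n_genes": len(genes),
        "causal_gene": causal_gene,
        "candidates": list(result.candidates),
        "audit": [
            {"step": s.step, "reason": s.description, "removed": list(s.removed)}
            for s in result.steps
        ],
    }

    # --- marker validation -------------------------------------------
    causal_idx = int(np.searchsorted(positions, cfg.causal_bp))
    causal_on_panel = (
        causal_idx < positions.size and positions[causal_idx] == cfg.causal_bp
    )
    if causal_on_panel:
        calls = {}
        for p in pop:
            d = int(p.dosage[causal_idx])
            calls[p.id] = ("AA", "AB", "BB")[d]
        coseg = markerval.cosegregation_check(calls, phenos)
        counts = markerval.SegCounts(
            sum(1 for v in calls.values() if v == "AA"),
            sum(1 for v in calls.values() if v == "AB"),
            sum(1 for v in calls.values() if v == "BB"),
        )
        chi2, df, pval = markerval.segregation_chi2(counts)
        report["stages"]["validate"] = {
            "perfect_cosegregation": coseg.perfect,
            "n_discordant": len(coseg.discordant),
            "n_called": coseg.n_called,
            "segregation_chi2": round(chi2, 4),
            "segregation_p": round(pval, 4),
        }

    report["success"] = (
        len(result.candidates) == 1 and result.candidates[0] == causal_gene
    )
    if write_outputs:
        _write_all(
            outdir, cfg, sites, windows, regions,
            panel=panel, genotypes=genotypes, pop=pop, report=report,
        )
    return report


def _interval_genes(
    cfg: PipelineConfig, left_bp: int, right_bp: int, seed: int
) -> tuple[list[genecand.GeneModel], list[genecand.VariantEffect], str | None]:
    """Tile the chromosome with gene models and give each gene inside the
    narrowed interval one seeded exonic variant.

    Only the gene containing the causal position carries an expressed
    nonsynonymous substitution; the others get synonymous SNVs, frameshift
    deletions, unexpressed nonsynonymous SNVs, or nothing.
    """
    rng = np.random.default_rng(seed)
    genes: list[genecand.GeneModel] = []
    effects: list[genecand.VariantEffect] = []
    causal_gene: str | None = None

    first = (left_bp // cfg.gene_span) * cfg.gene_span
    for start in range(first, right_bp + 1, cfg.gene_span):
        end = start + cfg.gene_span - 1
        gid = f"GENE_{start // cfg.gene_span:05d}"
        contains_causal = start <= cfg.causal_bp <= end
        kind = (
            "causal"
            if contains_causal
            else rng.choice(
                ["syn", "frameshift", "silent_none", "nonsyn_unexpr"],
                p=[0.6, 0.2, 0.1, 0.1],
            )
        )
        expressed = kind != "nonsyn_unexpr"
        genes.append(
            genecand.GeneModel(
                id=gid,
                chrom=cfg.chrom,
                start=max(start, 1),
                end=end,
                cds_segments=((max(start, 1), max(start, 1) + 299),),
                expressed_wt=expressed,
                expressed_mut=expressed,
            )
        )
        cds = simpop._random_cds(rng, 100)
        k = int(rng.integers(2, 98))
        if kind == "causal":
            causal_gene = gid
            cds = cds[: (k - 1) * 3] + "GAA" + cds[k * 3 :]
            effects.append(
                genecand.annotate_variant(cds, (k - 1) * 3 + 1, "G", "A", gene=gid)
            )
        elif kind == "syn":
            cds = cds[: (k - 1) * 3] + "GGA" + cds[k * 3 :]
            effects.append(
                genecand.annotate_variant(cds, k * 3, "A", "G", gene=gid)
            )
        elif kind == "frameshift":
            pos = int(rng.integers(4, 290))
            ref = cds[pos - 1 : pos + 1]
            effects.append(
                genecand.annotate_variant(cds, pos, ref, ref[0], gene=gid)
            )
        elif kind == "nonsyn_unexpr":
            cds = cds[: (k - 1) * 3] + "GAA" + cds[k * 3 :]
            effects.append(
                genecand.annotate_variant(cds, (k - 1) * 3 + 1, "G", "A", gene=gid)
            )
    return genes, effects, causal_gene


def _write_all(
    outdir: Path,
    cfg: PipelineConfig,
    sites,
    windows,
    regions,
    panel=None,
    genotypes=None,
    pop=None,
    report=None,
) -> None:
    write_pool_vcf(
        outdir / "pools.vcf", sites, extra_header=[f"bulkmapSeed={cfg.seed}"]
    )
    write_window_stats(outdir / "windows.tsv", windows)
    write_regions_bed(outdir / "regions.bed", regions)
    if panel is not None:
        write_marker_panel(outdir / "markers.tsv", panel)
    if genotypes is not None:
        write_genotype_matrix(outdir / "genotypes.tsv", genotypes)
    if pop is not None:
        phenos = pd.DataFrame(
            {
                "id": [p.id for p in pop],
                "spad": [round(p.spad, 3) for p in pop],
                "class": [p.pheno_class for p in pop],
            }
        ).set_index("id")
        write_phenotypes(outdir / "phenotypes.tsv", phenos)
    if report is not None:
        write_json_report(outdir / "report.json", report)
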