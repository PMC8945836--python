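"""Synthetic F2 populations, bulks, pooled depths, and worked-example fixtures.

The simulator crosses two homozygous parents differing at every panel SNP,
builds F2 individuals as unions of two recombinant gametes (crossovers as a
Poisson process on the centimorgan axis — Haldane, no interference), assigns
each individual a SPAD chlorophyll reading from its genotype at one causal
locus with incomplete dominance, and emulates pooled sequencing of
phenotype-selected bulks.

Fixture builders reproduce printed worked-example tables: a fine-mapping
genotype matrix realizing exact per-marker recombinant counts, and a
gene/variant/expression table realizing the candidate-filter counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bsaseq import SnpSite
from .finemap import MarkerPanel, classify_spad
from .genecand import GeneModel, VariantEffect, annotate_variant

__all__ = [
    "GeneticMap",
    "PhenoModel",
    "BulkSpec",
    "F2Individual",
    "simulate_gametes",
    "simulate_f2",
    "build_bulks",
    "sample_pool_depths",
    "pool_sites",
    "make_finemap_fixture",
    "make_gene_table_fixture",
    "gene_table_frames",
]


@dataclass(frozen=True)
class GeneticMap:
    """Ordered loci on one chromosome with physical (bp) and genetic (cM)
    coordinates, strictly increasing in both."""

    chrom: str
    loci: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("a genetic map needs at least one locus")
        bps = [bp for bp, _ in self.loci]
        cms = [cm for _, cm in self.loci]
        if any(b <= a for a, b in zip(bps, bps[1:])):
            raise ValueError("bp positions must be strictly increasing")
        if any(b <= a for a, b in zip(cms, cms[1:])):
            raise ValueError("cM positions must be strictly increasing")
        if cms[0] < 0:
            raise ValueError("cM positions must be >= 0")

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def positions_bp(self) -> np.ndarray:
        return np.array([bp for bp, _ in self.loci], dtype=np.int64)

    @property
    def positions_cm(self) -> np.ndarray:
        return np.array([cm for _, cm in self.loci], dtype=float)

    def interp_cm(self, bp: int) -> float:
        """Genetic position of ``bp`` by linear interpolation on the map."""
        bps = self.positions_bp
        if not bps[0] <= bp <= bps[-1]:
            raise ValueError("causal locus off map")
        return float(np.interp(bp, bps, self.positions_cm))

    @classmethod
    def uniform(
        cls, chrom: str, chrom_len: int, spacing_bp: int, cm_per_mb: float
    ) -> "GeneticMap":
        """One SNP every ``spacing_bp`` with a constant cM/Mb rate."""
        bps = np.arange(spacing_bp, chrom_len + 1, spacing_bp, dtype=np.int64)
        return cls(
            chrom, tuple((int(b), float(b) * cm_per_mb / 1e6) for b in bps)
        )


@dataclass(frozen=True)
class PhenoModel:
    """SPAD means per causal genotype class plus Gaussian noise.

    Defaults put the class means well inside the <10 / 10–20 / >20 bands so
    misclassification is negligible at sigma=2, while sigma can be raised
    for robustness experiments.
    """

    mu_wt: float = 30.0
    mu_het: float = 15.0
    mu_mut: float = 5.0
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if not self.mu_mut < 10.0 < self.mu_het < 20.0 < self.mu_wt:
            raise ValueError(
                "class means must satisfy mu_mut < 10 < mu_het < 20 < mu_wt"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class BulkSpec:
    n_per_bulk: int = 25
    coverage_g: float = 39.82
    coverage_y: float = 33.75

    def __post_init__(self) -> None:
        if self.n_per_bulk < 1:
            raise ValueError("n_per_bulk must be >= 1")
        if self.coverage_g <= 0 or self.coverage_y <= 0:
            raise ValueError("coverages must be > 0")


@dataclass
class F2Individual:
    """dosage counts mutant-parent alleles (0/1/2) at each map locus."""

    id: str
    dosage: np.ndarray
    spad: float
    pheno_class: str


def _gametes(rng: np.random.Generator, cm: np.ndarray, n: int) -> np.ndarray:
    """n gametes over loci at genetic positions ``cm`` (Haldane model).

    Returns an (n, n_loci) 0/1 array; 1 = mutant-parent allele.
    """
    span = float(cm[-1] - cm[0])
    out = np.empty((n, cm.size), dtype=np.int8)
    phase = rng.integers(0, 2, size=n)
    n_x = rng.poisson(span / 100.0, size=n)
    for i in range(n):
        if n_x[i] == 0:
            out[i] = phase[i]
            continue
        xpos = np.sort(rng.uniform(cm[0], cm[-1], size=n_x[i]))
        flips = np.searchsorted(xpos, cm, side="left")
        out[i] = (phase[i] + flips) % 2
    return out


def simulate_gametes(cm: Sequence[float], n: int, seed: int) -> np.ndarray:
    """n recombinant gametes over loci at genetic positions ``cm`` (in cM).

    Crossovers form a Poisson process on the cM axis (no interference), so
    the recombinant fraction between two loci d cM apart follows the
    Haldane map function r = (1 - exp(-2d/100)) / 2. Returns an (n, n_loci)
    0/1 array where 1 marks the mutant-parent allele.
    """
    return _gametes(
        np.random.default_rng(seed), np.asarray(cm, dtype=float), n
    )


def simulate_f2(
    n: int,
    gmap: GeneticMap,
    causal_bp: int,
    model: PhenoModel,
    seed: int,
) -> list[F2Individual]:
    """Simulate ``n`` F2 individuals from a cross segregating at one causal
    locus with incomplete dominance.

    Each individual is the union of two independent recombinant gametes.
    The causal locus may fall between panel SNPs; its genetic position is
    interpolated and it is simulated jointly with the panel.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    causal_cm = gmap.interp_cm(causal_bp)  # raises if off map
    rng = np.random.default_rng(seed)

    cm = gmap.positions_cm
    bp = gmap.positions_bp
    hit = np.flatnonzero(bp == causal_bp)
    if hit.size:
        aug_cm, causal_col, panel_cols = cm, int(hit[0]), slice(None)
    else:
        j = int(np.searchsorted(cm, causal_cm))
        aug_cm = np.insert(cm, j, causal_cm)
        causal_col = j
        panel_cols = np.delete(np.arange(aug_cm.size), j)

    g1 = _gametes(rng, aug_cm, n)
    g2 = _gametes(rng, aug_cm, n)
    dosage = (g1 + g2).astype(np.int8)

    mus = np.array([model.mu_wt, model.mu_het, model.mu_mut])
    causal_dose = dosage[:, causal_col] if n else np.empty(0, dtype=np.int8)
    spad = np.maximum(
        0.0, mus[causal_dose] + rng.normal(0.0, model.sigma, size=n)
    )

    pop = []
    for i in range(n):
        s = float(spad[i])
        pop.append(
            F2Individual(
                id=f"F2_{i + 1:05d}",
                dosage=np.asarray(dosage[i, panel_cols]),
                spad=s,
                pheno_class=classify_spad(s),
            )
        )
    return pop


def build_bulks(
    pop: Sequence[F2Individual], spec: BulkSpec, seed: int
) -> tuple[list[str], list[str]]:
    """Sample the wild-type (G) and homozygous-mutant (Y) bulks.

    Heterozygous-class individuals enter neither bulk.
    """
    rng = np.random.default_rng(seed)
    wt = [ind.id for ind in pop if ind.pheno_class == "WT"]
    mut = [ind.id for ind in pop if ind.pheno_class == "MUT"]
    for label, ids in (("WT", wt), ("MUT", mut)):
        if len(ids) < spec.n_per_bulk:
            raise ValueError(
                f"insufficient {label}-class individuals: "
                f"{len(ids)} < {spec.n_per_bulk}"
            )
    g_ids = list(rng.choice(wt, size=spec.n_per_bulk, replace=False))
    y_ids = list(rng.choice(mut, size=spec.n_per_bulk, replace=False))
    return g_ids, y_ids


def sample_pool_depths(
    bulk_ids: Sequence[str],
    pop: Sequence[F2Individual],
    gmap: GeneticMap,
    sites: Sequence[int],
    coverage: float,
    seed: int,
) -> np.ndarray:
    """Pooled read depths for one bulk at panel sites (bp positions).

    Pool mutant-allele frequency at a site is the bulk's mean dosage / 2;
    total depth is Poisson(coverage) and alt depth Binomial(depth, p).
    Returns an (n_sites, 2) integer array of (ref_depth, alt_depth).
    """
    if not bulk_ids:
        raise ValueError("empty bulk")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    by_id = {ind.id: ind for ind in pop}
    members = [by_id[i] for i in bulk_ids]
    bps = gmap.positions_bp
    site_bp = np.asarray(sites, dtype=np.int64)
    site_idx = np.searchsorted(bps, site_bp)
    if np.any(site_idx >= bps.size) or np.any(bps[site_idx] != site_bp):
        raise ValueError("site position is not a map locus")
    dosage = np.stack([m.dosage for m in members])  # (bulk, loci)
    p = dosage[:, site_idx].sum(axis=0) / (2.0 * len(members))
    rng = np.random.default_rng(seed)
    depth = rng.poisson(coverage, size=site_idx.size)
    alt = rng.binomial(depth, p)
    return np.stack([depth - alt, alt], axis=1)


def pool_sites(
    gmap: GeneticMap,
    g_counts: np.ndarray,
    y_counts: np.ndarray,
    ref: str = "G",
    alt: str = "A",
) -> list[SnpSite]:
    """Combine per-bulk (ref, alt) depth arrays over all map loci into sites."""
    bps = gmap.positions_bp
    if g_counts.shape != (bps.size, 2) or y_counts.shape != (bps.size, 2):
        raise ValueError("counts must cover every map locus")
    return [
        SnpSite(
            gmap.chrom,
            int(bps[i]),
            ref,
            alt,
            int(g_counts[i, 0]),
            int(g_counts[i, 1]),
            int(y_counts[i, 0]),
            int(y_counts[i, 1]),
        )
        for i in range(bps.size)
    ]


def make_finemap_fixture(
    counts_by_marker: Mapping[str, int],
    n_individuals: int,
    markers: MarkerPanel,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype matrix + phenotype table realizing exact per-marker
    recombinant counts with one breakpoint per recombinant.

    All individuals are mutant-class. The count profile must reach zero at
    the cosegregating marker(s) and be non-increasing toward them from each
    side; otherwise no single-breakpoint matrix realizes it.
    """
    names = list(markers.names)
    if set(counts_by_marker) != set(names):
        raise ValueError("counts must cover exactly the panel markers")
    c = np.array([counts_by_marker[m] for m in names], dtype=np.int64)
    if np.any(c < 0):
        raise ValueError("negative recombinant count")

    zero = np.flatnonzero(c == 0)
    if zero.size == 0 or np.any(np.diff(zero) != 1):
        raise ValueError("not realizable with single breakpoints")
    zb, ze = int(zero[0]), int(zero[-1])
    if np.any(np.diff(c[: zb + 1]) > 0) or np.any(np.diff(c[ze:]) < 0):
        raise ValueError("not realizable with single breakpoints")

    total = int(c[0] + c[-1])
    if total > n_individuals:
        raise ValueError("more recombinants than individuals")

    rng = np.random.default_rng(seed)
    ids = [f"MUT_{i + 1:05d}" for i in range(n_individuals)]
    rec_ids = rng.choice(n_individuals, size=total, replace=False)

    geno = np.full((n_individuals, len(names)), "B", dtype="U2")
    k = 0
    for i in range(zb):  # breakpoint between marker i and i+1, left side
        for _ in range(int(c[i] - c[i + 1])):
            geno[rec_ids[k], : i + 1] = "H"
            k += 1
    for j in range(len(names) - 1, ze, -1):  # right side
        for _ in range(int(c[j] - c[j - 1])):
            geno[rec_ids[k], j:] = "H"
            k += 1
    assert k == total

    genotypes = pd.DataFrame(geno, index=ids, columns=names)
    spad = np.clip(rng.normal(5.0, 1.5, size=n_individuals), 0.1, 9.9)
    phenos = pd.DataFrame(
        {"id": ids, "spad": np.round(spad, 3), "class": "MUT"}
    ).set_index("id")
    return genotypes, phenos


_SYN_CODON = ("GGA", "GGG")  # Gly -> Gly third-position change
_NONSYN_CODON = ("GAA", "AAA")  # Glu -> Lys first-position G>A


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    safe = ["GCT", "GGT", "CTG", "ACC", "TCA", "GTT", "CCA", "AAC"]
    body = rng.choice(safe, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def make_gene_table_fixture(
    seed: int,
    n_genes: int = 56,
    chrom: str = "A03",
    interval_start: int = 4_100_000,
) -> tuple[list[GeneModel], list[VariantEffect]]:
    """Gene models + exonic variant effects realizing the candidate-filter
    worked example.

    Of ``n_genes`` genes in the interval, 15 carry exonic variants: 2 with
    frameshift deletions, 3 with nonsynonymous SNVs (2 of which are
    expressed in neither line), and 10 with synonymous SNVs. Exactly one
    gene — nonsynonymous, expressed — survives triage.
    """
    if n_genes < 15:
        raise ValueError("need at least 15 genes for the worked example")
    rng = np.random.default_rng(seed)

    spacing = 5_000
    genes: list[GeneModel] = []
    variant_slots = list(rng.choice(n_genes, size=15, replace=False))
    frameshift_genes = variant_slots[:2]
    nonsyn_genes = variant_slots[2:5]
    syn_genes = variant_slots[5:]
    candidate = nonsyn_genes[0]
    unexpressed = set(nonsyn_genes[1:])

    for i in range(n_genes):
        start = interval_start + i * spacing
        end = start + spacing - 1_000
        expressed = i not in unexpressed
        genes.append(
            GeneModel(
                id=f"GENE{i + 1:03d}",
                chrom=chrom,
                start=start,
                end=end,
                strand="+" if i % 2 == 0 else "-",
                cds_segments=((start, start + 299),),
                annotation="candidate" if i == candidate else "",
                expressed_wt=expressed,
                expressed_mut=expressed,
            )
        )

    effects: list[VariantEffect] = []
    for i in frameshift_genes:
        cds = _random_cds(rng, 100)
        pos = int(rng.integers(4, 290))
        ref = cds[pos - 1 : pos + 1]  # 2-nt deletion -> frameshift
        effects.append(
            annotate_variant(cds, pos, ref, ref[0], gene=genes[i].id)
        )
    for i in nonsyn_genes:
        cds = _random_cds(rng, 100)
        k = int(rng.integers(2, 98))  # codon slot to overwrite
        cds = cds[: (k - 1) * 3] + _NONSYN_CODON[0] + cds[k * 3 :]
        effects.append(
            annotate_variant(cds, (k - 1) * 3 + 1, "G", "A", gene=genes[i].id)
        )
    for i in syn_genes:
        cds = _random_cds(rng, 100)
        k = int(rng.integers(2, 98))
        cds = cds[: (k - 1) * 3] + _SYN_CODON[0] + cds[k * 3 :]
        effects.append(
            annotate_variant(cds, k * 3, "A", "G", gene=genes[i].id)
        )
    return genes, effects


def gene_table_frames(seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DataFrame rendering of the gene-table fixture (deterministic)."""
    genes, effects = make_gene_table_fixture(seed)
    gdf = pd.DataFrame(
        [
            {
                "gene": g.id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "expressed_wt": g.expressed_wt,
                "expressed_mut": g.expressed_mut,
                "annotation": g.annotation,
            }
            for g in genes
        ]
    ).set_index("gene")
    edf = pd.DataFrame(
        [
            {
                "gene": e.gene,
                "cds_pos": e.cds_pos,
                "ref": e.ref,
                "alt": e.alt,
                "effect": e.effect,
                "ems_consistent": e.ems_consistent,
            }
            for e in effects
        ]
    ).set_index("gene")
    return gdf, edf
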