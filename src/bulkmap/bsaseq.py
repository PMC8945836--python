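"""SNP-index / Δ(SNP-index) scanning for two-bulk segregant sequencing.

Per-site statistics, 1 Mb / 10 kb sliding-window averaging, a Monte-Carlo
null confidence band conditional on pool depths, and candidate-region
calling from windows whose Δ(SNP-index) exceeds the band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SnpSite",
    "ScanConfig",
    "WindowStat",
    "Region",
    "UndefinedSnpIndexError",
    "snp_index",
    "delta_snp_index",
    "site_passes",
    "window_scan",
    "null_band",
    "NullBandCache",
    "compute_site_bands",
    "scan_with_band",
    "call_regions",
]


class UndefinedSnpIndexError(ValueError):
    """Raised when a pool has zero total depth so the index is undefined.

    Distinct from a numeric 0 index (which means all reads carry the
    reference-parent allele).
    """


@dataclass(frozen=True)
class SnpSite:
    """One biallelic parental-homozygous site with per-pool allele depths.

    ``ref`` is the reference-parent base, ``alt`` the mutant-parent base.
    ``g_*`` are wild-type-pool depths, ``y_*`` mutant-pool depths.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    g_ref: int
    g_alt: int
    y_ref: int
    y_alt: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        for name in ("g_ref", "g_alt", "y_ref", "y_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative depth in field {name}")
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")


@dataclass(frozen=True)
class ScanConfig:
    window_bp: int = 1_000_000
    step_bp: int = 10_000
    alpha: float = 0.05
    min_depth: int = 7
    n_null_reps: int = 10_000
    bulk_size: int = 25

    def __post_init__(self) -> None:
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must be <= window_bp")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_depth < 0 or self.n_null_reps < 1 or self.bulk_size < 1:
            raise ValueError("invalid ScanConfig")


@dataclass
class WindowStat:
    """Windowed averages; 1-based inclusive start, exclusive end."""

    chrom: str
    start: int
    end: int
    n_snps: int
    idx_g: float
    idx_y: float
    delta: float
    band_lo: float = math.nan
    band_hi: float = math.nan
    truncated: bool = False

    @property
    def has_data(self) -> bool:
        return self.n_snps > 0


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    mean_delta: float
    n_windows: int


def snp_index(ref_depth: int, alt_depth: int) -> float:
    """Fraction of pool reads carrying the mutant-parent (alt) allele."""
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("depths must be non-negative")
    total = ref_depth + alt_depth
    if total == 0:
        raise UndefinedSnpIndexError("total depth is zero; index undefined")
    return alt_depth / total


def delta_snp_index(site: SnpSite) -> float:
    """Δ(SNP-index) = index(Y-pool) − index(G-pool) at one site."""
    return snp_index(site.y_ref, site.y_alt) - snp_index(site.g_ref, site.g_alt)


def site_passes(site: SnpSite, min_depth: int) -> bool:
    """True iff both pools meet the per-pool minimum total depth."""
    return (site.g_ref + site.g_alt) >= min_depth and (
        site.y_ref + site.y_alt
    ) >= min_depth


def _window_starts(chrom_len: int, step_bp: int) -> np.ndarray:
    # windows are anchored at 1: starts 1, 1+s, 1+2s, ... <= chrom_len
    n = (chrom_len - 1) // step_bp + 1
    return 1 + step_bp * np.arange(n, dtype=np.int64)


def window_scan(
    sites: list[SnpSite],
    cfg: ScanConfig,
    chrom_len: int,
    site_bands: np.ndarray | None = None,
) -> list[WindowStat]:
    """Average per-site indexes in sliding windows along one chromosome.

    ``site_bands`` is an optional ``(len(sites), 2)`` array of per-site
    (lo, hi) null-band bounds aligned with ``sites``; window bands are the
    mean over member sites that pass the depth filter. Windows without any
    passing site carry NaN statistics and ``n_snps == 0``.
    """
    if sites:
        if chrom_len < max(s.pos for s in sites):
            raise ValueError("chrom_len smaller than max site position")
        chroms = {s.chrom for s in sites}
        if len(chroms) > 1:
            raise ValueError("window_scan handles one chromosome at a time")
        chrom = sites[0].chrom
    else:
        chrom = "NA"
    pos = np.array([s.pos for s in sites], dtype=np.int64)
    if np.any(np.diff(pos) < 0):
        raise ValueError("sites must be sorted by position")

    keep = np.array([site_passes(s, cfg.min_depth) for s in sites], dtype=bool)
    kept = [s for s, k in zip(sites, keep) if k]
    kpos = pos[keep]
    idx_g = np.array([snp_index(s.g_ref, s.g_alt) for s in kept])
    idx_y = np.array([snp_index(s.y_ref, s.y_alt) for s in kept])
    delta = idx_y - idx_g
    if site_bands is not None:
        site_bands = np.asarray(site_bands, dtype=float)
        if site_bands.shape != (len(sites), 2):
            raise ValueError("site_bands must have shape (n_sites, 2)")
        kbands = site_bands[keep]
    else:
        kbands = np.full((len(kept), 2), math.nan)

    # prefix sums for O(1) window means
    cg = np.concatenate([[0.0], np.cumsum(idx_g)])
    cy = np.concatenate([[0.0], np.cumsum(idx_y)])
    cd = np.concatenate([[0.0], np.cumsum(delta)])
    clo = np.concatenate([[0.0], np.cumsum(kbands[:, 0])])
    chi = np.concatenate([[0.0], np.cumsum(kbands[:, 1])])

    out: list[WindowStat] = []
    for start in _window_starts(chrom_len, cfg.step_bp):
        end = start + cfg.window_bp
        truncated = end > chrom_len + 1
        if truncated:
            end = chrom_len + 1
        lo_i = int(np.searchsorted(kpos, start, side="left"))
        hi_i = int(np.searchsorted(kpos, end, side="left"))
        n = hi_i - lo_i
        if n == 0:
            out.append(
                WindowStat(
                    chrom, int(start), int(end), 0,
                    math.nan, math.nan, math.nan,
                    truncated=truncated,
                )
            )
            continue
        out.append(
            WindowStat(
                chrom,
                int(start),
                int(end),
                n,
                float((cg[hi_i] - cg[lo_i]) / n),
                float((cy[hi_i] - cy[lo_i]) / n),
                float((cd[hi_i] - cd[lo_i]) / n),
                band_lo=float((clo[hi_i] - clo[lo_i]) / n),
                band_hi=float((chi[hi_i] - chi[lo_i]) / n),
                truncated=truncated,
            )
        )
    return out


class NullBandCache:
    """Depth-conditional Monte-Carlo Δ(SNP-index) null bands, memoised.

    The F2 null is shared across depth pairs: each replicate draws a pool
    allele frequency per bulk as (Binomial(2·bulk_size, ½)) / (2·bulk_size)
    — an unselected bulk of F2 dosages segregating 1:2:1 — and then
    resamples read counts binomially at the requested depths.
    """

    def __init__(self, cfg: ScanConfig, seed: int):
        self.cfg = cfg
        self._rng = np.random.default_rng(seed)
        two_n = 2 * cfg.bulk_size
        self._p_y = self._rng.binomial(two_n, 0.5, cfg.n_null_reps) / two_n
        self._p_g = self._rng.binomial(two_n, 0.5, cfg.n_null_reps) / two_n
        self._cache: dict[tuple[int, int], tuple[float, float]] = {}

    def band(self, depth_y: int, depth_g: int) -> tuple[float, float]:
        key = (int(depth_y), int(depth_g))
        if key not in self._cache:
            self._cache[key] = self._compute(*key)
        return self._cache[key]

    def _compute(self, depth_y: int, depth_g: int) -> tuple[float, float]:
        if depth_y < 1 or depth_g < 1:
            raise ValueError("depths must be >= 1 for a null band")
        d = (
            self._rng.binomial(depth_y, self._p_y) / depth_y
            - self._rng.binomial(depth_g, self._p_g) / depth_g
        )
        a = self.cfg.alpha
        lo, hi = np.quantile(d, [a / 2.0, 1.0 - a / 2.0])
        return float(lo), float(hi)


def null_band(
    depth_y: int, depth_g: int, cfg: ScanConfig, seed: int
) -> tuple[float, float]:
    """Empirical (α/2, 1−α/2) quantiles of Δ(SNP-index) at an unlinked site.

    Per replicate, each pool's allele frequency is drawn from bulk_size F2
    dosages in {0,1,2} with probabilities {¼,½,¼}; alt read counts are then
    Binomial(depth, p) per pool.
    """
    if cfg.n_null_reps < 100:
        logger.warning(
            "null_band with n_null_reps=%d (<100); quantiles will be noisy",
            cfg.n_null_reps,
        )
    return NullBandCache(cfg, seed).band(depth_y, depth_g)


def compute_site_bands(
    sites: list[SnpSite], cfg: ScanConfig, seed: int
) -> np.ndarray:
    """Per-site (lo, hi) bands conditional on each site's pool depths.

    Sites failing the depth filter get NaN rows. Depth pairs are memoised so
    the Monte-Carlo cost scales with the number of distinct pairs.
    """
    cache = NullBandCache(cfg, seed)
    out = np.full((len(sites), 2), math.nan)
    for i, s in enumerate(sites):
        if not site_passes(s, cfg.min_depth):
            continue
        out[i] = cache.band(s.y_ref + s.y_alt, s.g_ref + s.g_alt)
    return out


def scan_with_band(
    sites: list[SnpSite], cfg: ScanConfig, chrom_len: int, seed: int
) -> list[WindowStat]:
    """Window scan with the depth-conditional null band attached."""
    bands = compute_site_bands(sites, cfg, seed)
    return window_scan(sites, cfg, chrom_len, site_bands=bands)


def call_regions(windows: list[WindowStat]) -> list[Region]:
    """Merge runs of consecutive windows whose Δ exceeds the upper band.

    No-data windows and windows without a band break runs; runs whose
    genomic spans overlap (they share sites through the sliding window) are
    merged, with the mean Δ pooled over all member windows.
    """
    runs: list[list[WindowStat]] = []
    current: list[WindowStat] = []
    for w in windows:
        sig = (
            w.has_data
            and not math.isnan(w.band_hi)
            and w.delta > w.band_hi
        )
        if sig:
            current.append(w)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)

    regions: list[Region] = []
    for run in runs:
        start, end = run[0].start, max(w.end for w in run)
        members = list(run)
        if regions and regions[-1].chrom == run[0].chrom and start < regions[-1].end:
            prev = regions.pop()
            start = prev.start
            end = max(end, prev.end)
            total = prev.mean_delta * prev.n_windows + sum(w.delta for w in members)
            n = prev.n_windows + len(members)
            regions.append(Region(run[0].chrom, start, end, total / n, n))
        else:
            regions.append(
                Region(
                    run[0].chrom,
                    start,
                    end,
                    sum(w.delta for w in members) / len(members),
                    len(members),
                )
            )
    return regions
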