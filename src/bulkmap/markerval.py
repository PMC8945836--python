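"""Fluorescence-based genotype calling and cosegregation validation.

Two-channel (FAM/HEX) endpoint signals are gated with rectangular
thresholds: the FAM cluster is the wild-type-allele homozygote, HEX the
mutant homozygote, both channels the heterozygote, neither a no-call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "FluorSignal",
    "SegCounts",
    "CosegResult",
    "call_genotype",
    "cosegregation_check",
    "segregation_chi2",
]

GENO_TO_PHENO = {"AA": "WT", "AB": "HET", "BB": "MUT"}


@dataclass(frozen=True)
class FluorSignal:
    sample: str
    fam: float
    hex: float

    def __post_init__(self) -> None:
        if self.fam < 0 or self.hex < 0:
            raise ValueError("fluorescence intensities must be non-negative")


@dataclass(frozen=True)
class SegCounts:
    n_aa: int
    n_ab: int
    n_bb: int

    def __post_init__(self) -> None:
        if min(self.n_aa, self.n_ab, self.n_bb) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("need at least one observation")

    @property
    def total(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb


class CosegResult(NamedTuple):
    perfect: bool
    discordant: list[str]
    n_called: int


def call_genotype(
    sig: FluorSignal, fam_thresh: float, hex_thresh: float
) -> str:
    """Gate one signal into AA / AB / BB / NN (ties count as detected)."""
    if fam_thresh <= 0 or hex_thresh <= 0:
        raise ValueError("thresholds must be > 0")
    fam_on = sig.fam >= fam_thresh
    hex_on = sig.hex >= hex_thresh
    if fam_on and hex_on:
        return "AB"
    if fam_on:
        return "AA"
    if hex_on:
        return "BB"
    return "NN"


def cosegregation_check(
    genotypes: Mapping[str, str], phenos: Mapping[str, str]
) -> CosegResult:
    """Compare marker calls with phenotype classes sample by sample.

    AA must match WT, AB HET, BB MUT; NN samples are excluded from
    concordance (but not from n_called bookkeeping of informative calls).
    """
    shared = [s for s in genotypes if s in phenos]
    if not shared:
        raise ValueError("no overlapping samples between calls and phenotypes")
    discordant = []
    n_called = 0
    for s in shared:
        g = genotypes[s]
        if g == "NN":
            continue
        n_called += 1
        if GENO_TO_PHENO.get(g) != phenos[s]:
            discordant.append(s)
    return CosegResult(not discordant, discordant, n_called)


def segregation_chi2(
    counts: SegCounts, ratio: tuple[float, float, float] = (1.0, 2.0, 1.0)
) -> tuple[float, int, float]:
    """Pearson chi-square of observed genotype counts against a ratio."""
    obs = np.array([counts.n_aa, counts.n_ab, counts.n_bb], dtype=float)
    props = np.asarray(ratio, dtype=float)
    exp = counts.total * props / props.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))
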