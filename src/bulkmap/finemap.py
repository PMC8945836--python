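"""Phenotype classification, recombinant screening, and interval narrowing.

Works on a codominant genotype matrix (calls A/H/B/NN) over an ordered
marker panel, restricted to mutant-class individuals selected by their
SPAD chlorophyll reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CALLS",
    "MarkerPanel",
    "NarrowResult",
    "classify_spad",
    "recombinants_at",
    "nn_count_at",
    "marker_summary",
    "narrow_interval",
]

CALLS = ("A", "H", "B", "NN")

# SPAD class boundaries: mutant < 10, wild type > 20, heterozygote between.
SPAD_MUT_BELOW = 10.0
SPAD_WT_ABOVE = 20.0


def classify_spad(spad: float) -> str:
    """Classify a SPAD reading into WT / HET / MUT.

    Boundary values 10 and 20 are assigned HET (the heterozygous range is
    open-ended in the source thresholds; we close it at both ends).
    """
    if spad < 0:
        raise ValueError("SPAD values are non-negative")
    if spad < SPAD_MUT_BELOW:
        return "MUT"
    if spad > SPAD_WT_ABOVE:
        return "WT"
    return "HET"


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered markers with genomic positions on one chromosome."""

    names: tuple[str, ...]
    chrom: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.positions):
            raise ValueError("names and positions differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("marker names must be unique")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("marker positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.names)

    def position_of(self, marker: str) -> int:
        try:
            return self.positions[self.names.index(marker)]
        except ValueError:
            raise KeyError(f"marker {marker!r} not in panel") from None


@dataclass(frozen=True)
class NarrowResult:
    left_flank: str | None
    right_flank: str | None
    cosegregating: frozenset[str]
    counts: Mapping[str, int]
    fallback: bool = False


def _mut_ids(genotypes: pd.DataFrame, phenos: Mapping[str, str]) -> list[str]:
    missing = [i for i in genotypes.index if i not in phenos]
    if missing:
        raise ValueError(f"phenotype missing for individuals: {missing[:5]}")
    return [i for i in genotypes.index if phenos[i] == "MUT"]


def recombinants_at(
    marker: str, genotypes: pd.DataFrame, phenos: Mapping[str, str]
) -> set[str]:
    """Mutant-class individuals whose call at ``marker`` is A or H.

    NN calls carry no evidence and are excluded (tally them with
    :func:`nn_count_at`).
    """
    if marker not in genotypes.columns:
        raise KeyError(f"marker {marker!r} absent from genotype matrix")
    col = genotypes[marker]
    return {i for i in _mut_ids(genotypes, phenos) if col[i] in ("A", "H")}


def nn_count_at(
    marker: str, genotypes: pd.DataFrame, phenos: Mapping[str, str]
) -> int:
    if marker not in genotypes.columns:
        raise KeyError(f"marker {marker!r} absent from genotype matrix")
    col = genotypes[marker]
    return sum(1 for i in _mut_ids(genotypes, phenos) if col[i] == "NN")


def marker_summary(
    panel: MarkerPanel, genotypes: pd.DataFrame, phenos: Mapping[str, str]
) -> pd.DataFrame:
    """Per-marker recombinant and missing-call counts over MUT individuals."""
    rows = []
    for name, pos in zip(panel.names, panel.positions):
        rows.append(
            {
                "marker": name,
                "pos": pos,
                "n_recombinant": len(recombinants_at(name, genotypes, phenos)),
                "n_missing": nn_count_at(name, genotypes, phenos),
            }
        )
    return pd.DataFrame(rows).set_index("marker")


def narrow_interval(
    panel: MarkerPanel,
    genotypes: pd.DataFrame,
    phenos: Mapping[str, str],
) -> NarrowResult:
    """Flank the causal locus between the nearest markers with recombinants.

    Cosegregating markers are those with zero recombinants among
    mutant-class individuals. The flanks are the closest markers on either
    side of the cosegregating block that still show recombinants. If no
    marker cosegregates, the adjacent marker pair with the minimal combined
    recombinant count is returned with a warning; if every marker
    cosegregates the interval is unresolved.
    """
    if len(panel) < 2:
        raise ValueError("need at least two markers to narrow an interval")
    counts = {
        name: len(recombinants_at(name, genotypes, phenos))
        for name in panel.names
    }
    zero = [i for i, name in enumerate(panel.names) if counts[name] == 0]
    if len(zero) == len(panel):
        raise ValueError("interval unresolved, add markers")
    if not zero:
        best = min(
            range(len(panel) - 1),
            key=lambda i: counts[panel.names[i]] + counts[panel.names[i + 1]],
        )
        warnings.warn(
            "no cosegregating marker; returning the adjacent pair with "
            "fewest recombinants",
            stacklevel=2,
        )
        return NarrowResult(
            panel.names[best],
            panel.names[best + 1],
            frozenset(),
            counts,
            fallback=True,
        )
    lo, hi = min(zero), max(zero)
    left = panel.names[lo - 1] if lo > 0 else None
    right = panel.names[hi + 1] if hi < len(panel) - 1 else None
    coseg = frozenset(panel.names[i] for i in zero)
    return NarrowResult(left, right, coseg, counts)
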