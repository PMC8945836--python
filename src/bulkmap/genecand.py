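"""CDS-level variant effect annotation and the candidate-gene filter cascade.

Effects are computed in CDS space (1-based, 5'→3'); minus-strand gene
models must be reverse-complemented into CDS space before annotation (the
GFF3/FASTA readers do this). The triage cascade keeps genes carrying at
least one exonic variant, then drops genes whose variants are all
mutagenesis-inconsistent (indels), all synonymous, or that are expressed
in neither line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "EFFECTS",
    "GeneModel",
    "VariantEffect",
    "TriageStep",
    "TriageResult",
    "annotate_variant",
    "ems_consistent",
    "triage",
]

EFFECTS = (
    "synonymous",
    "nonsynonymous",
    "stop_gained",
    "stop_lost",
    "frameshift",
    "inframe_indel",
    "noncoding",
)

_NUCS = set("ACGT")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its genomic span, CDS layout, and expression flags."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    cds_segments: tuple[tuple[int, int], ...] = ()
    annotation: str = ""
    expressed_wt: bool = True
    expressed_mut: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.end < self.start:
            raise ValueError("gene end before start")
        prev_end = 0
        for a, b in self.cds_segments:
            if b < a or a <= prev_end:
                raise ValueError("CDS segments must be ordered, non-overlapping")
            prev_end = b

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_segments)


@dataclass(frozen=True)
class VariantEffect:
    gene: str
    cds_pos: int
    ref: str
    alt: str
    codon_index: int | None
    ref_aa: str | None
    alt_aa: str | None
    effect: str
    ems_consistent: bool

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect class {self.effect!r}")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in _NUCS
            and self.alt in _NUCS
        )


def annotate_variant(
    cds_sequence: str,
    cds_pos: int,
    ref: str,
    alt: str,
    gene: str = "",
) -> VariantEffect:
    """Classify a variant given in CDS coordinates (1-based).

    SNVs are translated codon-wise with the standard genetic code;
    length-changing variants are frameshift when the length difference is
    not a multiple of 3 and in-frame indels otherwise.
    """
    cds = cds_sequence.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if not 1 <= cds_pos <= len(cds):
        raise ValueError("cds_pos outside the CDS")
    ref = ref.upper()
    alt = alt.upper()
    if ref == alt:
        raise ValueError("ref and alt are identical")

    if len(ref) == 1 and len(alt) == 1 and ref in _NUCS and alt in _NUCS:
        if cds[cds_pos - 1] != ref:
            raise ValueError(
                f"reference allele disagrees with CDS at position {cds_pos}: "
                f"CDS has {cds[cds_pos - 1]}, variant says {ref}"
            )
        codon_index = (cds_pos - 1) // 3 + 1  # == ceil(cds_pos / 3)
        c0 = (codon_index - 1) * 3
        ref_codon = cds[c0 : c0 + 3]
        offset = cds_pos - 1 - c0
        alt_codon = ref_codon[:offset] + alt + ref_codon[offset + 1 :]
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if ref_aa == alt_aa:
            effect = "synonymous"
        elif alt_aa == "*":
            effect = "stop_gained"
        elif ref_aa == "*":
            effect = "stop_lost"
        else:
            effect = "nonsynonymous"
        return VariantEffect(
            gene, cds_pos, ref, alt, codon_index, ref_aa, alt_aa, effect, True
        )

    # indel / length-changing variant
    if abs(len(ref) - len(alt)) % 3 != 0:
        effect = "frameshift"
    else:
        effect = "inframe_indel"
    return VariantEffect(gene, cds_pos, ref, alt, None, None, None, effect, False)


def ems_consistent(effect: VariantEffect) -> bool:
    """EMS mutagenesis yields single-base substitutions; indels are not
    consistent with it."""
    return effect.is_snv


@dataclass(frozen=True)
class TriageStep:
    step: int
    description: str
    removed: tuple[str, ...]


@dataclass(frozen=True)
class TriageResult:
    candidates: tuple[str, ...]
    steps: tuple[TriageStep, ...]


def triage(
    genes: Sequence[GeneModel], effects: Iterable[VariantEffect]
) -> TriageResult:
    """Apply the four-step candidate filter cascade, recording an audit trail.

    1. keep genes with at least one exonic variant;
    2. drop genes whose variants are all EMS-inconsistent;
    3. drop genes whose variants are all synonymous;
    4. drop genes expressed in neither line.
    """
    by_id = {g.id: g for g in genes}
    per_gene: dict[str, list[VariantEffect]] = {g.id: [] for g in genes}
    for e in effects:
        if e.gene not in by_id:
            raise ValueError(f"effect references unknown gene {e.gene!r}")
        if e.effect != "noncoding":
            per_gene[e.gene].append(e)

    order = [g.id for g in genes]
    steps: list[TriageStep] = []

    def apply(step_no: int, desc: str, keep_pred) -> None:
        nonlocal order
        removed = tuple(g for g in order if not keep_pred(g))
        order = [g for g in order if keep_pred(g)]
        steps.append(TriageStep(step_no, desc, removed))

    apply(1, "no exonic variant", lambda g: len(per_gene[g]) > 0)
    apply(
        2,
        "all variants EMS-inconsistent",
        lambda g: any(ems_consistent(e) for e in per_gene[g]),
    )
    apply(
        3,
        "all variants synonymous",
        lambda g: any(e.effect != "synonymous" for e in per_gene[g]),
    )
    apply(
        4,
        "expressed in neither line",
        lambda g: by_id[g].expressed_wt or by_id[g].expressed_mut,
    )
    return TriageResult(tuple(order), tuple(steps))
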