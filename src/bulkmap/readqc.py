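"""Read-level quality-control filters and library-level duplicate removal.

Three pure per-read predicates (ambiguous-base fraction, low-quality
fraction, adapter contamination) plus exact sequence-pair duplicate
removal. A paired read is dropped when either mate fails a filter.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "filter_n_fraction",
    "filter_low_quality",
    "filter_adapter",
    "remove_duplicates",
    "qc_pairs",
    "read_fastq",
    "write_fastq",
]

N_FRACTION_MAX = 0.10  # drop at >= 10% ambiguous bases
LOW_QUAL_PHRED = 5
LOW_QUAL_FRACTION = 0.50  # drop at strictly > 50% low-quality bases
ADAPTER_MIN_SPAN = 10  # drop at strictly > 10 aligned nt
ADAPTER_MAX_MISMATCH = 0.10  # allowing <= 10% mismatches


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    qualities: tuple[int, ...]
    mate_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities differ in length")
        if any(q < 0 for q in self.qualities):
            raise ValueError("phred qualities must be >= 0")


def filter_n_fraction(read: Read) -> bool:
    """Keep unless >= 10% of bases are unidentified (N)."""
    if not read.sequence:
        raise ValueError("empty read")
    frac = read.sequence.upper().count("N") / len(read.sequence)
    return frac < N_FRACTION_MAX


def filter_low_quality(read: Read) -> bool:
    """Keep unless strictly more than 50% of bases have phred < 5."""
    if not read.sequence:
        raise ValueError("empty read")
    n_low = sum(1 for q in read.qualities if q < LOW_QUAL_PHRED)
    return n_low / len(read.qualities) <= LOW_QUAL_FRACTION


def filter_adapter(read: Read, adapter: str) -> bool:
    """Keep unless some ungapped alignment of an adapter substring spans
    more than 10 nt of the read with at most 10% mismatches.

    Every relative offset of the adapter against the read is scanned
    (covering both read ends), and within each overlap every sub-span
    longer than the minimum is tested.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.sequence.upper()
    adp = adapter.upper()
    n, m = len(seq), len(adp)
    for off in range(-m + 1, n):  # adapter start relative to read start
        lo, hi = max(0, off), min(n, off + m)
        span = hi - lo
        if span <= ADAPTER_MIN_SPAN:
            continue
        # prefix sums of mismatches over the overlap
        ps = [0]
        for i in range(lo, hi):
            ps.append(ps[-1] + (seq[i] != adp[i - off]))
        for a in range(span - ADAPTER_MIN_SPAN):
            for b in range(a + ADAPTER_MIN_SPAN + 1, span + 1):
                if ps[b] - ps[a] <= ADAPTER_MAX_MISMATCH * (b - a):
                    return False
    return True


def remove_duplicates(pairs: list[tuple[Read, Read]]) -> list[tuple[Read, Read]]:
    """Keep the first pair for each exact (sequence1, sequence2) identity."""
    seen: set[tuple[str, str]] = set()
    out = []
    for pair in pairs:
        key = (pair[0].sequence, pair[1].sequence)
        if key not in seen:
            seen.add(key)
            out.append(pair)
    return out


def qc_pairs(
    pairs: Iterable[tuple[Read, Read]], adapter: str
) -> tuple[list[tuple[Read, Read]], dict[str, int]]:
    """Run all filters then deduplicate; returns survivors and drop tallies."""
    counts = {"n_fraction": 0, "low_quality": 0, "adapter": 0, "duplicate": 0}
    kept: list[tuple[Read, Read]] = []
    for pair in pairs:
        if not all(filter_n_fraction(r) for r in pair):
            counts["n_fraction"] += 1
        elif not all(filter_low_quality(r) for r in pair):
            counts["low_quality"] += 1
        elif not all(filter_adapter(r, adapter) for r in pair):
            counts["adapter"] += 1
        else:
            kept.append(pair)
    deduped = remove_duplicates(kept)
    counts["duplicate"] = len(kept) - len(deduped)
    return deduped, counts


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> list[Read]:
    with _open_text(path, "r") as fh:
        return [
            Read(
                rec.id,
                str(rec.seq),
                tuple(rec.letter_annotations["phred_quality"]),
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(path: str | Path, reads: Iterable[Read]) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    with _open_text(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")
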