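"""Read-level quality control for paired CAG-repeat amplicon sequencing.

Four filters are applied, in order, to each read pair:

1. mean base Phred quality < 20 on either mate;
2. disagreement between the forward and reverse mate (no exact overlap of
   the reverse-complemented R2 with R1);
3. fewer than 6 CAG trinucleotides in the merged sense sequence;
4. absence of the full forward primer at the 5' end or the full reverse
   primer (as its reverse complement) near the 3' end.

A removed pair is attributed to the first filter it fails.  Kept pairs are
emitted as merged, sense-oriented sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .repeat_model import reverse_complement

__all__ = [
    "SequencedRead",
    "ReadPair",
    "QcParams",
    "QcReport",
    "FILTER_NAMES",
    "mean_phred",
    "merge_pair",
    "pair_concordant",
    "count_cag",
    "has_primers",
    "qc_filter",
    "read_fastq_pairs",
    "write_fastq_pairs",
]

FILTER_NAMES = ("mean_phred", "pair_discordant", "cag_count", "primer_missing")


@dataclass(frozen=True)
class SequencedRead:
    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quality strings differ in length")
        if self.quals and not (0 <= min(self.quals) and max(self.quals) <= 60):
            raise ValueError("Phred scores must lie in [0, 60]")


@dataclass(frozen=True)
class ReadPair:
    fwd: SequencedRead
    rev: SequencedRead

    def __post_init__(self) -> None:
        if self.fwd.id != self.rev.id:
            raise ValueError(f"mate ids differ: {self.fwd.id} vs {self.rev.id}")


@dataclass(frozen=True)
class QcParams:
    min_mean_phred: float = 20.0
    min_cag_count: int = 6
    primer_fwd: str = ""
    primer_rev: str = ""
    min_overlap: int = 30
    primer_search_window: int = 30  # nt from each end searched for a primer


@dataclass
class QcReport:
    n_input: int = 0
    n_kept: int = 0
    removed_by_filter: dict[str, int] = field(
        default_factory=lambda: {name: 0 for name in FILTER_NAMES}
    )
    kept_ids: list[str] = field(default_factory=list)

    def check(self) -> None:
        assert self.n_input == self.n_kept + sum(self.removed_by_filter.values())

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "removed_by_filter": dict(self.removed_by_filter),
        }


def mean_phred(read: SequencedRead) -> float:
    """Arithmetic mean of per-base Phred scores (a read at exactly the
    threshold is kept: only means strictly below 20 are removed)."""
    if not read.quals:
        raise ValueError("cannot take mean Phred of an empty read")
    return sum(read.quals) / len(read.quals)


def merge_pair(pair: ReadPair, min_overlap: int = 30) -> str | None:
    """Merge mates into a sense consensus by exact overlap.

    The reverse-complemented R2 is slid over R1; the largest zero-mismatch
    overlap of at least ``min_overlap`` nt defines the merge.  ``None`` when
    no such overlap exists (discordant pair).
    """
    f = pair.fwd.bases
    r = reverse_complement(pair.rev.bases)
    if not f or not r:
        return None
    # offset = position of r's first base relative to f's first base
    max_off = len(f) - min_overlap
    for off in range(0, max_off + 1):
        ov = min(len(f) - off, len(r))
        if ov < min_overlap:
            break
        if f[off : off + ov] == r[:ov]:
            return f[:off] + r if off + len(r) >= len(f) else f
    return None


def pair_concordant(pair: ReadPair, min_overlap: int = 30) -> bool:
    """True iff the mates agree exactly over an overlap of >= min_overlap."""
    return merge_pair(pair, min_overlap) is not None


def count_cag(seq: str) -> int:
    """Non-overlapping left-to-right count of the CAG trinucleotide."""
    n = i = 0
    while True:
        i = seq.find("CAG", i)
        if i < 0:
            return n
        n += 1
        i += 3


def has_primers(seq: str, params: QcParams) -> bool:
    """True iff the full forward primer occurs near the 5' end and the full
    reverse primer (reverse-complemented) occurs near the 3' end."""
    w = params.primer_search_window
    if params.primer_fwd:
        head = seq[: w + len(params.primer_fwd)]
        if params.primer_fwd not in head:
            return False
    if params.primer_rev:
        tail_probe = reverse_complement(params.primer_rev)
        tail = seq[-(w + len(tail_probe)) :]
        if tail_probe not in tail:
            return False
    return True


def qc_filter(
    pairs: Iterable[ReadPair], params: QcParams
) -> tuple[list[str], QcReport]:
    """Apply the four filters in order; return merged sense sequences of
    kept pairs and a per-filter removal tally."""
    report = QcReport()
    kept: list[str] = []
    for pair in pairs:
        report.n_input += 1
        if min(mean_phred(pair.fwd), mean_phred(pair.rev)) < params.min_mean_phred:
            report.removed_by_filter["mean_phred"] += 1
            continue
        merged = merge_pair(pair, params.min_overlap)
        if merged is None:
            report.removed_by_filter["pair_discordant"] += 1
            continue
        if count_cag(merged) < params.min_cag_count:
            report.removed_by_filter["cag_count"] += 1
            continue
        if not has_primers(merged, params):
            report.removed_by_filter["primer_missing"] += 1
            continue
        report.n_kept += 1
        report.kept_ids.append(pair.fwd.id)
        kept.append(merged)
    report.check()
    return kept, report


# ---------------------------------------------------------------------------
# FASTQ I/O (Sanger / Illumina 1.8+, Phred+33)


def read_fastq_pairs(r1: str | Path, r2: str | Path) -> Iterator[ReadPair]:
    from Bio import SeqIO

    for rec1, rec2 in zip(
        SeqIO.parse(str(r1), "fastq"), SeqIO.parse(str(r2), "fastq"), strict=True
    ):
        yield ReadPair(
            fwd=SequencedRead(
                rec1.id, str(rec1.seq), tuple(rec1.letter_annotations["phred_quality"])
            ),
            rev=SequencedRead(
                rec2.id, str(rec2.seq), tuple(rec2.letter_annotations["phred_quality"])
            ),
        )


def write_fastq_pairs(
    pairs: Sequence[ReadPair], r1: str | Path, r2: str | Path
) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    def rec(read: SequencedRead) -> "SeqRecord":
        r = SeqRecord(Seq(read.bases), id=read.id, description="")
        r.letter_annotations["phred_quality"] = list(read.quals)
        return r

    SeqIO.write([rec(p.fwd) for p in pairs], str(r1), "fastq")
    SeqIO.write([rec(p.rev) for p in pairs], str(r2), "fastq")
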