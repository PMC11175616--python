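"""Codon-wise conversion calling on QC-passed repeat amplicon reads.

QC-passed merged reads are decomposed into trinucleotides between the flank
anchors, assigned to the nearest known allele by length, and split into
indel-containing vs clean reads.  Clean reads are typed codon-wise against
the nine trinucleotides that single-base changes of CAG (and the reference
CAG itself) can produce, per-site CAG->CAA percentages are computed with
optional empty-vector (EV) baseline subtraction, and duplicated-interruption
and multi-conversion levels are summarized.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .repeat_model import CAA, CAG, LocusTemplate, RepeatAllele, repeat_site_indices

__all__ = [
    "CONVERSION_TYPES",
    "Indel",
    "ReadCall",
    "ConversionSummary",
    "extract_repeat_segment",
    "decompose_repeat",
    "classify_indel",
    "call_read",
    "call_reads",
    "conversion_type_counts",
    "per_site_conversion",
    "duplicated_interruption_fractions",
    "multiconversion_histogram",
    "indel_percentages",
    "summarize_sample",
    "allele_specific_summary",
]

#: The trinucleotide types tallied per read (the reference CAG, its
#: single-base variants reported by the study, and CCG).  CAT is not part of
#: the default set; pass ``extra_types`` to extend.
CONVERSION_TYPES = ("CAA", "CAC", "CAG", "CCG", "CGG", "CTG", "AAG", "GAG", "TAG")

_ANCHOR_LEN = 12


@dataclass(frozen=True)
class Indel:
    kind: str  # "none" | "insertion" | "deletion" | "frameshift"
    codons: int = 0  # whole-codon length change (0 for none/frameshift)

    @property
    def is_clean(self) -> bool:
        return self.kind == "none"

    @property
    def in_frame(self) -> bool:
        return self.kind in ("insertion", "deletion")


@dataclass
class ReadCall:
    allele: str
    codons: tuple[str, ...] | None  # None for frameshift reads
    indel: Indel
    conversion_sites: frozenset[int] = field(default_factory=frozenset)
    other_variants: dict[int, str] = field(default_factory=dict)


def extract_repeat_segment(seq: str, template: LocusTemplate) -> str | None:
    """Raw nucleotides between the 5'-flank anchor and the 3'-flank anchor,
    or None when either anchor is absent."""
    a5 = template.flank5[-_ANCHOR_LEN:]
    a3 = template.flank3[:_ANCHOR_LEN]
    i = seq.find(a5)
    if i < 0:
        return None
    start = i + len(a5)
    j = seq.find(a3, start)
    if j < 0:
        return None
    return seq[start:j]


def decompose_repeat(seq: str, template: LocusTemplate) -> tuple[str, ...] | None:
    """Trinucleotide decomposition of the repeat region, in frame with the
    repeat start; None when the flank anchors cannot be located.

    The returned list covers complete codons only; whether a trailing
    remainder exists (a frameshift) is judged from the raw segment by
    :func:`classify_indel`.
    """
    segment = extract_repeat_segment(seq, template)
    if segment is None:
        return None
    return tuple(segment[i : i + 3] for i in range(0, len(segment) - len(segment) % 3, 3))


def classify_indel(
    segment: str, alleles: Sequence[RepeatAllele]
) -> tuple[RepeatAllele, Indel]:
    """Assign a repeat segment to the nearest-length allele and call its
    indel status.

    Whole-codon length differences are in-frame insertions/deletions; a
    segment whose length is not a multiple of 3 is a frameshift.  Length
    ties go to the shorter allele.
    """
    if not alleles:
        raise ValueError("at least one reference allele required")
    n_nt = len(segment)
    assigned = min(alleles, key=lambda a: (abs(3 * len(a.codons) - n_nt), len(a.codons)))
    if n_nt % 3 != 0:
        return assigned, Indel("frameshift")
    delta = n_nt // 3 - len(assigned.codons)
    if delta == 0:
        return assigned, Indel("none")
    if delta > 0:
        return assigned, Indel("insertion", delta)
    return assigned, Indel("deletion", -delta)


def call_read(
    seq: str, template: LocusTemplate, alleles: Sequence[RepeatAllele] | None = None
) -> ReadCall | None:
    """Full per-read call: decompose, assign allele, call indel, and (for
    clean reads) record CAG->CAA conversion sites and other variant codons.

    Conversion sites are 1-based CAG indices of the assigned allele; the
    allele's own interruption codons (reference CAA) are not conversions.
    """
    alleles = list(alleles) if alleles is not None else list(template.alleles)
    segment = extract_repeat_segment(seq, template)
    if segment is None:
        return None
    allele, indel = classify_indel(segment, alleles)
    codons = (
        tuple(segment[i : i + 3] for i in range(0, len(segment), 3))
        if indel.kind != "frameshift"
        else None
    )
    call = ReadCall(allele=allele.name, codons=codons, indel=indel)
    if indel.is_clean and codons is not None:
        site_of = {
            idx: s
            for s, idx in enumerate(repeat_site_indices(allele.codons), start=1)
        }
        converted = set()
        for i, (obs, exp) in enumerate(zip(codons, allele.codons)):
            if obs == exp:
                continue
            if i in site_of and obs == CAA:
                converted.add(site_of[i])
            else:
                call.other_variants[i] = obs
        call.conversion_sites = frozenset(converted)
    return call


def call_reads(
    seqs: Sequence[str],
    template: LocusTemplate,
    alleles: Sequence[RepeatAllele] | None = None,
) -> list[ReadCall]:
    calls = [call_read(s, template, alleles) for s in seqs]
    return [c for c in calls if c is not None]


def _ref_allele(alleles: Sequence[RepeatAllele], name: str) -> RepeatAllele:
    for a in alleles:
        if a.name == name:
            return a
    raise KeyError(name)


def _scan_region(call: ReadCall, allele: RepeatAllele) -> tuple[str, ...]:
    """Codons of the read scanned for typing: the uninterrupted-CAG region
    of the assigned allele (the reference CAA-CAG interruption is excluded)."""
    assert call.codons is not None
    n_run = 0
    for c in allele.codons:
        if c == CAG:
            n_run += 1
        else:
            break
    return call.codons[:n_run]


def conversion_type_counts(
    calls: Sequence[ReadCall],
    alleles: Sequence[RepeatAllele],
    types: Sequence[str] = CONVERSION_TYPES,
) -> dict[str, int]:
    """Presence-based per-type read counts over indel-free reads.

    A read increments a type's count when at least one codon of its scanned
    region (interruption codons excluded) equals that type.
    """
    counts = {t: 0 for t in types}
    for call in calls:
        if not call.indel.is_clean or call.codons is None:
            continue
        region = set(_scan_region(call, _ref_allele(alleles, call.allele)))
        for t in types:
            if t in region:
                counts[t] += 1
    return counts


def _eligible(call: ReadCall, allele: RepeatAllele) -> bool:
    """Clean read of the expected codon count containing only CAG/CAA."""
    return (
        call.indel.is_clean
        and call.codons is not None
        and len(call.codons) == len(allele.codons)
        and all(c in (CAG, CAA) for c in call.codons)
    )


def per_site_conversion(
    calls: Sequence[ReadCall],
    allele: RepeatAllele,
    ev_baseline: Sequence[float] | None = None,
    denominator: str = "all",
) -> np.ndarray:
    """Percent of reads with CAA at each CAG site of ``allele``.

    Only clean CAG/CAA-only reads of the expected length contribute to the
    numerator; the denominator is every call passed in ("all", the QC-passed
    total, matching how percent conversion is reported) or only the eligible
    reads ("eligible").  ``ev_baseline`` (same per-site scale) is subtracted
    and negatives are floored at 0.
    """
    n_sites = allele.n_sites
    counts = np.zeros(n_sites)
    n_elig = 0
    sample_calls = [c for c in calls if c.allele == allele.name]
    for call in sample_calls:
        if not _eligible(call, allele):
            continue
        n_elig += 1
        for s in call.conversion_sites:
            counts[s - 1] += 1
    denom = len(sample_calls) if denominator == "all" else n_elig
    if denom == 0:
        raise ValueError("no eligible reads: per-site conversion undefined")
    pct = 100.0 * counts / denom
    if ev_baseline is not None:
        pct = np.maximum(pct - np.asarray(ev_baseline, dtype=float), 0.0)
    return pct


def duplicated_interruption_fractions(
    calls: Sequence[ReadCall],
) -> tuple[float, float]:
    """(% of QC-passed reads ending in CAA-CAG-CAA-CAG, % of those that also
    carry >= 1 additional CAA upstream of the doublets)."""
    if not calls:
        return 0.0, 0.0
    di = di_plus = 0
    for call in calls:
        if call.codons is None or len(call.codons) < 4:
            continue
        if tuple(call.codons[-4:]) == (CAA, CAG, CAA, CAG):
            di += 1
            if CAA in call.codons[:-4]:
                di_plus += 1
    n = len(calls)
    return 100.0 * di / n, 100.0 * di_plus / n


def multiconversion_histogram(
    calls: Sequence[ReadCall], allele: RepeatAllele
) -> Counter:
    """Distribution of the number of CAG->CAA conversions per clean
    CAG/CAA-only read, irrespective of position (so multiple conversions
    need not be consecutive)."""
    hist: Counter = Counter()
    for call in calls:
        if call.allele == allele.name and _eligible(call, allele):
            hist[len(call.conversion_sites)] += 1
    return hist


def indel_percentages(calls: Sequence[ReadCall]) -> dict[str, float]:
    """Percent of reads with any indel, in-frame insertions and in-frame
    deletions, over all calls."""
    n = len(calls)
    if n == 0:
        return {"indel_pct": 0.0, "inframe_ins_pct": 0.0, "inframe_del_pct": 0.0}
    ins = sum(1 for c in calls if c.indel.kind == "insertion")
    dele = sum(1 for c in calls if c.indel.kind == "deletion")
    any_indel = sum(1 for c in calls if not c.indel.is_clean)
    return {
        "indel_pct": 100.0 * any_indel / n,
        "inframe_ins_pct": 100.0 * ins / n,
        "inframe_del_pct": 100.0 * dele / n,
    }


@dataclass
class ConversionSummary:
    """Per-sample (optionally per-allele) conversion metrics."""

    n_reads: int
    type_counts: dict[str, int]
    per_site_caa_pct: np.ndarray
    di_fraction: float
    di_plus_other_fraction: float
    multiconv_hist: Counter
    indel_pct: float
    inframe_ins_pct: float
    inframe_del_pct: float

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "type_counts": dict(self.type_counts),
            "per_site_caa_pct": [float(x) for x in self.per_site_caa_pct],
            "di_fraction": self.di_fraction,
            "di_plus_other_fraction": self.di_plus_other_fraction,
            "multiconv_hist": {int(k): int(v) for k, v in sorted(self.multiconv_hist.items())},
            "indel_pct": self.indel_pct,
            "inframe_ins_pct": self.inframe_ins_pct,
            "inframe_del_pct": self.inframe_del_pct,
        }


def summarize_sample(
    calls: Sequence[ReadCall],
    allele: RepeatAllele,
    alleles: Sequence[RepeatAllele],
    ev_baseline: Sequence[float] | None = None,
) -> ConversionSummary:
    indels = indel_percentages(calls)
    return ConversionSummary(
        n_reads=len(calls),
        type_counts=conversion_type_counts(calls, alleles),
        per_site_caa_pct=per_site_conversion(calls, allele, ev_baseline),
        di_fraction=duplicated_interruption_fractions(calls)[0],
        di_plus_other_fraction=duplicated_interruption_fractions(calls)[1],
        multiconv_hist=multiconversion_histogram(calls, allele),
        **indels,
    )


def _conversion_efficiency(calls: Sequence[ReadCall], allele: RepeatAllele) -> float:
    """Percent of an allele's reads (clean CAG/CAA-only) carrying >= 1
    CAG->CAA conversion, relative to all reads assigned to the allele."""
    mine = [c for c in calls if c.allele == allele.name]
    if not mine:
        return float("nan")
    converted = sum(1 for c in mine if _eligible(c, allele) and c.conversion_sites)
    return 100.0 * converted / len(mine)


def allele_specific_summary(
    replicate_calls: Sequence[Sequence[ReadCall]],
    alleles: tuple[RepeatAllele, RepeatAllele],
) -> dict:
    """Per-allele editing summaries across replicates plus a Welch t-test
    comparing conversion efficiency between the two alleles.

    With fewer than two replicates the comparison is omitted (``test`` is
    None and a warning string is set).
    """
    a, b = alleles
    eff = {
        allele.name: np.array(
            [_conversion_efficiency(calls, allele) for calls in replicate_calls]
        )
        for allele in alleles
    }
    per_allele = {
        allele.name: {
            "conversion_efficiency_pct": eff[allele.name].tolist(),
            "per_site_caa_pct": np.mean(
                [per_site_conversion(calls, allele) for calls in replicate_calls], axis=0
            ).tolist(),
            "inframe_ins_pct": [
                indel_percentages([c for c in calls if c.allele == allele.name])[
                    "inframe_ins_pct"
                ]
                for calls in replicate_calls
            ],
            "inframe_del_pct": [
                indel_percentages([c for c in calls if c.allele == allele.name])[
                    "inframe_del_pct"
                ]
                for calls in replicate_calls
            ],
        }
        for allele in alleles
    }
    result = {"alleles": per_allele, "test": None, "warning": None}
    if len(replicate_calls) >= 2:
        t, p = stats.ttest_ind(eff[a.name], eff[b.name], equal_var=False)
        result["test"] = {"statistic": float(t), "p_value": float(p), "kind": "welch_t"}
    else:
        result["warning"] = "fewer than 2 replicates: allele comparison omitted"
    return result
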