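"""Repeat-allele arithmetic for the *HTT* CAG tract.

The glutamine-encoding tract of *HTT* exon 1 is modelled as an ordered list
of trinucleotides ("codons").  Most disease chromosomes carry a *canonical*
repeat: an uninterrupted run of CAG followed by a single CAA-CAG doublet.
Two rare variants exist: *loss of interruption* (LOI, no CAA-CAG) and
*duplicated interruption* (DI, two consecutive CAA-CAG doublets).  Because
CAA also encodes glutamine, alleles of equal uninterrupted CAG length differ
in polyglutamine length by class (canonical = CAG+2, LOI = CAG, DI = CAG+4),
which is what makes the structure classes informative about whether DNA
repeat length or protein polyglutamine length drives age-at-onset.

The downstream CCG-rich (proline) tract is not part of the codon list; it
lives in the 3' flank of the locus template.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RepeatStructureClass",
    "RepeatAllele",
    "LocusTemplate",
    "classify_structure",
    "glutamine_length",
    "uninterrupted_cag_length",
    "repeat_site_indices",
    "apply_conversion",
    "effective_cag",
    "build_amplicon_reference",
    "canonical_allele",
    "loi_allele",
    "di_allele",
    "reverse_complement",
    "default_htt_template",
    "load_locus_config",
    "write_reference_fasta",
]

CAG = "CAG"
CAA = "CAA"

_DNA_CODON = re.compile(r"^[ACGT]{3}$")

# *HTT* exon-1 sense-strand context around the CAG tract.  The 5' flank ends
# immediately before the first CAG; the 3' flank starts at the first CCG of
# the proline-rich tract.  The flanks contain the amplicon primer sites.
_HTT_FLANK5 = "ATGGCGACCCTGGAAAAGCTGATGAAGGCCTTCGAGTCCCTCAAGTCCTTC"
_HTT_FLANK3 = "CCGCCACCGCCGCCGCCGCCGCCGCCTCCTCAGCTTCCTCAGCCGCCGCCG"
_HTT_PRIMER_FWD = "ATGAAGGCCTTCGAGTCCC"
_HTT_PRIMER_REV = "GGCTGAGGAAGCTGAGGA"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class RepeatStructureClass(enum.Enum):
    """Interruption-structure class of a repeat allele."""

    CANONICAL = "canonical"
    LOI = "loss_of_interruption"
    DI = "duplicated_interruption"
    CUSTOM = "custom"


def _validate_codons(codons: Sequence[str]) -> None:
    for c in codons:
        if not isinstance(c, str) or not _DNA_CODON.match(c):
            raise ValueError(f"invalid codon {c!r}: codons must be uppercase DNA triplets")


def classify_structure(codons: Sequence[str]) -> RepeatStructureClass:
    """Classify a codon list as canonical, LOI, DI or custom.

    Canonical: (CAG)^n followed by exactly one CAA-CAG doublet.
    LOI:       (CAG)^n with nothing after.
    DI:        (CAG)^n followed by exactly two CAA-CAG doublets.
    Any other arrangement (internal CAA, non-CAG/CAA codons, ...) is CUSTOM.
    """
    if not codons:
        raise ValueError("empty codon list cannot be classified")
    _validate_codons(codons)
    codons = list(codons)
    if all(c == CAG for c in codons):
        return RepeatStructureClass.LOI
    for tail, cls in (
        ([CAA, CAG], RepeatStructureClass.CANONICAL),
        ([CAA, CAG, CAA, CAG], RepeatStructureClass.DI),
    ):
        n = len(codons) - len(tail)
        if n >= 1 and codons[n:] == tail and all(c == CAG for c in codons[:n]):
            return cls
    return RepeatStructureClass.CUSTOM


def uninterrupted_cag_length(codons: Sequence[str]) -> int:
    """Length of the longest run of consecutive CAG codons.

    This, not polyglutamine length, is the primary determinant of HD
    age-at-onset.
    """
    if not codons:
        raise ValueError("empty codon list")
    best = run = 0
    for c in codons:
        run = run + 1 if c == CAG else 0
        best = max(best, run)
    return best


@dataclass(frozen=True)
class RepeatAllele:
    """A repeat tract with its flanking context.

    ``codons`` covers the glutamine-encoding tract plus interruption codons
    only; the CCG tract belongs to the 3' flank of :class:`LocusTemplate`.
    """

    codons: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        _validate_codons(self.codons)
        object.__setattr__(self, "codons", tuple(self.codons))

    @property
    def structure(self) -> RepeatStructureClass:
        return classify_structure(self.codons)

    @property
    def cag_length(self) -> int:
        return uninterrupted_cag_length(self.codons)

    @property
    def glutamine_length(self) -> int:
        return glutamine_length(self)

    @property
    def n_cag_codons(self) -> int:
        return sum(1 for c in self.codons if c == CAG)

    @property
    def n_sites(self) -> int:
        """Number of addressable CAG sites (the uninterrupted repeat)."""
        return len(repeat_site_indices(self.codons))

    def sequence(self) -> str:
        return "".join(self.codons)


def glutamine_length(allele: RepeatAllele | Sequence[str]) -> int:
    """Number of glutamine codons (CAG or CAA) in the tract.

    Reproduces the per-class formulas: canonical encodes CAG+2 glutamines,
    LOI CAG, DI CAG+4.
    """
    codons = allele.codons if isinstance(allele, RepeatAllele) else allele
    _validate_codons(codons)
    return sum(1 for c in codons if c in (CAG, CAA))


def repeat_site_indices(codons: Sequence[str]) -> list[int]:
    """Codon indices of the numbered repeat sites, 5'->3'.

    Site numbering covers the repeat proper: every codon position before
    the trailing interruption tail (the maximal suffix of whole CAA-CAG
    doublets).  A canonical 43-CAG allele therefore has exactly 43 sites;
    the CAA-CAG interruption itself is never a numbered site.  Numbering is
    positional, so it is stable under prior conversions (a converted site
    reads CAA but keeps its index).
    """
    m = len(codons)
    while m >= 2 and codons[m - 2] == CAA and codons[m - 1] == CAG:
        m -= 2
    return list(range(m))


def apply_conversion(allele: RepeatAllele, site: int) -> RepeatAllele:
    """Convert the CAG at repeat site ``site`` (1-based, 5'->3') to CAA, as
    a cytosine base editor acting on the antisense strand would.

    Glutamine length and codon count are invariant under this operation;
    the structure class is re-derived from the new codon list.  Addressing
    a site that is already CAA (or any non-CAG codon) is an error.
    """
    sites = repeat_site_indices(allele.codons)
    if not 1 <= site <= len(sites):
        raise ValueError(
            f"allele {allele.name or '<unnamed>'} has {len(sites)} repeat "
            f"sites; cannot convert site {site}"
        )
    codons = list(allele.codons)
    if codons[sites[site - 1]] != CAG:
        raise ValueError(
            f"site {site} is {codons[sites[site - 1]]}, not CAG; nothing to convert"
        )
    codons[sites[site - 1]] = CAA
    return replace(allele, codons=tuple(codons))


def effective_cag(
    allele: RepeatAllele,
    offsets: Mapping[RepeatStructureClass, float] | None = None,
) -> float:
    """Canonical-equivalent CAG length: uninterrupted CAG plus the
    class-specific onset offset (defaults: LOI +3, DI -1, canonical 0).

    A DI allele of 41 CAG with offset -1 behaves, with respect to onset,
    like a canonical allele of 40 CAG.
    """
    table: dict[RepeatStructureClass, float] = {
        RepeatStructureClass.CANONICAL: 0,
        RepeatStructureClass.LOI: 3,
        RepeatStructureClass.DI: -1,
    }
    if offsets:
        table.update(offsets)
    cls = allele.structure
    if cls not in table:
        raise ValueError(f"no effective-CAG offset defined for structure {cls.name}")
    return allele.cag_length + table[cls]


# ---------------------------------------------------------------------------
# locus template


@dataclass(frozen=True)
class LocusTemplate:
    """Amplicon context of the repeat: flanks, primers and known alleles."""

    flank5: str
    flank3: str
    primer_fwd: str
    primer_rev: str
    alleles: tuple[RepeatAllele, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.primer_fwd and self.primer_fwd not in self.flank5:
            raise ValueError("forward primer not found in 5' flank")
        if self.primer_rev and reverse_complement(self.primer_rev) not in self.flank3:
            raise ValueError("reverse-complement of reverse primer not found in 3' flank")

    def allele_by_name(self, name: str) -> RepeatAllele:
        for a in self.alleles:
            if a.name == name:
                return a
        raise KeyError(name)

    def with_alleles(self, alleles: Iterable[RepeatAllele]) -> "LocusTemplate":
        return replace(self, alleles=tuple(alleles))


def build_amplicon_reference(template: LocusTemplate, allele: RepeatAllele) -> str:
    """Sense-strand amplicon reference: flank5 + tract + flank3."""
    if not template.flank5 or not template.flank3:
        raise ValueError("template flanks must be non-empty")
    return template.flank5 + allele.sequence() + template.flank3


def canonical_allele(n_cag: int, name: str = "") -> RepeatAllele:
    if n_cag < 1:
        raise ValueError("canonical allele needs >= 1 CAG")
    return RepeatAllele(codons=(CAG,) * n_cag + (CAA, CAG), name=name or f"canonical_{n_cag}")


def loi_allele(n_cag: int, name: str = "") -> RepeatAllele:
    if n_cag < 1:
        raise ValueError("LOI allele needs >= 1 CAG")
    return RepeatAllele(codons=(CAG,) * n_cag, name=name or f"loi_{n_cag}")


def di_allele(n_cag: int, name: str = "") -> RepeatAllele:
    if n_cag < 1:
        raise ValueError("DI allele needs >= 1 CAG")
    return RepeatAllele(
        codons=(CAG,) * n_cag + (CAA, CAG, CAA, CAG), name=name or f"di_{n_cag}"
    )


def default_htt_template(cag_lengths: Sequence[int] = (16, 17)) -> LocusTemplate:
    """The *HTT* exon-1 amplicon with canonical alleles of the given CAG
    lengths (HEK293 cells carry canonical 16 and 17)."""
    return LocusTemplate(
        flank5=_HTT_FLANK5,
        flank3=_HTT_FLANK3,
        primer_fwd=_HTT_PRIMER_FWD,
        primer_rev=_HTT_PRIMER_REV,
        alleles=tuple(canonical_allele(n) for n in cag_lengths),
    )


_BUILDERS = {
    "canonical": canonical_allele,
    "loi": loi_allele,
    "di": di_allele,
}


def load_locus_config(path: str | Path) -> LocusTemplate:
    """Load a locus template from YAML.

    Expected keys: flank5, flank3, primer_fwd, primer_rev, and alleles as a
    list of {name, cag, structure} (structure in canonical/loi/di) or
    {name, codons} for custom tracts.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    alleles = []
    for spec in cfg.get("alleles", []):
        if "codons" in spec:
            alleles.append(RepeatAllele(codons=tuple(spec["codons"]), name=spec.get("name", "")))
        else:
            builder = _BUILDERS[spec.get("structure", "canonical").lower()]
            alleles.append(builder(int(spec["cag"]), name=spec.get("name", "")))
    return LocusTemplate(
        flank5=cfg["flank5"],
        flank3=cfg["flank3"],
        primer_fwd=cfg.get("primer_fwd", ""),
        primer_rev=cfg.get("primer_rev", ""),
        alleles=tuple(alleles),
    )


def write_reference_fasta(template: LocusTemplate, path: str | Path) -> None:
    """Write one FASTA record per allele's amplicon reference."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(build_amplicon_reference(template, a)), id=a.name or f"allele{i}",
                  description=f"{a.structure.value} cag={a.cag_length}")
        for i, a in enumerate(template.alleles)
    ]
    SeqIO.write(records, str(path), "fasta")
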