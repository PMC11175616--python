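"""Guide-RNA register enumeration and base-editor target prediction on the
CAG repeat locus.

A cytosine base editor deaminates C within a fixed *activity window* of the
protospacer, counted from the PAM (13-17 nt for BE4-class editors, i.e.
spacer positions 4-8 from the PAM-distal end).  Converting sense-strand CAG
to CAA requires editing the C of the antisense CTG, so only registers whose
protospacer lies on the antisense strand can produce CAG->CAA.

On a periodic CTG tract a 20-mer spacer hybridizes at every in-frame shift,
so register enumeration, PAM classification and window mapping together
determine which CAG codons each guide/editor combination can convert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .repeat_model import (
    LocusTemplate,
    RepeatAllele,
    build_amplicon_reference,
    repeat_site_indices,
    reverse_complement,
)

__all__ = [
    "Guide",
    "EditorProfile",
    "TargetRegister",
    "INCOMPATIBLE",
    "enumerate_registers",
    "pam_rank",
    "window_cag_sites",
    "predict_edit_sites",
    "default_editors",
]

SPACER_LEN = 20
PAM_LEN = 3

#: Sentinel rank for a PAM no class of the editor accepts.
INCOMPATIBLE = None

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Guide:
    """A 20-nt spacer (written as the protospacer-matching sequence)."""

    name: str
    spacer: str

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LEN:
            raise ValueError(f"spacer must be {SPACER_LEN} nt, got {len(self.spacer)}")
        if set(self.spacer) - set("ACGT"):
            raise ValueError("spacer alphabet must be ACGT")


@dataclass(frozen=True)
class EditorProfile:
    """A cytosine base editor: ordered PAM preference and activity window.

    ``window_from_pam`` is the inclusive range of spacer positions counted
    from the PAM (position 1 = PAM-proximal nucleotide, spacer position 20).
    """

    name: str
    pam_classes: tuple[tuple[str, int], ...]
    window_from_pam: tuple[int, int] = (13, 17)
    wide_window: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.window_from_pam
        if not (1 <= lo <= hi <= SPACER_LEN):
            raise ValueError("activity window must lie within spacer positions 1..20")

    def window_spacer_indices(self) -> range:
        """0-based spacer indices (5'->3') covered by the activity window."""
        lo, hi = self.window_from_pam
        # position p from the PAM corresponds to spacer position 21-p (1-based)
        return range(SPACER_LEN - hi, SPACER_LEN - lo + 1)


def default_editors() -> dict[str, EditorProfile]:
    """The four editors characterized on the repeat locus.

    BE4max requires NGG; the NG/SpG variants accept NGN but retain an NGG
    preference (rank 1).  evoCDA1-SpG deaminates over a substantially wider
    window; 11-19 is a configurable stand-in for its unpublished bounds.
    """
    return {
        "BE4max": EditorProfile("BE4max", pam_classes=(("NGG", 1),)),
        "BE4-NG": EditorProfile("BE4-NG", pam_classes=(("NGG", 1), ("NGN", 2))),
        "BE4-SpG": EditorProfile("BE4-SpG", pam_classes=(("NGG", 1), ("NGN", 2))),
        "evo-SpG": EditorProfile(
            "evo-SpG", pam_classes=(("NGG", 1), ("NGN", 2)),
            window_from_pam=(11, 19), wide_window=True,
        ),
    }


@dataclass
class TargetRegister:
    """One candidate hybridization register of a spacer on the locus."""

    strand: str  # "sense" | "antisense"
    start: int  # 0-based offset of the protospacer on that strand
    mismatches: int
    mismatch_positions: tuple[int, ...]  # 0-based spacer indices
    pam: str
    pam_rank: int | None = None
    window_cag_sites: frozenset[int] = field(default_factory=frozenset)
    warning: str | None = None


def _iupac_match(pattern: str, pam: str) -> bool:
    return len(pattern) == len(pam) and all(
        b in _IUPAC[p] for p, b in zip(pattern, pam)
    )


def pam_rank(pam: str, editor: EditorProfile) -> int | None:
    """Rank of the first editor PAM class matching ``pam``; ``None``
    (INCOMPATIBLE) when no class matches."""
    for pattern, rank in editor.pam_classes:
        if _iupac_match(pattern, pam.upper()):
            return rank
    return INCOMPATIBLE


def enumerate_registers(
    guide: Guide, locus_seq: str, max_mismatch: int = 0
) -> list[TargetRegister]:
    """All protospacer placements on either strand with Hamming distance
    <= ``max_mismatch`` to the spacer, each with its 3-nt PAM.

    Bulges are not modelled; mismatches are positional (Hamming) only.
    """
    if len(locus_seq) < SPACER_LEN + PAM_LEN:
        raise ValueError("locus shorter than protospacer + PAM")
    out: list[TargetRegister] = []
    for strand, seq in (("sense", locus_seq), ("antisense", reverse_complement(locus_seq))):
        for start in range(len(seq) - SPACER_LEN - PAM_LEN + 1):
            proto = seq[start : start + SPACER_LEN]
            mm = tuple(i for i in range(SPACER_LEN) if proto[i] != guide.spacer[i])
            if len(mm) <= max_mismatch:
                out.append(
                    TargetRegister(
                        strand=strand,
                        start=start,
                        mismatches=len(mm),
                        mismatch_positions=mm,
                        pam=seq[start + SPACER_LEN : start + SPACER_LEN + PAM_LEN],
                    )
                )
    return out


def window_cag_sites(
    register: TargetRegister,
    editor: EditorProfile,
    template: LocusTemplate,
    allele: RepeatAllele,
) -> frozenset[int]:
    """Sense CAG sites (1-based, CAG codons only) whose third-position G
    pairs with an antisense C inside the editor's activity window of this
    register.

    Sense-strand registers cannot yield CAG->CAA (the edited C would be the
    first base of CAG, giving TAG); they return the empty set and set a
    warning on the register.
    """
    if register.strand != "antisense":
        register.warning = "sense-strand register: no CAG->CAA chemistry"
        return frozenset()
    amplicon = build_amplicon_reference(template, allele)
    L = len(amplicon)
    tract_start = len(template.flank5)
    codons = allele.codons
    # codon index -> 1-based addressable CAG site number
    cag_site_of = {
        idx: s for s, idx in enumerate(repeat_site_indices(codons), start=1)
    }
    sites = set()
    for j in editor.window_spacer_indices():
        anti_pos = register.start + j
        if anti_pos >= L:
            continue
        sense_pos = L - 1 - anti_pos
        if amplicon[sense_pos] != "G":
            continue  # the antisense base here is not a C
        off = sense_pos - tract_start
        if off < 0 or off >= 3 * len(codons) or off % 3 != 2:
            continue  # outside the tract or not the wobble G of a codon
        idx = off // 3
        if idx in cag_site_of:
            sites.add(cag_site_of[idx])
    return frozenset(sites)


def _ranking_key(reg: TargetRegister) -> tuple:
    # prefer low PAM rank, then few mismatches, then mismatches far from the
    # PAM (a PAM-distal mismatch is better tolerated than a proximal one)
    if reg.mismatch_positions:
        # distance from PAM of the most PAM-proximal mismatch (smaller =
        # closer to PAM = worse); spacer index i is 20-i nt from the PAM
        proximal = min(SPACER_LEN - i for i in reg.mismatch_positions)
    else:
        proximal = SPACER_LEN + 1
    return (reg.pam_rank, reg.mismatches, -proximal, reg.start)


def predict_edit_sites(
    guide: Guide,
    editor: EditorProfile,
    template: LocusTemplate,
    allele: RepeatAllele,
    max_mismatch: int = 0,
) -> list[tuple[TargetRegister, frozenset[int]]]:
    """Ranked convertible-site predictions for one guide/editor pair.

    Registers with a PAM the editor cannot use are dropped; the rest are
    sorted by (PAM rank, mismatch count, PAM-distal mismatch preference).
    """
    amplicon = build_amplicon_reference(template, allele)
    registers = enumerate_registers(guide, amplicon, max_mismatch)
    scored = []
    for reg in registers:
        reg.pam_rank = pam_rank(reg.pam, editor)
        if reg.pam_rank is INCOMPATIBLE:
            continue
        reg.window_cag_sites = window_cag_sites(reg, editor, template, allele)
        scored.append(reg)
    scored.sort(key=_ranking_key)
    return [(reg, reg.window_cag_sites) for reg in scored]
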