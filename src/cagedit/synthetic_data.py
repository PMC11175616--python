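"""Seeded simulators for every input the pipeline consumes.

Three generators emulate the study's raw materials:

* paired amplicon read pairs over configured repeat alleles, with per-site
  CAG->CAA conversion probabilities, non-CAA variant codons, whole-codon
  indels plus frameshifts (the ~10% apparent-indel background of repeat
  sequencing), per-base substitution error, quality scores, and injected
  mate discordance;
* age-at-onset cohorts whose LOI/DI carriers deviate from the canonical
  onset curve by configurable CAG-equivalent offsets (+3 / -1 by default);
* fragment-analysis peak traces with a modal allele and a geometrically
  decaying expansion tail.

Every simulator takes a single integer seed, derives an independent named
stream from it, and writes a machine-readable truth record so downstream
estimators can be validated against the generating parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon_qc import ReadPair, SequencedRead, write_fastq_pairs
from .conversion_calling import CONVERSION_TYPES
from .instability import Peak, PeakTrace
from .onset_model import OnsetModel, SIM_DEFAULT_COEFFS, expected_onset
from .repeat_model import (
    CAA,
    CAG,
    LocusTemplate,
    RepeatAllele,
    RepeatStructureClass,
    build_amplicon_reference,
    canonical_allele,
    default_htt_template,
    repeat_site_indices,
    di_allele,
    loi_allele,
    reverse_complement,
)

__all__ = [
    "ReadSimConfig",
    "CohortSimConfig",
    "TraceSimConfig",
    "simulate_read_pairs",
    "simulate_reads",
    "simulate_cohort",
    "simulate_trace",
    "default_read_config",
    "default_cohort_config",
]

_STREAMS = {"reads": 1, "cohort": 2, "trace": 3}

_OTHER_VARIANTS = tuple(t for t in CONVERSION_TYPES if t not in (CAG, CAA))
_BASES = "ACGT"


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


# ---------------------------------------------------------------------------
# amplicon reads


@dataclass
class ReadSimConfig:
    template: LocusTemplate
    allele_mix: dict[str, float]
    per_site_caa: dict[str, dict[int, float]] = field(default_factory=dict)
    other_variant_rate: float = 0.0  # per-codon, drawn over the 8 non-CAA types
    indel_rate: float = 0.10  # per-read apparent-indel probability
    frameshift_frac: float = 0.3  # fraction of indels that break the frame
    base_error_rate: float = 0.0
    discordant_pair_rate: float = 0.0
    phred_mean: float = 35.0
    phred_sd: float = 3.0
    low_quality_rate: float = 0.0  # reads drawn with mean Phred ~ 15
    n_pairs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (
            ("other_variant_rate", self.other_variant_rate),
            ("indel_rate", self.indel_rate),
            ("base_error_rate", self.base_error_rate),
            ("discordant_pair_rate", self.discordant_pair_rate),
            ("low_quality_rate", self.low_quality_rate),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be a probability, got {p}")
        total = sum(self.allele_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele proportions must sum to 1, got {total}")
        for p in (q for site_map in self.per_site_caa.values() for q in site_map.values()):
            if not 0 <= p <= 1:
                raise ValueError("per-site conversion rates must be probabilities")


def default_read_config(seed: int = 0, n_pairs: int = 1000) -> ReadSimConfig:
    """Study-like default: HEK293 16/17-CAG canonical alleles at equal
    proportions plus the engineered 51-CAG line absent, ~10% apparent
    indels."""
    template = default_htt_template((16, 17))
    return ReadSimConfig(
        template=template,
        allele_mix={a.name: 0.5 for a in template.alleles},
        indel_rate=0.10,
        seed=seed,
        n_pairs=n_pairs,
    )


def _mutate_codons(
    codons: list[str],
    allele: RepeatAllele,
    site_probs: Mapping[int, float],
    other_rate: float,
    rng: np.random.Generator,
) -> tuple[list[str], list[int]]:
    converted: list[int] = []
    for site, i in enumerate(repeat_site_indices(allele.codons), start=1):
        p = site_probs.get(site, 0.0)
        if p and rng.random() < p:
            codons[i] = CAA
            converted.append(site)
    if other_rate:
        for i in range(len(codons)):
            if rng.random() < other_rate:
                codons[i] = _OTHER_VARIANTS[rng.integers(len(_OTHER_VARIANTS))]
    return codons, converted


def _apply_indel(
    seq: str, tract_start: int, tract_end: int, frameshift: bool, rng: np.random.Generator
) -> tuple[str, str, int]:
    """Insert or delete inside the repeat tract; returns (seq, kind, k)."""
    k_codons = int(rng.geometric(0.6))  # mostly single-codon events
    n = 3 * k_codons if not frameshift else 3 * k_codons - (1 + int(rng.integers(2)))
    pos = int(rng.integers(tract_start, max(tract_start + 1, tract_end - n)))
    if rng.random() < 0.5 and pos + n <= tract_end:
        return seq[:pos] + seq[pos + n :], "deletion", k_codons
    ins = "".join(_BASES[rng.integers(4)] for _ in range(n)) if frameshift else CAG * k_codons
    return seq[:pos] + ins + seq[pos:], "insertion", k_codons


def _seq_error(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = _BASES[(_BASES.index(out[i]) + 1 + int(rng.integers(3))) % 4]
    return "".join(out)


def _quals(n: int, mean: float, sd: float, rng: np.random.Generator) -> tuple[int, ...]:
    q = rng.normal(mean, sd, size=n)
    return tuple(int(x) for x in np.clip(np.rint(q), 2, 40))


def simulate_read_pairs(config: ReadSimConfig) -> tuple[list[ReadPair], pd.DataFrame]:
    """Generate read pairs in memory with a per-read truth table.

    Both mates span the full amplicon (the repeat amplicon is shorter than
    a MiSeq read), so a concordant pair's merged consensus is the amplicon
    itself; discordant pairs get extra substitutions in the reverse mate
    only.
    """
    rng = _rng(config.seed, "reads")
    names = sorted(config.allele_mix)
    probs = np.array([config.allele_mix[n] for n in names])
    pairs: list[ReadPair] = []
    truth_rows = []
    for i in range(config.n_pairs):
        name = names[rng.choice(len(names), p=probs)]
        allele = config.template.allele_by_name(name)
        codons = list(allele.codons)
        codons, converted = _mutate_codons(
            codons, allele, config.per_site_caa.get(name, {}),
            config.other_variant_rate, rng,
        )
        seq = config.template.flank5 + "".join(codons) + config.template.flank3
        indel_kind, indel_k = "none", 0
        if rng.random() < config.indel_rate:
            frameshift = rng.random() < config.frameshift_frac
            t0 = len(config.template.flank5)
            t1 = t0 + 3 * len(allele.codons)
            seq, indel_kind, indel_k = _apply_indel(seq, t0, t1, frameshift, rng)
            if frameshift:
                indel_kind = "frameshift"
        fwd_seq = _seq_error(seq, config.base_error_rate, rng)
        rev_seq = _seq_error(reverse_complement(seq), config.base_error_rate, rng)
        discordant = rng.random() < config.discordant_pair_rate
        if discordant:
            # corrupt a window of the reverse mate so no exact overlap exists
            mid = len(rev_seq) // 2
            window = list(rev_seq[mid : mid + 8])
            rev_seq = rev_seq[:mid] + "".join(
                _BASES[(_BASES.index(b) + 2) % 4] for b in window
            ) + rev_seq[mid + 8 :]
        low_q = rng.random() < config.low_quality_rate
        mean_q = 15.0 if low_q else config.phred_mean
        rid = f"sim_{config.seed}_{i:07d}"
        pairs.append(
            ReadPair(
                fwd=SequencedRead(rid, fwd_seq, _quals(len(fwd_seq), mean_q, config.phred_sd, rng)),
                rev=SequencedRead(rid, rev_seq, _quals(len(rev_seq), mean_q, config.phred_sd, rng)),
            )
        )
        truth_rows.append(
            {
                "read_id": rid,
                "allele": name,
                "conversion_sites": ",".join(map(str, converted)),
                "indel": indel_kind,
                "indel_codons": indel_k,
                "discordant": discordant,
                "low_quality": low_q,
            }
        )
    return pairs, pd.DataFrame(truth_rows)


def simulate_reads(
    config: ReadSimConfig,
    r1: str | Path,
    r2: str | Path,
    truth: str | Path | None = None,
) -> pd.DataFrame:
    """File-based front end: write paired FASTQ (Phred+33) and a truth CSV."""
    pairs, truth_df = simulate_read_pairs(config)
    write_fastq_pairs(pairs, r1, r2)
    if truth is not None:
        truth_df.to_csv(truth, index=False)
    return truth_df


# ---------------------------------------------------------------------------
# onset cohorts


@dataclass
class CohortSimConfig:
    model: OnsetModel = field(
        default_factory=lambda: OnsetModel.parametric(*SIM_DEFAULT_COEFFS)
    )
    n_per_class: dict[RepeatStructureClass, int] = field(
        default_factory=lambda: {
            RepeatStructureClass.LOI: 21,
            RepeatStructureClass.DI: 69,
        }
    )
    cag_range: tuple[int, int] = (40, 50)
    class_offsets: dict[RepeatStructureClass, int] = field(
        default_factory=lambda: {
            RepeatStructureClass.CANONICAL: 0,
            RepeatStructureClass.LOI: 3,
            RepeatStructureClass.DI: -1,
        }
    )
    residual_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, n in self.n_per_class.items():
            if n < 1:
                raise ValueError(f"n for {cls.name} must be >= 1")
        if self.cag_range[0] > self.cag_range[1]:
            raise ValueError("invalid CAG range")


def default_cohort_config(seed: int = 0) -> CohortSimConfig:
    return CohortSimConfig(seed=seed)


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Cohort table (id, cag, structure, onset) with onsets drawn as
    expected_onset(CAG + class offset) + Normal(0, residual_sd)."""
    rng = _rng(config.seed, "cohort")
    lo, hi = config.cag_range
    rows = []
    for cls, n in config.n_per_class.items():
        offset = config.class_offsets.get(cls, 0)
        for i in range(n):
            cag = int(rng.integers(lo, hi + 1))
            mu = expected_onset(config.model, cag + offset)
            onset = mu + rng.normal(0.0, config.residual_sd)
            rows.append(
                {
                    "id": f"{cls.name.lower()}_{i:04d}",
                    "cag": cag,
                    "structure": cls.name,
                    "onset": max(onset, 1.0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fragment-analysis traces


@dataclass
class TraceSimConfig:
    main_cag: int = 110
    drift: float = 0.0  # mean of the expansion tail (repeat units); 0 = stable
    tail_decay: float = 0.5  # geometric decay of expansion-peak heights
    max_delta: int = 15
    main_height: float = 1000.0
    n_noise_peaks: int = 0
    noise_height_frac: float = 0.05  # below the 10% threshold by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drift < 0:
            raise ValueError("drift must be >= 0")
        if not 0 < self.tail_decay < 1:
            raise ValueError("tail_decay must be in (0, 1)")


def simulate_trace(config: TraceSimConfig) -> tuple[PeakTrace, dict]:
    """A modal peak plus a geometrically decaying expansion tail whose
    analytic expansion index is recorded in the truth dict.

    Tail heights are h_delta = main_height * drift_scale * decay**(delta-1);
    drift controls the total tail mass so that the analytic index of the
    noiseless trace equals sum(f_delta * delta) over retained peaks.
    """
    rng = _rng(config.seed, "trace")
    peaks = [Peak(config.main_cag, config.main_height)]
    if config.drift > 0:
        # scale tail mass so the mean gain over the whole trace ~ drift
        deltas = np.arange(1, config.max_delta + 1)
        w = config.tail_decay ** (deltas - 1)
        scale = config.drift / float(np.sum(w * deltas) / np.sum(w))
        tail_mass = scale / (1 + scale)
        heights = config.main_height * (tail_mass / (1 - tail_mass)) * w / np.sum(w)
        for d, h in zip(deltas, heights):
            if h > 0:
                peaks.append(Peak(config.main_cag + int(d), float(h)))
    for _ in range(config.n_noise_peaks):
        pos = config.main_cag + int(rng.integers(-30, 31))
        if pos != config.main_cag:
            peaks.append(
                Peak(pos, config.main_height * config.noise_height_frac * rng.random())
            )
    trace = PeakTrace(sample_id=f"sim_trace_{config.seed}", peaks=peaks,
                      main_allele=config.main_cag)
    # analytic index of the noiseless trace after the 10% threshold
    hmax = max(p.height for p in peaks)
    retained = [p for p in peaks if p.height >= 0.10 * hmax]
    total = sum(p.height for p in retained)
    analytic = sum(
        p.height / total * (p.position - config.main_cag)
        for p in retained
        if p.position > config.main_cag
    )
    truth = {"main_cag": config.main_cag, "drift": config.drift,
             "analytic_expansion_index": float(analytic)}
    return trace, truth


def write_truth_json(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
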