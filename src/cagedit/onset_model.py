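"""Age-at-onset modelling and interruption-structure offset estimation.

Expected age-at-onset in HD falls roughly exponentially with uninterrupted
CAG length; here the canonical-repeat relationship is represented either as
a parametric curve ``onset = alpha + exp(beta - gamma * CAG)`` or as a
lookup table of mean onsets by CAG.

Carriers of loss-of-interruption (LOI) and duplicated-interruption (DI)
alleles deviate systematically from the canonical curve.  The size of that
deviation, in CAG-equivalents, is estimated by a least-squares grid search:
shift every carrier's CAG by a candidate integer offset, compute the sum of
squared residuals against the canonical model, and take the offset with the
smallest sum of squares (ties broken toward 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .repeat_model import RepeatAllele, RepeatStructureClass, apply_conversion, effective_cag

__all__ = [
    "OnsetModel",
    "CohortRecord",
    "OffsetFit",
    "SIM_DEFAULT_COEFFS",
    "expected_onset",
    "fit_onset_model",
    "residual_ss",
    "estimate_offset",
    "onset_delay",
]

#: Coefficients used by the cohort simulator (alpha, beta, gamma).  These
#: are simulation defaults in the published family of onset-CAG models, not
#: estimates from any specific cohort.
SIM_DEFAULT_COEFFS = (21.5, 9.56, 0.146)


@dataclass(frozen=True)
class OnsetModel:
    """Canonical-repeat onset model: parametric, or a mean-onset table."""

    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    table: Mapping[float, float] | None = None
    residual_sd: float | None = None

    def __post_init__(self) -> None:
        parametric = None not in (self.alpha, self.beta, self.gamma)
        if not parametric and self.table is None:
            raise ValueError("OnsetModel needs (alpha, beta, gamma) or a table")

    @property
    def is_parametric(self) -> bool:
        return None not in (self.alpha, self.beta, self.gamma)

    @classmethod
    def from_table(cls, table: Mapping[float, float]) -> "OnsetModel":
        return cls(table=dict(table))

    @classmethod
    def parametric(cls, alpha: float, beta: float, gamma: float) -> "OnsetModel":
        return cls(alpha=alpha, beta=beta, gamma=gamma)


def expected_onset(model: OnsetModel, cag: float) -> float:
    """Predicted mean age-at-onset (years) at a given uninterrupted CAG."""
    if model.is_parametric:
        return model.alpha + math.exp(model.beta - model.gamma * cag)
    assert model.table is not None
    try:
        return model.table[cag]
    except KeyError:
        raise ValueError(f"CAG {cag} not present in onset lookup table") from None


def fit_onset_model(records: Sequence["CohortRecord"]) -> OnsetModel:
    """Nonlinear least-squares fit of alpha + exp(beta - gamma*CAG) to a
    canonical cohort; at least 3 distinct CAG values are required."""
    cags = np.array([r.cag for r in records], dtype=float)
    onsets = np.array([r.onset for r in records], dtype=float)
    if len(set(cags.tolist())) < 3:
        raise ValueError("need >= 3 distinct CAG values to fit the onset model")

    def f(x, a, b, g):
        return a + np.exp(b - g * x)

    a0, b0, g0 = SIM_DEFAULT_COEFFS
    try:
        popt, _ = curve_fit(f, cags, onsets, p0=(a0, b0, g0), maxfev=20000)
    except RuntimeError as e:
        raise RuntimeError(f"onset model fit failed to converge: {e}") from e
    resid = onsets - f(cags, *popt)
    sd = float(np.std(resid, ddof=3)) if len(records) > 3 else 0.0
    return OnsetModel(alpha=float(popt[0]), beta=float(popt[1]),
                      gamma=float(popt[2]), residual_sd=sd)


@dataclass(frozen=True)
class CohortRecord:
    id: str
    cag: int
    structure: RepeatStructureClass
    onset: float

    def __post_init__(self) -> None:
        if self.onset <= 0:
            raise ValueError("onset must be positive")


def residual_ss(
    records: Sequence[CohortRecord], model: OnsetModel, offset: float = 0.0
) -> float:
    """Sum of squared residuals of observed onset about the canonical model
    evaluated at CAG + offset."""
    return float(
        sum((r.onset - expected_onset(model, r.cag + offset)) ** 2 for r in records)
    )


@dataclass
class OffsetFit:
    grid: list[int]
    ss: dict[int, float]
    best_offset: int

    def to_dict(self) -> dict:
        return {"grid": self.grid, "ss": {int(k): v for k, v in self.ss.items()},
                "best_offset": self.best_offset}


def estimate_offset(
    records: Sequence[CohortRecord],
    model: OnsetModel,
    grid: Sequence[int] = tuple(range(-10, 11)),
) -> OffsetFit:
    """Grid search for the CAG-equivalent additional effect of a structure
    class: the integer offset minimizing the residual sum of squares.

    Ties in SS are broken toward smaller |offset| (parsimony).
    """
    if not records:
        raise ValueError("empty cohort")
    if not grid:
        raise ValueError("empty offset grid")
    ss = {int(o): residual_ss(records, model, o) for o in grid}
    best = min(ss, key=lambda o: (ss[o], abs(o), o))
    return OffsetFit(grid=[int(o) for o in grid], ss=ss, best_offset=best)


def onset_delay(
    allele: RepeatAllele,
    edit_site: int,
    offsets: Mapping[RepeatStructureClass, float],
    model: OnsetModel,
) -> float:
    """Predicted onset delay (years) from a single in-silico CAG->CAA edit:
    expected onset at the edited allele's effective CAG minus expected onset
    at the original allele's effective CAG."""
    edited = apply_conversion(allele, edit_site)
    return expected_onset(model, effective_cag(edited, offsets)) - expected_onset(
        model, effective_cag(allele, offsets)
    )
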