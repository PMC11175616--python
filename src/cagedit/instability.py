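"""Somatic repeat-instability quantification from fragment-analysis traces.

Fragment analysis of the CAG repeat yields a ladder of peaks (repeat size,
fluorescence height).  Somatic expansion is summarized by the *expansion
index*: after discarding peaks below a relative height threshold (10% of
the tallest retained reference by default), the heights of peaks to the
right of the main (modal) allele are normalized to fractions and each
fraction is weighted by its repeat-unit gain:

    EI = sum over peaks with delta > 0 of f_i * delta_i,

where delta_i = position_i - main_allele and f_i = h_i / sum(retained h).
The main allele is anchored on the highest peak of the matched tail-DNA
trace, so that liver/striatum traces are measured against the inherited
allele.  Treatment effects are assessed by ordinary least squares of the
expansion index on treatment with tail CAG, age, sex, and batch as
covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakTrace",
    "InstabilitySample",
    "threshold_peaks",
    "expansion_index",
    "contraction_index",
    "instability_regression",
    "read_peak_table",
]


@dataclass(frozen=True)
class Peak:
    position: int  # repeat units
    height: float

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("peak height must be >= 0")


@dataclass
class PeakTrace:
    sample_id: str
    peaks: list[Peak]
    main_allele: int | None = None  # anchored on the matched tail trace

    def highest_peak(self) -> Peak:
        if not self.peaks:
            raise ValueError(f"trace {self.sample_id} has no peaks")
        return max(self.peaks, key=lambda p: p.height)

    def anchored_main(self) -> int:
        if self.main_allele is not None:
            return self.main_allele
        warnings.warn(
            f"trace {self.sample_id}: no tail-anchored main allele; "
            "using this trace's highest peak",
            stacklevel=3,
        )
        return self.highest_peak().position


def threshold_peaks(
    trace: PeakTrace, threshold_frac: float = 0.10
) -> list[tuple[Peak, float]]:
    """Peaks at least ``threshold_frac`` of the tallest peak, each with its
    normalized height fraction (fractions sum to 1 over retained peaks)."""
    if not trace.peaks:
        raise ValueError(f"trace {trace.sample_id} has no peaks")
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    hmax = max(p.height for p in trace.peaks)
    retained = [p for p in trace.peaks if p.height >= threshold_frac * hmax]
    total = sum(p.height for p in retained)
    return [(p, p.height / total) for p in retained]


def _weighted_index(trace: PeakTrace, threshold_frac: float, sign: int) -> float:
    main = trace.anchored_main()
    return float(
        sum(
            f * sign * (p.position - main)
            for p, f in threshold_peaks(trace, threshold_frac)
            if sign * (p.position - main) > 0
        )
    )


def expansion_index(trace: PeakTrace, threshold_frac: float = 0.10) -> float:
    """Height-fraction-weighted mean repeat-unit gain of peaks right of the
    main allele (0 when no expanded peaks survive the threshold)."""
    return _weighted_index(trace, threshold_frac, +1)


def contraction_index(trace: PeakTrace, threshold_frac: float = 0.10) -> float:
    """Companion statistic over peaks left of the main allele."""
    return _weighted_index(trace, threshold_frac, -1)


@dataclass(frozen=True)
class InstabilitySample:
    trace: PeakTrace
    treatment: str  # "BE" | "PBS"
    tail_cag: int
    age: float  # weeks
    sex: str
    batch: str


def instability_regression(
    samples: Sequence[InstabilitySample],
    threshold_frac: float = 0.10,
    covariates: Sequence[str] = ("tail_cag", "age", "sex", "batch"),
) -> pd.DataFrame:
    """OLS of expansion index on treatment plus covariates.

    Categorical covariates are reference-coded (PBS, female, and the
    lexicographically first batch as references).  Returns the statsmodels
    coefficient table as a DataFrame (coef, std err, t, p).
    """
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "expansion_index": [expansion_index(s.trace, threshold_frac) for s in samples],
            "treatment": pd.Categorical(
                [s.treatment for s in samples], categories=["PBS", "BE"]
            ),
            "tail_cag": [s.tail_cag for s in samples],
            "age": [s.age for s in samples],
            "sex": pd.Categorical([s.sex for s in samples]),
            "batch": pd.Categorical([s.batch for s in samples]),
        }
    )
    if df["treatment"].nunique() < 2:
        raise ValueError("treatment must have both levels (BE and PBS)")
    terms = ["treatment"] + [c for c in covariates if c != "treatment"]
    # drop covariates with a single level to avoid spurious rank deficiency
    terms = [
        t for t in terms
        if not (df[t].dtype.name == "category" and df[t].nunique() < 2)
    ]
    formula = "expansion_index ~ " + " + ".join(terms)
    n_params = len(terms) + 1
    if len(samples) < n_params + 1:
        raise ValueError(f"need >= {n_params + 1} samples for {n_params} parameters")
    fit = smf.ols(formula, data=df).fit()
    from numpy.linalg import matrix_rank

    X = fit.model.exog
    if matrix_rank(X) < X.shape[1]:
        names = fit.model.exog_names
        raise ValueError(f"design matrix rank deficient; check columns {names}")
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "std_err": fit.bse,
            "t": fit.tvalues,
            "p_value": fit.pvalues,
        }
    )
    table.attrs["r_squared"] = float(fit.rsquared)
    table.attrs["n"] = int(fit.nobs)
    return table


def read_peak_table(path, sample_id_col: str = "sample_id") -> dict[str, PeakTrace]:
    """Read a peak CSV (sample_id, position_units, height) into traces."""
    df = pd.read_csv(path)
    traces = {}
    for sid, grp in df.groupby(sample_id_col):
        traces[str(sid)] = PeakTrace(
            sample_id=str(sid),
            peaks=[Peak(int(r.position_units), float(r.height)) for r in grp.itertuples()],
        )
    return traces
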