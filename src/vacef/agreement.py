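"""Method-comparison statistics: Bland-Altman agreement and percentage error.

Conventions follow common practice in hemodynamic validation studies:

* differences are oriented reference - test, so a test method reading lower
  than the reference yields a positive bias;
* limits of agreement are bias +/- m * SD of the differences, with m = 2 by
  default (m = 1.96 available via the ``multiplier`` argument);
* percentage error PE = 100 * 2*SD(diff) / mean(reference), with PE <= 30%
  the conventional clinical-acceptability threshold;
* the SD uses the n-1 sample estimator.

PE is scale-invariant: expressing both series in percent or as fractions gives
the same PE because numerator and denominator rescale together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "bland_altman",
    "summary_agreement",
    "PE_ACCEPTABILITY_THRESHOLD",
]

PE_ACCEPTABILITY_THRESHOLD = 30.0  # percent


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired reference/test series in a common unit, no missing values."""

    reference: np.ndarray
    test: np.ndarray

    def __post_init__(self):
        ref = np.asarray(self.reference, dtype=float)
        tst = np.asarray(self.test, dtype=float)
        if ref.shape != tst.shape or ref.ndim != 1:
            raise InvalidInputError(
                "reference/test", f"need equal-length 1-D series, got {ref.shape} vs {tst.shape}"
            )
        if np.isnan(ref).any() or np.isnan(tst).any():
            raise InvalidInputError("reference/test", "missing values are not allowed")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "test", tst)

    def __len__(self) -> int:
        return self.reference.size


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman summary.  ``r``/``r2`` are NaN when undefined (zero variance
    in either series) or unavailable (summary-level construction)."""

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    multiplier: float
    pe: float
    r: float
    r2: float
    acceptable: bool

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "multiplier": self.multiplier,
            "pe": self.pe,
            "r": self.r,
            "r2": self.r2,
            "acceptable": self.acceptable,
        }


def bland_altman(pairs: PairedMeasurements, multiplier: float = 2.0) -> AgreementReport:
    """Full Bland-Altman analysis of paired subject-level measurements.

    Requires n >= 3 and mean(reference) > 0 (the PE denominator).  Pearson r
    is reported as NaN, without aborting the rest, if either series has zero
    variance.
    """
    n = len(pairs)
    if n < 3:
        raise InvalidInputError("pairs", f"need at least 3 pairs, got {n}")
    ref, tst = pairs.reference, pairs.test
    diff = ref - tst
    bias = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))
    mean_ref = float(np.mean(ref))
    if not mean_ref > 0:
        raise InvalidInputError("reference", f"mean must be > 0 for PE, got {mean_ref}")
    if np.ptp(ref) == 0 or np.ptp(tst) == 0:
        r = math.nan
    else:
        r = float(stats.pearsonr(ref, tst).statistic)
    pe = 100.0 * (2.0 * sd_diff) / mean_ref
    return AgreementReport(
        n=n,
        bias=bias,
        sd_diff=sd_diff,
        loa_low=bias - multiplier * sd_diff,
        loa_high=bias + multiplier * sd_diff,
        multiplier=multiplier,
        pe=pe,
        r=r,
        r2=r * r,
        acceptable=pe <= PE_ACCEPTABILITY_THRESHOLD,
    )


def summary_agreement(
    bias: float, sd_diff: float, mean_reference: float, multiplier: float = 2.0
) -> AgreementReport:
    """Limits of agreement and PE from printed summary statistics alone.

    Lets published bias/SD/reference-mean triples be checked without
    subject-level data.  Correlation fields are NaN (unavailable); n is 0.
    """
    if sd_diff < 0:
        raise InvalidInputError("sd_diff", f"must be >= 0, got {sd_diff}")
    if not mean_reference > 0:
        raise InvalidInputError("mean_reference", f"must be > 0, got {mean_reference}")
    pe = 100.0 * (2.0 * sd_diff) / mean_reference
    return AgreementReport(
        n=0,
        bias=bias,
        sd_diff=sd_diff,
        loa_low=bias - multiplier * sd_diff,
        loa_high=bias + multiplier * sd_diff,
        multiplier=multiplier,
        pe=pe,
        r=math.nan,
        r2=math.nan,
        acceptable=pe <= PE_ACCEPTABILITY_THRESHOLD,
    )
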