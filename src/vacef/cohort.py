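"""Synthetic hemodynamic cohorts with known ground truth.

Every subject is parameterised by a true coupling ratio x = Ees/Ea, an
end-diastolic volume and a zero-pressure volume V0; the end-systolic volume is
derived as ESV = (EDV - V0)/(1 + x) + V0 so that SV/(ESV - V0) = x holds
exactly and the PV loop is internally consistent.  The observable beat (PEP,
ET, sBP, dBP) is then produced by inverting the coupling equation for ET:

    ET = PEP * ((x + 1) * Pes/Pad - 1) / k(x)

so the noiseless beat reproduces x exactly when run back through the solver.
Cuff pressures, PEP, EDV and x itself are drawn from truncated normal
distributions whose defaults mirror a healthy young-adult screening cohort
(sBP 119 +/- 10 mmHg, dBP 72 +/- 6 mmHg, PEP 97 +/- 14 ms, Ees/Ea 1.5 +/- 0.6).
Echo measurement noise is additive on the EF scale; timing noise (optional)
is additive on the derived ET.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np

from .coupling import (
    BeatRecord,
    CouplingConstants,
    estimate_pes,
    k_from_coupling,
)
from .errors import GenerationError, InfeasibleTruthError, InvalidInputError
from .pvloop import PVLoopState

__all__ = ["CohortConfig", "SubjectTruth", "timing_from_truth", "sample_cohort"]

# plausibility band for derived ejection time, ms (screening-device range)
_ET_PLAUSIBLE = (100.0, 600.0)


@dataclass(frozen=True)
class CohortConfig:
    """Sampling distributions for a synthetic cohort.

    Means/SDs default to a healthy-adult screening cohort; ``echo_ef_noise_sd``
    is in EF percentage points, ``timing_noise_sd`` in ms (0 = noiseless ET).
    ``coupling_trunc_low`` keeps sampled coupling ratios physiological.
    """

    n: int = 44
    seed: int = 0
    coupling_mean: float = 1.5
    coupling_sd: float = 0.6
    coupling_trunc_low: float = 0.2
    sbp_mean: float = 119.0
    sbp_sd: float = 10.0
    dbp_mean: float = 72.0
    dbp_sd: float = 6.0
    pep_mean: float = 97.0
    pep_sd: float = 14.0
    edv_mean: float = 120.0
    edv_sd: float = 20.0
    v0: float = 0.0
    echo_ef_noise_sd: float = 4.0
    timing_noise_sd: float = 0.0

    def __post_init__(self):
        if self.n < 1:
            raise InvalidInputError("n", f"must be >= 1, got {self.n}")
        for name in ("coupling_sd", "sbp_sd", "dbp_sd", "pep_sd", "edv_sd",
                     "echo_ef_noise_sd", "timing_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(name, "must be >= 0")
        if self.v0 < 0:
            raise InvalidInputError("v0", f"must be >= 0, got {self.v0}")


@dataclass(frozen=True)
class SubjectTruth:
    """One synthetic subject: ground-truth loop plus derived observables.

    ``ef_true`` and ``ef_echo_observed`` are fractions in (0, 1); at v0 = 0 and
    zero noise, coupling_true = SV/ESV and ef_true = coupling_true/(1 + coupling_true).
    """

    id: str
    loop: PVLoopState
    coupling_true: float
    beat: BeatRecord
    ef_true: float
    ef_echo_observed: float


def timing_from_truth(
    x_true: float,
    pep: float,
    sbp: float,
    dbp: float,
    constants: CouplingConstants = CouplingConstants(),
    id: str = "",
) -> BeatRecord:
    """Construct the beat whose coupling solution is exactly ``x_true``.

    Inverts the coupling equation for ejection time given PEP and cuff
    pressures.  Raises :class:`InfeasibleTruthError` when the implied ET is
    non-positive (possible only when Pes < Pad, i.e. off the physiological
    branch); warns when the implied ET falls outside the plausible
    measurement range.
    """
    if not x_true > 0:
        raise InvalidInputError("x_true", f"must be > 0, got {x_true}")
    pes = estimate_pes(sbp, dbp, constants)
    k = k_from_coupling(x_true, constants)
    et = pep * ((x_true + 1.0) * pes / dbp - 1.0) / k
    if et <= 0:
        raise InfeasibleTruthError(
            f"coupling {x_true:g} with pes/pad = {pes / dbp:g} implies et = {et:g} ms <= 0"
        )
    if not _ET_PLAUSIBLE[0] <= et <= _ET_PLAUSIBLE[1]:
        _warnings.warn(
            f"derived et = {et:.1f} ms outside plausible range {_ET_PLAUSIBLE}",
            stacklevel=2,
        )
    return BeatRecord(pep=pep, et=et, sbp=sbp, dbp=dbp, id=id)


def _identifiable(x: float, pad: float, pes: float, constants: CouplingConstants) -> bool:
    """Whether ``x`` is the larger (attracting) root of its own beat's residual.

    At a constructed root, g'(x) = p_k*(1 + x - pad/pes)/x - 1, so the root
    lies on the descending branch iff x > p_k*(1 - pad/pes)/(1 - p_k).  A
    margin on g' excludes near-tangency truths, where the two roots nearly
    merge and the solver's residual tolerance no longer pins x tightly.
    """
    a = pad / pes
    dg = constants.p_k * (1.0 + x - a) / x - 1.0
    return dg < -0.01


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float = np.inf
) -> tuple[float, int]:
    """One rejection-sampled truncated-normal draw; returns (value, rejections)."""
    if sd == 0:
        if not low <= mean <= high:
            raise GenerationError(f"degenerate draw {mean} outside bounds ({low}, {high})")
        return mean, 0
    rejections = 0
    while True:
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return x, rejections
        rejections += 1
        if rejections > 1000:
            raise GenerationError(
                f"truncated normal ({mean}, {sd}) rejected {rejections} draws "
                f"for bounds ({low}, {high}); adjust the configuration"
            )


def sample_cohort(config: CohortConfig) -> list[SubjectTruth]:
    """Draw a cohort of internally consistent synthetic subjects.

    Deterministic given ``config.seed``.  Raises :class:`GenerationError` when
    more than 20% of candidate draws are rejected or infeasible, which signals
    a configuration whose truncation distorts the requested distributions.
    """
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectTruth] = []
    attempts = 0
    failures = 0
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # plausibility warnings tallied as failures below
        while len(subjects) < config.n:
            attempts += 1
            if attempts > 20 and failures / attempts > 0.20:
                raise GenerationError(
                    f"{failures}/{attempts} draws infeasible (> 20%): "
                    "the configuration is unlikely to represent the requested cohort"
                )
            try:
                x, rej = _truncated_normal(
                    rng, config.coupling_mean, config.coupling_sd, config.coupling_trunc_low
                )
                failures += rej
                attempts += rej
                dbp, rej = _truncated_normal(rng, config.dbp_mean, config.dbp_sd, 20.0)
                failures += rej
                attempts += rej
                # sbp must exceed dbp for a valid cuff reading
                sbp, rej = _truncated_normal(rng, config.sbp_mean, config.sbp_sd, dbp + 1.0)
                failures += rej
                attempts += rej
                pep, rej = _truncated_normal(rng, config.pep_mean, config.pep_sd, 20.0)
                failures += rej
                attempts += rej
                edv, rej = _truncated_normal(
                    rng, config.edv_mean, config.edv_sd, config.v0 + 10.0
                )
                failures += rej
                attempts += rej

                pes_check = estimate_pes(sbp, dbp)
                if not _identifiable(x, dbp, pes_check, CouplingConstants()):
                    # smaller-root truths cannot be recovered by the solver's
                    # larger-root convention; redraw
                    failures += 1
                    continue
                esv = (edv - config.v0) / (1.0 + x) + config.v0
                sv = edv - esv
                pes = pes_check
                loop = PVLoopState(edv=edv, esv=esv, v0=config.v0, pes=pes)
                sid = f"s{len(subjects):04d}"
                beat = timing_from_truth(x, pep, sbp, dbp, id=sid)
                if config.timing_noise_sd > 0:
                    et_noised = beat.et + rng.normal(0.0, config.timing_noise_sd)
                    if et_noised <= 0:
                        failures += 1
                        continue
                    beat = BeatRecord(pep=pep, et=et_noised, sbp=sbp, dbp=dbp, id=sid)
                ef_true = sv / edv
                noise = (
                    rng.normal(0.0, config.echo_ef_noise_sd / 100.0)
                    if config.echo_ef_noise_sd > 0
                    else 0.0
                )
                ef_echo = ef_true + noise
                if not 0.0 < ef_echo < 1.0:
                    failures += 1
                    continue
            except (InfeasibleTruthError, InvalidInputError):
                failures += 1
                continue
            subjects.append(
                SubjectTruth(
                    id=sid,
                    loop=loop,
                    coupling_true=x,
                    beat=beat,
                    ef_true=ef_true,
                    ef_echo_observed=ef_echo,
                )
            )
    return subjects
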