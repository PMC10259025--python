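"""Ventricular-arterial coupling (Ees/Ea) from systolic time intervals and cuff pressures.

The chain implemented here estimates left-ventricular ejection fraction without
imaging.  From one beat's pre-ejection period (PEP), ejection time (ET) and cuff
systolic/diastolic pressures:

1. end-systolic pressure Pes is regressed from the cuff pressures
   (Pes = 0.205*sBP + 0.898*dBP + 0.4214, the Kappus regression);
2. the coupling ratio x = Ees/Ea is the root of

       g(x) = (Pad/Pes) * (1 + k(x) * ET/PEP) - 1 - x,   k(x) = 0.53 * x**0.51,

   which combines the clamped-aorta peak-pressure relation
   Pmax = Pad * (1 + k*ET/PEP) with the coupling identity
   Ees/Ea = (Pmax - Pes)/Pes and the empirical bilinear-elastance slope ratio k;
3. ventricular efficiency Eff = 1/(1 + 0.5/x) (external work over
   pressure-volume area for a linear ESPVR), and
4. ejection fraction EF = Eff/(2 - Eff), exact when the zero-pressure
   volume V0 is zero.

Diastolic cuff pressure stands in for the diastolic arterial pressure Pad in
the coupling equations.  All fractions are kept in (0, 1) internally;
formatting as percent happens at the I/O boundary.

Because 0 < 0.51 < 1, g is strictly concave on x > 0 with g -> -inf as
x -> inf.  In the physiological case Pad < Pes, g(0+) < 0, so g has zero or
two positive roots; the larger root (the attracting fixed point of the natural
iteration, matching observed cohort coupling near 1.5) is returned.  When
Pad >= Pes there is exactly one root, solved and flagged as suspect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import (
    DomainError,
    InvalidInputError,
    NonConvergenceError,
    NoSolutionError,
)

__all__ = [
    "BeatRecord",
    "CouplingConstants",
    "SolverSettings",
    "CouplingEstimate",
    "estimate_pes",
    "k_from_coupling",
    "coupling_residual",
    "pmax_hypothetical",
    "efficiency_from_coupling",
    "ef_from_efficiency",
    "solve_coupling",
    "beat_to_ef",
]


@dataclass(frozen=True)
class BeatRecord:
    """One beat's (or subject's) noninvasive measurements.

    Parameters
    ----------
    pep : float
        Pre-ejection period, ms.
    et : float
        Ejection time, ms.  Only the ratio ``et/pep`` enters the equations,
        so any common time unit works; the I/O layer standardises on ms.
    sbp, dbp : float
        Cuff systolic and diastolic pressure, mmHg.
    id : str
        Opaque label carried through to results.
    """

    pep: float
    et: float
    sbp: float
    dbp: float
    id: str = ""

    def __post_init__(self):
        if not self.pep > 0:
            raise InvalidInputError("pep", f"must be > 0, got {self.pep}")
        if not self.et > 0:
            raise InvalidInputError("et", f"must be > 0, got {self.et}")
        if not self.dbp > 0:
            raise InvalidInputError("dbp", f"must be > 0, got {self.dbp}")
        if not self.sbp > self.dbp:
            raise InvalidInputError(
                "sbp", f"must exceed dbp, got sbp={self.sbp}, dbp={self.dbp}"
            )


@dataclass(frozen=True)
class CouplingConstants:
    """Empirical constants of the pressure and slope-ratio regressions.

    ``pes_a/pes_b/pes_c`` are the Kappus end-systolic-pressure regression
    coefficients; ``c_k``/``p_k`` parameterise the bilinear-elastance slope
    ratio k = c_k * x**p_k.  ``p_k`` must lie in (0, 1) for the residual to be
    concave, which the root-selection logic relies on.
    """

    c_k: float = 0.53
    p_k: float = 0.51
    pes_a: float = 0.205
    pes_b: float = 0.898
    pes_c: float = 0.4214

    def __post_init__(self):
        if not self.c_k > 0:
            raise InvalidInputError("c_k", f"must be > 0, got {self.c_k}")
        if not 0 < self.p_k < 1:
            raise InvalidInputError("p_k", f"must be in (0, 1), got {self.p_k}")


@dataclass(frozen=True)
class SolverSettings:
    """Root-solver controls (tolerance is on the residual |g|)."""

    tolerance: float = 1e-10
    max_iterations: int = 100
    bracket_low: float = 1e-3
    bracket_high: float = 50.0
    initial_guess: float = 1.0

    def __post_init__(self):
        if not self.tolerance > 0:
            raise InvalidInputError("tolerance", "must be > 0")
        if self.max_iterations < 1:
            raise InvalidInputError("max_iterations", "must be >= 1")
        if not (0 < self.bracket_low < self.initial_guess < self.bracket_high):
            raise InvalidInputError(
                "bracket",
                "need 0 < bracket_low < initial_guess < bracket_high, got "
                f"({self.bracket_low}, {self.initial_guess}, {self.bracket_high})",
            )


@dataclass(frozen=True)
class CouplingEstimate:
    """Solved coupling ratio with the derived quantities and solver diagnostics.

    ``eff`` and ``ef`` are fractions in (0, 1); ``warnings`` collects
    physiological-plausibility flags (e.g. Pad >= Pes) without failing the beat.
    """

    ees_over_ea: float
    k: float
    pes: float
    pad: float
    pmax: float
    eff: float
    ef: float
    iterations: int
    converged: bool
    residual: float
    beat_id: str = ""
    warnings: tuple[str, ...] = field(default=())


def estimate_pes(sbp: float, dbp: float, constants: CouplingConstants = CouplingConstants()) -> float:
    """End-systolic pressure (mmHg) from cuff pressures via the Kappus regression."""
    if not dbp > 0:
        raise InvalidInputError("dbp", f"must be > 0, got {dbp}")
    if not sbp > dbp:
        raise InvalidInputError("sbp", f"must exceed dbp, got sbp={sbp}, dbp={dbp}")
    return constants.pes_a * sbp + constants.pes_b * dbp + constants.pes_c


def k_from_coupling(x: float, constants: CouplingConstants = CouplingConstants()) -> float:
    """Bilinear-elastance slope ratio k = c_k * x**p_k, strictly increasing in x."""
    if not x > 0:
        raise DomainError(f"coupling ratio must be > 0, got {x}")
    return constants.c_k * x ** constants.p_k


def coupling_residual(
    x: float,
    pad: float,
    pes: float,
    et: float,
    pep: float,
    constants: CouplingConstants = CouplingConstants(),
) -> float:
    """Residual g(x) whose root is the simultaneous solution for Ees/Ea.

    g(x) = (pad/pes) * (1 + c_k * x**p_k * et/pep) - 1 - x.  Strictly concave
    on x > 0 because 0 < p_k < 1.
    """
    if not x > 0:
        raise DomainError(f"coupling ratio must be > 0, got {x}")
    return (pad / pes) * (1.0 + constants.c_k * x ** constants.p_k * et / pep) - 1.0 - x


def _residual_derivative(
    x: float, pad: float, pes: float, et: float, pep: float, constants: CouplingConstants
) -> float:
    return (pad / pes) * constants.c_k * constants.p_k * x ** (constants.p_k - 1.0) * et / pep - 1.0


def pmax_hypothetical(pad: float, k: float, et: float, pep: float) -> float:
    """Hypothetical isovolumic peak pressure against a clamped aorta (mmHg)."""
    if not (pad > 0 and et > 0 and pep > 0):
        raise InvalidInputError("pad/et/pep", "all inputs must be > 0")
    if k < 0:
        raise InvalidInputError("k", f"must be >= 0, got {k}")
    return pad * (1.0 + k * et / pep)


def efficiency_from_coupling(x: float) -> float:
    """Ventricular efficiency Eff = 1/(1 + 0.5/x), increasing, range (0, 1)."""
    if not x > 0:
        raise DomainError(f"coupling ratio must be > 0, got {x}")
    return 1.0 / (1.0 + 0.5 / x)


def ef_from_efficiency(eff: float) -> float:
    """Ejection fraction EF = Eff/(2 - Eff); exact when V0 = 0, else an overestimate."""
    if not 0 <= eff <= 1:
        raise DomainError(f"efficiency must lie in [0, 1], got {eff}")
    return eff / (2.0 - eff)


def _argmax_residual(
    pad: float, pes: float, et: float, pep: float, constants: CouplingConstants
) -> float:
    # g'(x*) = 0  =>  x* = (A * c_k * p_k * et/pep)**(1/(1 - p_k)),  A = pad/pes
    a = (pad / pes) * constants.c_k * constants.p_k * et / pep
    return a ** (1.0 / (1.0 - constants.p_k))


def solve_coupling(
    beat: BeatRecord,
    constants: CouplingConstants = CouplingConstants(),
    settings: SolverSettings = SolverSettings(),
) -> CouplingEstimate:
    """Solve the coupling equations for one beat by safeguarded Newton iteration.

    Returns the largest positive root of :func:`coupling_residual` inside the
    settings bracket.  The concavity of g makes root selection deterministic:
    the maximiser x* of g is available in closed form, and the larger root lies
    on the descending branch [x*, bracket_high].  Newton steps use the analytic
    derivative; any step leaving the maintained sign-change bracket is replaced
    by bisection, so convergence is guaranteed.

    Raises
    ------
    NoSolutionError
        If g < 0 throughout (no positive root: ejection too short relative to
        the pressure ratio).
    NonConvergenceError
        If the iteration budget is exhausted (cannot happen with the default
        safeguard, kept for configurability).
    """
    pes = estimate_pes(beat.sbp, beat.dbp, constants)
    pad = beat.dbp
    warnings: list[str] = []
    if pad >= pes:
        warnings.append(
            f"pad ({pad:g} mmHg) >= estimated pes ({pes:g} mmHg): "
            "single-root regime, physiologically suspect"
        )

    def g(x: float) -> float:
        return coupling_residual(x, pad, pes, beat.et, beat.pep, constants)

    def dg(x: float) -> float:
        return _residual_derivative(x, pad, pes, beat.et, beat.pep, constants)

    # Restrict to the descending branch: largest root lives in [x*, hi].
    x_star = _argmax_residual(pad, pes, beat.et, beat.pep, constants)
    lo = min(max(x_star, settings.bracket_low), settings.bracket_high)
    hi = settings.bracket_high
    g_lo, g_hi = g(lo), g(hi)
    if g_lo < 0.0:
        raise NoSolutionError(
            "coupling residual has no positive root in bracket", g_lo, g_hi
        )
    while g_hi > 0.0:  # root beyond the configured bracket; extend rather than fail
        hi *= 2.0
        g_hi = g(hi)
        warnings.append(f"root beyond bracket_high, extended to {hi:g}")
        if hi > 1e6:
            raise NoSolutionError("no sign change found while extending bracket", g_lo, g_hi)

    x = settings.initial_guess
    if not (lo <= x <= hi):
        x = 0.5 * (lo + hi)
    gx = g(x)
    converged = abs(gx) <= settings.tolerance
    iterations = 0
    while not converged and iterations < settings.max_iterations:
        iterations += 1
        # maintain the sign-change bracket [lo, hi]: g(lo) >= 0 > g(hi)
        if gx >= 0.0:
            lo = x
        else:
            hi = x
        d = dg(x)
        if d != 0.0:
            x_new = x - gx / d
        else:
            x_new = 0.5 * (lo + hi)
        if not (lo < x_new < hi):
            x_new = 0.5 * (lo + hi)  # bisection fallback
        x = x_new
        gx = g(x)
        converged = abs(gx) <= settings.tolerance

    if not converged:
        raise NonConvergenceError(
            f"coupling solver did not converge in {settings.max_iterations} iterations",
            x,
            gx,
        )

    k = k_from_coupling(x, constants)
    pmax = pmax_hypothetical(pad, k, beat.et, beat.pep)
    eff = efficiency_from_coupling(x)
    ef = ef_from_efficiency(eff)
    return CouplingEstimate(
        ees_over_ea=x,
        k=k,
        pes=pes,
        pad=pad,
        pmax=pmax,
        eff=eff,
        ef=ef,
        iterations=iterations,
        converged=converged,
        residual=gx,
        beat_id=beat.id,
        warnings=tuple(warnings),
    )


def beat_to_ef(
    beat: BeatRecord,
    constants: CouplingConstants = CouplingConstants(),
    settings: SolverSettings = SolverSettings(),
) -> CouplingEstimate:
    """Full pipeline: cuff pressures -> Pes -> Ees/Ea -> Eff -> EF, for one beat."""
    try:
        return solve_coupling(beat, constants, settings)
    except (NoSolutionError, NonConvergenceError) as exc:
        exc.args = (f"beat {beat.id!r}: {exc.args[0]}",) + exc.args[1:]
        raise
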