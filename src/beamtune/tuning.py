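"""Iterative beam-parameter tuning: energy, energy spread, and beam optics.

The tuning pipeline determines, per nominal accelerator energy, the five
source parameters of a scanned pencil beam -- mean energy E, energy spread
sigma_E, and per transverse plane the optics triple (sigma, theta, epsilon)
-- by matching forward-simulated observables to commissioning measurements:

* energy tuning minimizes ``(R80_meas - R80_sim(E))^2``,
* spread tuning minimizes ``(BPW80_meas - BPW80_sim(sigma_E))^2`` at fixed E,
* optics tuning minimizes the sum of squared FWHM differences over all
  measured planes, optionally augmented by a regularization term
  ``lambda * [(sigma_j - sigma_{j-1})^2 + (theta_j - theta_{j-1})^2
  + (eps_j - eps_{j-1})^2]`` that ties each energy to the final parameters of
  the preceding (lower) energy.  The lowest energy is never regularized.

All minimizations use an in-package Nelder--Mead simplex with the standard
reflection/expansion/contraction/shrink coefficients (1, 2, 0.5, 0.5); the
stop criteria are a maximum per-coordinate simplex extent below
``stop_param_change`` or a best objective below ``stop_objective``.

Energies and energy spreads are weakly coupled through range straggling, so
energy and spread are tuned alternately for a small number of rounds rather
than jointly; optics planes are tuned independently of each other.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .depth_dose import (
    DepthDoseCurve,
    EnergySpectrum,
    energy_from_range,
    simulate_idc,
)
from .errors import BeamtuneError, DomainError
from .optics import (
    FWHM_PER_SIGMA,
    BeamlineGeometry,
    OpticsPlane,
    SecondMoments,
    drift,
    scattering_moments_at,
    spot_fwhm_at,
)
from .particles import ParticleSpec

logger = logging.getLogger(__name__)

PLANES = ("x", "y")

#: Additive penalty for simplex candidates outside the feasible region.
INFEASIBLE_PENALTY = 1e6


@dataclass(frozen=True)
class TuningConfig:
    """Optimizer settings; the defaults mirror the commissioning protocol.

    ``lambda_reg`` weights the optics regularization (0.1 by default),
    ``stop_param_change``/``stop_objective`` are the simplex stop criteria,
    ``simplex_step_rel`` sets the initial simplex extent as a fraction of
    each starting coordinate, and ``spectrum_rounds`` is the number of
    energy/spread alternations.
    """

    lambda_reg: float = 0.1
    stop_param_change: float = 1e-4
    stop_objective: float = 1e-5
    max_iterations: int = 400
    simplex_step_rel: float = 0.05
    simplex_restarts: int = 2
    spectrum_rounds: int = 2
    fwhm_estimator: str = "crossings"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise DomainError("lambda_reg must be >= 0")
        if self.stop_param_change <= 0 or self.stop_objective <= 0:
            raise DomainError("stop criteria must be > 0")
        if self.max_iterations < 1 or self.spectrum_rounds < 1:
            raise DomainError("iteration counts must be >= 1")
        if self.simplex_restarts < 0:
            raise DomainError("simplex_restarts must be >= 0")


@dataclass(frozen=True)
class MeasurementSet:
    """One machine's commissioning dataset.

    ``idcs`` maps each nominal energy to its depth-dose curve; ``spots`` is a
    table with columns ``energy_MeV, position_mm, fwhm_x_mm, fwhm_y_mm``.
    """

    particle: ParticleSpec
    geometry: BeamlineGeometry
    energies: np.ndarray
    idcs: dict
    spots: pd.DataFrame

    def __post_init__(self) -> None:
        energies = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "energies", energies)
        if energies.ndim != 1 or energies.size < 1:
            raise DomainError("need at least one nominal energy")
        if np.any(np.diff(energies) <= 0):
            raise DomainError("nominal energies must be strictly increasing")
        required = {"energy_MeV", "position_mm", "fwhm_x_mm", "fwhm_y_mm"}
        missing = required - set(self.spots.columns)
        if missing:
            raise DomainError(f"spot table misses columns {sorted(missing)}")
        counts = self.spots.groupby("energy_MeV")["position_mm"].count()
        for e in energies:
            if e not in self.idcs:
                raise DomainError(f"no IDC for nominal energy {e} MeV")
            if counts.get(e, 0) < 2:
                raise DomainError(f"fewer than 2 spot positions for {e} MeV")
        if counts.nunique() > 1:
            raise DomainError("spot-position count differs between energies")

    def spots_at(self, energy: float) -> pd.DataFrame:
        sel = self.spots[self.spots["energy_MeV"] == energy]
        return sel.sort_values("position_mm").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Nelder--Mead simplex
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NelderMeadResult:
    x: np.ndarray
    fun: float
    iterations: int
    nfev: int
    converged_by: str


def nelder_mead_minimize(
    objective,
    x0,
    config: TuningConfig | None = None,
    steps=None,
) -> NelderMeadResult:
    """Derivative-free simplex minimization.

    Deterministic given ``x0`` and ``config``; vertex ordering breaks ties by
    vertex index (stable sort).  The initial simplex offsets each coordinate
    by ``steps`` (default: ``simplex_step_rel`` of the coordinate, or the
    relative step as an absolute one where the coordinate is zero).
    """
    cfg = config or TuningConfig()
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    n = x0.size
    f0 = float(objective(x0))
    if not math.isfinite(f0):
        raise DomainError(f"objective is not finite at x0={x0}")
    if steps is None:
        steps = [
            cfg.simplex_step_rel * abs(v) if v != 0 else cfg.simplex_step_rel
            for v in x0
        ]
    steps = np.asarray(steps, dtype=float)
    simplex = np.tile(x0, (n + 1, 1))
    for i in range(n):
        simplex[i + 1, i] += steps[i]
    fvals = np.array([f0] + [float(objective(v)) for v in simplex[1:]])
    nfev = n + 1
    converged_by = "max_iterations"
    iteration = 0
    for iteration in range(1, cfg.max_iterations + 1):
        order = np.argsort(fvals, kind="stable")
        simplex, fvals = simplex[order], fvals[order]
        if fvals[0] < cfg.stop_objective:
            converged_by = "objective"
            break
        spread = np.max(simplex.max(axis=0) - simplex.min(axis=0))
        if spread < cfg.stop_param_change:
            converged_by = "parameter_change"
            break
        centroid = simplex[:-1].mean(axis=0)
        worst = simplex[-1]
        reflected = centroid + (centroid - worst)
        f_r = float(objective(reflected))
        nfev += 1
        if f_r < fvals[0]:
            expanded = centroid + 2.0 * (centroid - worst)
            f_e = float(objective(expanded))
            nfev += 1
            if f_e < f_r:
                simplex[-1], fvals[-1] = expanded, f_e
            else:
                simplex[-1], fvals[-1] = reflected, f_r
        elif f_r < fvals[-2]:
            simplex[-1], fvals[-1] = reflected, f_r
        else:
            if f_r < fvals[-1]:
                contracted = centroid + 0.5 * (reflected - centroid)
            else:
                contracted = centroid + 0.5 * (worst - centroid)
            f_c = float(objective(contracted))
            nfev += 1
            if f_c < min(f_r, fvals[-1]):
                simplex[-1], fvals[-1] = contracted, f_c
            else:  # shrink toward the best vertex
                for i in range(1, n + 1):
                    simplex[i] = simplex[0] + 0.5 * (simplex[i] - simplex[0])
                    fvals[i] = float(objective(simplex[i]))
                nfev += n
    order = np.argsort(fvals, kind="stable")
    best = order[0]
    return NelderMeadResult(
        x=simplex[best].copy(),
        fun=float(fvals[best]),
        iterations=iteration,
        nfev=nfev,
        converged_by=converged_by,
    )


def minimize_with_restarts(
    objective, x0, config: TuningConfig | None = None
) -> NelderMeadResult:
    """Nelder--Mead with fresh-simplex restarts from the incumbent best.

    A collapsed simplex can stall short of the minimum on noisy or
    ill-conditioned landscapes; re-spanning it at the best vertex is the
    standard remedy.  Restarting stops early once a restart no longer
    improves the objective meaningfully.
    """
    cfg = config or TuningConfig()
    result = nelder_mead_minimize(objective, x0, cfg)
    iterations, nfev = result.iterations, result.nfev
    for _ in range(cfg.simplex_restarts):
        if result.fun < cfg.stop_objective:
            break
        again = nelder_mead_minimize(objective, result.x, cfg)
        iterations += again.iterations
        nfev += again.nfev
        improved = result.fun - again.fun
        result = again if again.fun < result.fun else result
        result = NelderMeadResult(
            x=result.x, fun=result.fun, iterations=iterations, nfev=nfev,
            converged_by=result.converged_by,
        )
        if improved <= 1e-3 * abs(result.fun) + 1e-12:
            break
    return result


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------


def energy_objective(e_candidate: float, measured_r80: float, forward) -> float:
    """Squared R80 difference [mm^2]; ``forward`` maps energy -> simulated R80."""
    return (measured_r80 - forward(e_candidate)) ** 2


def spread_objective(sigma_e_candidate: float, measured_bpw80: float, forward) -> float:
    """Squared BPW80 difference [mm^2]; ``forward`` maps sigma_E -> BPW80."""
    return (measured_bpw80 - forward(sigma_e_candidate)) ** 2


def optics_objective(candidate: OpticsPlane, measured_fwhm, forward) -> float:
    """Sum of squared FWHM differences [mm^2] over all measured planes.

    ``forward`` maps an :class:`OpticsPlane` to the simulated FWHM array at
    the measurement positions.
    """
    measured = np.asarray(measured_fwhm, dtype=float)
    simulated = np.asarray(forward(candidate), dtype=float)
    if measured.shape != simulated.shape:
        raise DomainError("measured and simulated FWHM shapes differ")
    return float(np.sum((measured - simulated) ** 2))


def regularization_term(current, previous) -> float:
    """Sum of squared (sigma, theta, epsilon) differences between energies.

    Mixed units (mm, mrad, mm mrad) are summed as-is; the regularization
    weight is calibrated for exactly this convention.
    """
    cur = _as_triple(current)
    prev = _as_triple(previous)
    return float(np.sum((cur - prev) ** 2))


def regularized_optics_objective(
    candidate: OpticsPlane,
    measured_fwhm,
    forward,
    previous=None,
    lambda_reg: float = 0.1,
) -> float:
    """Optics objective plus ``lambda * R``; no term at the lowest energy."""
    value = optics_objective(candidate, measured_fwhm, forward)
    if previous is not None and lambda_reg > 0:
        value += lambda_reg * regularization_term(candidate, previous)
    return value


def _as_triple(plane) -> np.ndarray:
    if isinstance(plane, OpticsPlane):
        return np.array([plane.sigma, plane.theta, plane.epsilon])
    arr = np.asarray(plane, dtype=float)
    if arr.shape != (3,):
        raise DomainError("optics parameters must be a (sigma, theta, epsilon) triple")
    return arr


# ---------------------------------------------------------------------------
# Per-energy tuning stages
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrumFit:
    """Tuned spectrum for one nominal energy, with convergence diagnostics."""

    nominal_energy: float
    spectrum: EnergySpectrum
    r80_measured: float
    r80_simulated: float
    bpw80_measured: float
    bpw80_simulated: float
    energy_iterations: int
    spread_iterations: int
    energy_objective: float
    spread_objective: float


@dataclass(frozen=True)
class OpticsFit:
    """Tuned optics of one plane at one nominal energy."""

    nominal_energy: float
    plane_id: str
    plane: OpticsPlane
    objective: float
    data_term: float
    iterations: int
    fwhm_measured: np.ndarray
    fwhm_simulated: np.ndarray


@dataclass(frozen=True)
class TuningResult:
    """Complete tuned parameter set over all nominal energies."""

    energies: np.ndarray
    spectra: tuple
    optics: dict  # plane id -> tuple[OpticsFit, ...]

    def spectrum_at(self, energy: float) -> EnergySpectrum:
        for fit in self.spectra:
            if fit.nominal_energy == energy:
                return fit.spectrum
        raise KeyError(f"no tuned spectrum for {energy} MeV")


def tune_energy(
    idc: DepthDoseCurve,
    particle: ParticleSpec,
    config: TuningConfig | None = None,
    sigma_e: float = 0.0,
    e0: float | None = None,
) -> tuple[float, NelderMeadResult, float]:
    """Tune the mean energy against the measured R80 at fixed sigma_E.

    Returns ``(E*, simplex result, measured R80)``.  The initial guess
    inverts the range--energy rule at the measured R80.
    """
    cfg = config or TuningConfig()
    r80_meas = metrics.r80(idc)
    if e0 is None:
        e0 = energy_from_range(r80_meas, particle)

    def forward(e: float) -> float:
        return metrics.r80(simulate_idc(EnergySpectrum(e, sigma_e), particle))

    def objective(x) -> float:
        e = float(x[0])
        if e <= 0 or sigma_e >= 0.1 * e:
            return INFEASIBLE_PENALTY * (1.0 + abs(e))
        return energy_objective(e, r80_meas, forward)

    result = nelder_mead_minimize(objective, [e0], cfg)
    return float(result.x[0]), result, r80_meas


def tune_spread(
    idc: DepthDoseCurve,
    particle: ParticleSpec,
    energy: float,
    config: TuningConfig | None = None,
    sigma_e0: float | None = None,
) -> tuple[float, NelderMeadResult, float]:
    """Tune sigma_E against the measured BPW80 at fixed mean energy."""
    cfg = config or TuningConfig()
    bpw_meas = metrics.bragg_peak_width(idc, level=0.8)
    if sigma_e0 is None:
        sigma_e0 = 0.005 * energy

    def forward(sigma_e: float) -> float:
        return metrics.bragg_peak_width(
            simulate_idc(EnergySpectrum(energy, sigma_e), particle), level=0.8
        )

    def objective(x) -> float:
        s = float(x[0])
        if s < 0 or s >= 0.1 * energy:
            return INFEASIBLE_PENALTY * (1.0 + abs(s))
        return spread_objective(s, bpw_meas, forward)

    result = nelder_mead_minimize(objective, [sigma_e0], cfg)
    return max(float(result.x[0]), 0.0), result, bpw_meas


def tune_spectrum(
    idc: DepthDoseCurve,
    particle: ParticleSpec,
    config: TuningConfig | None = None,
    nominal_energy: float | None = None,
) -> SpectrumFit:
    """Alternate energy and spread tuning until both observables match.

    Energy and spread are weakly coupled (a larger spread shifts the distal
    80 % point slightly), so a second alternation round removes the residual
    bias of the first; the result is insensitive to the initial spread guess.
    """
    cfg = config or TuningConfig()
    r80_meas = metrics.r80(idc)
    e_star = energy_from_range(r80_meas, particle)
    sigma_star = 0.005 * e_star
    energy_iters = spread_iters = 0
    e_res = s_res = None
    for _ in range(cfg.spectrum_rounds):
        e_star, e_res, _ = tune_energy(idc, particle, cfg, sigma_e=sigma_star, e0=e_star)
        energy_iters += e_res.iterations
        sigma_star, s_res, bpw_meas = tune_spread(
            idc, particle, e_star, cfg, sigma_e0=sigma_star
        )
        spread_iters += s_res.iterations
    spectrum = EnergySpectrum(e_star, sigma_star)
    final = simulate_idc(spectrum, particle)
    fit = SpectrumFit(
        nominal_energy=float("nan") if nominal_energy is None else nominal_energy,
        spectrum=spectrum,
        r80_measured=r80_meas,
        r80_simulated=metrics.r80(final),
        bpw80_measured=metrics.bragg_peak_width(idc, level=0.8),
        bpw80_simulated=metrics.bragg_peak_width(final, level=0.8),
        energy_iterations=energy_iters,
        spread_iterations=spread_iters,
        energy_objective=e_res.fun,
        spread_objective=s_res.fun,
    )
    logger.info(
        "spectrum tuned: E=%.3f MeV sigma_E=%.3f MeV |dR80|=%.4f mm |dBPW80|=%.4f mm",
        e_star,
        sigma_star,
        abs(fit.r80_simulated - fit.r80_measured),
        abs(fit.bpw80_simulated - fit.bpw80_measured),
    )
    return fit


# ---------------------------------------------------------------------------
# Optics tuning
# ---------------------------------------------------------------------------


def _source_moment_estimate(
    positions_mm,
    fwhm_mm,
    geometry: BeamlineGeometry,
    spectrum: EnergySpectrum | None = None,
    particle: ParticleSpec | None = None,
) -> tuple[float, float, float]:
    """Unclamped (var_x, cov, var_xp) at the source from measured widths.

    Least-squares parabola through the scattering-corrected squared widths,
    drifted back to the source plane in vacuum.  Unbiased but noisy --
    especially the curvature (divergence) component, which rests on
    sub-percent differences over a short lever arm.
    """
    z = np.asarray(positions_mm, dtype=float)
    sig2 = (np.asarray(fwhm_mm, dtype=float) / FWHM_PER_SIGMA) ** 2
    if z.size < 2:
        raise DomainError("need >= 2 spot positions for an optics guess")
    if spectrum is not None and particle is not None:
        scat = np.array(
            [
                scattering_moments_at(geometry, spectrum.energy, particle, zi).var_x
                for zi in z
            ]
        )
        sig2 = np.maximum(sig2 - scat, 1e-4)
    deg = 2 if z.size >= 3 else 1
    coeffs = np.polyfit(z, sig2, deg)  # highest power first
    if deg == 2:
        a2, a1, a0 = coeffs
    else:
        a2, (a1, a0) = 0.0, coeffs
    var_iso = max(a0, 1e-2)
    cov_iso = a1 * 5e2  # var(z) = var0 + 2e-3 z cov + 1e-6 z^2 varxp
    var_xp = a2 * 1e6
    m_iso = SecondMoments(var_iso, cov_iso, max(var_xp, 0.0))
    m_src = drift(m_iso, geometry.source_z_mm)
    return m_src.var_x, m_src.cov_xxp, var_xp


def initial_optics_guess(
    positions_mm,
    fwhm_mm,
    geometry: BeamlineGeometry,
    spectrum: EnergySpectrum | None = None,
    particle: ParticleSpec | None = None,
) -> OpticsPlane:
    """Data-driven starting point for the optics search.

    sigma^2(z) of a drifting Gaussian beam is exactly quadratic in z, so
    after subtracting the (analytically known) air-scattering contribution
    from the measured squared widths, a least-squares parabola yields the
    vacuum moments at the isocenter, which drift back to the source plane
    in closed form.  With spectrum and particle omitted the scattering
    correction is skipped and the guess is correspondingly cruder.
    """
    var_src, cov_src, var_xp = _source_moment_estimate(
        positions_mm, fwhm_mm, geometry, spectrum, particle
    )
    var_src = max(var_src, 1e-2)
    var_xp = max(var_xp, 1e-2)
    sigma0 = math.sqrt(var_src)
    theta0 = math.sqrt(var_xp)
    det = var_src * var_xp - cov_src**2
    cap = math.pi * sigma0 * theta0
    if det > 0:
        eps0 = min(max(math.pi * math.sqrt(det), 0.05 * cap), 0.95 * cap)
    else:
        eps0 = 0.5 * cap
    sign = -1 if cov_src < 0 else 1
    return OpticsPlane(sigma=sigma0, theta=theta0, epsilon=eps0, sign=sign)


def _search_violation(x: np.ndarray, sign_constraint: int | None = None) -> float:
    """Distance outside the feasible search box (0 inside); continuous at 0.

    ``sign_constraint`` restricts the correlation to one half-space
    (boundary u = 0 included), used to keep a tuning sequence on a single
    convergence sign -- the only geometry an energy-parametrized model
    with one sign per plane can represent.
    """
    sigma, theta, u = x
    v = max(0.0, -sigma) + max(0.0, -theta)
    v += max(0.0, abs(u) - 1.0)
    if sign_constraint is not None:
        v += max(0.0, -sign_constraint * u)
    return v


def _plane_from_search(x: np.ndarray, sign_constraint: int | None = None) -> OpticsPlane:
    """Map search coordinates (sigma, theta, u) to a feasible optics plane.

    ``u`` is the signed position--angle correlation coefficient
    ``cov / (sigma * theta)``; the emittance follows as
    ``pi * sigma * theta * sqrt(1 - u^2)`` and the convergence sign as the
    sign of ``u``.  Unlike the raw (sigma, theta, epsilon, fixed-sign)
    triple, this chart is smooth across a beam-waist crossing (u = 0),
    where the correlation changes sign -- a physically unremarkable point
    that would otherwise be a hard boundary of the search space.
    """
    sigma = max(float(x[0]), 1e-3)
    theta = max(float(x[1]), 1e-3)
    u = float(np.clip(x[2], -1.0, 1.0))
    if sign_constraint is not None:
        u = sign_constraint * max(sign_constraint * u, 0.0)
        sign = sign_constraint
    else:
        sign = -1 if u < 0 else 1
    eps = math.pi * sigma * theta * math.sqrt(max(1.0 - u * u, 0.0))
    return OpticsPlane(sigma=sigma, theta=theta, epsilon=eps, sign=sign)


def _search_from_plane(plane: OpticsPlane) -> np.ndarray:
    frac = min(plane.emittance_fraction, 1.0)
    u = plane.sign * math.sqrt(max(1.0 - frac * frac, 0.0))
    return np.array([plane.sigma, plane.theta, u])


def tune_optics(
    positions_mm,
    fwhm_mm,
    geometry: BeamlineGeometry,
    spectrum: EnergySpectrum,
    particle: ParticleSpec,
    config: TuningConfig | None = None,
    previous: OpticsPlane | None = None,
    plane_id: str = "x",
    nominal_energy: float | None = None,
    x0: OpticsPlane | None = None,
    sign_constraint: int | None = None,
    epsilon_bounds: tuple[float, float] | None = None,
) -> OpticsFit:
    """Tune (sigma, theta, epsilon) of one plane against measured FWHMs.

    With ``previous`` given (the tuned result of the preceding, lower
    energy) the objective carries the regularization term.  The simplex
    searches the smooth chart (sigma, theta, correlation) described in
    :func:`_plane_from_search`, so the convergence sign is determined by
    the data rather than held fixed; candidates outside the feasible box
    are evaluated at their projection onto it plus a penalty proportional
    to the violation, keeping the objective finite and continuous.
    """
    cfg = config or TuningConfig()
    z = np.asarray(positions_mm, dtype=float)
    measured = np.asarray(fwhm_mm, dtype=float)
    if z.size < 2:
        raise DomainError("optics tuning needs >= 2 spot positions")
    if x0 is not None:
        guess = x0
    elif previous is not None:
        # Warm start: the preceding energy's optimum is close by (the
        # parameter curves are smooth) and already feasible.
        guess = previous
    else:
        guess = initial_optics_guess(z, measured, geometry, spectrum, particle)

    def forward(plane: OpticsPlane) -> np.ndarray:
        return spot_fwhm_at(plane, geometry, spectrum.energy, particle, z)

    def objective(x) -> float:
        x = np.asarray(x, dtype=float)
        plane = _plane_from_search(x, sign_constraint)
        value = regularized_optics_objective(
            plane, measured, forward, previous=previous, lambda_reg=cfg.lambda_reg
        )
        violation = _search_violation(x, sign_constraint)
        if epsilon_bounds is not None:
            lo, hi = epsilon_bounds
            scale = max(hi, 1e-6)
            violation += (
                max(0.0, plane.epsilon - hi) + max(0.0, lo - plane.epsilon)
            ) / scale
        # Continuous at the box boundary: the simplex can slide along it
        # without jamming against a discontinuous wall.
        return value + INFEASIBLE_PENALTY * violation

    start = _search_from_plane(guess)
    result = minimize_with_restarts(objective, start, cfg)
    best = _plane_from_search(result.x, sign_constraint)
    simulated = forward(best)
    data_term = float(np.sum((measured - simulated) ** 2))
    return OpticsFit(
        nominal_energy=float("nan") if nominal_energy is None else nominal_energy,
        plane_id=plane_id,
        plane=best,
        objective=result.fun,
        data_term=data_term,
        iterations=result.iterations,
        fwhm_measured=measured,
        fwhm_simulated=np.asarray(simulated),
    )


def pooled_optics_guesses(
    measurements: MeasurementSet,
    plane_id: str,
    spectra: dict,
) -> dict:
    """Initial guess at one energy pooled from every energy's moment fit.

    The single-energy moment estimate has a large variance in the curvature
    (divergence) direction; since the true parameter curves are smooth in
    energy, pooling the per-energy *moment* estimates -- a linear trend for
    beam size and correlation, a robust median for the curvature --
    suppresses that noise by roughly the square root of the energy count.
    Returns one starting :class:`OpticsPlane` per nominal energy, all
    sharing the majority correlation sign.
    """
    column = f"fwhm_{plane_id}_mm"
    energies, var_srcs, cov_srcs, var_xps = [], [], [], []
    for energy in measurements.energies:
        spots = measurements.spots_at(energy)
        var_src, cov_src, var_xp = _source_moment_estimate(
            spots["position_mm"].to_numpy(),
            spots[column].to_numpy(),
            measurements.geometry,
            spectra[energy],
            measurements.particle,
        )
        energies.append(float(energy))
        var_srcs.append(var_src)
        cov_srcs.append(cov_src)
        var_xps.append(var_xp)
    e = np.asarray(energies)
    deg = 1 if e.size >= 2 else 0
    var_fit = np.polyfit(e, var_srcs, deg)
    cov_fit = np.polyfit(e, cov_srcs, deg)
    # The curvature component is noisy enough that fitting a trend is
    # counterproductive; the median across energies is a robust pooled
    # value (slightly biased toward mid-range).
    var_xp = max(float(np.median(var_xps)), 1e-2)
    sign = -1 if float(np.median(cov_srcs)) < 0 else 1
    guesses = {}
    for energy in measurements.energies:
        var_src = max(float(np.polyval(var_fit, energy)), 1e-2)
        cov_src = float(np.polyval(cov_fit, energy))
        sigma0 = math.sqrt(var_src)
        theta0 = math.sqrt(var_xp)
        det = var_src * var_xp - cov_src**2
        cap = math.pi * sigma0 * theta0
        eps0 = math.pi * math.sqrt(det) if det > 0 else 0.0
        # The ellipse-area (determinant) direction is by far the sloppiest:
        # its pooled estimate can be off by several-fold.  Starting too
        # high is costly -- the regularized chain then drags sigma*theta up
        # to keep the area feasible, degrading the fit -- while starting
        # low is free because the correlation absorbs it.  Cap at half the
        # waist bound.
        eps0 = min(max(eps0, 0.05 * cap), 0.5 * cap)
        guesses[float(energy)] = OpticsPlane(
            sigma=sigma0, theta=theta0, epsilon=eps0, sign=sign
        )
    return guesses


def tune_optics_sequence(
    measurements: MeasurementSet,
    plane_id: str,
    spectra: dict,
    config: TuningConfig | None = None,
) -> list[OpticsFit]:
    """Tune one plane over all energies, lowest first.

    Each energy beyond the first is regularized toward the final parameters
    of the preceding energy.  Every energy starts its simplex at the pooled
    cross-energy moment estimate: the per-energy least-squares optimum is
    nearly degenerate along the emittance direction, and starting each
    search from the same smooth parameter curve keeps the chain from
    drifting collectively along that valley.  The correlation sign is held
    chain-consistent (the majority sign of the pooled estimates), matching
    the single-sign-per-plane geometry the compiled beam model can
    represent.  On a per-energy failure the exception is re-raised with the
    partial results attached to its ``partial`` attribute.
    """
    cfg = config or TuningConfig()
    column = f"fwhm_{plane_id}_mm"
    fits: list[OpticsFit] = []
    previous: OpticsPlane | None = None
    guesses = pooled_optics_guesses(measurements, plane_id, spectra)
    first = guesses[float(measurements.energies[0])]
    sign = first.sign
    # The lowest energy fixes the emittance scale of the whole chain (the
    # regularizer ties each energy's ellipse area to its predecessor), yet
    # single-plane width data leaves that scale nearly unidentified: an
    # unconstrained fit drifts to a noise-determined extreme, which is
    # harmless at the lowest energy itself but degrades every subsequent
    # regularized fit.  The anchor fit is therefore confined to a bracket
    # around the pooled moment estimate -- a constraint acting only along
    # the unidentifiable direction.
    anchor_cap = math.pi * first.sigma * first.theta
    anchor_bounds = (0.2 * anchor_cap, 0.6 * anchor_cap)
    for energy in measurements.energies:
        spots = measurements.spots_at(energy)
        try:
            fit = tune_optics(
                spots["position_mm"].to_numpy(),
                spots[column].to_numpy(),
                measurements.geometry,
                spectra[energy],
                measurements.particle,
                cfg,
                previous=previous,
                plane_id=plane_id,
                nominal_energy=float(energy),
                x0=guesses[float(energy)],
                sign_constraint=sign,
                epsilon_bounds=None if previous is not None else anchor_bounds,
            )
        except BeamtuneError as exc:
            exc.partial = fits
            raise
        fits.append(fit)
        previous = fit.plane
    return fits


def tune_all(
    measurements: MeasurementSet, config: TuningConfig | None = None
) -> TuningResult:
    """Run the full sequential tuning pipeline over a measurement set."""
    cfg = config or TuningConfig()
    spectra_fits = []
    spectra = {}
    for energy in measurements.energies:
        fit = tune_spectrum(
            measurements.idcs[energy],
            measurements.particle,
            cfg,
            nominal_energy=float(energy),
        )
        spectra_fits.append(fit)
        spectra[energy] = fit.spectrum
    optics = {
        plane: tuple(tune_optics_sequence(measurements, plane, spectra, cfg))
        for plane in PLANES
    }
    return TuningResult(
        energies=measurements.energies.copy(),
        spectra=tuple(spectra_fits),
        optics=optics,
    )
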