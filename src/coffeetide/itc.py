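"""One-site binding isotherm: forward model and least-squares fit for
isothermal titration calorimetry (ITC).

The forward model is the standard single-site equilibrium with per-injection
displacement mixing: each injection of volume dV into a cell of volume V0
dilutes cell contents by (1 - dV/V0) and delivers syringe titrant; the bound
complex concentration follows from the quadratic root of

    [MX] = ( (Xt + n*Mt + Kd) - sqrt((Xt + n*Mt + Kd)^2 - 4*n*Mt*Xt) ) / 2

with Mt the cell macromolecule, Xt the titrant, n the stoichiometry and Kd
the dissociation constant.  The measured per-injection heat, normalized per
mole of injectant, is the increment of the cell heat content V0*dH*[MX]
corrected for the displaced volume.

Derived thermodynamics use the standard state 1 M:
dG = R*T*ln(Kd), -T*dS = dG - dH, with R = 1.9872e-3 kcal/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "R_KCAL",
    "TitrationProtocol",
    "Isotherm",
    "BindingFit",
    "FitFailure",
    "simulate_isotherm",
    "fit_one_site",
    "thermodynamics",
]

#: Gas constant, kcal/(mol K).
R_KCAL = 1.987204e-3


@dataclass(frozen=True)
class TitrationProtocol:
    """Cell/syringe concentrations and the injection schedule.

    Units: volumes in litres, concentrations in mol/L, temperature in K.
    """

    cell_volume: float = 200e-6
    cell_concentration: float = 40e-6
    syringe_concentration: float = 400e-6
    injection_volumes: Tuple[float, ...] = tuple([2.5e-6] * 20)
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if min(
            self.cell_volume,
            self.cell_concentration,
            self.syringe_concentration,
            self.temperature,
        ) <= 0:
            raise ValueError("protocol quantities must be positive")
        if len(self.injection_volumes) < 2 or any(v <= 0 for v in self.injection_volumes):
            raise ValueError("at least two positive injections required")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


@dataclass(frozen=True)
class Isotherm:
    """Per-injection normalized heats (kcal per mol of injectant) and the
    running molar ratio titrant/macromolecule in the cell."""

    heats: Tuple[float, ...]
    molar_ratios: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.heats) != len(self.molar_ratios):
            raise ValueError("heats and molar ratios must have equal length")


def _bound_concentration(m_total: float, x_total: float, n: float, kd: float) -> float:
    """Complex concentration from the one-site quadratic (per monomer sites)."""
    sites = n * m_total
    b = x_total + sites + kd
    disc = b * b - 4.0 * sites * x_total
    return 0.5 * (b - math.sqrt(max(disc, 0.0)))


def _model_heats(
    proto: TitrationProtocol, n: float, kd: float, dh: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Noiseless per-injection heats and molar ratios under the model."""
    v0 = proto.cell_volume
    m = proto.cell_concentration
    x = 0.0
    bound_prev = 0.0
    heats = np.empty(proto.n_injections)
    ratios = np.empty(proto.n_injections)
    for i, dv in enumerate(proto.injection_volumes):
        f = 1.0 - dv / v0  # displacement dilution
        m *= f
        x = x * f + proto.syringe_concentration * dv / v0
        bound = _bound_concentration(m, x, n, kd)
        moles_injected = proto.syringe_concentration * dv
        dq = v0 * dh * (bound - bound_prev * f)
        heats[i] = dq / moles_injected
        ratios[i] = x / m
        bound_prev = bound
    return heats, ratios


def simulate_isotherm(
    proto: TitrationProtocol,
    n: float,
    kd: float,
    dh: float,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> Isotherm:
    """Simulate a titration under the one-site model.

    ``noise_sd`` is the Gaussian standard deviation added to each normalized
    heat (kcal/mol of injectant), seeded for reproducibility.
    """
    if n <= 0 or kd <= 0:
        raise ValueError("stoichiometry and Kd must be positive")
    heats, ratios = _model_heats(proto, n, kd, dh)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.size)
    return Isotherm(tuple(heats.tolist()), tuple(ratios.tolist()))


@dataclass(frozen=True)
class BindingFit:
    """Fitted one-site parameters with derived thermodynamics."""

    n: float
    kd: float  # mol/L
    dh: float  # kcal/mol
    dg: float  # kcal/mol
    minus_tds: float  # kcal/mol
    rss: float
    temperature: float

    @property
    def kd_uM(self) -> float:
        return self.kd * 1e6


class FitFailure(RuntimeError):
    """Raised when no start converges or the isotherm is uninformative."""

    def __init__(self, message: str, residuals: Optional[np.ndarray] = None):
        super().__init__(message)
        self.residuals = residuals


def thermodynamics(kd: float, temperature: float, dh: float = 0.0) -> Tuple[float, float]:
    """(dG, -T*dS) in kcal/mol from Kd (mol/L, standard state 1 M)."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    dg = R_KCAL * temperature * math.log(kd)
    return dg, dg - dh


def fit_one_site(
    iso: Isotherm,
    proto: TitrationProtocol,
    starts: Optional[Sequence[Tuple[float, float, float]]] = None,
) -> BindingFit:
    """Nonlinear least squares for (n, Kd, dH) on per-injection heats.

    Multi-start over a coarse logarithmic Kd grid unless explicit starts are
    given; Kd is fitted on a log scale.  Raises :class:`FitFailure` for
    uninformative (flat) isotherms or when no start converges.
    """
    heats = np.asarray(iso.heats, dtype=float)
    if heats.size < 3:
        raise FitFailure("need at least three informative injections")
    scale = float(np.max(np.abs(heats)))
    if scale == 0.0 or np.ptp(heats) == 0.0:
        raise FitFailure("flat isotherm: binding parameters unidentifiable", residuals=heats)

    if starts is None:
        dh0 = heats[0]
        kd_grid = [1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3]
        starts = [(1.0, kd, dh0) for kd in kd_grid]

    def residuals(theta: np.ndarray) -> np.ndarray:
        n, log_kd, dh = theta
        model, _ = _model_heats(proto, n, 10.0 ** log_kd, dh)
        return model - heats

    best = None
    last_res = None
    for n0, kd0, dh0 in starts:
        try:
            sol = least_squares(
                residuals,
                x0=[n0, math.log10(kd0), dh0],
                bounds=([1e-3, -12.0, -np.inf], [100.0, 0.0, np.inf]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        last_res = sol.fun
        if not sol.success:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise FitFailure("no start converged", residuals=last_res)
    rss, (n_hat, log_kd_hat, dh_hat) = best
    kd_hat = 10.0 ** log_kd_hat
    dg, minus_tds = thermodynamics(kd_hat, proto.temperature, dh_hat)
    return BindingFit(
        n=float(n_hat),
        kd=float(kd_hat),
        dh=float(dh_hat),
        dg=dg,
        minus_tds=minus_tds,
        rss=rss,
        temperature=proto.temperature,
    )
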