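"""Excess area and excess Gibbs free energy of binary monolayers.

For a two-component film, ideal mixing predicts the mean molecular area
``A_id(pi) = x1 A1(pi) + x2 A2(pi)`` from the endmember isotherms.  The
departure ``A12 - x1 A1 - x2 A2`` integrated over surface pressure gives the
excess Gibbs free energy of mixing

    dG_exc(pi2) = N_A * int_0^pi2 (A12 - x1 A1 - x2 A2) dpi

with areas in Angstrom^2 and pi in mN/m; 1 Angstrom^2 * mN/m = 1e-23 J, so
dG_exc [J/mol] = 6.02214076 * I where I is the integral in those units.
Positive values indicate net repulsive interactions between the components
relative to the pure films; negative values indicate a stabilised mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlignmentError, RangeError, ValidationError
from .isotherm import Isotherm

__all__ = [
    "AVOGADRO",
    "GIBBS_UNIT",
    "AreaOfPressure",
    "ExcessEntry",
    "ExcessProfile",
    "resample_by_pressure",
    "excess_area",
    "excess_gibbs",
    "excess_profile",
]

AVOGADRO = 6.02214076e23  # 1/mol
# 1 A^2 * mN/m = 1e-20 m^2 * 1e-3 N/m = 1e-23 J; times N_A -> J/mol
GIBBS_UNIT = AVOGADRO * 1e-23  # = 6.02214076 J/mol per (A^2 mN/m)

DEFAULT_PRESSURES = (5.0, 10.0, 20.0, 25.0)


@dataclass
class AreaOfPressure:
    """Molecular area A(pi) interpolated onto a uniform pressure grid."""

    grid: np.ndarray  # increasing pi values, mN/m, starting at 0
    areas: np.ndarray  # A(pi), Angstrom^2

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        areas = np.asarray(self.areas, dtype=float)
        if grid.ndim != 1 or grid.size != areas.size:
            raise ValidationError("grid and areas must be 1-D arrays of equal length")
        if np.any(np.diff(grid) <= 0.0):
            raise ValidationError("pressure grid must be strictly increasing")
        if np.any(areas <= 0.0):
            raise ValidationError("interpolated areas must be positive")
        self.grid = grid
        self.areas = areas


def _monotone_segment(iso: Isotherm) -> tuple[np.ndarray, np.ndarray]:
    """Strictly increasing pi prefix of the compression-ordered curve.

    Points are scanned in compression order up to the global pressure maximum;
    any point not exceeding the running maximum (noise dips) is dropped.
    """
    stop = int(np.argmax(iso.pressure)) + 1
    p = iso.pressure[:stop]
    a = iso.area[:stop]
    keep = np.empty(p.size, dtype=bool)
    running = -np.inf
    for i, v in enumerate(p):
        keep[i] = v > running
        if keep[i]:
            running = v
    return p[keep], a[keep]


def resample_by_pressure(
    iso: Isotherm,
    pi_max: float,
    step: float = 0.1,
    max_extension: float = 1.0,
) -> AreaOfPressure:
    """Interpolate A(pi) on a uniform grid 0 .. ``pi_max`` (step ``step``).

    Uses the strictly increasing (pre-collapse) segment of the isotherm with
    linear interpolation.  Extrapolation above the achievable maximum is
    refused; a curve that does not quite reach pi = 0 is linearly extended
    from its two lowest-pressure points over a gap of at most
    ``max_extension`` mN/m.
    """
    if step <= 0:
        raise ValidationError("step must be positive")
    p, a = _monotone_segment(iso)
    if p.size < 2:
        raise ValidationError("no usable monotone segment")
    achievable = float(p[-1])
    if pi_max > achievable + 1e-9:
        raise RangeError(
            f"pi_max = {pi_max} mN/m beyond achievable maximum {achievable:.3f} mN/m"
        )
    if p[0] > 0.0:
        if p[0] > max_extension:
            raise RangeError(
                f"lowest pressure {p[0]:.3f} mN/m too far above 0 to extend "
                f"(limit {max_extension} mN/m)"
            )
        # linear extension from the two lowest-pressure points down to pi = 0
        slope = (a[1] - a[0]) / (p[1] - p[0])
        a0 = a[0] - slope * p[0]
        p = np.concatenate(([0.0], p))
        a = np.concatenate(([a0], a))
    n = int(round(pi_max / step))
    grid = np.linspace(0.0, pi_max, n + 1)
    areas = np.interp(grid, p, a)
    return AreaOfPressure(grid=grid, areas=areas)


def _check_aligned(*curves: AreaOfPressure) -> None:
    ref = curves[0].grid
    for c in curves[1:]:
        if c.grid.size != ref.size or not np.allclose(c.grid, ref, atol=1e-9):
            raise AlignmentError("pressure grids do not match")


def _grid_index(grid: np.ndarray, pi: float) -> int:
    idx = int(np.argmin(np.abs(grid - pi)))
    if abs(grid[idx] - pi) > 1e-6 + 1e-9 * abs(pi):
        raise RangeError(f"pi = {pi} mN/m is not on the resampled grid")
    return idx


def excess_area(
    mix: AreaOfPressure,
    end1: AreaOfPressure,
    end2: AreaOfPressure,
    x1: float,
    at_pi: float,
) -> float:
    """Excess molecular area A12 - x1 A1 - (1-x1) A2 at one pressure, Angstrom^2."""
    if not (0.0 <= x1 <= 1.0):
        raise ValidationError(f"x1 = {x1} not in [0, 1]")
    _check_aligned(mix, end1, end2)
    i = _grid_index(mix.grid, at_pi)
    return float(mix.areas[i] - x1 * end1.areas[i] - (1.0 - x1) * end2.areas[i])


def excess_gibbs(
    mix: AreaOfPressure,
    end1: AreaOfPressure,
    end2: AreaOfPressure,
    x1: float,
    pi2: float,
) -> float:
    """Excess Gibbs free energy of mixing up to ``pi2``, J/mol.

    Trapezoidal integration of the excess area over [0, pi2] on the shared
    grid, converted with 1 A^2 mN/m = 1e-23 J and multiplied by N_A.
    """
    if not (0.0 <= x1 <= 1.0):
        raise ValidationError(f"x1 = {x1} not in [0, 1]")
    _check_aligned(mix, end1, end2)
    grid = mix.grid
    if pi2 < 0 or pi2 > grid[-1] + 1e-9:
        raise RangeError(f"pi2 = {pi2} outside integration grid [0, {grid[-1]}]")
    integrand = mix.areas - x1 * end1.areas - (1.0 - x1) * end2.areas
    mask = grid <= pi2 + 1e-12
    x = grid[mask]
    y = integrand[mask]
    if x.size == 0 or x[-1] < pi2 - 1e-9:
        # pi2 between grid points: append the interpolated endpoint
        y_end = np.interp(pi2, grid, integrand)
        x = np.concatenate((x, [pi2]))
        y = np.concatenate((y, [y_end]))
    integral = float(np.trapezoid(y, x))  # A^2 mN/m
    return GIBBS_UNIT * integral


@dataclass(frozen=True)
class ExcessEntry:
    pi: float  # mN/m
    excess_area: float  # Angstrom^2
    delta_g_exc: float  # J/mol
    interaction: str  # "repulsive" | "attractive" | "ideal"


@dataclass
class ExcessProfile:
    """Excess mixing quantities of one binary film at several target pressures."""

    x1: float
    entries: list[ExcessEntry]

    @property
    def x2(self) -> float:
        return 1.0 - self.x1

    def to_dict(self) -> dict:
        return {
            "x1": self.x1,
            "x2": self.x2,
            "entries": [
                {
                    "pi_mN_m": e.pi,
                    "excess_area_A2": e.excess_area,
                    "delta_G_exc_J_mol": e.delta_g_exc,
                    "interaction": e.interaction,
                }
                for e in self.entries
            ],
        }


def _classify(value: float, tol: float = 1e-9) -> str:
    if value > tol:
        return "repulsive"
    if value < -tol:
        return "attractive"
    return "ideal"


def excess_profile(
    mix: AreaOfPressure,
    end1: AreaOfPressure,
    end2: AreaOfPressure,
    x1: float,
    pressures: Sequence[float] = DEFAULT_PRESSURES,
) -> ExcessProfile:
    """Excess area and dG_exc at each requested pressure.

    A positive dG_exc flags net repulsive component interactions (less stable
    than the pure films); negative flags a stabilised, attractive mixture.
    """
    if len(pressures) == 0:
        raise ValidationError("at least one target pressure required")
    entries = []
    for pi in sorted(float(p) for p in pressures):
        dg = excess_gibbs(mix, end1, end2, x1, pi)
        ea = excess_area(mix, end1, end2, x1, pi)
        entries.append(
            ExcessEntry(pi=pi, excess_area=ea, delta_g_exc=dg, interaction=_classify(dg))
        )
    return ExcessProfile(x1=x1, entries=entries)
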