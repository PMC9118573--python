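"""Synthetic datasets with exact ground truth for every analysis stage.

Each generator is the right inverse of its analyzer in the noiseless limit:

* :func:`generate_isotherm` builds a pi-A curve from known A_lim, collapse
  pressure, optional LE/LC plateau and condensed-branch slope, so feature
  extraction can be scored against the requested truth;
* :func:`generate_mixture` composes a binary film from two endmembers plus a
  controlled excess-area function with a closed-form (or fine-grid) excess
  Gibbs energy;
* :func:`generate_epr_series` inverts the order-parameter formula to produce
  hyperfine splittings realising a requested S(T) profile;
* :func:`generate_mobility` inverts the Smoluchowski relation to produce
  mobilities realising a requested zeta potential.

All randomness flows from one explicit seed; equal seeds give byte-identical
output.  Noise models are Gaussian: on pi for isotherms, on each splitting
for EPR, and on zeta for mobilities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .electrokinetics import EPS0, MOBILITY_UNIT, MobilityRecord, water_properties
from .epr import ORDER_PREFACTOR, SplittingRecord
from .errors import ValidationError
from .isotherm import Composition, Isotherm
from .mixing import GIBBS_UNIT, resample_by_pressure
from .presets import ISOTHERM_PRESETS

__all__ = [
    "PlateauSpec",
    "IsothermSpec",
    "ExcessFn",
    "MixtureSpec",
    "SyntheticGroundTruth",
    "generate_isotherm",
    "generate_mixture",
    "generate_epr_series",
    "generate_mobility",
    "isotherm_preset",
    "true_excess_gibbs",
]


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """The *_true parameters behind a generated dataset, serialisable as JSON."""

    kind: str
    values: dict

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "values": self.values}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticGroundTruth":
        obj = json.loads(text)
        return cls(kind=obj["kind"], values=obj["values"])

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


# --------------------------------------------------------------------------- #
# isotherms


@dataclass(frozen=True)
class PlateauSpec:
    """An LE/LC coexistence plateau: near-flat segment at ``pi_plateau``.

    The segment has width ``width`` (Angstrom^2), a small residual slope
    (|dpi/dA| in mN/m per A^2, so the plateau is not perfectly horizontal)
    and a cubic bow controlled by ``curvature`` that makes the modulus
    minimum land at the segment centre, where pi equals ``pi_plateau``.
    """

    pi_plateau: float
    width: float = 8.0
    residual_slope: float = 0.05
    curvature: float = 0.02

    @property
    def half_rise(self) -> float:
        """Pressure gain from the plateau centre to either edge."""
        h = self.width / 2.0
        return self.residual_slope * h + (self.curvature / 3.0) * h**3


@dataclass(frozen=True)
class IsothermSpec:
    """Generator parameters for one synthetic compression isotherm.

    The curve is a C0 piecewise construction in the (A, pi) plane, sampled on
    a uniform area grid (compression direction):

    * liquid-expanded tail: exponential pressure rise with decay scale
      ``tail_decay`` (auto-chosen so the tail is softer than the condensed
      branch when not given), joining the next segment at its lowest pressure;
    * optional plateau segment (see :class:`PlateauSpec`);
    * affine condensed branch A = A_lim_true - pi / s_c, which makes the
      tangent construction of the limiting area exact;
    * post-collapse branch with dpi/dA = ``post_slope`` >= 0, so pressure
      stops increasing at the collapse point.

    Gaussian noise of standard deviation ``sigma_pi`` (mN/m) is added to pi.
    """

    a_lim_true: float
    s_c: float  # condensed-branch slope |dpi/dA|, mN/m per A^2
    pi_coll_true: float
    plateau: PlateauSpec | None = None
    onset_pressure: float = 5.0  # tail/condensed join pressure when no plateau
    tail_decay: float | None = None  # Angstrom^2; None -> auto
    tail_span_decays: float = 4.0  # tail length in units of the decay scale
    post_slope: float = 0.3  # mN/m per A^2, >= 0
    post_span: float = 6.0  # Angstrom^2 beyond collapse
    sigma_pi: float = 0.0
    n_points: int = 1000
    seed: int = 0
    temperature: float = 20.0
    label: str = "synthetic"
    composition: Composition | None = None

    def __post_init__(self) -> None:
        if self.a_lim_true <= 0 or self.s_c <= 0:
            raise ValidationError("A_lim_true and s_c must be positive")
        if self.pi_coll_true <= 0:
            raise ValidationError("pi_coll_true must be positive")
        if self.post_slope < 0:
            raise ValidationError("post-collapse slope must be >= 0")
        if self.sigma_pi < 0:
            raise ValidationError("sigma_pi must be >= 0")
        if self.n_points < 10:
            raise ValidationError("need at least 10 grid points")
        if self.plateau is not None:
            pl = self.plateau
            if not (0.0 < pl.pi_plateau < self.pi_coll_true):
                raise ValidationError(
                    f"plateau pressure {pl.pi_plateau} must lie strictly between 0 "
                    f"and the collapse pressure {self.pi_coll_true}"
                )
            if pl.pi_plateau - pl.half_rise <= 0:
                raise ValidationError("plateau bottom pressure must stay positive")
            if pl.pi_plateau + pl.half_rise >= self.pi_coll_true:
                raise ValidationError("plateau top pressure must stay below collapse")
        elif not (0.0 < self.onset_pressure < self.pi_coll_true):
            raise ValidationError("onset pressure must lie between 0 and collapse")

    # geometry helpers -------------------------------------------------------
    @property
    def join_pressure(self) -> float:
        """Pressure where the LE tail meets the plateau (or condensed branch)."""
        if self.plateau is not None:
            return self.plateau.pi_plateau - self.plateau.half_rise
        return self.onset_pressure

    @property
    def branch_top_pressure(self) -> float:
        """Pressure at the upper (large-A) end of the condensed branch."""
        if self.plateau is not None:
            return self.plateau.pi_plateau + self.plateau.half_rise
        return self.onset_pressure

    @property
    def branch_top_area(self) -> float:
        return self.a_lim_true - self.branch_top_pressure / self.s_c

    @property
    def join_area(self) -> float:
        """Area where the LE tail ends (plateau outer edge or branch top)."""
        if self.plateau is not None:
            return self.branch_top_area + self.plateau.width
        return self.branch_top_area

    @property
    def collapse_area(self) -> float:
        return self.a_lim_true - self.pi_coll_true / self.s_c

    @property
    def decay(self) -> float:
        if self.tail_decay is not None:
            return self.tail_decay
        # keep the tail softer than the condensed branch: slope at the join
        # is join_pressure / decay, targeted at 0.6 * s_c
        return max(self.join_pressure / (0.6 * self.s_c), 4.0)

    @property
    def cs_inv_max_true(self) -> float:
        """Modulus at the condensed-branch top, s_c * A: the curve's maximum."""
        return self.s_c * self.branch_top_area


def _spec_pressure(spec: IsothermSpec, area: np.ndarray) -> np.ndarray:
    """Noiseless pi(A) of the piecewise construction."""
    a_join = spec.join_area
    a_top = spec.branch_top_area
    a_coll = spec.collapse_area
    p = np.empty_like(area)

    tail = area >= a_join
    p[tail] = spec.join_pressure * np.exp(-(area[tail] - a_join) / spec.decay)

    if spec.plateau is not None:
        pl = spec.plateau
        centre = a_top + pl.width / 2.0
        mid = (area < a_join) & (area >= a_top)
        d = area[mid] - centre
        p[mid] = pl.pi_plateau - (pl.residual_slope * d + (pl.curvature / 3.0) * d**3)

    cond = (area < a_top) & (area >= a_coll)
    p[cond] = spec.s_c * (spec.a_lim_true - area[cond])

    post = area < a_coll
    p[post] = spec.pi_coll_true + spec.post_slope * (area[post] - a_coll)
    return p


def generate_isotherm(spec: IsothermSpec) -> tuple[Isotherm, SyntheticGroundTruth]:
    """Sample the spec's curve on a uniform area grid and attach ground truth."""
    if spec.collapse_area <= 0:
        raise ValidationError(
            f"collapse area {spec.collapse_area:.2f} A^2 not positive; "
            "A_lim_true, s_c and pi_coll_true are inconsistent"
        )
    a_max = spec.join_area + spec.tail_span_decays * spec.decay
    a_min = spec.collapse_area - spec.post_span
    if a_min <= 0:
        raise ValidationError("post-collapse span extends below zero area")
    area = np.linspace(a_max, a_min, spec.n_points)
    pressure = _spec_pressure(spec, area)
    if spec.sigma_pi > 0:
        rng = np.random.default_rng(spec.seed)
        pressure = pressure + rng.normal(0.0, spec.sigma_pi, size=pressure.size)
    iso = Isotherm(
        area=area,
        pressure=pressure,
        temperature=spec.temperature,
        composition=spec.composition,
        label=spec.label,
        replicate_id=spec.seed,
    )
    truth = SyntheticGroundTruth(
        kind="isotherm",
        values={
            "A_lim_true": spec.a_lim_true,
            "pi_coll_true": spec.pi_coll_true,
            "pi_plateau_true": None if spec.plateau is None else spec.plateau.pi_plateau,
            "cs_inv_max_true": spec.cs_inv_max_true,
            "s_c": spec.s_c,
            "sigma_pi": spec.sigma_pi,
            "seed": spec.seed,
        },
    )
    return iso, truth


def isotherm_preset(
    name: str,
    sigma_pi: float = 0.0,
    n_points: int = 1000,
    seed: int = 0,
) -> IsothermSpec:
    """An :class:`IsothermSpec` parameterised from a named published system."""
    try:
        a_lim, pi_coll, pi_plateau, cs_max, temperature = ISOTHERM_PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {sorted(ISOTHERM_PRESETS)}"
        ) from None
    plateau = None if pi_plateau is None else PlateauSpec(pi_plateau=pi_plateau)
    # invert cs_inv_max_true = s_c * A_lim - branch_top_pressure for s_c
    top = plateau.pi_plateau + plateau.half_rise if plateau else 5.0
    s_c = (cs_max + top) / a_lim
    return IsothermSpec(
        a_lim_true=a_lim,
        s_c=s_c,
        pi_coll_true=pi_coll,
        plateau=plateau,
        sigma_pi=sigma_pi,
        n_points=n_points,
        seed=seed,
        temperature=temperature,
        label=name,
    )


# --------------------------------------------------------------------------- #
# binary mixtures


@dataclass(frozen=True)
class ExcessFn:
    """Named excess-area function f(pi) added to the ideal-mixing area.

    Forms: ``zero``; ``constant`` (f = amplitude, Angstrom^2); ``half_sine``
    (f = amplitude * sin(pi_rad * p / pi_max), one half-period over
    [0, pi_max]).
    """

    kind: str = "zero"
    amplitude: float = 0.0
    pi_max: float = 25.0

    def __post_init__(self) -> None:
        if self.kind not in ("zero", "constant", "half_sine"):
            raise ValidationError(f"unknown excess function kind {self.kind!r}")

    def __call__(self, pressures: np.ndarray) -> np.ndarray:
        p = np.asarray(pressures, dtype=float)
        if self.kind == "zero":
            return np.zeros_like(p)
        if self.kind == "constant":
            return np.full_like(p, self.amplitude)
        return self.amplitude * np.sin(math.pi * p / self.pi_max)


def true_excess_gibbs(fn: ExcessFn, pi2: float, n_fine: int = 100_000) -> float:
    """Ground-truth dG_exc for an excess-area function, J/mol.

    Closed form for the zero and constant forms (N_A * c * pi2 with the
    Angstrom^2-mN/m to J conversion); midpoint Riemann sum on a fine grid for
    the half-sine form.
    """
    if fn.kind == "zero":
        return 0.0
    if fn.kind == "constant":
        return GIBBS_UNIT * fn.amplitude * pi2
    edges = np.linspace(0.0, pi2, n_fine + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    return GIBBS_UNIT * float(np.sum(fn(mid)) * (pi2 / n_fine))


@dataclass(frozen=True)
class MixtureSpec:
    """A binary film composed from two endmembers plus an excess-area function."""

    end1: IsothermSpec | Isotherm
    end2: IsothermSpec | Isotherm
    x1: float
    excess_fn: ExcessFn = field(default_factory=ExcessFn)
    pi_max: float | None = None  # common grid upper bound; None -> auto
    step: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.x1 <= 1.0):
            raise ValidationError(f"x1 = {self.x1} not in [0, 1]")


def _endmember_isotherm(end) -> Isotherm:
    if isinstance(end, Isotherm):
        return end
    iso, _ = generate_isotherm(end)
    return iso


def generate_mixture(
    spec: MixtureSpec,
) -> tuple[Isotherm, tuple[Isotherm, Isotherm], SyntheticGroundTruth]:
    """Compose A12(pi) = x1 A1 + x2 A2 + f(pi) on the common pre-collapse range.

    Returns the mixture isotherm, the two endmember isotherms, and ground
    truth carrying the excess function (hence the true dG_exc at any pi2 via
    :func:`true_excess_gibbs`).
    """
    iso1 = _endmember_isotherm(spec.end1)
    iso2 = _endmember_isotherm(spec.end2)
    if spec.pi_max is not None:
        pi_max = spec.pi_max
    else:
        pi_max = min(iso1.pressure.max(), iso2.pressure.max()) - 1.0
        pi_max = math.floor(pi_max / spec.step) * spec.step
    a1 = resample_by_pressure(iso1, pi_max, spec.step)
    a2 = resample_by_pressure(iso2, pi_max, spec.step)
    fn = spec.excess_fn
    if fn.kind == "half_sine" and abs(fn.pi_max - pi_max) > 1e-9:
        fn = ExcessFn(kind="half_sine", amplitude=fn.amplitude, pi_max=pi_max)
    areas = spec.x1 * a1.areas + (1.0 - spec.x1) * a2.areas + fn(a1.grid)
    if np.any(areas <= 0.0):
        raise ValidationError("excess function drives the mixture area non-positive")
    if np.any(np.diff(areas) >= 0.0):
        raise ValidationError("mixture area must decrease strictly with pressure")
    mixture = Isotherm(
        area=areas,
        pressure=a1.grid,
        temperature=iso1.temperature,
        label=f"mixture(x1={spec.x1})",
    )
    truth = SyntheticGroundTruth(
        kind="mixture",
        values={
            "x1": spec.x1,
            "pi_max": pi_max,
            "excess_fn": {
                "kind": fn.kind,
                "amplitude": fn.amplitude,
                "pi_max": fn.pi_max,
            },
            "delta_g_exc_true_at_pi_max": true_excess_gibbs(fn, pi_max),
        },
    )
    return mixture, (iso1, iso2), truth


# --------------------------------------------------------------------------- #
# EPR splittings


def generate_epr_series(
    s_profile: dict[float, float],
    a0_target: float = 15.0,
    sigma: float = 0.0,
    n_per_temperature: int = 3,
    seed: int = 0,
) -> tuple[list[SplittingRecord], SyntheticGroundTruth]:
    """Hyperfine splittings realising a requested S(T) profile.

    Inverts the order-parameter formula: with d = S * a0 / 0.5407 the pair
    A'par = a0 + 2d/3, A'perp = a0 - d/3 has isotropic splitting exactly
    ``a0_target`` and order parameter exactly ``S``.  Gaussian noise of
    standard deviation ``sigma`` (gauss) is added to each splitting.
    """
    if not s_profile:
        raise ValidationError("empty S profile")
    if a0_target <= 0:
        raise ValidationError("a0_target must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for temperature in sorted(s_profile):
        s_true = s_profile[temperature]
        if abs(s_true) >= 1.0:
            raise ValidationError(f"|S_true| = {abs(s_true)} must be < 1")
        d = s_true * a0_target / ORDER_PREFACTOR
        a_par = a0_target + 2.0 * d / 3.0
        a_perp = a0_target - d / 3.0
        if a_par <= 0 or a_perp <= 0:
            raise ValidationError(
                f"S_true = {s_true} at a0 = {a0_target} G gives a non-positive splitting"
            )
        for rep in range(n_per_temperature):
            records.append(
                SplittingRecord(
                    temperature=temperature,
                    a_par=a_par + (rng.normal(0.0, sigma) if sigma > 0 else 0.0),
                    a_perp=a_perp + (rng.normal(0.0, sigma) if sigma > 0 else 0.0),
                    replicate_id=rep,
                )
            )
    truth = SyntheticGroundTruth(
        kind="epr",
        values={
            "S_true": {str(t): s for t, s in sorted(s_profile.items())},
            "a0_true": a0_target,
            "sigma": sigma,
            "seed": seed,
        },
    )
    return records, truth


# --------------------------------------------------------------------------- #
# electrophoretic mobilities


def generate_mobility(
    zeta_true_mv: float,
    temperature: float = 20.0,
    n: int = 10,
    sigma_mv: float = 2.0,
    seed: int = 0,
    sample: str = "sample",
) -> tuple[list[MobilityRecord], SyntheticGroundTruth]:
    """Mobility records realising a requested zeta potential.

    Noise is applied in zeta space (where the instrument's replicate scatter
    lives) and inverted through the Smoluchowski relation,
    mu = zeta * eps0 * eps_r / eta, expressed in instrument units.
    """
    if n < 1:
        raise ValidationError("need at least one replicate")
    medium = water_properties(temperature)
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(n):
        zeta_mv = zeta_true_mv + (rng.normal(0.0, sigma_mv) if sigma_mv > 0 else 0.0)
        mu_si = (zeta_mv * 1e-3) * EPS0 * medium.eps_r / medium.viscosity
        records.append(
            MobilityRecord(
                sample=sample,
                temperature=temperature,
                mobility=mu_si / MOBILITY_UNIT,
                replicate_id=rep,
            )
        )
    truth = SyntheticGroundTruth(
        kind="zeta",
        values={
            "zeta_true_mV": zeta_true_mv,
            "temperature_C": temperature,
            "sigma_mV": sigma_mv,
            "n": n,
            "seed": seed,
        },
    )
    return records, truth
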