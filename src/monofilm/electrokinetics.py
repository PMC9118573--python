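"""Zeta potential of liposome suspensions via the Smoluchowski relation.

An electrophoretic-mobility instrument (Zetasizer convention) reports
mobilities mu in micrometre-centimetre per volt-second; 1 instrument unit is
1e-8 m^2 V^-1 s^-1.  In the thin-double-layer (Smoluchowski) limit the
electrokinetic potential at the slip plane is

    zeta = eta * mu / (eps0 * eps_r)

with eta the medium viscosity (Pa s), eps_r its relative permittivity and
eps0 the vacuum permittivity.  No Henry-function or relaxation corrections
are applied.  Replicate measurements are summarised as mean +/- SE per
sample, mirroring the layout of a zeta-potential results table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, ValidationError
from .reporting import replicate_summary

__all__ = [
    "EPS0",
    "MOBILITY_UNIT",
    "WATER_TABLE",
    "MobilityRecord",
    "MediumProperties",
    "ZetaSummary",
    "water_properties",
    "zeta_smoluchowski",
    "summarize_zeta",
    "read_mobilities",
    "write_zeta_summaries",
]

EPS0 = 8.8541878128e-12  # F/m
MOBILITY_UNIT = 1e-8  # m^2 V^-1 s^-1 per instrument unit (um cm / V s)
MOBILITY_SANITY_BOUND = 20.0  # instrument units

# Handbook water properties: temperature C -> (viscosity mPa s, relative permittivity)
WATER_TABLE: dict[float, tuple[float, float]] = {
    5.0: (1.5182, 85.90),
    10.0: (1.3059, 83.96),
    15.0: (1.1375, 82.06),
    20.0: (1.0016, 80.18),
    25.0: (0.8900, 78.36),
    30.0: (0.7972, 76.58),
}


@dataclass(frozen=True)
class MobilityRecord:
    """One electrophoretic mobility measurement, instrument units."""

    sample: str
    temperature: float  # degrees C
    mobility: float  # um cm / V s  (1 unit = 1e-8 m^2/V/s)
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if abs(self.mobility) >= MOBILITY_SANITY_BOUND:
            raise ValidationError(
                f"|mobility| = {abs(self.mobility)} exceeds sanity bound "
                f"{MOBILITY_SANITY_BOUND} instrument units"
            )


@dataclass(frozen=True)
class MediumProperties:
    """Viscosity and permittivity of the suspending medium."""

    viscosity: float  # Pa s
    eps_r: float  # dimensionless

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise DomainError("viscosity must be positive")
        if not (1.0 <= self.eps_r <= 100.0):
            raise DomainError(f"relative permittivity {self.eps_r} outside [1, 100]")


@dataclass(frozen=True)
class ZetaSummary:
    sample: str
    zeta_mv: float
    se_mv: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.se_mv < 0:
            raise ValidationError("SE must be non-negative")


def water_properties(
    temperature: float, table: dict[float, tuple[float, float]] | None = None
) -> MediumProperties:
    """Water viscosity and permittivity at ``temperature`` by linear interpolation.

    Built-in handbook values at 5, 10, 15, 20, 25, 30 C; a custom ``table``
    (same shape) overrides them.  Valid for 0 < T < 60 C; outside the table
    span the two nearest nodes are extrapolated linearly.
    """
    if not (0.0 < temperature < 60.0):
        raise DomainError(f"temperature {temperature} C outside supported range (0, 60)")
    tab = WATER_TABLE if table is None else table
    temps = np.array(sorted(tab))
    eta = np.array([tab[t][0] for t in temps])
    eps = np.array([tab[t][1] for t in temps])

    def _interp(values: np.ndarray) -> float:
        if temperature <= temps[0]:
            i = 0
        elif temperature >= temps[-1]:
            i = temps.size - 2
        else:
            i = int(np.searchsorted(temps, temperature) - 1)
        t0, t1 = temps[i], temps[i + 1]
        w = (temperature - t0) / (t1 - t0)
        return float(values[i] * (1 - w) + values[i + 1] * w)

    return MediumProperties(viscosity=_interp(eta) * 1e-3, eps_r=_interp(eps))


def zeta_smoluchowski(mobility: float, medium: MediumProperties) -> float:
    """zeta = eta * mu / (eps0 * eps_r), returned in mV; sign preserved."""
    mu_si = mobility * MOBILITY_UNIT
    zeta_v = medium.viscosity * mu_si / (EPS0 * medium.eps_r)
    return zeta_v * 1e3


def summarize_zeta(
    records: list[MobilityRecord],
    medium: MediumProperties | dict[float, MediumProperties] | None = None,
) -> list[ZetaSummary]:
    """Per-sample mean +/- SE of converted zeta potentials.

    ``medium`` may be a single :class:`MediumProperties`, a mapping from
    temperature to properties, or None to use :func:`water_properties` at
    each record's temperature.  Samples appear in order of first occurrence.
    """
    if not records:
        raise ValidationError("no mobility records supplied")

    def _medium_for(temperature: float) -> MediumProperties:
        if medium is None:
            return water_properties(temperature)
        if isinstance(medium, MediumProperties):
            return medium
        try:
            return medium[temperature]
        except KeyError as exc:
            raise DomainError(f"no medium properties for T = {temperature} C") from exc

    by_sample: dict[str, list[float]] = {}
    for r in records:
        z = zeta_smoluchowski(r.mobility, _medium_for(r.temperature))
        by_sample.setdefault(r.sample, []).append(z)
    out = []
    for sample, zetas in by_sample.items():
        mean, se, n = replicate_summary(zetas)
        out.append(ZetaSummary(sample=sample, zeta_mv=mean, se_mv=se, n=n))
    return out


# --------------------------------------------------------------------------- #
# CSV I/O: header sample,temperature_C,mobility_um_cm_per_V_s,replicate_id

_COLUMNS = ["sample", "temperature_C", "mobility_um_cm_per_V_s"]


def read_mobilities(source) -> list[MobilityRecord]:
    frame = pd.read_csv(source if hasattr(source, "read") else Path(source))
    for col in _COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"missing required column {col!r}")
    if "replicate_id" not in frame.columns:
        frame["replicate_id"] = 0
    return [
        MobilityRecord(
            sample=str(row.sample),
            temperature=float(row.temperature_C),
            mobility=float(row.mobility_um_cm_per_V_s),
            replicate_id=int(row.replicate_id),
        )
        for row in frame.itertuples()
    ]


def write_mobilities(records: list[MobilityRecord], dest) -> None:
    pd.DataFrame(
        {
            "sample": [r.sample for r in records],
            "temperature_C": [r.temperature for r in records],
            "mobility_um_cm_per_V_s": [r.mobility for r in records],
            "replicate_id": [r.replicate_id for r in records],
        }
    ).to_csv(dest, index=False)


def write_zeta_summaries(summaries: list[ZetaSummary], dest) -> None:
    pd.DataFrame(
        {
            "sample": [s.sample for s in summaries],
            "zeta_mV": [s.zeta_mv for s in summaries],
            "se_mV": [s.se_mv for s in summaries],
            "n": [s.n for s in summaries],
        }
    ).to_csv(dest, index=False)
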