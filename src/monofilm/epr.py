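"""Order parameter of a nitroxide spin probe from EPR hyperfine splittings.

A doxyl stearic acid probe (here 16-SASL, reporting on the hydrophobic core
of the bilayer) gives an EPR spectrum whose outer and inner hyperfine
splittings A'par and A'perp (gauss) measure the residual anisotropy of the
nitroxide hyperfine tensor.  The order parameter

    S = 0.5407 (A'par - A'perp) / a0,      a0 = (A'par + 2 A'perp) / 3

is 0 for isotropic motion (maximum disorder) and approaches 1 for a fully
ordered acyl-chain environment.  The 0.5407 prefactor encodes the anisotropy
of the nitroxide hyperfine tensor and is used as a fixed constant.

Raw spectra are out of scope; splittings are taken as inputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, ValidationError
from .reporting import replicate_summary

__all__ = [
    "ORDER_PREFACTOR",
    "SplittingRecord",
    "OrderRecord",
    "isotropic_splitting",
    "order_parameter",
    "order_series",
    "read_splittings",
    "write_order_series",
]

ORDER_PREFACTOR = 0.5407


@dataclass(frozen=True)
class SplittingRecord:
    """Hyperfine splittings of one spectrum: A'par (outer), A'perp (inner), gauss."""

    temperature: float  # degrees C
    a_par: float
    a_perp: float
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.a_par <= 0 or self.a_perp <= 0:
            raise DomainError("hyperfine splittings must be positive")
        if not (0.0 <= self.temperature <= 60.0):
            raise DomainError(
                f"temperature {self.temperature} C outside instrument range 0-60 C"
            )


@dataclass(frozen=True)
class OrderRecord:
    """Per-temperature order parameter summary across replicates."""

    temperature: float
    a0: float  # mean isotropic splitting, gauss
    s: float  # mean order parameter
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise DomainError("a0 must be positive")
        if abs(self.s) > 1.05:
            raise ValidationError(f"|S| = {abs(self.s):.3f} exceeds physical bound 1.05")


def isotropic_splitting(a_par: float, a_perp: float) -> float:
    """a0 = (A'par + 2 A'perp) / 3, gauss."""
    if a_par <= 0 or a_perp <= 0:
        raise DomainError("hyperfine splittings must be positive")
    return (a_par + 2.0 * a_perp) / 3.0


def order_parameter(a_par: float, a_perp: float) -> float:
    """S = 0.5407 (A'par - A'perp) / a0; 0 = isotropic, 1 = maximal order."""
    a0 = isotropic_splitting(a_par, a_perp)
    return ORDER_PREFACTOR * (a_par - a_perp) / a0


def order_series(records: list[SplittingRecord]) -> list[OrderRecord]:
    """Per-temperature mean +/- SE of S, temperatures sorted ascending.

    S is computed per replicate, then summarised; SE is the sample standard
    deviation over sqrt(n), zero for a single replicate.
    """
    if not records:
        raise ValidationError("no splitting records supplied")
    by_t: dict[float, list[SplittingRecord]] = {}
    for r in records:
        by_t.setdefault(r.temperature, []).append(r)
    out = []
    for t in sorted(by_t):
        group = by_t[t]
        s_vals = [order_parameter(r.a_par, r.a_perp) for r in group]
        a0_vals = [isotropic_splitting(r.a_par, r.a_perp) for r in group]
        s_mean, se, n = replicate_summary(s_vals)
        out.append(
            OrderRecord(
                temperature=t,
                a0=float(np.mean(a0_vals)),
                s=s_mean,
                se=se,
                n=n,
            )
        )
    return out


# --------------------------------------------------------------------------- #
# CSV I/O: header temperature_C,A_par_G,A_perp_G,replicate_id

_COLUMNS = ["temperature_C", "A_par_G", "A_perp_G", "replicate_id"]


def read_splittings(source) -> list[SplittingRecord]:
    if hasattr(source, "read"):
        frame = pd.read_csv(source)
    else:
        frame = pd.read_csv(Path(source))
    for col in _COLUMNS[:3]:
        if col not in frame.columns:
            raise FormatError(f"missing required column {col!r}")
    if "replicate_id" not in frame.columns:
        frame["replicate_id"] = 0
    return [
        SplittingRecord(
            temperature=float(row.temperature_C),
            a_par=float(row.A_par_G),
            a_perp=float(row.A_perp_G),
            replicate_id=int(row.replicate_id),
        )
        for row in frame.itertuples()
    ]


def write_splittings(records: list[SplittingRecord], dest) -> None:
    frame = pd.DataFrame(
        {
            "temperature_C": [r.temperature for r in records],
            "A_par_G": [r.a_par for r in records],
            "A_perp_G": [r.a_perp for r in records],
            "replicate_id": [r.replicate_id for r in records],
        }
    )
    frame.to_csv(dest, index=False)


def write_order_series(series: list[OrderRecord], dest) -> None:
    frame = pd.DataFrame(
        {
            "temperature_C": [r.temperature for r in series],
            "a0_G": [r.a0 for r in series],
            "S": [r.s for r in series],
            "se": [r.se for r in series],
            "n": [r.n for r in series],
        }
    )
    frame.to_csv(dest, index=False)
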