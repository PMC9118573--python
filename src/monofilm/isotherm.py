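"""Langmuir pi-A isotherms: containers, CSV I/O, smoothing and feature extraction.

A surface-pressure/area isotherm records the surface pressure pi (mN/m) of a
spread film as a function of the mean area per molecule A (Angstrom^2) during
compression.  Four structural parameters summarise such a curve:

* ``A_lim`` -- limiting area per molecule: the tangent to the condensed branch,
  taken at the point of maximal compression modulus, extrapolated to pi = 0.
  For a film whose condensed branch is affine this is exact.
* ``pi_coll`` -- collapse pressure: the pressure at which the film fails and
  stops supporting further pressure increase.
* ``pi_plateau`` -- pressure of the LE/LC coexistence plateau (first-order
  liquid-expanded to liquid-condensed transition), when one exists.
* ``Cs^-1_max`` -- maximum of the compression modulus
  ``Cs^-1 = -dpi/dlnA = -A dpi/dA``, the in-plane stiffness of the film.

Units are fixed package-wide: A in Angstrom^2, pi in mN/m, Cs^-1 in mN/m.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import (
    DomainError,
    FormatError,
    ParameterError,
    ParseError,
    ValidationError,
)

__all__ = [
    "Composition",
    "Isotherm",
    "CompressionModulusCurve",
    "IsothermFeatures",
    "FeatureConfig",
    "CollapseResult",
    "PlateauResult",
    "read_isotherm",
    "write_isotherm",
    "smooth_isotherm",
    "compression_modulus",
    "detection_curve",
    "detect_collapse",
    "detect_plateau",
    "limiting_area",
    "extract_features",
    "features_to_frame",
]

MIN_POINTS = 10
MIN_PRESSURE = -0.5  # small negative baseline tolerated (mN/m)


# --------------------------------------------------------------------------- #
# containers


@dataclass(frozen=True)
class Composition:
    """Molar composition of a spread film.

    ``components`` maps component names to mole fractions over *all* spread
    molecules (lipid plus any steroid).  ``lipid_to_br_ratio`` records the
    lipid : brassinosteroid molar ratio of the preparation (4:1 by default).
    """

    components: tuple[tuple[str, float], ...]
    lipid_to_br_ratio: float = 4.0

    def __post_init__(self) -> None:
        fractions = [f for _, f in self.components]
        if not fractions:
            raise ValidationError("composition needs at least one component")
        for name, f in self.components:
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"mole fraction of {name!r} = {f} not in [0, 1]")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValidationError(f"mole fractions sum to {sum(fractions)}, not 1")

    @property
    def x_cs(self) -> float | None:
        """Mole fraction of castasterone within the CS/HCS sub-mixture, or None."""
        f = dict((name.upper(), frac) for name, frac in self.components)
        total_br = f.get("CS", 0.0) + f.get("HCS", 0.0)
        if total_br <= 0.0:
            return None
        return f.get("CS", 0.0) / total_br


@dataclass
class Isotherm:
    """A compression-ordered pi-A isotherm.

    Points are stored with strictly decreasing area (compression direction);
    input supplied in expansion order or shuffled is canonicalised by sorting.
    Duplicate abscissae are rejected.
    """

    area: np.ndarray
    pressure: np.ndarray
    temperature: float = 20.0
    composition: Composition | None = None
    label: str = ""
    replicate_id: int = 0

    def __post_init__(self) -> None:
        area = np.asarray(self.area, dtype=float)
        pressure = np.asarray(self.pressure, dtype=float)
        if area.ndim != 1 or pressure.ndim != 1 or area.size != pressure.size:
            raise ValidationError("area and pressure must be 1-D arrays of equal length")
        if area.size < MIN_POINTS:
            raise ValidationError(
                f"isotherm needs at least {MIN_POINTS} points, got {area.size}"
            )
        if not np.all(np.isfinite(area)) or not np.all(np.isfinite(pressure)):
            raise ValidationError("non-finite value in isotherm")
        order = np.argsort(-area, kind="stable")
        area = area[order]
        pressure = pressure[order]
        if np.any(np.diff(area) == 0.0):
            dup = area[np.nonzero(np.diff(area) == 0.0)[0][0]]
            raise ValidationError(f"duplicate abscissa: A = {dup} appears more than once")
        if np.any(area <= 0.0):
            raise ValidationError("all areas must be positive")
        if np.any(pressure < MIN_PRESSURE):
            raise ValidationError(
                f"surface pressure below tolerated baseline {MIN_PRESSURE} mN/m"
            )
        self.area = area
        self.pressure = pressure
        self.temperature = float(self.temperature)
        self.replicate_id = int(self.replicate_id)

    def __len__(self) -> int:
        return self.area.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Isotherm):
            return NotImplemented
        return (
            np.array_equal(self.area, other.area)
            and np.array_equal(self.pressure, other.pressure)
            and self.temperature == other.temperature
            and self.composition == other.composition
            and self.label == other.label
            and self.replicate_id == other.replicate_id
        )


@dataclass
class CompressionModulusCurve:
    """Compression modulus Cs^-1 = -A dpi/dA sampled along an isotherm."""

    pressure: np.ndarray
    area: np.ndarray
    cs_inv: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.cs_inv)):
            raise ValidationError("non-finite compression modulus")


@dataclass(frozen=True)
class CollapseResult:
    pi_coll: float
    index: int
    detected: bool


@dataclass(frozen=True)
class PlateauResult:
    pi_plateau: float
    span: tuple[int, int]  # inclusive index range of the modulus valley
    detected: bool


@dataclass(frozen=True)
class IsothermFeatures:
    """Structural parameters extracted from one isotherm."""

    a_lim: float
    pi_coll: float
    pi_plateau: float | None
    cs_inv_max: float
    at_cs_max: tuple[float, float]  # (pi*, A*) where the modulus peaks
    collapse_detected: bool
    plateau_detected: bool

    def __post_init__(self) -> None:
        if self.a_lim <= 0.0:
            raise ValidationError("A_lim must be positive")
        if self.cs_inv_max <= 0.0:
            raise ValidationError("Cs^-1_max must be positive")
        if self.pi_plateau is not None and self.pi_plateau >= self.pi_coll:
            raise ValidationError("pi_plateau must be below pi_coll")

    def to_dict(self) -> dict:
        return {
            "A_lim": self.a_lim,
            "pi_coll": self.pi_coll,
            "pi_plateau": self.pi_plateau,
            "cs_inv_max": self.cs_inv_max,
            "at_cs_max": list(self.at_cs_max),
            "collapse_detected": self.collapse_detected,
            "plateau_detected": self.plateau_detected,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable knobs of the feature-extraction pipeline.

    ``window``/``degree`` control the Savitzky-Golay pre-smoothing used for
    collapse and plateau detection; ``stiffness_window`` is the (wider) window
    of the derivative estimate behind Cs^-1_max and A_lim, where noise
    amplification matters most.  ``drop_fraction`` is the modulus-drop
    criterion for collapse, ``plateau_ceiling`` the Cs^-1 level below which a
    region can qualify as an LE/LC plateau, ``shoulder_factor`` the factor by
    which both flanks must exceed the valley minimum.
    """

    window: int = 11
    degree: int = 2
    cs_smooth_window: int = 31
    stiffness_window: int = 41
    drop_fraction: float = 0.2
    min_collapse_pressure: float = 5.0
    plateau_ceiling: float = 50.0
    shoulder_factor: float = 2.0
    min_plateau_run: int = 5
    plateau_merge_gap: int = 25
    smooth: bool = True


# --------------------------------------------------------------------------- #
# I/O: CSV with `# key: value` metadata comment lines

_AREA_COL = "area_A2"
_PRESSURE_COL = "pressure_mN_m"


def _format_components(comp: Composition) -> str:
    return ",".join(f"{name}={frac!r}" for name, frac in comp.components)


def _parse_components(text: str, ratio: float) -> Composition:
    parts = []
    for chunk in text.split(","):
        name, _, frac = chunk.partition("=")
        try:
            parts.append((name.strip(), float(frac)))
        except ValueError as exc:
            raise FormatError(f"bad components entry {chunk!r}") from exc
    return Composition(tuple(parts), lipid_to_br_ratio=ratio)


def read_isotherm(source) -> Isotherm:
    """Read an isotherm from CSV with ``# key: value`` metadata comments.

    The table must carry columns ``area_A2`` and ``pressure_mN_m``.  Rows may
    be supplied in either compression or expansion order; they are
    canonicalised to strictly decreasing area.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            key, _, value = stripped.lstrip("#").partition(":")
            if value:
                meta[key.strip()] = value.strip()
        elif stripped:
            body_lines.append(line)
    if not body_lines:
        raise FormatError("empty isotherm file")
    frame = pd.read_csv(io.StringIO("\n".join(body_lines)), float_precision="round_trip")
    for col in (_AREA_COL, _PRESSURE_COL):
        if col not in frame.columns:
            raise FormatError(f"missing required column {col!r}")
    for col in (_AREA_COL, _PRESSURE_COL):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ParseError(
                f"non-numeric value {frame[col].iloc[row]!r} in column {col!r} at row {row}"
            )
        if numeric.isna().any():
            row = int(np.nonzero(numeric.isna().to_numpy())[0][0])
            raise ParseError(f"missing value in column {col!r} at row {row}")
        frame[col] = numeric
    ratio = float(meta.get("lipid_to_br_ratio", 4.0))
    composition = (
        _parse_components(meta["components"], ratio) if "components" in meta else None
    )
    return Isotherm(
        area=frame[_AREA_COL].to_numpy(),
        pressure=frame[_PRESSURE_COL].to_numpy(),
        temperature=float(meta.get("temperature_C", 20.0)),
        composition=composition,
        label=meta.get("label", ""),
        replicate_id=int(meta.get("replicate_id", 0)),
    )


def write_isotherm(iso: Isotherm, dest) -> None:
    """Write an isotherm as CSV; inverse of :func:`read_isotherm`."""
    lines = [
        f"# temperature_C: {iso.temperature!r}",
        f"# label: {iso.label}",
        f"# replicate_id: {iso.replicate_id}",
    ]
    if iso.composition is not None:
        lines.append(f"# components: {_format_components(iso.composition)}")
        lines.append(f"# lipid_to_br_ratio: {iso.composition.lipid_to_br_ratio!r}")
    lines.append(f"{_AREA_COL},{_PRESSURE_COL}")
    for a, p in zip(iso.area, iso.pressure):
        lines.append(f"{float(a)!r},{float(p)!r}")
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


# --------------------------------------------------------------------------- #
# smoothing and differentiation


def _check_window(window: int, degree: int, n: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if window > n:
        raise ParameterError(f"window {window} exceeds series length {n}")
    if degree >= window:
        raise ParameterError(f"degree {degree} must be smaller than window {window}")


def _clip_window(window: int, n: int) -> int:
    """Largest odd window <= min(window, n)."""
    w = min(window, n)
    return w if w % 2 == 1 else w - 1


def smooth_isotherm(iso: Isotherm, window: int = 11, degree: int = 2) -> Isotherm:
    """Replace pi by local-polynomial (Savitzky-Golay) fitted values.

    Areas are unchanged.  Endpoints are filled by evaluating the edge-window
    polynomial fits, so no points are lost.  Exact for pressures that are a
    polynomial of degree <= ``degree`` in the point index.
    """
    _check_window(window, degree, len(iso))
    smoothed = savgol_filter(iso.pressure, window, degree, mode="interp")
    return replace(iso, pressure=smoothed)


def compression_modulus(iso: Isotherm) -> CompressionModulusCurve:
    """Compression modulus Cs^-1(i) = -A(i) * (dpi/dA)(i), mN/m.

    Centred finite differences in the interior, one-sided at the endpoints.
    """
    if len(iso) < 3:
        raise ValidationError("need at least 3 points to differentiate")
    dpda = np.gradient(iso.pressure, iso.area)
    cs_inv = -iso.area * dpda
    return CompressionModulusCurve(
        pressure=iso.pressure.copy(), area=iso.area.copy(), cs_inv=cs_inv
    )


def _stiffness_curve(iso: Isotherm, window: int, degree: int) -> CompressionModulusCurve:
    """Cs^-1 from a single-stage Savitzky-Golay derivative of the raw curve.

    Used for Cs^-1_max and A_lim, where a wider window keeps derivative noise
    below the recovery tolerances.  Requires a (nearly) uniform area grid;
    falls back to smooth-then-difference otherwise.
    """
    n = len(iso)
    w = _clip_window(window, n)
    if w < 3:
        return compression_modulus(iso)
    d = min(degree, w - 1)
    steps = np.diff(iso.area)
    h = -np.mean(steps)  # area decreases with index
    if h <= 0 or np.max(np.abs(-steps - h)) > 1e-6 * h:
        return compression_modulus(smooth_isotherm(iso, w, d))
    dpd_index = savgol_filter(iso.pressure, w, d, deriv=1, delta=1.0, mode="interp")
    dpda = dpd_index / (-h)
    cs_inv = -iso.area * dpda
    return CompressionModulusCurve(
        pressure=iso.pressure.copy(), area=iso.area.copy(), cs_inv=cs_inv
    )


# --------------------------------------------------------------------------- #
# feature detection


def detection_curve(
    iso: Isotherm,
    window: int = 11,
    degree: int = 2,
    cs_smooth_window: int = 31,
) -> tuple[Isotherm, CompressionModulusCurve]:
    """Pre-smoothed isotherm and smoothed modulus curve for feature detection.

    Two stages: Savitzky-Golay smoothing of pi (``window``), then a second
    local-polynomial pass over the modulus itself (``cs_smooth_window``),
    which tames the noise amplification of differentiation in the soft
    low-pressure tail where Cs^-1 is small but A is large.
    """
    n = len(iso)
    w = _clip_window(window, n)
    smoothed = smooth_isotherm(iso, w, min(degree, w - 1))
    curve = compression_modulus(smoothed)
    wc = _clip_window(cs_smooth_window, n)
    cs = (
        savgol_filter(curve.cs_inv, wc, min(2, wc - 1), mode="interp")
        if wc >= 3
        else curve.cs_inv
    )
    return smoothed, CompressionModulusCurve(
        pressure=curve.pressure, area=curve.area, cs_inv=cs
    )


def detect_collapse(
    iso: Isotherm,
    curve: CompressionModulusCurve,
    drop_fraction: float = 0.2,
    min_pressure: float = 5.0,
    back_tolerance: float = 0.15,
) -> CollapseResult:
    """Locate the collapse point, scanning in compression direction.

    Collapse is the earlier of two signatures:

    (a) the first attainment of the maximum of pi, provided pi stops
        increasing afterwards (the maximum is not the last point) and exceeds
        ``min_pressure``; a small ``back_tolerance`` walks the index back
        across a noise-flat top to its first point;
    (b) the first point after the attained Cs^-1 maximum where the modulus
        falls below ``drop_fraction`` times that maximum.

    When neither occurs (a monotonically rising curve), the last point is
    returned with ``detected = False``.
    """
    p = iso.pressure
    n = p.size
    candidates: list[int] = []

    i_max = int(np.argmax(p))
    if i_max < n - 1 and p[i_max] >= min_pressure:
        j = i_max
        while j > 0 and p[j - 1] >= p[i_max] - back_tolerance:
            j -= 1
        candidates.append(j)

    cs = curve.cs_inv
    k = int(np.argmax(cs))
    if cs[k] > 0:
        below = np.nonzero(cs[k + 1 :] < drop_fraction * cs[k])[0]
        if below.size:
            candidates.append(k + 1 + int(below[0]))

    if not candidates:
        return CollapseResult(pi_coll=float(p[-1]), index=n - 1, detected=False)
    idx = min(candidates)
    return CollapseResult(pi_coll=float(p[idx]), index=idx, detected=True)


def detect_plateau(
    iso: Isotherm,
    curve: CompressionModulusCurve,
    collapse_index: int | None = None,
    plateau_ceiling: float = 50.0,
    shoulder_factor: float = 2.0,
    min_run: int = 5,
    merge_gap: int = 25,
    edge_trim: int = 31,
) -> PlateauResult | None:
    """Locate an LE/LC coexistence plateau in the pre-collapse segment.

    A plateau is a contiguous interior run of Cs^-1 below ``plateau_ceiling``
    bounded on *both* sides by regions whose modulus exceeds the run minimum
    by at least ``shoulder_factor``.  The two-sided requirement is what
    separates a plateau from collapse: collapse has no condensed branch after
    it.  Runs separated by fewer than ``merge_gap`` above-ceiling points are
    merged, so noise flicker around the ceiling cannot split the soft
    low-pressure tail into spurious "interior" valleys.  ``pi_plateau`` is pi
    at the modulus minimum inside the run.
    """
    cs = curve.cs_inv
    end = cs.size if collapse_index is None else collapse_index
    if end < 3:
        return None
    seg = cs[:end]
    below = seg < plateau_ceiling
    # the first smoothing window suffers edge-fit artifacts; fold it into the
    # leading boundary region so a spike there cannot manufacture an
    # "interior" run out of the soft low-pressure tail
    below[: min(edge_trim, end)] = True
    # contiguous runs of True
    edges = np.diff(below.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)  # exclusive
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        stops.append(end)
    merged: list[tuple[int, int]] = []
    for i0, i1 in zip(starts, stops):
        if merged and i0 - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))
    for i0, i1 in merged:
        if i0 == 0 or i1 == end:
            continue  # touches the segment boundary: tail onset or collapse side
        if i1 - i0 < min_run:
            continue
        run = seg[i0:i1]
        # the run's typical level: the median is robust to single-point noise
        # dips (which can push the pointwise minimum to zero or below)
        level = max(float(np.median(run)), float(run.min()), 0.0)
        left = float(seg[:i0].max())
        right = float(seg[i1:end].max())
        if left >= shoulder_factor * level and right >= shoulder_factor * level:
            # keep the minimum search away from the smeared run edges, where
            # a local polynomial fit across the steep shoulders undershoots
            trim = min(edge_trim, (i1 - i0) // 3)
            j = i0 + trim + int(np.argmin(seg[i0 + trim : i1 - trim]))
            return PlateauResult(
                pi_plateau=float(iso.pressure[j]), span=(i0, i1 - 1), detected=True
            )
    return None


def limiting_area(
    iso: Isotherm,
    curve: CompressionModulusCurve,
    collapse_index: int | None = None,
) -> tuple[float, int]:
    """Limiting area per molecule from the tangent at the Cs^-1 maximum.

    At the pre-collapse point of maximal modulus (pi*, A*), the tangent in the
    (A, pi) plane extrapolated to pi = 0 gives
    ``A_lim = A* (1 + pi* / Cs^-1_max)``.  Exact for affine condensed
    branches.  Returns ``(A_lim, index_of_maximum)``.
    """
    end = curve.cs_inv.size if collapse_index is None else collapse_index
    if end < 1:
        raise ValidationError("empty pre-collapse segment")
    i_star = int(np.argmax(curve.cs_inv[:end]))
    cs_star = float(curve.cs_inv[i_star])
    if cs_star <= 0.0:
        raise DomainError("degenerate curve: Cs^-1_max <= 0")
    a_star = float(iso.area[i_star])
    p_star = float(iso.pressure[i_star])
    return a_star * (1.0 + p_star / cs_star), i_star


def extract_features(iso: Isotherm, config: FeatureConfig | None = None) -> IsothermFeatures:
    """Full pipeline: smooth -> modulus -> collapse -> plateau -> A_lim, Cs^-1_max.

    Deterministic for a fixed configuration.  Collapse and plateau detection
    run on the pre-smoothed curve (window ``config.window``); the reported
    collapse pressure is refined to the local maximum of the *raw* pressures
    near the detected index, and Cs^-1_max / A_lim come from the wider
    ``stiffness_window`` derivative of the raw curve.
    """
    cfg = config or FeatureConfig()
    n = len(iso)
    w = _clip_window(cfg.window, n)
    if cfg.smooth:
        iso_s, det_curve = detection_curve(iso, w, cfg.degree, cfg.cs_smooth_window)
    else:
        iso_s = iso
        det_curve = compression_modulus(iso)

    collapse = detect_collapse(
        iso_s, det_curve, cfg.drop_fraction, cfg.min_collapse_pressure
    )
    if collapse.detected:
        hw = w // 2
        lo = max(0, collapse.index - hw)
        hi = min(n, collapse.index + hw + 1)
        pi_coll = float(np.max(iso.pressure[lo:hi]))
        upper = collapse.index
    else:
        pi_coll = float(iso.pressure[-1])
        upper = n
    if upper < 3:
        raise ValidationError("pre-collapse segment too short for feature extraction")

    plateau = detect_plateau(
        iso_s,
        det_curve,
        collapse_index=upper if collapse.detected else None,
        plateau_ceiling=cfg.plateau_ceiling,
        shoulder_factor=cfg.shoulder_factor,
        min_run=cfg.min_plateau_run,
        merge_gap=cfg.plateau_merge_gap,
        edge_trim=cfg.cs_smooth_window,
    )

    # clip the stiffness window to the condensed-branch length so that a
    # short branch after a high plateau is not smeared away entirely
    branch_len = upper - (plateau.span[1] + 1) if plateau is not None else upper
    w_branch = max(5, branch_len // 2) | 1
    stiff = _stiffness_curve(iso, min(cfg.stiffness_window, w_branch), cfg.degree)
    a_lim, i_star = limiting_area(iso, stiff, collapse_index=upper)
    cs_inv_max = float(stiff.cs_inv[i_star])

    pi_plateau = None
    plateau_detected = False
    if plateau is not None and plateau.pi_plateau < pi_coll:
        pi_plateau = plateau.pi_plateau
        plateau_detected = True

    return IsothermFeatures(
        a_lim=a_lim,
        pi_coll=pi_coll,
        pi_plateau=pi_plateau,
        cs_inv_max=cs_inv_max,
        at_cs_max=(float(iso.pressure[i_star]), float(iso.area[i_star])),
        collapse_detected=collapse.detected,
        plateau_detected=plateau_detected,
    )


def features_to_frame(
    entries: Sequence[tuple[str, float, IsothermFeatures]]
) -> pd.DataFrame:
    """Tabulate ``(label, temperature, features)`` records in table layout.

    Columns mirror the printed monolayer tables: A_lim, pi_coll, pi_plateau,
    cs_inv_max.
    """
    rows = []
    for label, temperature, feats in entries:
        rows.append(
            {
                "system": label,
                "temperature_C": temperature,
                "A_lim": feats.a_lim,
                "pi_coll": feats.pi_coll,
                "pi_plateau": feats.pi_plateau if feats.pi_plateau is not None else math.nan,
                "cs_inv_max": feats.cs_inv_max,
            }
        )
    return pd.DataFrame(rows)
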