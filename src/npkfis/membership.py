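"""Triangular fuzzy sets, linguistic variables and fuzzification.

A soil reading (say 27 ppm nitrogen) rarely belongs crisply to one category.
This module represents each nutrient category (LOW, ADEQUATE, HIGH, EXCESSIVE
for measured inputs; LOW, AVERAGE, HIGH for recommended outputs) as a
triangular membership function and converts crisp readings into degrees of
membership in each category.

Variables are constructed from interval tables of the kind soil-test
interpretation charts print (one [min, max] row per category).  Each
category's triangle peaks at its printed interval midpoint and its feet
extend to the neighbouring categories' peaks; the first and last categories
are shouldered so membership saturates at the domain edges.  The resulting
family is a Ruspini partition: at every in-domain point the degrees sum to
exactly 1 and at most two categories are active, so no reading ever falls
into a coverage gap.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence, Union

import numpy as np

from .errors import ConfigError, InvalidInputError

logger = logging.getLogger("npkfis")

__all__ = [
    "InputLevel",
    "OutputLevel",
    "Shoulder",
    "TriangularMF",
    "LevelBand",
    "LinguisticVariable",
    "membership_degree",
    "variable_from_intervals",
    "fuzzify",
    "variable_from_dict",
    "variable_to_dict",
    "variables_from_json",
]


class InputLevel(str, Enum):
    """Linguistic category of a measured nutrient, in increasing order."""

    LOW = "L"
    ADEQUATE = "A"
    HIGH = "H"
    EXCESSIVE = "E"

    @property
    def order(self) -> int:
        return _INPUT_ORDER[self]


class OutputLevel(str, Enum):
    """Linguistic category of a recommended output, in increasing order.

    The distinguished consequent value NIL ("no contribution") is *not* a
    member of this enum: rules represent it as ``None`` and no output
    variable ever carries a NIL band.
    """

    LOW = "L"
    AVERAGE = "M"
    HIGH = "H"

    @property
    def order(self) -> int:
        return _OUTPUT_ORDER[self]


_INPUT_ORDER = {lvl: i for i, lvl in enumerate(InputLevel)}
_OUTPUT_ORDER = {lvl: i for i, lvl in enumerate(OutputLevel)}

Level = Union[InputLevel, OutputLevel]


class Shoulder(str, Enum):
    """Saturation behaviour of a triangular set at the domain edges."""

    NONE = "none"
    LEFT = "left"
    RIGHT = "right"
    BOTH = "both"


@dataclass(frozen=True)
class TriangularMF:
    """A triangular fuzzy set with feet ``a``/``c`` and peak ``b``.

    ``shoulder`` saturates membership to 1 beyond the peak on the indicated
    side (LEFT: 1 on (-inf, b]; RIGHT: 1 on [b, inf); BOTH: the degenerate
    whole-domain set).  Outside [a, c] on a non-shoulder side membership is 0.
    """

    a: float
    b: float
    c: float
    shoulder: Shoulder = Shoulder.NONE

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b) and math.isfinite(self.c)):
            raise ConfigError(f"non-finite triangle parameters {(self.a, self.b, self.c)}")
        if not self.a <= self.b <= self.c:
            raise ConfigError(
                f"triangle requires a <= b <= c, got {(self.a, self.b, self.c)}"
            )

    def __call__(self, x: np.ndarray | float) -> np.ndarray:
        """Vectorised membership degrees for an array of crisp values."""
        x = np.asarray(x, dtype=float)
        sh = self.shoulder
        if sh is Shoulder.BOTH:
            return np.ones_like(x)
        if sh is Shoulder.LEFT:
            if self.c == self.b:
                return (x <= self.b).astype(float)
            return np.interp(x, [self.b, self.c], [1.0, 0.0], left=1.0, right=0.0)
        if sh is Shoulder.RIGHT:
            if self.a == self.b:
                return (x >= self.b).astype(float)
            return np.interp(x, [self.a, self.b], [0.0, 1.0], left=0.0, right=1.0)
        # plain triangle; tolerate a degenerate vertical flank (a == b or b == c)
        if self.a == self.b == self.c:
            return (x == self.b).astype(float)
        if self.a == self.b:
            return np.interp(x, [self.b, self.c], [1.0, 0.0], left=0.0, right=0.0)
        if self.b == self.c:
            return np.interp(x, [self.a, self.b], [0.0, 1.0], left=0.0, right=0.0)
        return np.interp(x, [self.a, self.b, self.c], [0.0, 1.0, 0.0], left=0.0, right=0.0)


def membership_degree(x: float, mf: TriangularMF) -> float:
    """Degree in [0, 1] to which crisp value ``x`` belongs to ``mf``.

    Exactly 1.0 at the peak and exactly 0.0 at and beyond the feet on a
    non-shoulder side.  Raises :class:`InvalidInputError` for non-finite x.
    """
    if not math.isfinite(x):
        raise InvalidInputError(f"crisp value must be finite, got {x!r}")
    return float(mf(x))


@dataclass(frozen=True)
class LevelBand:
    """One linguistic category of a variable: its printed crisp interval
    [lo, hi] (used for crisp classification) and its fuzzy set."""

    level: Level
    lo: float
    hi: float
    mf: TriangularMF


@dataclass(frozen=True)
class LinguisticVariable:
    """A named universe of discourse partitioned into labelled fuzzy sets.

    ``role`` is ``"input"`` (measured nutrient, ppm) or ``"output"``
    (recommendation / fertility on the 0-100 scale).
    """

    name: str
    role: str
    domain: tuple[float, float]
    bands: tuple[LevelBand, ...]

    @property
    def levels(self) -> tuple[Level, ...]:
        return tuple(b.level for b in self.bands)

    def band(self, level: Level) -> LevelBand:
        for b in self.bands:
            if b.level is level:
                return b
        raise KeyError(f"{self.name} has no level {level}")

    def mf(self, level: Level) -> TriangularMF:
        return self.band(level).mf

    def clip(self, x: float) -> float:
        lo, hi = self.domain
        if x < lo or x > hi:
            logger.warning(
                "%s reading %.6g outside domain [%g, %g]; clipped", self.name, x, lo, hi
            )
            return min(max(x, lo), hi)
        return x


def variable_from_intervals(
    name: str,
    role: str,
    domain: tuple[float, float],
    intervals: Sequence[tuple[Level, float, float]],
) -> LinguisticVariable:
    """Build a Ruspini-partitioned variable from a printed interval table.

    ``intervals`` lists ``(level, lo, hi)`` rows in increasing level order.
    Rows must tile the domain without overlap; a small positive gap between
    a row's hi and the next row's lo (the ".1" convention of printed soil
    charts, e.g. 20 / 20.1) is treated as an abutting boundary.  A printed
    lo slightly below the domain floor (charts print -1 for "below
    detection") is clamped for coverage purposes, but the peak is still the
    midpoint of the *printed* interval.

    Construction: peak b_i = (lo_i + hi_i) / 2; feet stretch to the
    neighbouring peaks; the first (last) level is left- (right-) shouldered.
    A single-interval variable degenerates to membership 1 everywhere.
    """
    lo_d, hi_d = float(domain[0]), float(domain[1])
    if not lo_d < hi_d:
        raise ConfigError(f"{name}: domain lo must be < hi, got {domain}")
    if not intervals:
        raise ConfigError(f"{name}: at least one interval row required")
    if role not in ("input", "output"):
        raise ConfigError(f"{name}: role must be 'input' or 'output', got {role!r}")

    rows = [(lvl, float(lo), float(hi)) for lvl, lo, hi in intervals]
    for lvl, lo, hi in rows:
        if not lo < hi:
            raise ConfigError(f"{name}/{lvl}: interval lo must be < hi, got [{lo}, {hi}]")
        if hi > hi_d + 1e-9 or hi <= lo_d:
            raise ConfigError(f"{name}/{lvl}: interval [{lo}, {hi}] outside domain")
    for (l0, lo0, hi0), (l1, lo1, hi1) in zip(rows, rows[1:]):
        gap = lo1 - hi0
        if gap < -1e-9:
            raise ConfigError(f"{name}: intervals {l0}/{l1} overlap ({hi0} > {lo1})")
        if gap > 0.5:
            raise ConfigError(f"{name}: gap between {l0} and {l1} ({hi0}..{lo1})")
    if rows[0][1] > lo_d + 1e-9:
        raise ConfigError(f"{name}: first interval starts above domain lo")
    if abs(rows[-1][2] - hi_d) > 1e-9:
        raise ConfigError(f"{name}: last interval must end at domain hi ({hi_d})")

    peaks = [(lo + hi) / 2.0 for _, lo, hi in rows]
    if any(p1 <= p0 for p0, p1 in zip(peaks, peaks[1:])):
        raise ConfigError(f"{name}: interval midpoints not strictly increasing")

    n = len(rows)
    bands = []
    for i, ((lvl, lo, hi), b) in enumerate(zip(rows, peaks)):
        a = lo_d if i == 0 else peaks[i - 1]
        c = hi_d if i == n - 1 else peaks[i + 1]
        if n == 1:
            shoulder = Shoulder.BOTH
        elif i == 0:
            shoulder = Shoulder.LEFT
        elif i == n - 1:
            shoulder = Shoulder.RIGHT
        else:
            shoulder = Shoulder.NONE
        # shoulders carry their plateau implicitly; clamp feet into the domain
        bands.append(
            LevelBand(lvl, lo, hi, TriangularMF(max(a, lo_d), min(max(b, lo_d), hi_d), min(c, hi_d), shoulder))
        )
    return LinguisticVariable(name, role, (lo_d, hi_d), tuple(bands))


def fuzzify(var: LinguisticVariable, x: float) -> dict[Level, float]:
    """Per-level membership degrees of a crisp reading.

    Out-of-domain readings are clipped to the nearest domain edge (with a
    logged warning) before evaluation, so a shoulder level reports degree 1.
    With the default Ruspini construction the degrees sum to 1 and at most
    two adjacent levels are nonzero.
    """
    if not isinstance(x, (int, float)) or not math.isfinite(x):
        raise InvalidInputError(f"{var.name}: crisp value must be finite, got {x!r}")
    xc = var.clip(float(x))
    return {b.level: float(b.mf(xc)) for b in var.bands}


# ---------------------------------------------------------------------------
# JSON configuration
# ---------------------------------------------------------------------------

def _level_cls(role: str):
    return InputLevel if role == "input" else OutputLevel


def variable_from_dict(d: Mapping) -> LinguisticVariable:
    """Build a variable from the JSON config schema
    ``{name, role, domain: [lo, hi], levels: [{label, lo, hi}]}``."""
    try:
        name = d["name"]
        role = d["role"]
        domain = tuple(d["domain"])
        cls = _level_cls(role)
        intervals = [(cls[e["label"].upper()], e["lo"], e["hi"]) for e in d["levels"]]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed variable config: {exc}") from exc
    return variable_from_intervals(name, role, domain, intervals)


def variable_to_dict(var: LinguisticVariable) -> dict:
    return {
        "name": var.name,
        "role": var.role,
        "domain": [var.domain[0], var.domain[1]],
        "levels": [{"label": b.level.name, "lo": b.lo, "hi": b.hi} for b in var.bands],
    }


def variables_from_json(text: str) -> dict[str, LinguisticVariable]:
    """Parse a ``{"variables": [...]}`` JSON document into a name-keyed map."""
    try:
        doc = json.loads(text)
        entries = doc["variables"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ConfigError(f"malformed system config: {exc}") from exc
    out: dict[str, LinguisticVariable] = {}
    for entry in entries:
        var = variable_from_dict(entry)
        if var.name in out:
            raise ConfigError(f"duplicate variable {var.name!r} in config")
        out[var.name] = var
    return out
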