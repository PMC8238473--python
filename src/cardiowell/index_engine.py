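"""Anchored exponential mapping from disease probability to a well-being index.

The transform f(x) = A + B*exp(C*x) is pinned by three (probability, index)
anchors. A and B are eliminated analytically from the first two anchors:

    B = (f2 - f1) / (exp(C*x2) - exp(C*x1))        A = f1 - B*exp(C*x1)

leaving a one-dimensional root-finding problem in C on the third anchor.
With the default anchors (0 -> 5, 1 -> -5, 0.55 -> -2.5) the fitted curve is
decreasing: rising disease risk pushes the index down exponentially, so high
risk is flagged early. Index values discretize into traffic-light colour
bands at thresholds 2.5, 0 and -2.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = ["IndexCurve", "CurveFitError", "fit_index_curve", "index_of",
           "colour_of", "DEFAULT_ANCHORS", "COLOUR_THRESHOLDS",
           "save_curve", "load_curve"]

DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.0, 5.0),    # no risk -> best index
    (1.0, -5.0),   # certain disease -> worst index
    (0.55, -2.5),  # orange/red threshold
)

INDEX_MIN, INDEX_MAX = -5.0, 5.0
# lower-inclusive bands: red [-5,-2.5) orange [-2.5,0) yellow [0,2.5) green [2.5,5]
COLOUR_THRESHOLDS = (2.5, 0.0, -2.5)


class CurveFitError(ValueError):
    """No exponential with C < 0 satisfies the anchors."""


@dataclass(frozen=True)
class IndexCurve:
    A: float
    B: float
    C: float
    anchors: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS

    def __call__(self, p):
        return self.A + self.B * np.exp(self.C * np.asarray(p, dtype=float))


def fit_index_curve(anchors: Sequence[tuple[float, float]] = DEFAULT_ANCHORS,
                    c_bracket: tuple[float, float] = (-50.0, -1e-6),
                    ) -> IndexCurve:
    """Solve A, B, C against three anchors (residual <= ~1e-9).

    Raises :class:`CurveFitError` when the anchors admit no decreasing
    exponential (e.g. collinear anchors), instead of failing silently.
    """
    if len(anchors) != 3:
        raise ValueError("exactly 3 anchors are required")
    pts = sorted((float(x), float(f)) for x, f in anchors)
    (x1, f1), (x2, f2), (x3, f3) = pts
    if x1 == x2 or x2 == x3:
        raise ValueError("anchor x values must be distinct")

    def solve_ab(c: float) -> tuple[float, float]:
        b = (f2 - f1) / (math.exp(c * x2) - math.exp(c * x1))
        return f1 - b * math.exp(c * x1), b

    def residual(c: float) -> float:
        a, b = solve_ab(c)
        return a + b * math.exp(c * x3) - f3

    lo, hi = c_bracket
    # scan a log-spaced grid for a sign change, then polish with Brent
    grid = -np.geomspace(-hi, -lo, 200)[::-1]  # from lo (most negative) to hi
    vals = np.array([residual(c) for c in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise CurveFitError(
            "no exponential f(x)=A+B*exp(Cx) with C in "
            f"[{lo}, {hi}] fits the anchors {list(anchors)}")
    i = sign_change[0]
    c = brentq(residual, grid[i], grid[i + 1], xtol=1e-12, rtol=8.9e-16)
    a, b = solve_ab(c)
    return IndexCurve(A=a, B=b, C=c, anchors=tuple((x, f) for x, f in anchors))


def index_of(curve: IndexCurve, p):
    """Evaluate the curve at probability ``p`` (scalar or array), clamped to [-5, 5]."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("probability must lie in [0, 1]")
    out = np.clip(curve(arr), INDEX_MIN, INDEX_MAX)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def colour_of(index: float) -> str:
    """Traffic-light band of an index value (lower-inclusive thresholds)."""
    if not INDEX_MIN <= index <= INDEX_MAX:
        raise ValueError(f"index {index} outside [{INDEX_MIN}, {INDEX_MAX}]")
    g, y, o = COLOUR_THRESHOLDS
    if index >= g:
        return "green"
    if index >= y:
        return "yellow"
    if index >= o:
        return "orange"
    return "red"


def colours_of(indexes: Iterable[float]) -> list[str]:
    return [colour_of(v) for v in indexes]


def save_curve(curve: IndexCurve, path) -> None:
    """Persist as plain text: three coefficient lines, then the anchors."""
    lines = [f"A {curve.A!r}", f"B {curve.B!r}", f"C {curve.C!r}"]
    lines += [f"anchor {x!r} {f!r}" for x, f in curve.anchors]
    Path(path).write_text("\n".join(lines) + "\n")


def load_curve(path) -> IndexCurve:
    coeffs: dict[str, float] = {}
    anchors: list[tuple[float, float]] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "anchor":
            anchors.append((float(parts[1]), float(parts[2])))
        else:
            coeffs[parts[0]] = float(parts[1])
    return IndexCurve(A=coeffs["A"], B=coeffs["B"], C=coeffs["C"],
                      anchors=tuple(anchors) or DEFAULT_ANCHORS)
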