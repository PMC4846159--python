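"""Esterase kinetics: absorbance traces to normalized fold activities.

The assay follows p-nitrophenyl acetate (p-NPA) hydrolysis by the yellow
product p-nitrophenol (p-NP) at 400 nm.  Because peptide suspensions scatter
light, every reaction trace has a matched no-substrate reference channel
(turbidity only) that is subtracted point by point before the Beer-Lambert
conversion c = A / (epsilon * pathlength) with epsilon(p-NP) =
15600 M^-1 cm^-1.

Activity is the initial rate: the ordinary-least-squares slope of product
concentration over the first 120 s of the record (configurable; falls back
to the first 10 points when the window is under-sampled).  One construct in
the panel — the collagen-mimetic fusion, panel id 4 — is instead scored by
the product concentration 1200 s after mixing.  Activities are normalized by
the no-peptide control (background hydrolysis in PBS/MeOH), giving the
dimensionless fold activity of the 12-entry panel; the leupeptin-inhibited
assembly is additionally reported as a percentage of the uninhibited one.

Michaelis-Menten fitting is deliberately out of scope: the assay shows a
near-linear concentration dependence in the studied range, so kcat/Km are
not identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EPSILON_PNP",
    "DEFAULT_RATE_WINDOW_S",
    "DEFAULT_ENDPOINT_S",
    "KineticsTrace",
    "ActivityResult",
    "absorbance_to_concentration",
    "subtract_reference",
    "initial_rate",
    "endpoint_activity",
    "analyze_trace",
    "normalized_activity",
    "fold_enhancement",
    "panel_report",
    "assay_concentrations",
]

#: Molar extinction coefficient of p-nitrophenol at 400 nm (M^-1 cm^-1).
EPSILON_PNP = 15600.0

DEFAULT_RATE_WINDOW_S = 120.0
DEFAULT_ENDPOINT_S = 1200.0
_MIN_RATE_POINTS = 3
_FALLBACK_POINTS = 10

METHOD_INITIAL_RATE = "initial-rate"
METHOD_ENDPOINT = "endpoint-1200s"


@dataclass
class KineticsTrace:
    """Time series of absorbance at 400 nm with an optional reference channel."""

    time_s: np.ndarray
    absorbance: np.ndarray
    reference: np.ndarray | None = None
    reference_time_s: np.ndarray | None = None
    label: str = ""
    pathlength_cm: float = 1.0

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.absorbance.shape:
            raise ValueError("time and absorbance must be 1-D arrays of equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.time_s < 0):
            raise ValueError("times must be >= 0")
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength must be > 0")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference_time_s is None:
                self.reference_time_s = self.time_s.copy()
            else:
                self.reference_time_s = np.asarray(self.reference_time_s, dtype=float)
            if self.reference.shape != self.reference_time_s.shape:
                raise ValueError("reference and its time grid must match in length")


@dataclass(frozen=True)
class ActivityResult:
    """Measured activity of one construct.

    ``value`` is an initial rate in M/s (method ``initial-rate``) or a product
    concentration in M at the endpoint (method ``endpoint-1200s``).  ``fold``
    is filled in by :func:`normalized_activity`.
    """

    label: str
    method: str
    value: float
    control_value: float | None = None
    fold: float | None = None
    panel_id: int | None = None


def absorbance_to_concentration(absorbance, epsilon: float = EPSILON_PNP,
                                pathlength_cm: float = 1.0,
                                clip_negative: bool = True):
    """Beer-Lambert conversion c = A / (epsilon * l), in molar.

    Small negative corrected absorbances (reference noise) fall outside the
    Beer-Lambert domain; they are clipped to zero by default.  Rate fitting
    passes ``clip_negative=False`` so that zero-mean noise does not bias the
    slope.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if pathlength_cm <= 0:
        raise ValueError("pathlength must be > 0")
    a = np.asarray(absorbance, dtype=float)
    c = a / (epsilon * pathlength_cm)
    if clip_negative:
        c = np.clip(c, 0.0, None)
    return c if c.ndim else float(c)


def subtract_reference(trace: KineticsTrace,
                       reference: KineticsTrace | None = None,
                       interpolate: bool = False) -> KineticsTrace:
    """Subtract the no-substrate reference channel, pointwise on the common
    time grid.

    The reference may be carried by the trace itself or passed separately.
    Mismatched grids are a hard error unless ``interpolate`` is set, in which
    case the reference is linearly interpolated onto the overlap of the two
    grids (points of the trace outside the reference range are dropped).
    """
    if reference is not None:
        ref_t = reference.time_s
        ref_a = reference.absorbance
    elif trace.reference is not None:
        ref_t = trace.reference_time_s
        ref_a = trace.reference
    else:
        raise ValueError(f"trace {trace.label!r} has no reference channel")

    if trace.time_s.shape == ref_t.shape and np.allclose(trace.time_s, ref_t):
        corrected = trace.absorbance - ref_a
        t = trace.time_s
    elif interpolate:
        lo, hi = ref_t[0], ref_t[-1]
        mask = (trace.time_s >= lo) & (trace.time_s <= hi)
        if not np.any(mask):
            raise ValueError("trace and reference time ranges do not overlap")
        t = trace.time_s[mask]
        corrected = trace.absorbance[mask] - np.interp(t, ref_t, ref_a)
    else:
        raise ValueError(
            "trace and reference time grids differ; enable interpolate=True "
            "or resample upstream"
        )
    return KineticsTrace(t, corrected, reference=None, label=trace.label,
                         pathlength_cm=trace.pathlength_cm)


def initial_rate(time_s, concentration_M, window_s: float = DEFAULT_RATE_WINDOW_S):
    """Initial reaction rate (M/s): OLS slope of concentration vs time over the
    early window.

    The window keeps points with t <= ``window_s`` (measured from the first
    sample); if fewer than three fall inside, the first ten points are used
    instead.  Fewer than three points overall is an error.
    """
    t = np.asarray(time_s, dtype=float)
    c = np.asarray(concentration_M, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("time and concentration must be 1-D arrays of equal length")
    mask = t <= t[0] + float(window_s)
    if mask.sum() < _MIN_RATE_POINTS:
        mask = np.zeros_like(mask)
        mask[:_FALLBACK_POINTS] = True
    if mask.sum() < _MIN_RATE_POINTS:
        raise ValueError(
            f"initial-rate fit needs >= {_MIN_RATE_POINTS} points, "
            f"got {int(mask.sum())}"
        )
    slope, _ = np.polyfit(t[mask], c[mask], 1)
    return float(slope)


def endpoint_activity(time_s, concentration_M,
                      endpoint_s: float = DEFAULT_ENDPOINT_S):
    """Product concentration (M) at the endpoint time, linearly interpolated
    between samples."""
    t = np.asarray(time_s, dtype=float)
    c = np.asarray(concentration_M, dtype=float)
    if not (t[0] <= endpoint_s <= t[-1]):
        raise ValueError(
            f"trace [{t[0]}, {t[-1]}] s does not span the endpoint {endpoint_s} s"
        )
    return float(np.interp(endpoint_s, t, c))


def analyze_trace(trace: KineticsTrace, method: str = METHOD_INITIAL_RATE,
                  epsilon: float = EPSILON_PNP,
                  window_s: float = DEFAULT_RATE_WINDOW_S,
                  endpoint_s: float = DEFAULT_ENDPOINT_S,
                  interpolate_reference: bool = False,
                  panel_id: int | None = None) -> ActivityResult:
    """Reference subtraction, Beer-Lambert conversion, then rate or endpoint."""
    corrected = (subtract_reference(trace, interpolate=interpolate_reference)
                 if trace.reference is not None else trace)
    if method == METHOD_INITIAL_RATE:
        conc = absorbance_to_concentration(
            corrected.absorbance, epsilon, corrected.pathlength_cm,
            clip_negative=False)  # unbiased slope
        value = initial_rate(corrected.time_s, conc, window_s)
    elif method == METHOD_ENDPOINT:
        conc = absorbance_to_concentration(
            corrected.absorbance, epsilon, corrected.pathlength_cm)
        value = endpoint_activity(corrected.time_s, conc, endpoint_s)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ActivityResult(label=trace.label, method=method, value=value,
                          panel_id=panel_id)


def normalized_activity(result: ActivityResult,
                        control: ActivityResult) -> ActivityResult:
    """Fold activity = measured / no-peptide control (same method on both)."""
    if result.method != control.method:
        raise ValueError(
            f"method mismatch: {result.method!r} vs control {control.method!r}"
        )
    if control.value <= 0:
        raise ValueError("control activity must be > 0")
    return replace(result, control_value=control.value,
                   fold=result.value / control.value)


def fold_enhancement(fold_a: float, fold_b: float) -> float:
    """Ratio of two normalized fold activities (e.g. assembled over monomer)."""
    if fold_b <= 0:
        raise ValueError("denominator fold must be > 0")
    return float(fold_a) / float(fold_b)


def panel_report(results: Iterable[ActivityResult],
                 reference_panel_id: int = 2) -> pd.DataFrame:
    """Tabulate the activity panel.

    Columns: panel_id, construct, method, fold, pct_of_reference.  The
    percentage column is each construct's fold relative to the reference
    construct (default panel id 2, the uninhibited assembly) — this is the
    denominator under which the leupeptin entry (12) reads as a percentage
    of the uninhibited assembly.
    """
    results = list(results)
    if not results:
        raise ValueError("panel is empty")
    ids = [r.panel_id for r in results]
    if any(i is None for i in ids):
        raise ValueError("every panel entry needs a panel_id")
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate panel_id(s): {dupes}")
    if any(r.fold is None for r in results):
        raise ValueError("panel entries must be normalized (fold is None)")
    by_id = {r.panel_id: r for r in results}
    ref_fold = by_id[reference_panel_id].fold if reference_panel_id in by_id else None
    rows = []
    for r in sorted(results, key=lambda r: r.panel_id):
        rows.append({
            "panel_id": r.panel_id,
            "construct": r.label,
            "method": r.method,
            "fold": r.fold,
            "pct_of_reference": (100.0 * r.fold / ref_fold
                                 if ref_fold else np.nan),
        })
    return pd.DataFrame(rows)


def assay_concentrations(buffer_uL: float = 440.0,
                         peptide_uL: float = 50.0,
                         peptide_stock_mM: float = 1.0,
                         substrate_uL: float = 10.0,
                         substrate_stock_mM: float = 25.0) -> tuple:
    """Final (peptide, substrate) concentrations in mM after mixing.

    Default volumes reproduce the assay recipe: 440 uL PBS + 50 uL of 1 mM
    peptide + 10 uL of 25 mM p-NPA in methanol -> 0.1 mM peptide and
    0.5 mM substrate in 500 uL.
    """
    total = buffer_uL + peptide_uL + substrate_uL
    if total <= 0:
        raise ValueError("total volume must be > 0")
    return (peptide_uL * peptide_stock_mM / total,
            substrate_uL * substrate_stock_mM / total)
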