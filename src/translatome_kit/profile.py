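"""Polysome absorbance profiles and ribosome-number calibration.

A sucrose-gradient run elutes mRNA-ribosome complexes in order of
increasing ribosome load while a UV detector records A254 absorbance.
The gradient is cut into 11 elution fractions whose biochemical roles
(free RNA, 30S and 50S subunits, monosome, polysomes of increasing
size) are assigned experimentally and taken here as input.

Two quantities are derived from the trace:

* a log-linear calibration ``ln(elution time) = a * ln(polysome size) + b``
  that converts fraction boundary times into ribosome-number ranges,
  anchored at the monosome peak (polysome size 1); and
* the percentage of ribosomes engaged in translation, the A254 area over
  elution fractions 4-11 relative to fractions 2-11 (fraction 1 holds
  free RNA and carries no ribosomal signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FRACTION_LABELS",
    "TRANSLATING_FRACTIONS",
    "PolysomeProfile",
    "RibosomeCalibration",
    "fit_ribosome_calibration",
    "ribosomes_for_fraction",
    "fraction_ranges_from_boundaries",
    "engaged_ribosome_fraction",
]

#: Pooled-array labels, in gradient order (B holds elution fractions 1-2,
#: C fraction 3, D-G fractions 4-7, H fractions 8-11).
FRACTION_LABELS = ("B", "C", "D", "E", "F", "G", "H")

#: Pooled fractions whose mRNAs carry at least one complete ribosome.
TRANSLATING_FRACTIONS = ("D", "E", "F", "G", "H")

#: Role names for the 11 elution fractions.
DEFAULT_ROLES = {1: "free_RNA", 2: "subunit_30S", 3: "subunit_50S", 4: "monosome"}
DEFAULT_ROLES.update({i: "polysome" for i in range(5, 12)})


@dataclass
class PolysomeProfile:
    """A sampled A254 trace with elution-fraction boundaries and roles.

    Parameters
    ----------
    time
        Strictly increasing elution times (minutes or any monotone unit).
    absorbance
        Nonnegative A254 readings, same length as ``time``.
    boundaries
        12 strictly increasing times delimiting the 11 elution fractions,
        all within the sampled time range.
    roles
        Map from elution-fraction index (1-11) to its role name.
    """

    time: np.ndarray
    absorbance: np.ndarray
    boundaries: np.ndarray
    roles: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_ROLES))

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.absorbance.shape:
            raise ValueError("time and absorbance must be 1-D arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.absorbance < 0):
            raise ValueError("absorbance must be nonnegative")
        if self.boundaries.size != 12:
            raise ValueError("exactly 12 boundaries delimit the 11 elution fractions")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.boundaries[0] < self.time[0] or self.boundaries[-1] > self.time[-1]:
            raise ValueError("boundaries must lie within the sampled time range")

    def fraction_area(self, first: int, last: int) -> float:
        """Trapezoidal A254 area over elution fractions ``first..last`` (1-based)."""
        if not 1 <= first <= last <= 11:
            raise ValueError("fraction indices must satisfy 1 <= first <= last <= 11")
        return _area_between(self.time, self.absorbance,
                             self.boundaries[first - 1], self.boundaries[last])


@dataclass
class RibosomeCalibration:
    """Fitted ``ln t = a ln P + b`` calibration.

    ``a`` is the slope averaged over replicate gradients; ``b`` holds one
    intercept per replicate, anchored analytically at that replicate's
    monosome elution time (``b = ln t_monosome``, so polysome size 1 maps
    exactly onto the monosome peak). ``fraction_ranges`` maps pooled
    fractions D-H to (min, max, representative) ribosome numbers.
    """

    a: float
    b: np.ndarray
    fraction_ranges: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.a == 0:
            raise ValueError("calibration slope a must be nonzero")

    @property
    def b_mean(self) -> float:
        return float(np.mean(self.b))

    def polysome_size(self, elution_time: float, replicate: int | None = None) -> float:
        """Invert the calibration: polysome size at a given elution time."""
        if elution_time <= 0:
            raise ValueError("elution time must be positive")
        b = self.b_mean if replicate is None else float(self.b[replicate])
        return float(np.exp((np.log(elution_time) - b) / self.a))


def fit_ribosome_calibration(
    monosome_times: Sequence[float],
    resolved_peaks: Sequence[Sequence[tuple[float, float]]],
) -> RibosomeCalibration:
    """Fit the log-linear elution-time/polysome-size relation per replicate.

    Parameters
    ----------
    monosome_times
        Elution time of the monosome peak for each replicate gradient.
    resolved_peaks
        For each replicate, the resolved polysome peaks as
        ``(polysome_size, elution_time)`` pairs; at least two distinct
        peaks per replicate are required for a slope.

    Returns
    -------
    RibosomeCalibration
        Slope ``a`` = mean of per-replicate least-squares slopes of
        ``ln t`` on ``ln P``; per-replicate intercept ``b = ln t_monosome``.
    """
    monosome_times = np.asarray(monosome_times, dtype=float)
    if len(resolved_peaks) != monosome_times.size:
        raise ValueError("one peak list per replicate is required")
    if np.any(monosome_times <= 0):
        raise ValueError("monosome elution times must be positive")
    slopes = []
    for rep, peaks in enumerate(resolved_peaks):
        arr = np.asarray(peaks, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or len(np.unique(arr[:, 0])) < 2:
            raise ValueError(
                f"replicate {rep}: at least two distinct resolved peaks are "
                "required to fit the calibration"
            )
        if np.any(arr <= 0):
            raise ValueError(f"replicate {rep}: sizes and times must be positive")
        ln_p, ln_t = np.log(arr[:, 0]), np.log(arr[:, 1])
        slope = np.polyfit(ln_p, ln_t, 1)[0]
        slopes.append(slope)
    return RibosomeCalibration(a=float(np.mean(slopes)), b=np.log(monosome_times))


def ribosomes_for_fraction(
    cal: RibosomeCalibration,
    boundary_times: tuple[float, float],
    replicate: int | None = None,
    fraction: str | None = None,
) -> tuple[float, float, float]:
    """Ribosome-number range for one pooled fraction.

    Inverts the calibration at both boundary times; the representative
    value is the arithmetic midpoint of the bounds, reported to one
    decimal. The monosome fraction D is forced to (1, 1, 1): by
    construction it holds exactly one ribosome per transcript.
    """
    if fraction == "D":
        return (1.0, 1.0, 1.0)
    t_low, t_high = boundary_times
    if not 0 < t_low < t_high:
        raise ValueError("boundary times must satisfy 0 < t_low < t_high")
    p_low = cal.polysome_size(t_low, replicate)
    p_high = cal.polysome_size(t_high, replicate)
    if p_high < p_low:  # a < 0 convention: larger polysomes elute earlier
        p_low, p_high = p_high, p_low
    return (p_low, p_high, _round_half_up((p_low + p_high) / 2.0))


def _round_half_up(x: float, decimals: int = 1) -> float:
    """Half-up rounding with a 1e-9 guard so exact .X5 midpoints produced
    through log/exp round trips land deterministically on the upper value."""
    scale = 10.0 ** decimals
    return float(np.floor(x * scale + 0.5 + 1e-9) / scale)


def fraction_ranges_from_boundaries(
    cal: RibosomeCalibration,
    pooled_boundaries: Mapping[str, tuple[float, float]],
) -> dict[str, tuple[float, float, float]]:
    """Build the D-H fraction_ranges map from pooled boundary times.

    Uses the replicate-averaged intercept. The result is stored on the
    calibration and returned.
    """
    ranges: dict[str, tuple[float, float, float]] = {}
    for frac in TRANSLATING_FRACTIONS:
        if frac not in pooled_boundaries:
            raise ValueError(f"missing boundary times for fraction {frac}")
        ranges[frac] = ribosomes_for_fraction(
            cal, pooled_boundaries[frac], replicate=None, fraction=frac
        )
    lows = [ranges[f][0] for f in TRANSLATING_FRACTIONS]
    if np.any(np.diff(lows) < 0):
        raise ValueError("fraction ranges must increase from D to H")
    cal.fraction_ranges = ranges
    return ranges


def engaged_ribosome_fraction(profile: PolysomeProfile) -> float:
    """Percentage of ribosomes engaged in translation.

    Trapezoidal A254 area over elution fractions 4-11 (monosome +
    polysomes) divided by the area over fractions 2-11 (all complete
    ribosomal particles, including free 30S/50S subunits), as a
    percentage. Invariant under uniform rescaling of the absorbance.
    """
    for idx in range(2, 12):
        if idx not in profile.roles:
            raise ValueError(f"elution fraction {idx} has no assigned role")
    total = profile.fraction_area(2, 11)
    if total <= 0:
        raise ValueError("zero ribosomal A254 area over fractions 2-11; "
                         "engaged fraction is undefined")
    return 100.0 * profile.fraction_area(4, 11) / total


def _area_between(time: np.ndarray, absorbance: np.ndarray,
                  t0: float, t1: float) -> float:
    """Trapezoid area of the sampled curve restricted to [t0, t1].

    Endpoint values are linearly interpolated so the area is exact for
    piecewise-linear traces regardless of where boundaries fall.
    """
    inside = (time > t0) & (time < t1)
    ts = np.concatenate(([t0], time[inside], [t1]))
    ys = np.concatenate((
        [np.interp(t0, time, absorbance)],
        absorbance[inside],
        [np.interp(t1, time, absorbance)],
    ))
    return float(np.trapezoid(ys, ts))
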