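"""Kovats retention indices on a temperature-programmed GC.

A compound's retention index (RI) places its retention time on the scale set
by the n-alkane ladder: the alkane with n carbons has RI = 100*n by
definition, and a compound eluting between the C_n and C_{n+1} alkanes gets

    RI = 100*n + 100 * (rt - rt_n) / (rt_{n+1} - rt_n)

(van den Dool-Kratz linear interpolation, the standard convention for
programmed-temperature runs; the logarithmic isothermal form is out of
scope).  Methyl branching lowers RI relative to the n-alkane of the same
carbon count, so reference curves of mean RI vs. total carbons, one per
branch count, let a (carbons, branches) hypothesis from mass-spectral
evidence be cross-checked against the measured RI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_core import HydrocarbonStructure

__all__ = [
    "AlkaneLadder",
    "RetentionIndex",
    "RICurveSet",
    "ConsistencyResult",
    "LadderRangeError",
    "LadderGapWarning",
    "retention_index",
    "build_ri_curves",
    "check_consistency",
]


class LadderRangeError(ValueError):
    """Retention time outside the span of the calibration ladder."""


class LadderGapWarning(UserWarning):
    """Bracketing alkanes are not consecutive; interpolating across the gap."""


@dataclass(frozen=True)
class AlkaneLadder:
    """n-alkane calibration ladder: (carbon number, retention time) pairs."""

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("ladder needs at least two alkanes")
        carbons = [c for c, _ in self.entries]
        rts = [rt for _, rt in self.entries]
        if any(b <= a for a, b in zip(carbons, carbons[1:])):
            raise ValueError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must be strictly increasing")

    @classmethod
    def from_pairs(cls, pairs) -> "AlkaneLadder":
        return cls(tuple(sorted((int(c), float(rt)) for c, rt in pairs)))

    @classmethod
    def from_csv(cls, path) -> "AlkaneLadder":
        """Read a headered CSV with columns ``carbon_number, rt_min``."""
        frame = pd.read_csv(path, float_precision="round_trip")
        return cls.from_pairs(zip(frame["carbon_number"], frame["rt_min"]))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.entries, columns=["carbon_number", "rt_min"]).to_csv(
            path, index=False, float_format=lambda x: repr(float(x))
        )

    @property
    def span(self) -> tuple[float, float]:
        return self.entries[0][1], self.entries[-1][1]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class RetentionIndex:
    value: float
    rounded: int
    bracket: tuple[int, int]

    @property
    def crosses_gap(self) -> bool:
        lo, hi = self.bracket
        return hi - lo > 1


def retention_index(rt: float, ladder: AlkaneLadder) -> RetentionIndex:
    """Kovats RI of a peak at ``rt`` minutes against ``ladder``.

    When the bracketing alkanes are not consecutive in carbon number
    (missing ladder members) the interpolation spans the gap and a
    :class:`LadderGapWarning` is issued.  Rounding is half-up to match the
    integer RI convention of the compound table.
    """
    lo_rt, hi_rt = ladder.span
    if not (lo_rt <= rt <= hi_rt):
        raise LadderRangeError(
            f"rt {rt} min outside ladder span [{lo_rt}, {hi_rt}]"
        )
    entries = ladder.entries
    for (n0, t0), (n1, t1) in zip(entries, entries[1:]):
        if t0 <= rt <= t1:
            if n1 - n0 > 1:
                warnings.warn(
                    f"no C{n0 + 1}..C{n1 - 1} alkane in ladder; interpolating "
                    f"C{n0}-C{n1}",
                    LadderGapWarning,
                    stacklevel=2,
                )
            value = 100.0 * n0 + 100.0 * (n1 - n0) * (rt - t0) / (t1 - t0)
            return RetentionIndex(value, _round_half_up(value), (n0, n1))
    raise LadderRangeError(f"rt {rt} not bracketed")  # pragma: no cover


@dataclass(frozen=True)
class RICurveSet:
    """Per-branch-count reference curves of mean RI vs. total carbon count.

    ``curves`` maps branch count k (0 = linear .. 5 = pentamethylated) to
    sorted arrays (carbons, mean RI); evaluation is piecewise linear through
    the means.
    """

    curves: dict[int, tuple[np.ndarray, np.ndarray]]

    def branch_counts(self) -> list[int]:
        return sorted(self.curves)

    def value(self, total_carbons: int, branch_count: int) -> float | None:
        """Curve value, or None when ``total_carbons`` is outside the span."""
        if branch_count not in self.curves:
            return None
        carbons, means = self.curves[branch_count]
        if not (carbons[0] <= total_carbons <= carbons[-1]):
            return None
        return float(np.interp(total_carbons, carbons, means))


def build_ri_curves(reference) -> RICurveSet:
    """Average a reference RI table into per-branch-count curves.

    ``reference`` is an iterable of ``(total_carbons, branch_count, ri)``
    rows (multiple rows per (carbons, k) are averaged) or a DataFrame with
    columns ``carbons, branches, ri``.  Within each branch count the mean RI
    must increase with carbon count; violations are reported.
    """
    if isinstance(reference, pd.DataFrame):
        frame = reference.rename(columns=str.lower)
    else:
        frame = pd.DataFrame(reference, columns=["carbons", "branches", "ri"])
    if frame.empty:
        raise ValueError("empty reference table")
    if frame["branches"].max() > 5:
        raise ValueError("reference curves are defined for 0..5 methyl branches")
    curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k, grp in frame.groupby("branches"):
        means = grp.groupby("carbons")["ri"].mean().sort_index()
        carbons = means.index.to_numpy(dtype=float)
        values = means.to_numpy(dtype=float)
        bad = np.nonzero(np.diff(values) <= 0)[0]
        if bad.size:
            points = ", ".join(
                f"C{int(carbons[i])}->C{int(carbons[i + 1])}" for i in bad
            )
            raise ValueError(
                f"mean RI not strictly increasing for k={int(k)} at {points}"
            )
        curves[int(k)] = (carbons, values)
    return RICurveSet(curves)


@dataclass(frozen=True)
class ConsistencyResult:
    verdict: str  # "pass" | "fail" | "inconclusive"
    deviation: float | None
    expected: float | None
    observed: float
    tolerance: float

    def __bool__(self) -> bool:
        return self.verdict == "pass"


def check_consistency(
    hypothesis: HydrocarbonStructure,
    observed_ri: float,
    curves: RICurveSet,
    tol: float = 15.0,
) -> ConsistencyResult:
    """Does the observed RI fit the (carbons, branches) hypothesis?

    Passes when the observed RI lies within ``tol`` RI units of the
    reference curve for the hypothesis's branch count evaluated at its
    total carbon count; a carbon count outside the curve span yields an
    ``inconclusive`` verdict, distinct from failure.
    """
    expected = curves.value(hypothesis.total_carbons, hypothesis.n_branches)
    if expected is None:
        return ConsistencyResult("inconclusive", None, None, observed_ri, tol)
    deviation = abs(observed_ri - expected)
    verdict = "pass" if deviation <= tol else "fail"
    return ConsistencyResult(verdict, deviation, expected, observed_ri, tol)
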