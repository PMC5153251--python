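"""Branch-count and branch-position inference from EI mass spectra.

The 70 eV EI spectrum of a saturated chain hydrocarbon is dominated by the
alkyl fragment ladder CnH2n+1+ at m/z = 14n + 1 (43, 57, 71, ...), whose
intensities fall off smoothly with mass.  The workflow models that envelope
as an exponential decay I(m) = A * exp(-lambda * m) and looks for series
members that sit well above it: a methyl branch promotes cleavage at the
branch carbon, so its pair of diagnostic ions emerges from the envelope.
Pairing the enhanced ions against the molecular mass counts the branches,
inverting the low-mass member of each pair locates them, and the resulting
structure hypothesis is cross-checked against the retention-index reference
curves.

The fit is restricted to the alkyl series (not every fragment ion) so that
the CnH2n-1 satellite series cannot contaminate the envelope, the two
lowest-mass members are excluded from fitting (in real spectra they are
dominated by non-specific fragmentation), and fitting is outlier-aware:
ions flagged as enhanced are removed and the envelope refit, so that the
branch ions themselves cannot bias the curve they are judged against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kovats
from .chem_core import HydrocarbonStructure, diagnostic_ions, format_structure

__all__ = [
    "EISpectrum",
    "DecayFit",
    "BranchCountEstimate",
    "ElucidationConfig",
    "ElucidationResult",
    "InsufficientSeriesError",
    "FlatSpectrumWarning",
    "alkyl_series",
    "fit_decay",
    "enhanced_ions",
    "estimate_branch_count",
    "infer_branch_positions",
    "identify_compound",
]

#: Lowest alkyl fragment considered (C3H7+ at m/z 43).
_SERIES_MIN_N = 3
#: Members of the series excluded from the decay fit at the low-mass end.
_N_LOW_EXCLUDED = 2


class InsufficientSeriesError(ValueError):
    """Fewer than four alkyl-series members are present in the spectrum."""


class FlatSpectrumWarning(UserWarning):
    """Fitted decay rate is not positive; enhancement calls are unreliable."""


@dataclass(frozen=True)
class EISpectrum:
    """An electron-impact spectrum for one chromatographic peak."""

    mz: np.ndarray
    intensity: np.ndarray
    parent_mass: int | None = None
    rt: float | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        order = np.argsort(mz)
        mz, inten = mz[order], inten[order]
        if np.any(np.diff(mz) <= 0):
            raise ValueError("duplicate m/z values in spectrum")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    @classmethod
    def from_csv(cls, path, parent_mass=None, rt=None) -> "EISpectrum":
        """Read a headered CSV with columns ``mz, intensity``."""
        frame = pd.read_csv(path, float_precision="round_trip")
        return cls(
            frame["mz"].to_numpy(), frame["intensity"].to_numpy(),
            parent_mass=parent_mass, rt=rt,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame({"mz": self.mz, "intensity": self.intensity}).to_csv(
            path, index=False, float_format=lambda x: repr(float(x))
        )


def alkyl_series(
    spectrum: EISpectrum, match_tol: float = 0.5
) -> list[tuple[int, float]]:
    """Extract the CnH2n+1 series (m/z = 14n + 1, n >= 3) from a spectrum.

    Series members are matched within ``match_tol`` m/z; the ladder stops at
    parent_mass - 15 when the parent mass is known (loss of one methyl),
    otherwise at the largest observed m/z.  Missing members are simply
    absent from the result, never recorded as zeros.
    """
    upper = (
        spectrum.parent_mass - 15
        if spectrum.parent_mass is not None
        else int(spectrum.mz.max())
    )
    series: list[tuple[int, float]] = []
    target = 14 * _SERIES_MIN_N + 1
    while target <= upper:
        idx = np.argmin(np.abs(spectrum.mz - target))
        if abs(spectrum.mz[idx] - target) <= match_tol:
            series.append((target, float(spectrum.intensity[idx])))
        target += 14
    if len(series) < 4:
        raise InsufficientSeriesError(
            f"only {len(series)} alkyl-series members found (need >= 4)"
        )
    return series


@dataclass(frozen=True)
class DecayFit:
    """Fitted exponential envelope of the alkyl series."""

    amplitude: float
    rate: float
    fitted_mz: tuple[int, ...]
    residual_ratio: dict[int, float]  # observed / predicted, all series ions
    domain: tuple[int, int]
    flat: bool = False

    def predict(self, mz) -> np.ndarray:
        return self.amplitude * np.exp(-self.rate * np.asarray(mz, dtype=float))


def _log_linear(mz: np.ndarray, inten: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(mz, np.log(inten), 1)
    return float(np.exp(intercept)), float(-slope)


def fit_decay(
    series: list[tuple[int, float]],
    tau: float = 3.0,
    max_iterations: int = 5,
) -> DecayFit:
    """Outlier-aware least-squares fit of I(m) = A * exp(-lambda * m).

    The fit is least squares on log intensities (equivalently, relative
    residuals): EI fragment intensities span orders of magnitude and their
    scatter is multiplicative, so a log-space loss weights the whole ladder
    evenly where an absolute-intensity loss would see only the few most
    intense low-mass ions and leave the high-mass end — where one of each
    diagnostic pair sits — essentially unconstrained.  The two lowest-mass
    series members are excluded from fitting, and the fit is outlier-aware:
    ions whose observed/predicted ratio is >= ``tau`` are dropped and the
    envelope refit (at most ``max_iterations`` rounds).  Residual ratios
    are reported for every series member, including the excluded ones, so
    enhancement can be judged over the whole ladder.
    """
    if len(series) < 4:
        raise InsufficientSeriesError("need >= 4 series members to fit")
    mz_all = np.array([m for m, _ in series], dtype=float)
    i_all = np.array([i for _, i in series], dtype=float)
    if np.any(i_all <= 0):
        raise ValueError("decay fit requires positive intensities")

    fit_mask = np.ones(len(series), dtype=bool)
    fit_mask[:_N_LOW_EXCLUDED] = False
    if fit_mask.sum() < 3:
        fit_mask[:] = True  # tiny series: keep everything

    included = fit_mask.copy()
    amp, rate = _log_linear(mz_all[included], i_all[included])
    for _ in range(max_iterations):
        pred = amp * np.exp(-rate * mz_all)
        outlier = (i_all / pred >= tau) & fit_mask
        new_included = fit_mask & ~outlier
        if new_included.sum() < 3 or np.array_equal(new_included, included):
            included = new_included if new_included.sum() >= 3 else included
            break
        included = new_included
        amp, rate = _log_linear(mz_all[included], i_all[included])
    amp, rate = _log_linear(mz_all[included], i_all[included])

    flat = rate <= 0
    if flat:
        warnings.warn(
            "fitted decay rate is not positive; spectrum envelope is flat",
            FlatSpectrumWarning,
            stacklevel=2,
        )
    pred = amp * np.exp(-rate * mz_all)
    ratios = {int(m): float(i / p) for m, i, p in zip(mz_all, i_all, pred)}
    return DecayFit(
        amplitude=amp,
        rate=rate,
        fitted_mz=tuple(int(m) for m in mz_all[included]),
        residual_ratio=ratios,
        domain=(int(mz_all[0]), int(mz_all[-1])),
        flat=flat,
    )


def enhanced_ions(
    spectrum: EISpectrum, fit: DecayFit, tau: float = 3.0
) -> list[tuple[int, float]]:
    """Series ions whose intensity exceeds the fitted envelope by >= ``tau``.

    Returns (m/z, observed/predicted ratio) pairs sorted by m/z; an empty
    list is the expected result for a linear alkane.
    """
    series = alkyl_series(spectrum)
    pred = fit.predict([m for m, _ in series])
    out = [
        (m, float(i / p))
        for (m, i), p in zip(series, pred)
        if i / p >= tau
    ]
    return sorted(out)


@dataclass(frozen=True)
class BranchCountEstimate:
    k: int
    pairs: tuple[tuple[int, int], ...]
    unpaired: tuple[int, ...]
    target_sum: int | None
    warning: str | None = None


def _greedy_pair(
    ions: list[int], target: float, tol: float
) -> tuple[list[tuple[int, int]], list[int]]:
    remaining = sorted(ions)
    pairs: list[tuple[int, int]] = []
    while remaining:
        i = remaining.pop(0)
        partner = None
        for j in remaining:
            if abs((i + j) - target) <= tol:
                partner = j
                break
        if partner is not None:
            remaining.remove(partner)
            pairs.append((i, partner))
        elif abs(2 * i - target) <= tol:
            pairs.append((i, i))  # chain-midpoint ion pairs with itself
        # else: leave unpaired
    paired = {m for p in pairs for m in p}
    unpaired = [m for m in ions if m not in paired]
    return pairs, unpaired


def estimate_branch_count(
    enhanced: list[tuple[int, float]] | list[int],
    parent_mass: int,
    pairing_tolerance: float = 1.0,
    max_branches: int = 5,
) -> BranchCountEstimate:
    """Count methyl branches by pairing enhanced ions against the parent mass.

    For a monomethyl alkane the diagnostic pair sums to parent + 28; each
    additional branch shortens the backbone by one carbon and shifts every
    pair sum down by 14, so for k branches the common sum is
    parent + 42 - 14*k.  Branch-count hypotheses k = 1..``max_branches`` are
    tried in order and the first whose pairing yields exactly k pairs wins;
    the monomethyl case therefore reduces to the parent + 28 rule.  Enhanced
    ions present but unpairable give k = 0 with a warning.
    """
    ions = [m for m, *_ in (e if isinstance(e, tuple) else (e,) for e in enhanced)]
    if not ions:
        return BranchCountEstimate(0, (), (), None)
    for k_hyp in range(1, max_branches + 1):
        target = parent_mass + 42 - 14 * k_hyp
        pairs, unpaired = _greedy_pair(ions, target, pairing_tolerance)
        if len(pairs) == k_hyp:
            return BranchCountEstimate(
                k_hyp, tuple(pairs), tuple(unpaired), target
            )
    return BranchCountEstimate(
        0, (), tuple(ions), None,
        warning="enhanced ions present but none pairable against parent mass",
    )


def infer_branch_positions(
    pairs: tuple[tuple[int, int], ...] | list[tuple[int, int]],
    parent_mass: int,
) -> list[HydrocarbonStructure]:
    """Invert diagnostic-ion pairs to branch locants.

    The parent mass fixes the total carbon count N = (M - 2) / 14 for a
    CnH2n+2 alkane; with k = len(pairs) branches the backbone has
    L = N - k carbons and the low-mass member of each pair inverts to
    b = (m_low - 15) / 14.  Pairs whose inversion is not a positive integer
    interior to the chain are rejected; an empty candidate list means no
    structure is consistent with the pairing.
    """
    if (parent_mass - 2) % 14 != 0:
        raise ValueError(
            f"parent mass {parent_mass} is not a CnH2n+2 alkane mass"
        )
    total_carbons = (parent_mass - 2) // 14
    k = len(pairs)
    backbone = total_carbons - k
    if k == 0:
        if backbone < 1:
            return []
        return [HydrocarbonStructure(backbone_length=backbone)]
    positions: list[int] = []
    for pair in pairs:
        m_low = min(pair)
        b, rem = divmod(m_low - 15, 14)
        if rem != 0 or not (1 < b < backbone):
            return []
        positions.append(int(b))
    if len(set(positions)) != len(positions):
        return []
    try:
        return [
            HydrocarbonStructure(
                backbone_length=backbone, branch_positions=tuple(positions)
            )
        ]
    except ValueError:
        return []


@dataclass(frozen=True)
class ElucidationConfig:
    """Tunable thresholds of the elucidation workflow."""

    tau: float = 3.0  # enhancement threshold on observed/predicted ratio
    max_fit_iterations: int = 5
    pairing_tolerance: float = 1.0  # Da, on pair-sum matching
    ri_tolerance: float = 15.0  # RI units for curve consistency


@dataclass
class ElucidationResult:
    """Outcome of the full identification chain for one spectrum."""

    branch_count: int
    candidates: list[HydrocarbonStructure]
    enhanced: list[tuple[int, float]]
    pairs: tuple[tuple[int, int], ...]
    unpaired: tuple[int, ...]
    fit: DecayFit | None
    retention_index: kovats.RetentionIndex | None
    ri_check: kovats.ConsistencyResult | None
    ambiguous: bool = False
    inconclusive: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def structure(self) -> HydrocarbonStructure | None:
        return self.candidates[0] if self.candidates else None

    def proposed_name(self) -> str | None:
        if self.structure is None:
            return None
        return format_structure(self.structure, ambiguous=self.ambiguous)


def identify_compound(
    spectrum: EISpectrum,
    rt: float | None,
    ladder: kovats.AlkaneLadder | None,
    curves: kovats.RICurveSet | None,
    config: ElucidationConfig | None = None,
) -> ElucidationResult:
    """Run the full elucidation chain on one spectrum.

    Chains series extraction -> envelope fit -> enhanced-ion detection ->
    branch counting -> position inversion -> retention-index consistency.
    A flat envelope (non-positive decay rate) short-circuits enhancement
    calls and flags the result inconclusive.  Stage failures carry the
    stage name in the raised error.
    """
    cfg = config or ElucidationConfig()
    if spectrum.parent_mass is None:
        raise ValueError("identify_compound requires a parent mass")
    rt = rt if rt is not None else spectrum.rt

    try:
        series = alkyl_series(spectrum)
    except InsufficientSeriesError as err:
        raise InsufficientSeriesError(f"alkyl_series: {err}") from err
    fit = fit_decay(series, tau=cfg.tau, max_iterations=cfg.max_fit_iterations)

    if fit.flat:
        return ElucidationResult(
            branch_count=0, candidates=[], enhanced=[], pairs=(), unpaired=(),
            fit=fit, retention_index=None, ri_check=None,
            inconclusive=True, notes=["flat envelope: no enhancement calls made"],
        )

    enh = enhanced_ions(spectrum, fit, tau=cfg.tau)
    estimate = estimate_branch_count(
        enh, spectrum.parent_mass, pairing_tolerance=cfg.pairing_tolerance
    )
    candidates = infer_branch_positions(estimate.pairs, spectrum.parent_mass)
    notes = [estimate.warning] if estimate.warning else []
    ambiguous = len(candidates) > 1

    ri = None
    ri_check = None
    if rt is not None and ladder is not None:
        ri = kovats.retention_index(rt, ladder)
        if curves is not None and candidates:
            ri_check = kovats.check_consistency(
                candidates[0], ri.value, curves, tol=cfg.ri_tolerance
            )
    return ElucidationResult(
        branch_count=estimate.k,
        candidates=candidates,
        enhanced=enh,
        pairs=estimate.pairs,
        unpaired=estimate.unpaired,
        fit=fit,
        retention_index=ri,
        ri_check=ri_check,
        ambiguous=ambiguous,
        inconclusive=False,
        notes=notes,
    )
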