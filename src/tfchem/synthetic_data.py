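"""Seeded generators for every input class the pipeline consumes.

Each generator emulates one of the study's data types with known ground
truth, so every stage is testable without the deposited instrument data:

* an n-alkane calibration ladder (monotone retention times per carbon),
* EI spectra of saturated alkanes — alkyl series with an exponentially
  decaying envelope, branch-diagnostic ions multiplicatively enhanced,
  optional multiplicative log-normal noise,
* a chromatogram cohort (five colonies, trophallactic-fluid and whole-body
  extracts) built from Gaussian peaks drawn from a species-level peak set,
  with the fluid profiles sharing more peaks across colonies than the body
  profiles,
* spectral-count matrices with protein-length-proportional negative-
  binomial counts and a multiplicative condition effect on a subset of
  proteins.

All randomness flows through a mandatory seed (or an explicit Generator);
identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_core import HydrocarbonStructure, diagnostic_ions, formula_of, nominal_mass
from .kovats import AlkaneLadder
from .profile_analysis import Chromatogram
from .proteomic_counts import SpectralCountMatrix
from .spectrum_inference import EISpectrum

__all__ = [
    "LadderConfig",
    "SpectrumConfig",
    "CohortConfig",
    "CountsConfig",
    "ReferenceRIConfig",
    "gen_alkane_ladder",
    "gen_ei_spectrum",
    "gen_cohort",
    "gen_count_matrix",
    "gen_reference_ri_table",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is mandatory for stochastic generation")
    return np.random.default_rng(seed)


# --- n-alkane ladder -------------------------------------------------------


@dataclass(frozen=True)
class LadderConfig:
    """Emulates a C8-C40 n-alkane standard mixture."""

    carbon_min: int = 8
    carbon_max: int = 40
    rt_start: float = 5.0  # min, elution of the first alkane
    spacing: float = 1.2  # min between successive alkanes
    jitter: float = 0.0  # relative jitter on each spacing, in [0, 1)


def gen_alkane_ladder(config: LadderConfig = LadderConfig(), seed=None) -> AlkaneLadder:
    """Monotone ladder of (carbon number, retention time) pairs."""
    n = config.carbon_max - config.carbon_min + 1
    if config.jitter > 0:
        rng = _rng(seed)
        deltas = config.spacing * (
            1.0 + config.jitter * rng.uniform(-0.5, 0.5, size=n - 1)
        )
    else:
        deltas = np.full(n - 1, config.spacing)
    rts = config.rt_start + np.concatenate([[0.0], np.cumsum(deltas)])
    carbons = range(config.carbon_min, config.carbon_max + 1)
    return AlkaneLadder.from_pairs(zip(carbons, rts))


# --- EI spectra ------------------------------------------------------------


@dataclass(frozen=True)
class SpectrumConfig:
    """Alkyl-series envelope and branch-enhancement parameters."""

    amplitude: float = 1000.0  # envelope intensity at m/z 0 (arbitrary units)
    decay: float = 0.02  # per Da
    enhancement: float = 5.0  # multiplicative boost of diagnostic ions
    noise_sigma: float = 0.15  # log-normal multiplicative noise (0 = noiseless)
    parent_fraction: float = 0.5  # parent-ion intensity vs envelope at M


def gen_ei_spectrum(
    structure: HydrocarbonStructure,
    config: SpectrumConfig = SpectrumConfig(),
    seed=None,
) -> EISpectrum:
    """EI spectrum of a saturated alkane with known ground truth.

    The CnH2n+1 ladder runs from m/z 43 to parent - 15 with intensity
    A*exp(-decay*m); each diagnostic ion of the structure is multiplied by
    the enhancement factor (branch ions emerge from the envelope); a weak
    parent ion sits at the nominal molecular mass.  With noise_sigma > 0
    every intensity is multiplied by exp(sigma * N(0,1)) and a seed is
    required.
    """
    if structure.other_class is not None or not structure.is_saturated:
        raise ValueError("spectrum generation supports saturated alkanes only")
    parent = nominal_mass(formula_of(structure))
    enhanced = diagnostic_ions(structure)
    mz = np.arange(43, parent - 15 + 1, 14, dtype=float)
    inten = config.amplitude * np.exp(-config.decay * mz)
    for ion in enhanced:
        inten[mz == ion] *= config.enhancement
    mz = np.append(mz, parent)
    inten = np.append(
        inten,
        config.parent_fraction * config.amplitude * np.exp(-config.decay * parent),
    )
    if config.noise_sigma > 0:
        rng = _rng(seed)
        inten = inten * np.exp(config.noise_sigma * rng.standard_normal(len(inten)))
    return EISpectrum(mz=mz, intensity=inten, parent_mass=parent)


# --- chromatogram cohort ---------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Five-colony trophallactic-fluid / whole-body chromatogram cohort.

    A species-level set of candidate peak positions is drawn once; each
    sample includes a master peak with the per-source sharing probability,
    so fluid profiles (tf_share) overlap more across colonies than body
    profiles (body_share).  Setting the two probabilities equal gives the
    null cohort for calibration.
    """

    n_colonies: int = 5
    sources: tuple[str, ...] = ("tf", "body")
    window: tuple[float, float] = (36.0, 51.0)
    dt: float = 0.005  # min, trace sampling step
    n_master_peaks: int = 30
    min_separation: float = 0.4  # min, between master peak positions
    tf_share: float = 0.9
    body_share: float = 0.5
    peak_sigma: float = 0.02  # min, Gaussian peak width
    amp_low: float = 0.15
    amp_high: float = 1.0
    amp_sigma: float = 0.3  # log-normal per-sample amplitude jitter
    noise_sd: float = 0.01  # additive baseline noise


def gen_cohort(
    config: CohortConfig = CohortConfig(), seed=None
) -> tuple[list[Chromatogram], pd.DataFrame]:
    """Generate the cohort and its ground-truth peak table.

    Returns the chromatograms (one per colony x source) and a truth table
    with one row per (sample, master peak): position, drawn amplitude and
    whether the peak was included in that sample.
    """
    rng = _rng(seed)
    lo, hi = config.window
    margin = 0.5
    slots = np.arange(lo + margin, hi - margin, config.min_separation)
    if len(slots) < config.n_master_peaks:
        raise ValueError("window too narrow for the requested master peaks")
    positions = np.sort(rng.choice(slots, size=config.n_master_peaks, replace=False))
    positions = positions + rng.uniform(
        0, config.min_separation * 0.25, size=len(positions)
    )
    master_amp = rng.uniform(config.amp_low, config.amp_high, size=len(positions))

    share = {"tf": config.tf_share, "body": config.body_share}
    grid = np.arange(lo, hi + config.dt / 2, config.dt)
    chroms: list[Chromatogram] = []
    truth_rows = []
    for c in range(1, config.n_colonies + 1):
        colony = f"C{10 + c}"
        for source in config.sources:
            sample_id = f"{colony}_{source}"
            include = rng.uniform(size=len(positions)) < share[source]
            if not include.any():  # degenerate draw: keep one peak
                include[rng.integers(len(positions))] = True
            amps = master_amp * np.exp(
                config.amp_sigma * rng.standard_normal(len(positions))
            )
            trace = np.zeros_like(grid)
            for pos, amp, inc in zip(positions, amps, include):
                if inc:
                    trace += amp * np.exp(
                        -0.5 * ((grid - pos) / config.peak_sigma) ** 2
                    )
            trace += rng.normal(0, config.noise_sd, size=len(grid))
            trace = np.clip(trace, 0, None)
            chroms.append(
                Chromatogram(
                    sample_id=sample_id, colony=colony, source=source,
                    rt=grid, abundance=trace,
                )
            )
            for pos, amp, inc in zip(positions, amps, include):
                truth_rows.append((sample_id, colony, source, pos, amp, bool(inc)))
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "colony", "source", "peak_rt", "amplitude", "included"],
    )
    return chroms, truth


# --- spectral-count matrices ----------------------------------------------


@dataclass(frozen=True)
class CountsConfig:
    """In-colony vs. isolated spectral-count design.

    Counts are negative-binomial with mean proportional to protein length
    times a per-protein abundance factor; ``affected_fraction`` of proteins
    carry a multiplicative ``effect_size`` in the second condition
    (effect_size = 1 is the null).  One sample per colony per condition,
    i.e. a paired design.
    """

    n_proteins: int = 40
    n_per_condition: int = 6
    length_low: int = 100
    length_high: int = 1000
    count_scale: float = 0.5  # mean counts per residue of abundance 1
    abundance_sigma: float = 1.0  # log-normal spread of protein abundances
    effect_size: float = 5.0
    affected_fraction: float = 0.075  # 3 of 40 proteins
    dispersion: float = 5.0  # NB size parameter r (larger = closer to Poisson)
    conditions: tuple[str, str] = ("in_colony", "isolated")


def gen_count_matrix(
    config: CountsConfig = CountsConfig(), seed=None
) -> tuple[SpectralCountMatrix, pd.Series]:
    """Generate counts plus per-protein truth flags (condition-affected)."""
    rng = _rng(seed)
    proteins = [f"P{i:03d}" for i in range(1, config.n_proteins + 1)]
    lengths = pd.Series(
        rng.integers(config.length_low, config.length_high + 1, config.n_proteins),
        index=proteins, name="length_aa",
    )
    abundance = np.exp(config.abundance_sigma * rng.standard_normal(config.n_proteins))
    n_affected = int(round(config.affected_fraction * config.n_proteins))
    affected_idx = rng.choice(config.n_proteins, size=n_affected, replace=False)
    affected = np.zeros(config.n_proteins, dtype=bool)
    affected[affected_idx] = True

    cond_a, cond_b = config.conditions
    meta_rows = []
    data = {}
    r = config.dispersion
    for j in range(1, config.n_per_condition + 1):
        colony = f"C{j}"
        for cond in config.conditions:
            sample = f"{colony}_{cond}"
            mu = config.count_scale * lengths.to_numpy() * abundance / 100.0
            if cond == cond_b:
                mu = np.where(affected, mu * config.effect_size, mu)
            p = r / (r + mu)
            counts = rng.negative_binomial(r, p)
            if counts.sum() == 0:  # keep the sample valid
                counts[int(np.argmax(mu))] = 1
            data[sample] = counts
            meta_rows.append((sample, cond, colony))
    counts = pd.DataFrame(data, index=proteins)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "condition", "colony"])
    matrix = SpectralCountMatrix(counts=counts, lengths=lengths, meta=meta)
    truth = pd.Series(affected, index=proteins, name="affected")
    return matrix, truth


# --- reference RI tables ---------------------------------------------------


@dataclass(frozen=True)
class ReferenceRIConfig:
    """Synthetic reference RI table: RI = 100*C - offset*k + noise."""

    carbon_min: int = 20
    carbon_max: int = 36
    max_branches: int = 5
    branch_offset: float = 35.0  # RI units lost per methyl branch
    noise_sd: float = 2.0
    n_replicates: int = 3


def gen_reference_ri_table(
    config: ReferenceRIConfig = ReferenceRIConfig(), seed=None
) -> pd.DataFrame:
    """Reference table of (carbons, branches, ri) rows for curve building."""
    rng = _rng(seed) if config.noise_sd > 0 else None
    rows = []
    for c in range(config.carbon_min, config.carbon_max + 1):
        for k in range(config.max_branches + 1):
            base = 100.0 * c - config.branch_offset * k
            for _ in range(config.n_replicates):
                noise = rng.normal(0, config.noise_sd) if rng is not None else 0.0
                rows.append((c, k, base + noise))
    return pd.DataFrame(rows, columns=["carbons", "branches", "ri"])
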