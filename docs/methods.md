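# Methods

This note documents the models and procedures implemented in `tfchem`,
the parameters that matter, what the synthetic-data generators do and do
not emulate, and the numerical and design choices made where more than one
reasonable option existed.

## Branched-alkane elucidation from EI spectra

**Model.**  Under 70 eV electron impact a saturated chain hydrocarbon
fragments predominantly into the alkyl series CₙH₂ₙ₊₁⁺ at m/z = 14n + 1,
whose intensity falls off approximately exponentially with mass,
I(m) = A·e^(−λm).  A methyl branch weakens the two C–C bonds at the branch
carbon, so the secondary carbocations formed there are over-produced: for a
branch at position b on a backbone of L carbons the pair of even-electron
diagnostic ions is m_low = 14b + 15 and m_high = 14(L − b + 2) + 1.  For a
monomethyl alkane of molecular mass M the pair sums to M + 28; every
additional branch shortens the backbone by one carbon and shifts the common
pair sum down by 14 (M + 42 − 14k for k branches).  At the chain midpoint
the two ions coincide and the ion self-pairs.

**Procedure.**  `identify_compound` chains: alkyl-series extraction
(members matched within ±0.5 m/z, ladder capped at M − 15) → outlier-aware
envelope fit → enhanced-ion detection (observed/predicted ≥ τ, default 3)
→ branch counting by pair-sum matching (±1 Da) over k = 1..5, accepting
the smallest k whose pairing yields exactly k pairs → locant inversion
(b = (m_low − 15)/14, rejected if not an interior integer) → retention-index
consistency check.  A non-positive fitted decay rate flags the spectrum
inconclusive and suppresses enhancement calls.

**Fit loss.**  The envelope is fitted by least squares on log intensities
(iteratively: fit → drop ions with ratio ≥ τ → refit, at most 5 rounds,
always excluding the two lowest-mass members, which in real spectra are
dominated by non-specific fragmentation).  The log-space loss is a
deliberate choice: fragment intensities span orders of magnitude with
multiplicative scatter, and an absolute-intensity loss is dominated by the
few intense low-mass ions, leaving λ so poorly constrained that the
envelope at m/z ≈ 400 can be off two-fold for a 10% λ error — exactly where
the high-mass member of a diagnostic pair sits.  In simulation this choice
raises exact-structure recovery at lognormal noise σ = 0.15 from 89% to
100%, and λ-within-15% recovery at σ = 0.1 from 95% to 100%.

**Limits.**  Double-bond localization is out of scope (alkenes are carried
as annotated records with starred positions); dimethyl positional isomers
are resolved only insofar as the pairing is unique, otherwise candidates
are flagged ambiguous.

## Kovats retention indices

Retention indices use van den Dool–Kratz linear interpolation between
bracketing n-alkanes — the standard convention for temperature-programmed
GC (the logarithmic isothermal form is not implemented).  Integer RIs are
rounded half-up, matching the convention of the packaged compound table.
A ladder gap (missing alkane) is interpolated across with a warning rather
than an error.  Reference curves of RI vs. total carbons, one per branch
count k = 0..5, are built by averaging all reference values per
(carbons, k) and interpolating piecewise-linearly through the means;
non-monotone means are rejected with the offending points listed.  The
consistency check passes a hypothesis when the observed RI is within a
tolerance (default 15 RI units, roughly a quarter of the ~62-unit RI
deficit per methyl branch observed in the compound table) of the curve,
and returns a distinct *inconclusive* verdict outside the curve span.

One caveat documented by the packaged table itself: interpolating the
table's own n-alkanes reproduces most printed RIs within a few units, but
one row (a tricosene at Rt 26.27, printed RI 2279) is internally
inconsistent with its printed bracketing alkanes (it computes to 2287
under any interpolation through the printed C22/C23 times), and the
printed MW 295 for C21H44 disagrees with its own formula (296).  The table
loader flags rather than resolves these.

## Chromatographic profile comparison

Each trace is restricted to the cuticular-hydrocarbon window (36–51 min,
covering C28–C37 at the emulated gradient) and min-max normalized to
[0, 1].  Peaks are strict local maxima (plateaus contribute their leftmost
point) at or above 7% of the normalized range — the threshold is applied
after normalization, which is how the stated order of operations reads.
Peaks are summed into 0.03-min bins anchored at 0.0 min so all samples
share bin edges.  Similarity is the coefficient-normalized
cross-correlation of the binned vectors — with the default lag range of 0,
the cosine of the two vectors — maximized over integer bin lags |ℓ| ≤
max_lag when a lag search is requested.  It is symmetric, bounded by 1 and
scale-invariant.

The group comparison tests cross-colony within-fluid pairs against
within-body pairs; Welch's t-test is the default, with pooled-variance and
a randomization test (exhaustively enumerated when there are at most
`n_perm` regroupings) as alternatives.

**Known limitation — the test is anti-conservative.**  The C(5,2) = 10
pairwise similarities per group are not independent: any per-sample
variation makes pairs sharing a sample positively correlated, and a t-test
that treats pair values as independent observations rejects a true null
well above nominal (14–24% at α = 0.05 across null generator settings, for
the Welch, pooled and permutation variants alike).  This is a property of
the prescribed statistic, not of a particular implementation; p-values
from `compare_groups` should be read as descriptive.  A calibrated
alternative would permute sample labels (Mantel-style) rather than pair
values.

**Clustering.**  Agglomerative clustering (correlation distance, average
linkage; constant profiles get maximal correlation distance) with edge
support from feature bootstrap: each replicate resamples bins (or
proteins) with replacement and support is the percentage of replicates
whose tree contains the same leaf set.  `multiscale=True` adds the
multiscale-bootstrap correction: bootstrap proportions at resampling
fractions r ∈ [0.5, 1.4] are extrapolated through the probit regression
z(r) = v√r + c/√r to the approximately unbiased support 1 − Φ(v − c).
Ordinary bootstrap proportions are the default because they are fully
specifiable and cheap; AU support is the fidelity upgrade used by the
pvclust lineage of tools.  Dendrograms serialize to Newick with support as
internal node labels.

## NSAF spectral counting

NSAF_p,s = (SpC_p,s / L_p) / Σ_q (SpC_q,s / L_q); columns sum to exactly 1,
zero counts give NSAF 0 with no pseudocounts.  For displaying a subset
(e.g. the 40 most abundant proteins by mean NSAF) values are re-normalized
within the subset.  Condition testing is a per-protein two-sample t-test
on NSAF values — paired by colony when every colony contributes exactly
one sample to each condition (the isolation design resampled the same
groups), Welch otherwise — with Bonferroni control over the tested family
(default: the number of proteins tested).  Zero-variance proteins are
skipped with a warning.

Because NSAF is compositional, a strong abundance increase in a few
proteins necessarily depresses the relative abundance of all others; in
the low-noise limit those secondary shifts are themselves significant
(direction "down").  Interpreting flag directions should keep this closure
effect in mind.

## Synthetic data: what it emulates, and what it does not

All generators draw from `numpy.random.default_rng` with a mandatory seed;
identical seeds give byte-identical outputs, and every emitted file uses
exactly the CSV dialect its consuming module reads (full-precision floats,
`float_precision="round_trip"` on read, so file round trips are lossless).

* **Ladder** (`gen_alkane_ladder`): C8–C40, 1.2 min uniform spacing from
  5 min, optional bounded spacing jitter — a stylized standard mixture
  under a linear gradient.
* **EI spectra** (`gen_ei_spectrum`): the full alkyl ladder with exact
  exponential envelope (A = 1000, λ = 0.02 /Da), diagnostic ions multiplied
  by the enhancement factor (default 5×), a weak parent ion, and optional
  multiplicative lognormal noise (default σ = 0.15).  *Not* emulated:
  the CₙH₂ₙ₋₁ satellite series, isotope envelopes, low-mass non-specific
  fragmentation, detector saturation.  Passing round-trip tests therefore
  show the inference is correct when the envelope model holds, not that it
  is robust to every real-spectrum artifact.
* **Cohort** (`gen_cohort`): five colonies × (fluid, body); a species-level
  set of 30 Gaussian peaks (σ = 0.02 min) at ≥ 0.4-min spacing in the
  36–51 min window; each sample includes each peak with the per-source
  sharing probability (fluid 0.9, body 0.5 by default — equal sharing is
  the null), lognormal amplitude jitter (σ = 0.3) and additive baseline
  noise (SD 0.01).  *Not* emulated: retention drift between runs, peak
  shape asymmetry, co-elution.
* **Counts** (`gen_count_matrix`): negative-binomial counts (size r = 5 by
  default — deliberately overdispersed to stress the t-test) with mean
  proportional to protein length × lognormal abundance, one sample per
  colony per condition (6 colonies), and a multiplicative effect (default
  5×) on 7.5% of proteins (3 of 40).  At these defaults the 5× effect is
  *not* reliably Bonferroni-detectable with n = 6 — the paired t statistic
  on raw NSAF sits near the corrected threshold — which is the realistic
  operating point; the low-noise limit (r → ∞, high depth) recovers all
  affected proteins, as the tests verify.

Simulation sizes used by the test suite (200 replicates for recovery
rates, 400 for error-rate calibration, 2 000 bootstrap replicates in the
analysis drivers, 10 000 as the library default for final figures) were
chosen so the Monte-Carlo error is small relative to each asserted margin.

## Tolerances and degenerate inputs

Pair-sum matching ±1 Da; series matching ±0.5 m/z; RI consistency ±15 RI
units; enhancement τ = 3 (all exposed in `ElucidationConfig`).  Flat
traces, zero-norm profiles, all-zero count columns, sub-4-member alkyl
series and λ ≤ 0 envelopes raise typed errors or warnings rather than
propagating NaNs.  Bin edges are anchored at 0.0 min so binning is
translation-consistent across samples; rounding of retention indices is
half-up.
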