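# Methods

This note records the models, numerical choices and validation strategy behind
`rxntriage`, in the spirit of a software methods section. It states nothing
that the test suite or `scripts/acceptance.py` does not itself compute.

## Scope and model of the decision problem

The package models the *analysis and decision* half of an autonomous
synthesis platform. Each reaction at each campaign stage is reduced to a pair
of binary verdicts — one from ¹H NMR, one from (UPLC-)MS — combined by a
conjunction: a reaction is a hit only when every applicable evidence branch
passes. A weighted combination (w_nmr·s_nmr + w_ms·s_ms ≥ 1) is implemented
for forward compatibility; its default weights (0.5, 0.5) reproduce the pure
AND rule exactly, so the default behaviour and the weighted machinery cannot
drift apart silently. Branches whose stage criteria are `none` (e.g. NMR at
MS-only diversification stages) are *not applicable* rather than auto-pass of
a measured branch: a stage must declare at least one active branch.

Stage flow is a small state machine: screen → scale-up (divergent) or
six-fold replication (supramolecular) → diversification or guest assay.
`plan_next` emits instructions only for logged hits; the decision log is
append-only and keeps failures, so a campaign is fully auditable after the
fact.

## Expected-chemistry enumeration

Molecular formulas are immutable element→count maps validated against the
NIST atomic-mass table shipped with pyteomics; monoisotopic masses (key 0 of
the table) are used for all m/z arithmetic, abundance-weighted average masses
are available for reporting. Adduct ions subtract the electron mass
(e.g. [M+H]⁺ = M + 1.007276).

Reaction transforms are formula deltas attached to role patterns: urea,
thiourea and CuAAC are pure additions; imine condensation removes one H₂O per
C=N bond formed; Sonogashira removes HBr. Route enumeration is stage-wise
combinatorial expansion, so library sizes are exact products of block-set
sizes (3 amines × 2 electrophiles = 6; × 2 diversifications = 12).

Metal–organic assemblies are enumerated as homoleptic, coordination-balanced
stoichiometries under maximal site occupancy: (m, l) with
m × capacity = l × topicity, where capacity is the number of bidentate
pyridyl-imine chelation sites per metal (3 for octahedral Zn²⁺, 2 for
tetrahedral Cu⁺) and topicity the number of primary amines per polytopic
amine. Solutions form the integer-multiple series of the minimal balanced
pair, capped at 10 metals for Zn²⁺ and 12 for Cu⁺. Mononuclear species are
included by default (`include_mononuclear=False` excludes them); published
enumeration rules for such screens are not standardized, so both conventions
are one switch apart. Net charge is Q = m × metal charge; each assembly's
charge ladder holds exactly Q values, m/z(z) = (M + (Q−z)·M_ct)/z. The
counterion is a required configuration field (screening solvents and salts
vary); the synthetic campaigns use triflate (CF₃SO₃⁻, 148.95 Da
monoisotopic) as a realistic default choice.

## NMR processing

All spectra are interpolated onto a shared grid, 0–12 ppm at 0.002 ppm
(6001 points — the digital-resolution scale of an 80 MHz benchtop
instrument), solvent regions zeroed by masks, and max-normalized so decision
thresholds are dimensionless.

**DTW.** Classic dynamic programming with |a−b| local cost and symmetric
steps, banded (Sakoe–Chiba radius, default 5 % of length ≈ 0.6 ppm — wide
enough to absorb benchtop drift, narrow enough that resonances in genuinely
different positions cannot be aligned away). The numba kernel keeps the full
cumulative matrix so the optimal path length can be recovered; thresholds act
on distance/path-length. A pure-Python dynamic program with the same band
geometry serves as the oracle in tests (sequences ≤ 50 points).

**Thresholds.** The platform this models exposes thresholds per campaign and
fixes them on synthetic/pilot data; the numeric defaults here were calibrated
once against the synthetic generator at its default noise envelope and then
frozen. Measured normalized-distance distributions (10 seeds): changed
reactions 0.016–0.022, unreacted mixtures 0.0060–0.0062, true replicates
0.0047–0.0051, non-replicates 0.0087–0.0090. Defaults: chemical change
0.010, parity 0.0065 (the enforced ordering parity < change is a
configuration invariant). These separate the observed distributions by ≥ 27 %
relative margin on each side; they are configuration values, not constants.

**Peak picking.** Local maxima above 5 % of the spectrum maximum, merged
within 0.02 ppm, after a light Lorentzian apodization (2 Hz — one natural
linewidth) that prevents baseline noise riding on a peak flank from splitting
one resonance into several maxima. On noiseless spectra with separations
above three linewidths the planted peak count is recovered exactly
(property-tested).

**Line broadening.** Lorentzian convolution with exact per-cell kernel
integrals (arctan differences) rather than point samples — at benchtop
linewidths the half-width is only ~6 grid steps, where point sampling
composes poorly. The kernel is unit-sum-normalized and the output re-scaled
to the input's total intensity, so area is conserved to machine precision
even for kernels truncated at the spectrum edge; two successive broadenings
compose to the summed width within 0.1 % (Lorentzians are closed under
convolution).

**Guest binding.** Both spectra are broadened by 10 Hz (emulating fast
exchange), peaks are picked in the aromatic window (6.0–9.5 ppm) and kept
above 20 % of the tallest window peak — heavy broadening leaves ripple that
must not count as a resonance — and each host peak is paired with its nearest
counterpart. Any shift ≥ 0.02 ppm, or a major peak appearing/disappearing,
calls the guest bound. The window bounds and shift threshold are exposed
configuration.

## MS processing

Chromatographic peaks: prominence-based maxima (≥ 5 % of TIC maximum) on a
5-point moving average, merged within 0.05 min, integrated trapezoidally
valley-to-valley; "main" peaks carry ≥ 10 % of the summed peak area. Peak
spectra are TIC-weighted scan averages re-centroided into 0.1 Da bins.
Matching uses a 0.5 Da tolerance and a 2 % relative-intensity floor — unit
resolution single-quadrupole settings. Direct-injection runs are collapsed to
one time-averaged spectrum before table matching. The two-charge-state rule
(≥ 2 distinct (z, n) ladder values of a single assembly) is the false-positive
guard for table matching; matching is tolerance-monotone and is tested against
an exhaustive all-pairs oracle. Blank-subtraction exists as an optional hook
concept only; carry-over is treated as instrument hygiene, not computation.

## Synthetic data generator

The generator emulates the platform's measurements well enough to exercise
every decision path, with one campaign seed spawning named substreams (CRC of
the object's key path) so a single integer reproduces a whole campaign.

* NMR: sums of Lorentzians (default FWHM 2 Hz at 80 MHz) on the standard
  grid, Gaussian noise at 1 % of the tallest peak (within the ≤ 2 % envelope
  the recovery guarantees assume), and a global shift drift of σ = 0.003 ppm
  per acquisition emulating an unlocked magnet.
* LC-MS: Gaussian elution envelopes (σ = 0.05 min on a 2.5 min run — a 2 min
  gradient plus hold) carrying centroid stick spectra; direct injection uses
  constant envelopes. Background sticks in false reactions are rejection-
  sampled to stay ≥ 1.5 Da away from every table value, so "no assembly
  formed" is actually encoded in the data rather than left to chance.
* Planted truths mirror realistic outcome shapes: 2 true assemblies of 18
  combinations (a Zn₄L₄ cage binding 3 of 6 guests and a Zn₂L₃ helicate
  binding none), with failure modes including unreacted mixtures, an
  NMR-symmetric species with no matching ions, a single-charge-state
  coincidence, and an oligomer-like peak forest; and 5 of 6 successful
  (thio)urea condensations with scale-up and two diversifications each.

What the generator does **not** model: J-coupling multiplets, solvent
suppression artefacts, isotope patterns, detector saturation, retention-time
drift, or ion-suppression effects. Passing the synthetic recovery tests
therefore demonstrates the decision logic and its thresholds are coherent
under realistic noise and drift — not that the thresholds transfer unchanged
to any particular instrument; they are configuration for that reason.

## Validation strategy

Every numeric operation is checked against an independent oracle: hand-summed
atomic masses for formula arithmetic; mass conservation of all transforms
over 1000 random formulas (to 1 µDa); an exhaustive (m, l) double loop for
assembly enumeration over all 18 grid combinations; charge-ladder
completeness (|ladder| = Q, z + n = Q); a pure-Python DP for banded and
unconstrained DTW; an all-pairs scan for table matching; closed-form products
for route counts; and a full truth table plus randomized gate-soundness
checks for the decision layer. End-to-end, both campaign shapes must recover
their planted truths exactly — the supramolecular campaign over 20 seeds with
zero false positives (~45 s on one CPU; the problem sizes above were chosen
to keep the whole suite under a minute).

## Known limitations

* DTW parity is a global metric: a single sharp extra resonance contributes
  little normalized distance and can pass parity; substantial new features
  (broad or multiple peaks) are what the threshold is calibrated to catch.
* Peak counting on 80 MHz data is dispersion-limited; the MS branch of the
  AND rule is the intended guard against the resulting NMR false positives.
* The JCAMP-DX reader covers AFFN `(X++(Y..Y))` tables and simple NTUPLES
  real pages only (no SQZ/DIF compression); mzML is read (centroided MS1)
  but not written — the documented CSV dialects are the portable write path.
* No isotope-pattern scoring, charge-envelope deconvolution, retention-time
  prediction or MS/MS; no structure generation or retrosynthesis.
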