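# rxntriage

Heuristic reaction-outcome triage from orthogonal ¹H NMR and (UPLC-)MS
evidence, for autonomous exploratory-chemistry campaigns.

## The problem

Autonomous synthesis platforms screen dozens of reactions in parallel and must
decide — without a chemist in the loop — which ones worked. A single
characterization technique is not enough: some products give clean mass
spectra and messy NMR, others the reverse. `rxntriage` implements the
decision-maker for such a platform: each reaction at each campaign stage gets
a binary pass/fail grade from ¹H NMR and from (UPLC-)MS independently, and
only reactions that pass **both** orthogonal tests are hits that advance to
the next stage (scale-up, replication, diversification, or a host–guest
binding assay). The evidence heuristics are deliberately loose — they look for
*any* plausible product, not a specific signal — so that serendipitous
discoveries (unexpected self-assembled architectures, say) are not filtered
out by prior expectations.

The package targets three campaign shapes:

* **Divergent synthesis** (medicinal-chemistry style): screen combinatorial
  condensations, scale up hits, confirm scale-up parity, then diversify
  (Sonogashira coupling, CuAAC "click").
* **Supramolecular discovery**: screen amine × carbonyl-pyridine × metal
  combinations for self-assembled cages/helicates, replicate hits six-fold,
  then assay guest binding by chemical-shift perturbation.
* **MS-only grading** for stages where low-field ¹H NMR is uninformative
  (diversification products, photochemistry screens).

## The decision heuristics

**NMR.** Spectra live on a common ppm grid (0–12 ppm, 0.002 ppm step,
max-normalized). Two comparisons drive decisions:

* *Chemical change* — dynamic time warping (DTW) distance between the
  reaction spectrum and the weighted sum of starting-material spectra, with
  absolute-difference local cost and a Sakoe–Chiba band (5 % of length).
  The normalized distance d = D/|path| is thresholded: d > 0.010 ⇒ a chemical
  change occurred; a *tighter* threshold (d ≤ 0.0065) confirms scale-up or
  replicate parity. DTW tolerates the small shift drifts of an unlocked
  benchtop magnet while penalizing genuinely new or missing resonances.
* *Symmetric-product test* — for self-assembly screens: the reaction must show
  a peak count comparable to the **sum** of the starting-material peak counts
  (± 2) with most peaks at *new* chemical shifts (≥ 0.02 ppm from every
  starting-material peak). This selects single symmetric architectures and
  deselects both unreacted mixtures and oligomer-like peak forests.
* *Guest binding* — after heavy Lorentzian line broadening (10 Hz, emulating
  fast exchange), any aromatic-window (6.0–9.5 ppm) peak that moves ≥ 0.02 ppm
  (or appears/disappears) upon guest addition calls the guest "bound".

**MS.** For gradient UPLC-MS runs, the total-ion chromatogram is peak-picked
(prominence on a smoothed trace, valley-to-valley trapezoidal areas), the
spectra under each *main* peak (≥ 10 % relative area) are averaged, and the
anticipated product m/z values ([M+H]⁺, [M+Na]⁺, [M+NH₄]⁺) are matched within
0.5 Da. For direct-injection supramolecular screens, the time-averaged
spectrum is matched against a precalculated look-up table of every
coordination-balanced assembly [MₘLₗ]^Q+ (Q = m × metal charge, m×capacity =
l×topicity, up to 10 Zn²⁺ / 12 Cu⁺) and its full counterion charge ladder

```
m/z(z) = (M + (Q − z) · M_counterion) / z,   z = 1 … Q .
```

To guard against chance matches in a table this large, a spectrum passes only
if **at least two different charge combinations** of one assembly are present.

## Worked example

Run the built-in synthetic supramolecular campaign (18 screening combinations,
seeded, ground truth planted by the generator — see `docs/methods.md`):

```bash
rxntriage run-campaign --scenario supramolecular --seed 7 --out results/supra7
```

prints

```
{"hits": ["24+28+Zn", "24+29+Zn"], "replicate_instructions": 12,
 "assay_instructions": 12, "bound_per_host": {"24+28+Zn": 3, "24+29+Zn": 0}}
```

Two of the 18 combinations pass both the symmetric-product NMR test and the
two-charge-state MS rule: the tritopic amine **28** gives the tetrahedral cage
`[Zn4(24_3,28)4]^8+` and the ditopic amine **29** the helicate
`[Zn2(24_2,29)3]^4+`. Each hit fans out into six replicate instructions
(12 total); after all replicates pass DTW parity and the MS test, the binding
assay finds that three of six guests shift the cage's aromatic resonances
while none perturb the helicate — the matrix written to
`results/supra7/binding.csv`, the full decision log (hits *and* failures) to
`results/supra7/decisions.jsonl`.

The m/z ladder behind the cage hit, from the enumeration engine:

```python
>>> from rxntriage.synthgen import default_supramolecular_blocks
>>> from rxntriage.chemspace import enumerate_assemblies, mz_series
>>> b = default_supramolecular_blocks()
>>> cage = enumerate_assemblies(b["24"], b["28"], b["Zn"], 10)[3]
>>> cage.label, round(cage.mass(), 2)
('[Zn4(243,28)4]8+', 1908.65)
>>> [(z, n, round(mz, 2)) for z, n, mz in mz_series(cage, b["OTf"])[:4]]
[(1, 7, 2951.31), (2, 6, 1401.18), (3, 5, 884.47), (4, 4, 626.11)]
```

The divergent campaign works the same way
(`rxntriage run-campaign --scenario divergent --seed 2 --out results/div2`):
5 of 6 (thio)urea condensations pass screening, all 5 scale-ups pass parity,
and 10 diversification reactions (5 hits × {Sonogashira, CuAAC}) are planned
and graded by UPLC-MS alone.

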