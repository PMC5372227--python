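# Methods

## Model and assumptions

`gapstitch` operates downstream of deconvolution: every input peak is assumed
to be a neutral monoisotopic fragment mass of the analyzed protein, and the
precursor mass its intact neutral mass. The central assumption is that the
errors of two nearby fragment masses within one spectrum are similar, so the
*difference* of two peak masses matches a residue mass to a tight constant
tolerance (2ε = 8 mDa) even when the absolute calibration is worse. Offsets
of tags (leftmost-peak masses) can be large and carry larger errors, and the
same offset difference can arise from small or large offset pairs; gap
estimation therefore never compares offsets at a fixed tolerance but bins
offset *differences* at two resolutions (10⁻⁴ Da and 1 Da) and works with
multiplicities.

All sequence masses are pure residue-mass sums (no terminal water, no
ion-type constant). This is deliberate: a constant term shared by the two
tags of a pair cancels in their offset difference, so prefix-type and
reflected (suffix-type) series both yield correct separating masses without
the package ever knowing which ion types it is looking at. I and L are
isobaric and always reported as L.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| k | 4 | residues | tag length; longer tags are more specific but rarer |
| ε | 0.004 | Da | tag tolerance; edges require a residue match within 2ε |
| Gmax | 3000 | Da | largest acceptable gap (≈ 27 residues) |
| Bmin | 20 | — | minimum multiplicity of a candidate binned difference |
| Amin | 6 | residues | minimum coverage of each string by supporting tags |
| εabs | 10 | ppm | offset-comparison tolerance in the embedding overlap check |
| h | 4 | — | scaling exponent; scaled differences live at 10⁻⁴ Da |

`m* = Amin − k + 1` is the number of distinct k-tag windows needed to cover
Amin residues of a string. The support rule accepts counts (≥m\*, ≥m\*), or
(≥m\*+1, ≥m\*−1) in either order; failing that, if both counts are ≥ m\*−1
and a neighbouring bin (±1 Da) occurred with counts (≥m\*−1, ≥m\*) in either
order, the estimate is still accepted. The "either order" reading of the
unbalanced clauses is this package's choice: nothing distinguishes the two
strings' roles, so a symmetric rule avoids an arbitrary asymmetry.

## Numerical choices

- **Rounding** is half-away-from-zero for both scaled and binned
  differences, and the binned value is derived from the scaled one so that
  every scaled difference maps to exactly one bin.
- **Ties**: among equally multiplicitous bins, the top three-bin score wins
  and remaining ties go to the smallest bin; within the winning bin, the
  modal scaled difference wins, ties again to the smallest value. In the
  spectrum-graph dynamic program, equal-score paths are resolved by the
  smaller starting-peak mass, then lexicographically by edge labels. All tie
  rules exist purely for determinism.
- **Raw differences are kept exact** until binning; only float-identical
  values are merged early. This avoids double rounding and makes the
  reversal symmetry `T(s1,s2) = T(s̄2,s̄1)` hold to the last bit (both sides
  evaluate the same shift expressions on the same strings).
- **Candidate selection is single-shot**: if the best bin fails the support
  check the pair is rejected rather than falling back to a weaker bin. A
  weaker bin that could not win the multiplicity contest is poor evidence
  for a gap, and the iterative assembly will revisit the pair anyway if new
  evidence arises from other merges.
- **Water-loss removal** only deletes a peak whose putative parent (at
  +18.0106 Da) is at least as intense; deleting a peak more intense than its
  parent would more likely destroy real signal than remove an artifact. The
  removal runs before reflection so loss artifacts are not duplicated.
- **Embedding** accommodates a guest path into a host gap when the gap
  estimate covers the guest's total mass within the ppm tolerance
  (`|a − b| ≤ εabs·10⁻⁶·max(a, b)` on offsets measured from the host's
  origin); the remainder becomes a trailing gap, clamped at zero when within
  tolerance. The first qualifying gap wins.

## The synthetic generator

The generator emulates what the real pipeline consumes, not the physics that
produces it. A simulated spectrum covers a contiguous window of a known
protein (full-length by default, as for intact-protein fragmentation); each
interior cleavage site emits, with probability 0.8, a peak at the cumulative
residue-mass prefix sum, with 1 mDa Gaussian error (well inside ε) and
log-normal intensity; with a configurable probability a peak is further
shifted by exactly ±1 Da, mimicking wrong monoisotope assignment during
deconvolution. The precursor is the window mass plus water, so the package's
own reflection step reconstructs the complementary (suffix-type) series.
Fragment strings are non-overlapping substrings with known separating
subsequences; each is reversed with probability 0.5 by default, since
aggregated de novo fragments carry no orientation.

What the generator does *not* model: charge-state envelopes and deisotoping
artifacts other than ±1 Da, intensity physics (fragmentation propensities),
chimeric spectra, PTMs, and contaminants beyond an optional second
independent protein. Passing tests on this generator therefore demonstrate
the correctness of the tagging/convolution/assembly logic and its robustness
to dropout, small mass error, ±1 Da shifts, and orientation flips — not
performance on real instrument data.

A consequence of modelling ±1 Da errors per peak: a surviving k-tag needs
k+1 shift-consistent consecutive peaks, so most surviving tags are unshifted
and the ±1 Da neighbour bins stay sparse; coherently shifted runs do occur
and are absorbed by the three-bin score, which is exercised directly in the
tests.

## Known failure mode

When one string is tested in the wrong orientation against the other,
prefix-series tags of one string can pair with reflected-series tags of the
other; the shifts then cancel the positional terms and every such pair
contributes one and the same spurious value (water + intact mass − the two
fragment-end prefix masses), which can reach a convincingly high
multiplicity. Whenever that constant falls outside `[0, Gmax]` — the usual
case — it is filtered, but for fragment pairs placed so that it lands inside
the window, a wrong-orientation combination examined before the correct one
can win. This is an inherent property of the method (correlated b/y tag
pairs), not of this implementation; recognizing such joins requires
inspection of the assembled scaffolds against other evidence.

## Problem sizes

The test suite's parameter-recovery experiments use a 300-residue protein,
200 full-length spectra at coverage 0.8, and four 40-residue fragments with
8/12/16-residue gaps; replicate counts are 50 for the ±1 Da and
negative-control experiments. These sizes give every gap bin a multiplicity
in the thousands — two orders of magnitude above Bmin — which is the regime
the method is designed for, while keeping the whole suite around a minute of
runtime. The recovery experiments keep orientation flips off so that they
measure gap-estimate accuracy in isolation; orientation handling is
exercised by dedicated all-flipped end-to-end tests.
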