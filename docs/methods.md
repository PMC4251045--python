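# Methods

## Model and assumptions

`xlpm` identifies inter-peptide cross-links by exhaustive candidate
enumeration: the search space is every unordered pair of tryptic peptides
(self-pairs included, since homodimeric complexes genuinely produce links
between two copies of the same peptide) whose residues can react with the
two ends of the cross-linker. The method assumes

* centroided MS/MS peak lists (MGF) from collision-induced dissociation;
* fragmentation into plain b/y series — a/c/x/z ions, immonium and internal
  ions, neutral losses and isotope envelopes are ignored;
* that a cross-linked residue behaves like a residue carrying a modification
  of mass `M(partner chain) + Δ(bridge)`, so fragments spanning the link site
  shift by that amount and fragments on the other side do not;
* the mobile-proton picture for high-charge cross-linked precursors: protons
  do not cross the bridge, so a 4+ pair fragments like two roughly 2+
  peptides. This motivates both the charge-partitioned fragment search (b at
  charge `z_b`, complement y at `z_p − z_b`) and the simulator's charge model.

## Mass conventions

All masses are monoisotopic (residue masses and elemental compositions from
the standard tables shipped with pyteomics). Charge arithmetic uses the
hydrogen-*atom* convention, `M = z·(m/z) − z·1.007825`, which is the
convention the published precursor-mass anchors reproduce to their printed
precision. Bridge deltas: DSS `C8H10O2` = 138.06808 Da (both NHS esters
displaced); SDA `C5H6O` = 82.04186 Da (NHS displaced at the amine end, N₂
lost on diazirine photolysis, carbene inserted at the other). The published
result tables this package was validated against carry a constant ≈ +0.016 Da
offset in their *calculated*-mass column relative to standard monoisotopic
arithmetic; the implementation therefore standardizes on the values above and
validates against *observed* precursor masses, where agreement is within
2 ppm. Full ¹⁵N metabolic labeling shifts each chain by 0.9970349 Da per
nitrogen atom, counted from residue elemental composition; reagent-derived
modification nitrogens (e.g. carbamidomethyl) are treated as unlabeled
because they do not come from the growth medium.

## Candidate filters

Three rules prune digested peptides before pairing: length < 3; no linkable
residue for either linker end; and the forced-missed-cleavage rule — a
peptide whose *only* linkable residue is its C-terminal cleavage residue is
removed, because a cross-link there would have blocked proteolysis, so the
true cross-linked species must be the longer missed-cleavage form (which the
digest, run with missed cleavages allowed, already contains). The protein
α-amine counts as an amine-reactive site whenever a peptide starts at
protein position 1; it is encoded as a distinct `N-term` token rather than
position 0, and its mass contribution travels with residue 1 in fragment
ladders. Variable modifications expand combinatorially with a configurable
cap (default 2 per peptide) to bound database size. Mixed ¹⁴N/¹⁵N pair
variants are enumerated only when a run is declared a labeling experiment;
the default is single-label.

## Scoring

`score = N_mb/N_tb + (N_my/N_ty)·(1/R_yb(z))`, counts only — intensities are
not used. A fragment position counts once toward `N_mb` regardless of how
many charge states matched, keeping `N_mb ≤ N_tb` well defined; a
complementary y ion is only ever *sought*, at the remaining charge, for a b
ion that matched, so `N_my ≤ N_mb` by construction. Fragment matching is
nearest-peak within an absolute Da tolerance without peak consumption (one
observed peak may satisfy several theoretical ions). The `1/R_yb` weight is
applied to the y term only: `R_yb` is defined as a y-to-b ratio correction,
so dividing the b term by it too has no justification — the alternative
global grouping remains available via `score_grouping="global"` for
comparison. Site localization evaluates every compatible (site A, site B)
assignment, returns the maximum, and breaks ties toward the
lexicographically smallest assignment while recording all co-optimal
assignments in an ambiguity flag.

### Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| precursor tolerance | 10 | ppm | Orbitrap-class precursor accuracy |
| fragment tolerance | 0.5 | Da | ion-trap CID; use 0.02 for FT-acquired fragments |
| `R_yb` table | {2: 0.50, 3: 0.40, 4: 0.30, 5+: 0.25} | — | explicit placeholder, *not* library-derived; regenerate with `xlpm by-stats` from any annotated MSP library. The table is echoed into the run manifest because scores are meaningless without it |
| max missed cleavages | 2 | — | one forced by the cross-link plus one genuine miss |
| variable-mod cap | 2 | per peptide | bounds combinatorial expansion |
| assumed charges (no CHARGE in MGF) | 3–8 | — | cross-linked precursors ionize at 4+ and higher; 3 retained as a margin |

## R_yb estimation

For each annotated library spectrum, every annotated b ion with charge below
the precursor charge contributes one unit to the denominator (per-ion
counting, matching the ratio's definition); the numerator counts those whose
complementary y ion at the remaining charge is annotated in the same
spectrum. Spectra with no qualifying b ion are excluded. Medians are taken
per precursor-charge bin {2, 3, 4, 5+} (five-and-higher pooled); empty bins
are omitted and covered at search time by nearest-charge fallback. Only plain
b/y annotations count — neutral-loss, isotope and internal-ion annotations
are set aside at parse time.

## FDR and the relaxed-specificity ROC

Targets and decoys (whole-protein sequence reversal) are searched
*separately*, and the FDR estimate at threshold t is
`#{decoys ≥ t} / max(1, #{targets ≥ t})` — the estimator matching the
separate-search design, not the 2d/(t+d) concatenated form. q-values are the
running minimum of this estimate from the lowest score upward, hence
monotone. Because the database filters (no linkable site, forced missed
cleavage, length < 3) apply identically to target and decoy, the two
databases have similar composition, but the small number of true cross-links
means a few decoy hits move the estimate substantially; thresholds should be
read conservatively.

The relaxed-specificity ROC validates localization: a specific amine-amine
linker is re-searched with one end non-specific, each identification is
labeled by whether its localized sites all fall on truly reactive residues
(Lys or the α-amine), and the ROC sweeps the score threshold. The curve is
built with scikit-learn's threshold sweep; tied scores appear as diagonal
segments, so the trapezoidal AUC equals the Mann–Whitney pair-comparison
probability with half-credit for ties (a property the tests verify against
an exhaustive oracle).

## The simulator

`xlpm.synthetic` generates CID spectra of cross-linked pairs with ground
truth. For each backbone cleavage of each chain, a b charge is drawn
uniformly from `1..z_p−1`; the b ion is emitted with probability
`detect_prob` (default 0.8) and, when emitted, its complementary y at the
remaining charge follows with a per-charge coupling probability (defaults
0.70/0.55/0.40/0.30 for 2/3/4/5+, falling with charge as annotated libraries
show). Noise peaks are uniform on [200, 2000] Th (default 20 per spectrum),
peak positions jitter uniformly within ±0.2 Da, precursor charges are drawn
from {4, 5, 6}, and intensities are exponential with unit mean — arbitrary,
since scoring is count-based. All randomness flows from one integer seed,
recorded in the truth-table header.

What the simulator does *not* emulate: physically realistic intensities,
isotope envelopes, co-isolated (chimeric) precursors, non-b/y ion chemistry,
and correlated noise near fragment masses. Passing closure tests therefore
demonstrate the bookkeeping (mass arithmetic, charge partitioning, site
localization, label assignment) is correct under the stated noise model, not
that real-spectrum identification rates will match.

## Numerical and design choices

* Peak lookup is binary search over the sorted m/z array; nearest peak within
  tolerance, no tie-breaking needed since only presence is tested.
* Candidate pairs are deduplicated on a canonical chain ordering (sequence,
  protein, coordinates, modifications, label), making the database invariant
  to input peptide order; results sort by score descending then scan id, so
  repeated runs are byte-identical.
* The Ryb median is clamped below at 1e-3 to keep `1/R_yb` finite in
  degenerate calibrations.
* `m/z` round-trips neutral mass to 1e-9 relative; out-of-range sites,
  unknown residue letters (with position), non-positive masses and charges
  raise `ValueError` early.
* Result tables print the eight conventional columns first (m/z, the two
  sequences, calculated and precursor mass, charge, score, linked protein
  coordinates), followed by site residue letters, scan id, label combo and a
  decoy flag needed by the validation tooling.

## Problem sizes used in the test suite

Digest-vs-brute-force equivalence runs 1,000 random proteins of up to 60
residues; end-to-end recovery plants 200 spectra under the default noise
model (≥ 95% rank-1 required); the null-ROC and Ryb-recovery checks use
2,000 simulated spectra (±0.05 tolerance). These sizes give stable
statistics for the stochastic checks while keeping the suite fast.

## Known limitations

Mono-links and loop-links are not modeled; protein-level FDR is out of
scope (validation operates at spectrum/pair level); only b/y series are
searched (a c/z variant for ETD would be a mechanical extension); average
masses are not supported; and the shipped default `R_yb` table is a
placeholder that should be replaced by a library-derived one for any serious
comparison of scores.
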