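# xlpm — cross-linked peptide search with a b → complementary-y filter

Chemical cross-linking mass spectrometry maps protein–protein contacts:
a bifunctional reagent (e.g. the amine-reactive DSS, or the photo-activatable,
semi-specific SDA) covalently bridges two residues, the protein is digested
with trypsin, and the cross-linked peptide *pairs* are identified from their
MS/MS spectra. These species are rare, carry high precursor charges (4+ and
above), and — when one linker end is non-specific — explode the search space.
`xlpm` is a search engine for exactly this problem, aimed at the few-protein
scale (purified complexes, in-vitro cross-linking).

## The method

1. **Candidate database.** Proteins are digested in silico; peptides shorter
   than 3 residues, peptides with no linkable residue, and peptides whose only
   linkable residue is their C-terminal cleavage residue (a cross-link there
   would have blocked proteolysis — the *forced missed cleavage* rule) are
   removed. All remaining unordered peptide pairs, including self-pairs, form
   the candidate database, with masses
   `M(pair) = M(A) + M(B) + Δ(bridge)` (DSS: Δ = 138.06808 Da; SDA after
   photolysis: Δ = 82.04186 Da). Optional ¹⁵N metabolic labeling adds
   0.9970349 Da per nitrogen atom, per chain, enabling mixed ¹⁴N×¹⁵N pairs
   that prove inter-complex contacts.
2. **Precursor matching.** Observed precursors are converted to neutral mass
   (`M = z·(m/z) − z·m(H)`, hydrogen-atom convention) and matched against the
   database within a ppm tolerance.
3. **The b → complementary-y filter.** For each candidate site assignment the
   partner chain plus bridge is treated as a modification on the linked
   residue. Theoretical b ions of both chains are matched at every charge
   below the precursor charge; whenever a b ion is found, the spectrum is
   searched for the complementary y ion at the *remaining* charge (b and y
   fragments share the precursor's protons). Observing the complement is
   strong evidence of a high-quality match.
4. **Score.**
   `score = N_mb/N_tb + (N_my/N_ty) · 1/R_yb(z)`,
   where `N_mb`/`N_my` count matched b ions and complementary y ions,
   `N_tb = N_ty` is the number of backbone cleavages of both chains, and
   `R_yb(z)` is the per-precursor-charge median complementary-y/b ratio
   estimated from an annotated linear-peptide library (`xlpm by-stats`).
5. **Localization and validation.** The best-scoring site assignment is
   reported (ties flagged as ambiguous); FDR is controlled with a separately
   searched reversed-sequence decoy database; and site assignment itself is
   validated by the *relaxed-specificity ROC*: a specific linker is searched
   as non-specific, localizations off the known-reactive residues count as
   false positives, and the score threshold is swept.

A seeded simulator (`xlpm simulate`) generates CID spectra of cross-linked
pairs with ground truth, so the whole pipeline is testable end to end.

## Worked example

```sh
cat > toy.fasta <<'EOF'
>protA
MDFSKLEDAKGTTLSKVQRYLKYSIASQPR
>protB
MAKWDDGSKGTRVEANKFLHKSR
EOF
xlpm simulate --fasta toy.fasta --n 20 --seed 7 --out sim.mgf --truth truth.tsv
xlpm search   --mgf sim.mgf --fasta toy.fasta --linker DSS --ppm 10 \
              --frag-tol 0.5 --out results.tsv
xlpm search   --mgf sim.mgf --fasta toy.fasta --decoy --out decoys.tsv
xlpm validate --results results.tsv --decoy-results decoys.tsv --fdr 0.05
```

prints

```
wrote 20 spectra to sim.mgf (truth: truth.tsv)
reported 20 identifications (20 precursor matches)
reported 1 identifications (1 precursor matches)
score threshold at 5% FDR: 0.15
targets kept: 20 / 20 (decoys: 1)
```

and the top of `results.tsv` reads

```
m/z           Sequence 1      Sequence 2      Calculated mass Precursor mass  Charge  XLPM score   Cross-linked residues
711.7982563   VQRYLKYSIASQPR  VQRYLKYSIASQPR  3553.952156     3553.952156     5       3.076923077  22-22
529.8081166   GTTLSKVQR       GTTLSKVQR       2115.201166     2115.201166     4       2.666666667  16-16
```

Twenty simulated spectra were searched; all twenty planted pairs were matched
by precursor mass and scored. The single decoy hit (score 0.15) sets the 5%
FDR threshold, which keeps every target. The first row is a homodimeric
cross-link between the lysines at protein position 22 of two copies of the
same peptide — its score of 3.08 decomposes as 24 of 26 b ions matched
(24/26 ≈ 0.92) plus 14 complementary y ions found, up-weighted by the default
`1/R_yb(5+) = 4` (14/26 · 4 ≈ 2.15).

The same objects are available as a library:

```python
from xlpm import DSS, SearchConfig, read_mgf, read_fasta
from xlpm.pipeline import run_search

rows, manifest = run_search("toy.fasta", "sim.mgf", SearchConfig(), DSS)
```

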