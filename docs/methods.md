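# Methods

## The dual-decrementation model

The package models a 70-residue polypeptide proteoform ("sSgII-70",
assembled by peptide splicing of secretogranin II modules: master residues
367–375 followed by 178–238) whose MALDI-TOF signature is not one ion but a
family of them. Two independent loss processes generate the family:
C-terminal residue loss (70mer down through shorter *n*-mers) and loss of
integer numbers of water molecules. A *ladder* is the complete grid of
predicted species over a mer range and water cap; an observed peak list is
explained by assigning each peak to its nearest grid cell.

Species conventions, fixed by the published tables and validated against
them cell-for-cell:

* truncated *n*-mers are **b-type**: Σ(residues 1..n) + 1.008 Da, i.e.
  17.007 Da below the hydrolysed peptide. The full-length row alone is the
  hydrolysed peptide (Σ + 18.015). The tables offer no chemical mechanism
  for this asymmetry; we reproduce the printed arithmetic without asserting
  one.
* protonation adds exactly 1.008 Da; C-terminal-loss matching uses MH⁺
  cells, N-terminal-loss matching uses unprotonated cells (both published
  polarities).
* water columns subtract 18.015 Da per step, capped at eight by default
  (the published grid has eight water columns); deeper losses require an
  explicit larger cap.
* dimers and multimers share a single charge: MH⁺ + M(+M…), i.e.
  MH⁺ + (m−1)(MH⁺ − 1.008).

Mass arithmetic uses the Expasy average residue-mass table held as exact
decimals, so residue sums never drift through binary floating point.

## Exact versus printed masses

Every ladder cell carries an exact mass and a *printed* two-decimal mass.
The published grids were evidently produced from two-decimal Expasy MW
displays with spreadsheet-style chained subtraction, and the package
mirrors that reporting pipeline exactly:

1. `MW_disp = round₂(Σ residues + 18.01524)` — the MW display of the
   hydrolysed *n*-mer;
2. truncated-row M column: `round₂(MW_disp − 18.015 + 1.008)`; the
   full-length M column is `MW_disp` itself;
3. MH⁺ column: `round₂(M_disp + 1.008)`;
4. water columns: repeated subtraction of 18.015 from the *displayed* MH⁺,
   rounded at each step with two-decimal ties resolved downward (the
   behaviour of binary-float spreadsheet displays).

With this convention the package regenerates 109 of the 110 printed grid
cells, all twelve printed peak matches (hence the caption statistics
exactly), all seven minor-peak matches, and the published N-terminal match
values. The single irreproducible cell is the 69mer row's M entry: as
printed, that row's M (8044.84) and MH⁺ (8045.86) differ by 1.02 rather
than the header's 1.008, so they are mutually inconsistent and no
arithmetic can reproduce both; the package follows the MH⁺ (which the
row's eight water columns chain from) and regenerates M as 8044.85.

Fit statistics are computed from the printed (two-decimal) match values,
which is how the source tallied them; assignment *selection* (nearest cell,
ties to fewer waters then larger mer) uses exact masses. The default
acceptance window is 10 Da — no cutoff is stated in the source, and the
largest published accepted deviation is 7.84 Da. The "chi-squared" figure
is the raw quantity Σ(O−M)²/M, which reproduces the printed 0.024 and
0.016; it is exposed as `chi_sq_quantity`, not a p-value, since no
degrees-of-freedom referral is stated.

## The 70mer sequence

The canonical sequence is

```
MLKTGEKPVFKRTNEMVEEQYTPQNLATLESVFQELGKLTGPNNQKHERADEEQKLYTDDEDDIYKANNI
```

reconstructed from printed constraints: the tryptic fragments fix residues
1–11, 39–49 and 50–66; the C-terminal-loss column fixes 61–70; the
charged-residue census fixes the ten basic and fifteen acidic positions;
Edman coverage fixes M16, Q20, Y21, S31, V32, G37 and K38; and the
secretoneurin region supplies the template for 13–45. The reconstruction
reproduces every published mass (full-length 8175.01 Da and MH⁺ 8176.02,
all grid rows, all minor peaks, all digest fragments, the N-terminal match
values, and the low-mass ramp integers 699/1061/1133/1153). One residue is
fixed only to composition: the template requires a single substitution
27.0256 Da heavier (S→N or T→Q) at position 22, 25 or 28, and no printed
quantity distinguishes the three sites; N25 was chosen on homology
grounds. Any of the three choices yields identical numbers everywhere.

The packaged master protein is a *synthetic* scaffold whose segments
178–238 and 367–375 are the true proteoform modules, letting
`splice_proteoform` be exercised against the real coordinates; the genuine
database record is not redistributed. The scan-census totals of the real
ovine proteome depend on a TrEMBL snapshot and are documented, not tested.

## Digestion

Trypsin cleaves after K/R except before P. The proline rule is required:
the N-terminal fragment TGEKPVFK spans its internal K–P bond with zero
missed cleavages only under the rule. Met-sulfoxide variants (+15.9994 Da
per oxidised Met) are generated as separate candidates; the 14mer control
peptide yields seven predicted fragments once its two sulfoxide variants
are counted, matching the published count and the printed 1002/1018 Da
values. Ambiguous digest assignments are resolved by fewer oxidations,
then smaller deviation, then fewer missed cleavages — unmodified
assignments are preferred over modified ones when both fit, as in standard
fingerprinting practice and as required to reproduce the published primary
assignment for the 1298.04 peak (the sulfoxide alternative is preserved as
a secondary candidate). Default matching tolerance is 4 Da, admitting the
largest printed digest difference (+3.625).

## Motif census and exclusion scan

The census counts motif-bearing proteins (overlapping occurrences counted;
configurable), total occurrences, and the candidate anchor-Met pool.
"Discounting initiator methionines" is implemented as excluding residue 1
of every protein when it is M — the simplest reading consistent with the
published census sentence. The exclusion scan slides an 11-residue
M-anchored window over motif-bearing proteins, rejects windows whose
positions 2–11 contain any residue outside the reference alphabet
(ARNDCQHISWY plus M forbidden), and scores survivors by distinct reference
residues covered (1–9). Candidates are ranked by score, ties by protein id
then position.

## Shuffle statistics

The Edman output is treated as a shuffled deck: `rising_sequences` counts
maximal runs of consecutive face values (1 + the number of descents in the
value-position map); after *s* riffles a deck has at most 2^s rising
sequences. `riffle_reachable` decides reachability by exact search — one
riffle's results are enumerated as all cut/interleaving merges, and the
final step is tested against the target's un-riffle preimages (all 2ⁿ
subsequence splits), keeping two shuffles of a 14-card deck under a
second. Selection probabilities are exact rationals over C(14,5) = 2002
unordered draws. The Gilbert–Shannon–Reeds model (binomial cut, drops
proportional to remaining packet sizes) provides the null distribution of
signatures; simulations are deterministic under a mandatory seed.

## Synthetic data

`simulate_peaklist` forward-models the study's artefact taxonomy: each
recipe event is a (mer, waters) cell emitted as a monomer, homodimer or
stacked multimer, with Gaussian m/z noise (default sd 0.5 Da; the source
states no error model and its accepted deviations reach ~8 Da), log-normal
intensities, and uniform contaminant peaks. `simulate_proteome` emits
decoy proteins with i.i.d. residues at controlled frequencies, an
initiator M, and planted candidate windows at recorded interior positions;
`ensure_motif` writes the epitope motif into host proteins so
motif-restricted scans keep them in the pool, as the real candidate
protein does. Both generators return truth tables and are deterministic
under their seeds.

What the generators do not emulate: calibration drift and mass-dependent
error, peak-shape/centroiding effects, matrix-cluster chemistry, isotope
envelopes, adducts, multiple charging, and realistic proteome composition
(homology, domain structure, length/frequency correlations). Passing
recovery tests therefore show the assignment logic is sound under the
model's own assumptions, not that the model is true of any real spectrum.

## Problem sizes and numerics

The test suite and the acceptance script use: ladders of 7–70 mers × 9
water columns (≈1 200 cells), 1 000-peak randomised oracle comparisons,
10⁴ Gilbert–Shannon–Reeds replicates on 52 cards, 100 seeded spectra
(8 species + 5 contaminants, sd 0.3) and 100 seeded decoy proteomes of 150
proteins for planted-window recovery — sizes chosen so the full suite runs
in well under a minute on one core while leaving the stochastic assertions
(≥95 % recovery, modal signature 4, 100/100 rank-1 recovery) far from
their thresholds. pI is found by bisection on [0, 14] with the
Expasy/Bjellqvist pKa set to a 0.005 pH tolerance; the net charge at the
returned pH is within ±0.01 charge units of zero.

## Known limitations

* The printed 69mer-row inconsistency and the published formula's hydrogen
  count (129, incompatible with the published MW 1618.95, which demands
  123) are followed to the arithmetic, not the misprint.
* Position 25 of the 70mer is certain only to composition (see above).
* The published heterodimer example is 15 Da from its own calculated sum,
  outside the default window; recovering it requires an explicit window of
  about 20 Da.
* Monoisotopic masses and post-translational modifications other than Met
  oxidation are out of scope, as are raw-spectrum processing and database
  retrieval.
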