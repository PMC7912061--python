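# Methods

## Scope and model

The package treats the desk analysis of an enzymatic protein hydrolysate as
a pipeline over four quantities: theoretical peptide masses, encrypted
bioactive fragments, sequence novelty, and assay arithmetic. MS acquisition
and database searching are out of scope — the pipeline starts from an
identification table (accession, sequence, reported MW) and a local
bioactive-peptide reference file standing in for a curated online database.

## Mass computation and reconciliation

Monoisotopic mass is the sum of standard residue (water-loss) masses plus
one water (18.01056 Da); residue masses come from pyteomics to full
precision. Average mass is provided for convenience; the packaged table's
printed values are monoisotopic (average masses disagree by >0.3 Da on
hand-checked rows, monoisotopic agrees at 2 dp on all eight).

Reported masses are compared at a tolerance of ±0.011 Da on unrounded
values: one unit in the last printed (2-dp) place plus margin for either
rounding convention. Display rounding is half-up (printed tables round
628.345 to 628.35), implemented with decimal arithmetic; full precision is
kept internally.

Residuals outside tolerance are searched against a modification catalogue
(shipped as an editable TSV resource): deamidation +0.98402 (N/Q),
oxidation +15.99491 (M/W), N-terminal acetylation +42.01057 (any peptide),
carbamidomethylation +57.02146 (C), dehydration −18.01056 (S/T/E/D). This
is the smallest set explaining the common search-engine deltas seen in the
packaged table. The search is over subsets of size ≤ `max_mods` (default 1:
parsimonious, and multi-modification combinations explode combinatorially);
the smallest explaining subset wins, ties broken by smallest absolute
mismatch, then lexicographic modification names, so results are
deterministic. Applicability is a containment check (the peptide must
contain an eligible residue), not a site assignment — the reported MW does
not localize the modification, so the package does not pretend to.
Cysteine is treated as free by default: the packaged table's only
C-containing row (SVGPCKSHRESLGGLPE, 1751.86) matches without
carbamidomethyl. Leucine/isoleucine are never disambiguated; they are
isobaric and both accepted.

On the packaged 114-row table this yields 95 `match`, 15 `modified_match`
(12 deamidation, 1 oxidation, 2 dehydration) and 4 `unexplained`
rows whose residuals (+1.96, +16.98, +28.00, +31.99 Da) are consistent with
modifications outside the catalogue or with two-modification combinations;
they are frozen in the test suite as an explicit allowlist rather than
guessed at.

## The packaged identification table

The fixture is a verbatim transcription of the study's printed table: 114
rows, all sequences pairwise distinct, lengths 7–36 residues, every row
carrying an accession and a reported MW. The source prose claims "113
unique peptide sequences", one fewer than the printed table; the
transcription keeps the printed rows and a test documents the count. The
abstract also names the heaviest peptide with an `...SSGRRGD` C-terminus
while the table prints `...SSGPRGD`; only the table's form reproduces the
printed 2343.14 Da, so the fixture uses it. A SHA-256 checksum of the
fixture is asserted in tests so silent edits fail loudly.

## Fragmentomic scan and novelty

The scanner finds every occurrence of every reference sequence as a
contiguous substring of every peptide, counting overlaps (GG occurs three
times in GGGG), left to right, output sorted by (peptide, start, motif).
"Found in N peptides" means distinct peptides with ≥1 occurrence; total
occurrences are reported alongside. FG/GF are two independent motifs.
Novelty is exact full-sequence identity against the reference only —
containing a known dipeptide does not make a peptide known; that separation
mirrors how novelty claims are made against curated databases.

On the packaged table the scan finds DF in 2 peptides and SF in 4, whereas
the source prose states 4 and 5. The prose counts are treated as documented
claims, not oracles: the scanner is validated against a brute-force
double-loop search instead, and the package reports its own counts.

## Assay arithmetic

Percent inhibition is (control − sample)/control × 100; negative values
(sample absorbance above control) are returned unclamped for the caller to
flag. IC50 fitting uses the log-logistic (Hill) model on log10
concentration with asymptotes fixed at 0 and 100 by default — bounded
percent-inhibition data from a single plate rarely constrain four
parameters; a flag frees them. Initialisation: Hill slope 1, log-IC50 at
the dose whose response is nearest 50%. If fewer than three points are
available or the optimizer fails, log-linear interpolation between the two
points straddling 50% is used and labelled as such. Data that never cross
50% raise an identifiability error rather than returning an extrapolation.

Degree of hydrolysis uses the standard pH-stat relation
DH = B·N_B·(1/α)/(M_P·h_tot)·100, with B in mL and N_B in eq/L so B·N_B is
in meq. h_tot (meq peptide bonds per g protein) and 1/α are
substrate-dependent and required inputs; no defaults are invented for snail
protein. Yields are mass ratios in percent; protein from nitrogen uses the
conventional factor 6.25, rejecting nitrogen above 16% (which would imply
more than 100% protein).

## Synthetic data

The digest simulator models a broad subtilisin-like protease: each position
whose residue is in {A, F, I, L, M, V, W, Y} (configurable) is cut
independently with probability `cleavage_prob`; missed cleavages arise from
probabilities below 1 rather than an explicit counter, a simpler generative
story with the same marginal effect. Fragments outside the 6–40 residue
retention window are recorded but flagged excluded, so concatenating a
parent's fragments always reconstructs it and fragment masses conserve the
parent mass up to the water per cut. Retained peptides carry their computed
monoisotopic mass as `reported_mass` (optionally Gaussian-perturbed), so
the simulator-to-reconciliation loop closes with zero unexplained rows by
construction. With cleavage probability ~0.25–0.35 on random 300-residue
parents, most retained fragments fall in the 7–36 residue window of the
packaged table.

Dose-response simulation is the 4PL curve plus additive Gaussian noise on
the percentage scale (σ default 2 points, matching plate-reader replicate
scatter), clipped to [−5, 105]. Titration traces solve the DH relation for
the endpoint volume exactly and approach it along a saturating exponential
with small positive jitter, kept non-decreasing and capped at the endpoint.

What the generators do **not** emulate: real digests have position-dependent
kinetics, partial specificity and LC-MS detectability bias; real reported
masses carry search-engine-specific modification conventions; real
titrations have baseline drift. Passing tests therefore demonstrate
correctness of the arithmetic and the algorithms under the stated generative
assumptions, not robustness to instrument artefacts.

## Problem sizes and numerical choices

Property checks use 500 random scanner cases, 1000 random mass sequences,
50 noisy dose-response curves at 8 doses, and 100 seeded digests of
150-residue parents — sizes at which the checked invariants are exercised
densely while the whole suite runs in seconds. Mass additivity is asserted
at 1e-9 Da (float association), cross-library mass agreement at 1e-6 Da,
digest mass conservation at 1e-6 Da, titration round-trip at 1e-9. All
randomness flows through explicit integer seeds (numpy `default_rng` or
`random.Random`); the CLI refuses to simulate without `--seed`.

## Known limitations

- Modification inference is containment-based and non-localizing; with
  `max_mods` > 1 the subset search grows combinatorially (fine for the
  packaged 5-entry catalogue, not for large ones).
- The novelty check is exact-identity only; it does not do homology or
  I/L-equivalent matching.
- The IC50 fit assumes monotone dose-response; biphasic curves will fit
  poorly and are not detected.
- The bundled bioactive reference is a 10-entry local stand-in, not a
  mirror of any online database; novelty flags are only as good as the
  reference supplied.
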