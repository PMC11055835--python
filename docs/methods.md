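# Methods

This note records the models, conventions and design choices behind
`phlipkit`, and what the synthetic-data generators do and do not emulate.

## Peptides and descriptors (`seqcore`)

A `Peptide` is a validated sequence over the 20 canonical residues with
two modification slots: a C-terminal amide flag and an N-terminal adduct
mass (e.g. a bifunctional chelator such as NOTA). Sequences are
case-normalized on construction; non-canonical letters are rejected with
the offending position rather than skipped, because every sequence this
package targets is canonical and silent skipping would corrupt
descriptors.

Property scales are immutable named tables shipped as plain-text files
under `src/phlipkit/scales/`, each with a mandatory `# reference:` header:

* Kyte–Doolittle hydropathy (per-residue) — GRAVY and hydropathy profiles.
* Fauchère–Pliska octanol/water hydrophobicity (per-residue) — helix
  analytics; this is the scale used by HeliQuest-style tools.
* Guruprasad dipeptide instability weight values, DIWV (all 400 ordered
  pairs) — instability index.
* Average residue masses and formal side-chain charges.

Descriptor conventions:

* **Net charge** counts side chains only: Asp/Glu −1, Lys/Arg +1, His and
  both termini 0. This is the helix-design convention for short peptides
  and the only one consistent with the published values for these
  sequences (the termini of the tracer peptides are chemically blocked
  anyway — N-terminal chelator, C-terminal amide).
* **GRAVY** is the unweighted Kyte–Doolittle mean over the full sequence,
  unaffected by terminal modifications.
* **Instability index** is `(10/L)·Σ DIWV` over the `L−1` consecutive
  dipeptides. For a dimer repeat `(XY)ⁿ` it converges to
  `10·(DIWV(X,Y)+DIWV(Y,X))/2` with a finite-size deviation of exactly
  `10·DIWV(Y,X)/(2n)`, which the tests assert in closed form.
* **Average mass** is the sum of average residue masses plus one water,
  minus 0.98476 Da (−OH → −NH₂) for a C-terminal amide, plus the
  user-supplied N-terminal adduct mass. Monoisotopic masses and isotope
  envelopes are out of scope. No default chelator mass is claimed: the
  exact chelator/linker structures used in tracer syntheses vary by
  several hundred daltons and must be supplied by the caller.
* **Hydropathy profiles** follow the ProtScale convention: odd window,
  no edge padding, output of length `L − w + 1`, 1-based centers.
* Report formatting rounds the instability index to 2 decimals and
  GRAVY/hydrophobicity/moment to 3; internal values are unrounded.

## Helix analytics (`helix`)

Residue `k` of a window sits at angle `k·δ mod 360°` with `δ = 100°` for
an ideal α-helix (parameterized for 3₁₀/π helices). A wheel therefore
repeats after 18 residues, which is also the window used for the
**membrane-insertion region**, operationalized as the C-terminal 18
residues of the peptide. Two facts motivated that choice: it is the
natural full-wheel window, and with the Fauchère–Pliska scale it exactly
reproduces the published per-residue insertion-region hydrophobicities of
the designed peptide (0.763) and Var7 (0.893). Var3's published 0.841
does not correspond to its C-terminal 18-mer under this convention (we
compute 0.991); its window choice in the original analysis is
undetermined, so no test asserts it.

The **hydrophobic moment** is the Eisenberg vector sum
`μH = (1/N)·√[(Σ Hₖ sin kδ)² + (Σ Hₖ cos kδ)²]`, non-negative, invariant
under a global rotation offset, and equal to `|H|` for a single residue.
The mean (1/N) normalization is the default; the raw-sum variant is
exposed via `normalization="sum"`. The moment values published for these
peptides (0.385, 0.366, 0.389, 0.373) came from a web tool whose window
and normalization cannot be reconstructed: the mean-vector convention on
the C-terminal 18-mer gives 0.358 for the designed peptide but happens to
give 0.373 for Var7. Combinations tried: mean and sum normalization on
the C-terminal 18-mer and on the best-scoring 18-mer; none reproduces all
four printed values. The implementation therefore treats window, scale,
δ and normalization as parameters, and correctness is established against
an independent brute-force trigonometric oracle (1000 random windows,
1e−9 tolerance) rather than against the printed numbers.

The wheel annotates D, E, K, R, H, N, Q, S, T, Y as polar and the rest as
apolar, recorded in the output CSV.

## Consensus design (`design`)

Families are pre-aligned, equal-length, gap-free blocks (the insertion
regions being compared are equal-length segments; no aligner is built
in). The frequency matrix holds exact per-position counts. Consensus
selection takes the most frequent residue per position; ties break
lexicographically by one-letter code — a deterministic, documented rule —
before the substitution policy is applied. The default policy maps
E → D residue-wise after selection, so an E-dominant column yields D even
when D never occurs there; applying the rule per column or pre-filtering
Glu from candidates gives the same output for E-dominant columns, and the
post-selection order is the one implemented. The five study peptides ship
as a demonstration fixture, not as the (unpublished) family that entered
the original design.

## Radiometrics (`radiometrics`)

* Decay correction references gamma-counter counts back to injection
  time: `counts · 2^(t/T½)`, with the Ga-68 half-life fixed at 67.71 min
  as a physical constant and exposed as configuration.
* `%ID/g = 100 · counts_at_injection / dose_counts / weight_g`, where the
  dose reference is a counts-equivalent standard (an aliquot counted on
  the same counter); its calibration is the caller's input. Because
  published tables do not always state whether they are decay-corrected,
  the tidy output carries both `pid_g_corrected` and `pid_g_uncorrected`,
  explicitly labeled.
* Cohort summaries report n, mean and sample SD (n−1 denominator) per
  organ × timepoint. Group comparison uses Levene's test (center = mean)
  for homogeneity of variance and one-way ANOVA, two-sided, α = 0.05. No
  multiple-testing correction is applied — per-timepoint comparisons are
  reported as-is, matching common practice in small-animal
  biodistribution work; users comparing many organs should correct
  downstream.
* Serum protein binding: after an acetonitrile crash, protein-bound
  activity precipitates, so bound % = 100·sediment/(sediment+supernatant).
* Yield = 100·product/starting activity; purity = 100·main radio-HPLC
  peak area/total area.

## Synthetic data (`synthsim`)

Both generators are pure functions of their spec, seed included.

**Families**: each member copies the template residue per position with
probability `conservation`, otherwise draws uniformly from the 19
alternatives. This emulates positional conservation only — no
phylogenetic correlation between members, no substitution-matrix
structure, no indels. Passing consensus-recovery tests therefore shows
the estimator handles i.i.d. positional noise, not that it would handle
realistically correlated families.

**Biodistribution**: per organ × timepoint, true %ID/g values are drawn
log-normally (positive support; published SD/mean ratios of ~0.2 are
consistent with a multiplicative noise model) with the specified mean and
CV, then raw counts are back-computed through the physical decay so the
analysis pipeline recovers exactly those values. Defaults are the study
conditions for the tracer cohort: tumor 5.94/6.72/4.54, liver
20.49/14.46/10.22, blood 19.61/8.23/3.38 %ID/g at 1/2/4 h, with
per-organ CVs of 0.21/0.18/0.20 (the observed 1-h SD/mean ratios) and
n = 3 animals per group × timepoint. Organ weights are drawn uniformly
from plausible murine ranges (tumor 0.2–0.8 g for a 0.8–1.0 cm tumor,
liver 0.8–1.4 g, blood sample 0.1–0.5 g) — a documented fixture, not
data. The generator does not model pharmacokinetics, inter-organ dose
conservation, excretion, or counter dead-time; round-trip tests
demonstrate the quantification layer, not tracer biology.

Validation sizes: round-trip mean recovery is checked at n = 1000 animals
per cell (within 3 standard errors), consensus recovery over 200 seeded
replicates of 100-member families at conservation 0.6, and the ANOVA
type-I error rate over 1000 null replicates — all complete in seconds.

## Command-line surface (`cli`)

Thin wrappers over the library: `design`, `profile`, `wheel`, `scan`,
`simulate-family`, `simulate-biodist`, `biodist`. Results go to files or
stdout; logs to stderr; every directory-producing run writes a
`provenance.json` (tool version, subcommand, parameters). Numeric output
formatting is fixed (`%.6f` for measurement CSVs) so seeded runs are
byte-reproducible.

## Known limitations

* The insertion-region window (C-terminal 18-mer) is a convention; for
  peptides whose helical segment is longer, shorter, or internal, use
  `scan_windows` and choose explicitly.
* Net charge is formal, not pH-dependent; no pKa or Henderson–Hasselbalch
  modelling, although the pH trigger of these peptides is precisely a
  protonation effect.
* CD spectroscopy, radio-HPLC trace processing, PET reconstruction and
  3-D structure prediction are out of scope.
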