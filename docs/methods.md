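# Methods

This note documents the models, rules and numerical choices behind
`mrmpanel`, and what the synthetic test harness does and does not show
about real data.

## Assay-design model

**Digestion.** Trypsin is modeled as cleavage C-terminal to K or R with
the classical proline rule (no cleavage of K/R–P bonds) on by default. The
rule is a design choice: targeted assays conventionally assume it, and it
is configurable off. Missed cleavages default to 0 for peptidome
construction (targeted peptides are fully tryptic) and may be raised to 2
when reconciling discovery-run tables that contain missed-cleavage forms.
Candidate peptides are restricted to 7–18 residues with no methionine:
shorter peptides are rarely proteotypic, longer ones fragment poorly on a
triple quadrupole, and methionine oxidation splits signal between
chemical forms unpredictably.

**Ion math.** Monoisotopic masses come from an embedded residue table
(full published precision, ~1e-11 Da per residue). Carbamidomethylation of
cysteine (+57.02146 Da) is a fixed modification by default because the
upstream discovery workflow alkylates with iodoacetamide; it can be
disabled. Transitions pair the 2+ precursor with the singly charged
y3…y(n−1) series. y1/y2 are immonium-contaminated and poorly selective;
y(n) is excluded because it is the precursor at another charge state, so
the terminal monitored fragment is y(n−1) and every peptide of length n
yields n−3 candidate transitions. Product ions outside a configurable
transmission window (default 10–2000 Th — wide enough to pass the terminal
y-ions of 16-residue panel peptides, which exceed 1500 Th) are dropped
with a logged reason. Collision energy is the linear instrument ramp
CE = slope·(precursor m/z) + intercept per charge; the shipped
coefficients (2+: 0.034, 3.314; 3+: 0.044, 3.314 eV) are the generic
Thermo triple-quadrupole defaults used by common transition-list tools and
are meant to be replaced with instrument-calibrated values via the config
file.

## Specificity tiers

Classification is a precedence rule over the categories of background
proteomes in which a candidate occurs: any hit in an unrelated ("other")
proteome makes it **non-specific** (removed), otherwise any hit in a
related organohalide-respiring organism makes it **semi-specific** (kept
with caveat), otherwise it is **specific**. Matching defaults to
membership in the background's filtered tryptic peptidome, which mirrors
tryptic-peptide database lookups; a raw substring mode against undigested
sequences (protein-level homology style) is provided because the two can
disagree on peptides spanning cleavage sites. I/L equivalence is off by
default (the digestion config controls it) since high-resolution discovery
data can distinguish contexts even though MRM cannot.

Peptidome similarity is reported as a percentage under two definitions —
Jaccard, 100·|A∩B|/|A∪B| (default), and overlap coefficient,
100·|A∩B|/min(|A|,|B|) — because published "peptidome similarity"
figures rarely state their metric; both are exposed and the choice is
logged. Similarity is symmetric, bounded in [0,100], and 100 exactly when
the peptide sets coincide.

## Transition refinement

Within a peptide, each transition's contribution is its integrated area
divided by the peptide's summed area; the top five by contribution are
retained, ties breaking toward the lower y-index for determinism. The
ranking is scale-invariant, so it is unaffected by absolute loading.
Retention may be ragged — peptides with fewer than five usable transitions
keep what they have, which is why a merged panel's transition count can be
less than 5× its peptide count. When strains disagree on the retained set
for a shared peptide, the strain with the larger total AUC wins (the
better-measured pattern); an intersection mode is available for
conservative panels. Signal-quality triage that is done by eye in practice
is encoded as an objective flag: total AUC must correlate with column load
(Pearson r ≥ 0.9) and increase strictly across loads; peptides seen at one
load only are flagged `not_evaluable` rather than silently passed.

## Detection rules

Peak integration is trapezoidal over the trace (areas in intensity·s);
apex RT is the time of the maximum of a centered moving average (default
width 3 points) to resist single-sample spikes. A transition is *present*
when its smoothed apex exceeds a robust noise floor, median + 3·1.4826·MAD
of the raw trace — flat or empty traces are absent, not errors.

Detection requires all of:

- **A, co-elution:** max pairwise apex spread ≤ 0.2 min (configurable; the
  criterion is standard but no published tolerance exists, so the default
  is roughly one chromatographic peak width);
- **B, pattern fidelity:** arithmetic mean across technical replicates of
  dotp(observed areas, reference ratios) strictly greater than 0.80. dotp
  is the normalized dot product of nonnegative vectors, scale-invariant,
  1 iff proportional; a zero observed vector is defined as 0 with a
  warning. An optional square-root intensity transform (off by default)
  is provided because reference implementations differ on this point;
- **C, reproducibility:** every replicate has all transitions present and
  co-eluting.

The spike-in gate additionally requires the spiked run's total area to
exceed the endogenous one by more than 50% of the endogenous area
(configurable fold), endogenous dotp > 0.80 against the standard's
pattern, and |ΔRT| ≤ 3.0 min inclusive. Boundary semantics are exact:
mean dotp equal to the threshold fails (strict >), RT difference equal to
3.0 min passes (inclusive ≤).

## Synthetic data

The simulator stands in for pure cultures, a defined consortium and
groundwater runs. Proteomes are uniform-random residue strings (default 30
proteins of mean length 300 ± 80); chosen peptides are planted flanked by
arginine so they digest out cleanly, giving every specificity tier
known-truth members. Chromatograms are Gaussian peaks (σ = 0.05 min,
sampled at 1 s — typical nano-LC peak widths and MRM cycle times) whose
amplitudes follow the reference ratios, with per-transition RT jitter
(σ = 0.005 min), relative Gaussian or Poisson noise, and a flat baseline
of 50 counts. Reference patterns used for decoy construction are geometric
(1, r, r², …; r = 0.5), because a cyclic shift of a geometric vector has a
closed-form dotp against the original (0.545 for five transitions) safely
below the 0.80 threshold — ratio-permuted decoys therefore fail criterion
B *by construction*, not by tuning. Dropout decoys fail criterion A
(missing transition) and absent groups fail criterion C.

What passing these tests shows: the decision rules implement their
definitions exactly, estimators converge to analytic values as noise
vanishes, and planted truth is recovered at realistic noise levels. What
they do not show: robustness to matrix interference, peak tailing,
co-eluting isobars, retention-time drift between runs, or electrospray
saturation — none of which the Gaussian model emulates. Real-data
thresholds should be revisited with instrument-specific QC.

## Determinism and numerics

All randomness flows through one seeded NumPy generator; fixed seed means
byte-identical FASTA/CSV fixtures and traces. Output CSVs are sorted
deterministically (protein, peptide, ascending y-index; reports by peptide
sequence) and m/z values print at 4 decimals, so reruns are byte-identical
and diffs are meaningful. Every CLI output embeds a hash of the resolved
configuration plus the seed. Mass arithmetic is plain summation
(deterministic to ~1e-9 Da at peptide length); the y/b complementarity
identity y(i) + b(n−i) = M + H₂O + 2H⁺ is verified internally even though
b-ions are never emitted.

## Known limitations

- Only trypsin, y-ions, 2+ precursors and 1+ products are modeled; no
  neutral losses, semi-tryptic peptides or isotope envelopes.
- Specificity screening is exact matching against user-supplied proteomes;
  it does not replace an exhaustive search of public databases, and its
  verdicts are only as complete as the supplied background registry.
- Absolute quantification against isotopically labeled standards is out of
  scope; the spike-in gate verifies identity, not molar amount.
- The acceptance check on real UniProt reference proteomes (peptidome
  similarity among *Dhc* strains vs *Dehalogenimonas*) requires the user
  to download those proteomes to `data/reference_proteomes/`; they are too
  large to ship with the package.

## Problem sizes used in the shipped checks

Digestion oracle equivalence runs on 1,000 random proteins of 50–500
residues; dotp invariance on 10,000 random vector pairs; detection/decoy
rates on 200 + 200 single-replicate peak groups; the panel scenario on 37
peptides × 3 replicates; specificity recovery on seven-proteome registries
of 30 proteins each. These sizes give stable (100%-saturated) rates at the
default noise settings while keeping the full suite under a few seconds.
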