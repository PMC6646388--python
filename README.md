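# mrmpanel

Toolkit for designing and validating targeted LC-MRM-MS (multiple reaction
monitoring) peptide assays, built around the workflow used to monitor
*Dehalococcoides mccartyi* (*Dhc*) biomarker proteins — GroEL, EF-Tu,
rpL7/L12, the S-layer protein, FdhA and the reductive dehalogenases TceA
and BvcA — in mixed cultures and contaminated groundwater. It is aimed at
environmental proteomics groups who need to go from proteome FASTA files to
an instrument-ready transition list, and from raw MRM chromatograms to
defensible peptide detection calls.

## What it does

1. **Design** (`digestion`, `ion_math`): in-silico tryptic digestion
   (cleave after K/R, not before P), candidate filtering to 7–18-residue
   methionine-free peptides, and enumeration of transitions — doubly
   charged precursor, singly charged y3…y(n−1) fragment series, with
   monoisotopic m/z (fixed carbamidomethyl-C by default) and a linear
   collision-energy ramp CE = a·(m/z) + b per precursor charge.
2. **Specificity screening** (`specificity`): each candidate is matched
   against labeled background peptidomes and tiered **specific** (target
   organism only → keep), **semi-specific** (also in related
   organohalide-respiring bacteria → keep with caveat) or **non-specific**
   (in any unrelated organism → remove), with non-specific taking
   precedence. Pairwise peptidome similarity (Jaccard or overlap
   coefficient, in %) supports species-level assay feasibility checks.
3. **Refinement** (`panel`): per peptide, transitions are ranked by
   fractional contribution to total chromatographic AUC and the top five
   retained (ties break toward the lower y-index); per-strain panels merge
   into one cross-strain panel; AUC-vs-load linearity flags
   (Pearson r ≥ 0.9 and strictly increasing response) encode signal-quality
   triage.
4. **Validation** (`validation`): a peptide is *detected* in a sample only
   when (A) all transitions co-elute (apex spread ≤ 0.2 min default),
   (B) the mean normalized spectral contrast **dotp** = Σaᵢbᵢ/(‖a‖‖b‖)
   against the reference intensity ratios exceeds 0.80 (strict), and
   (C) the signal is present and co-eluting in every technical replicate.
   Spiked unlabeled standards add a fourth gate: clear total-area increase,
   dotp > 0.80 versus the standard pattern, and RT agreement within 3 min
   (inclusive).
5. **Simulation** (`simulate`): seeded synthetic proteomes with planted
   known-tier peptides, and Gaussian-peak MRM traces with controlled
   amplitude ratios, RT jitter, noise and decoy corruptions
   (ratio permutation, transition dropout, RT shift, absence), so the whole
   pipeline is testable without any external data.

## Worked example

Design a transition panel for a chaperonin-like demo protein (synthetic
example sequence, `data/` not required):

```bash
$ mrmpanel design groel.fasta --target Q3Z6L3 --out panel.csv
wrote 57 transitions to panel.csv
filtered 3 peptide(s): excluded_residue
filtered 2 peptide(s): too_long
filtered 11 peptide(s): too_short

$ head -4 panel.csv
# mrmpanel config_hash=acca61ade375
protein,peptide,precursor_mz,product_mz,fragment_label,collision_energy,charge
Q3Z6L3,ALGIVYLDSQAR,653.3617,374.2146,y3,25.5283,2
Q3Z6L3,ALGIVYLDSQAR,653.3617,461.2467,y4,25.5283,2
```

Each retained peptide (e.g. the FdhA marker ALGIVYLDSQAR, 2+ precursor at
653.3617 Th) contributes its full y3…y(n−1) series; the collision energy
(25.53 eV) follows the configured linear ramp. Simulate a 37-peptide
monitoring run in which 13 peptides carry faithful signal, then validate:

```bash
$ mrmpanel simulate --seed 1 --outdir sim --n-targeted 37 --n-detectable 13
synthetic fixtures written to sim (seed=1)
$ mrmpanel validate sim/traces.csv --library sim/library.csv --out verdicts.csv
detected 13 of 37 targeted peptides
```

`verdicts.csv` carries one row per peptide with the co-elution spread, mean
dotp, per-criterion flags and the final call:

```
peptide,n_replicates,coelution_pass,max_apex_spread_min,mean_dotp,dotp_pass,replicate_pass,detected,reasons
PEP000SIMK,3,True,0.0167,0.9995,True,True,True,
```

The specificity screen (`mrmpanel screen panel.csv --registry registry.yaml
--out report.csv`) exits with code 2 whenever a peptide had to be removed
as non-specific, so pipelines can react mechanically.

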