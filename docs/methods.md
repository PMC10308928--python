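# Methods

## Model and assumptions

`metaphi` treats the *metaprotein* — the set of accepted PSMs whose
candidate proteins' annotated homolog hits all carry one functional
description string — as the quantification unit, and attributes its
expression to taxonomic sequence bins by alignment strength rather than by
exact database membership. The underlying assumptions are:

- spectral counts, once length-normalized (NSAF), are proportional to
  relative protein abundance within a sample;
- the bins jointly represent the major taxa of the community, so min-max
  normalizing a peptide's bit scores across bins is meaningful ("minimum
  and maximum production" map to 0 and 1);
- alignment bit score of a peptide's candidate proteins against a bin is a
  monotone proxy for the probability that organisms of that bin produced
  the peptide;
- one spectrum yields at most one peptide sequence after FDR filtering.

Peptide identity collapses leucine to isoleucine (isobaric residues are
indistinguishable by shotgun MS).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `q_cutoff` | 0.01 | target-decoy q-value cutoff for PSMs |
| `evalue_gate` | 0.01 | maximum E-value for a peptide-bin alignment to qualify for φ |
| `top_hit_fraction` | 0.10 | homolog hits kept if bit score ≥ (1 − fraction)·max |
| `hit_cap` | 5 | even subsample size of retained hits |
| gap open / extend | 11 / 1 | affine gap costs (a gap of length g costs 11 + g) |
| λ, K | 0.267, 0.041 | Karlin–Altschul statistics for gapped BLOSUM62-11-1 |

The defaults of the first four are the method's stated operating point;
the alignment parameters are the conventional gapped-BLOSUM62 set, fixed
rather than estimated per database, and configurable.

"Within the top 10% by bit score" is read as a score threshold
(bit ≥ 0.9·max), not the top decile by count. The even-subsampling rule
keeps 1-based ranks floor(1 + i(m−1)/(cap−1)), i = 0..cap−1, which
reproduces the canonical worked example m = 500 → {1, 125, 250, 375, 500}
and always includes the first and last hit.

## Numerical and edge-case choices

- **FDR.** FDR(t) = #decoys ≥ t / #targets ≥ t over observed score
  thresholds; q is the monotone minimum over thresholds at or below the
  PSM's score, with tied scores sharing one threshold. Decoys must be
  pre-labeled; absence of decoys is an error, not a pass-through.
- **Degenerate φ normalization.** When a peptide qualifies in exactly one
  bin, or all qualifying bit scores are equal, every qualifying bin
  receives a normalized score of 1: with no spread, every qualifying bin
  *is* the maximum, and assigning 0 would erase real signal.
- **Weakest qualifying bin.** With a nondegenerate range, the minimum-S′
  bin receives a normalized score of 0 and hence φ = 0 even though it
  aligned below the gate. This is the metric's published behavior and is
  kept deliberately.
- **S′ range.** S′_min/S′_max are taken over qualifying (E < gate)
  alignments only; non-qualifying bins do not define the range.
- **NSAF denominator.** All identified peptides enter the denominator,
  including those excluded from metaproteins for lacking a consistent
  annotation. When a candidate has no homolog hits, its own length backs
  up L_N; with several candidates, L_N pools retained subject lengths
  across candidates.
- **φ summation.** φ_P sums φ_N over *distinct peptides*; the spectral
  count already enters through NSAF, so summing per PSM would double-count
  it.
- **Missing cells** (function absent from a sample) are zeros, not NA, for
  averaging and multivariate input.
- **All-zero rows/columns** yield Φ = 0; any nonzero row/column attains
  exactly 1 after rescaling.
- **E-value search space** is query length × total bin residues, with no
  length corrections.
- **Tie-breaks.** Equal lowest E-values break to the higher bit score,
  then the lexicographically smaller candidate id, so best-candidate
  selection is independent of input order.
- **Elbow detection.** The SSE breakpoint is the k maximizing the second
  difference of the best-of-restarts SSE curve; the full curve is exported
  so the choice can be audited. k-means uses Euclidean distance,
  k-means++ initialization, 100 restarts, and a fixed seed.
- **LDA regularization.** With many functions and few bins the
  within-class scatter is singular; Ledoit–Wolf shrinkage (sklearn's
  `shrinkage="auto"`, eigen solver) regularizes it. Separation fractions
  are between-class variance shares per discriminant.
- **Welch's t-tests** are reported raw, matching the published convention
  of uncorrected per-function P-values; a Benjamini–Hochberg column
  (`p_bh`) is emitted alongside as a clearly labeled extension.
- **PCA sign convention:** each component is flipped so its
  largest-magnitude loading is positive, making axes reproducible.

## Build-or-buy

Local alignment is exhaustive Smith–Waterman via Biopython's
`PairwiseAligner` (tests cross-check it against an independent recursive
path-enumeration oracle); at the scale of candidate-vs-bin comparisons the
exact optimum is affordable and removes any dependence on an external
search binary. A 12-column tabular alignment file can be substituted for
the internal aligner, and a homolog hit table for the direct candidate
annotations, so outputs of real external tools drop in stage for stage.
k-means/PCA/LDA are scikit-learn; Welch's test is SciPy. The FDR filter,
hit filtering/subsampling, metaprotein inference, NSAF and the φ/Φ chain
are implemented here.

## The simulator

`metaphi.simulate` generates, from a single seed: one random base protein
per function; per-bin orthologs with a chosen fraction of residues
substituted (replacements uniform over the 19 non-identical residues,
giving the mildly negative mismatch scores of distant homologs and hence a
bit-score gradient across bins); candidate proteins copied (optionally
truncated) from bin sequences; tryptic peptides (cleave after K/R, not
before P, with configurable missed cleavages); per-(peptide, sample)
spectral counts from a negative binomial (variance = μ + αμ², α = 0 →
Poisson) whose mean is the per-function expression mean split evenly over
the protein's peptides; and decoy PSMs with null scores below the target
score distribution.

Default community: 4 bins, 8 functions (one per Functional Group,
including a Ribosome row), 120-residue proteins, 30% inter-bin divergence,
8 samples over three vegetation ecotypes, dispersion 0.3, decoy fraction
0.5 — a desk-scale analogue of a soil community with a dozen taxa and a
hundred-odd functional categories.

Two canned scenarios define the recovery studies:

- `bin_exclusive_design`: 3 bins at 90% divergence, one function expressed
  only in one bin (mean 40 spectra), two housekeeping functions expressed
  everywhere. 90% divergence is used because cross-bin attribution is only
  expected to vanish when foreign-bin alignments fail the E < 0.01 gate;
  at moderate divergence (≤ ~0.8) a 120-residue ortholog still aligns
  convincingly — and then nonzero cross-bin Φ is the *correct* output of
  the metric, not an attribution error.
- `ecotype_effect_design`: 12 functions, 3 bins, six samples per ecotype,
  NB dispersion 0.2. Four Functional Groups are induced 6-fold in tussock
  samples *in their dominant bin only*. The bin-specificity matters: a
  uniform fold change across bins cancels exactly under Φ_bin's row
  normalization (the metric measures partitioning, not level), so an
  ecotype effect is only visible to Φ_bin-based LDA when the partitioning
  itself shifts. The induced bins are spread across all three bins so
  every bin's profile moves between ecotypes. The overall relative
  abundance shift (~3.5-fold at the Functional Group level) puts the
  planted effects comfortably inside Welch-test power at n = 6 per group,
  comparable to the strong transport-function contrasts the approach is
  meant to detect.

What the simulator does *not* emulate: spectra and fragmentation, chimeric
or one-hit-wonder identifications, shared peptides between unrelated
functions, candidate sets spanning multiple functions, or realistic
proteome sizes (thousands of proteins, 141 Functional Groups). Passing
recovery tests therefore demonstrates the pipeline's logic is correct
under its own assumptions, not that real soil data will be as clean.

## Problem sizes

Tests and the acceptance checks run on deliberately small instances: 500
random pairs of length ≤ 12 for the alignment oracle, 200 random score
sets for the FDR oracle, 100 random fixtures for NSAF conservation, 20
simulator seeds per recovery scenario (3 bins × 3–12 functions × 2–12
samples, a few thousand PSMs each). These sizes give the property checks
comfortable statistical resolution while keeping a full run on one CPU in
the low minutes.

## Known limitations

- Karlin–Altschul λ/K are fixed constants; E-values are therefore
  comparable within a run but not calibrated per database.
- The consistent-description rule is exact, case-sensitive string
  equality (an optional case-folding flag exists); annotation tools that
  vary descriptions cosmetically will fragment metaproteins.
- Whether hit filtering precedes the description-identity requirement is
  an open ordering question; this implementation filters first.
- The weakest-qualifying-bin-gets-zero behavior (above) means a function
  genuinely expressed by the lowest-scoring bin contributes nothing there.
- LDA separation fractions depend on the shrinkage choice; they are not
  asserted to equal any particular external implementation's output.
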