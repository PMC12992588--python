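# Methods

## The frequency-bias statistic

For a proteome with composition q (per-letter frequencies over the 20
standard amino acids, computed over all standard residues), the bias of
a k-mer s is the observed window frequency divided by the
independence-model expectation:

    bias(s) = [ n(s) / N ] / Π_i q(s_i)

with n(s) the number of sliding windows equal to s and N the total
number of valid windows.  Conventions that matter:

* **Windows, not proteins.**  Overlapping windows all count; a protein
  carrying a motif twice contributes two occurrences.  A per-protein
  presence mode (`bias_table(..., per_protein=True)`) exists as a
  sensitivity check, because for very rare motifs (one or a few
  carriers per genome) the two definitions nearly coincide.
* **Non-standard letters.**  Windows containing X/B/Z/J/U/O are
  excluded from both the numerator and N, and those residues are
  excluded from the composition.  This keeps Σ_s f_obs(s) = 1 exactly
  and avoids an arbitrary projection of ambiguity codes onto the
  20-letter alphabet.
* **Undefined vs zero.**  When a pattern's expected frequency is 0 (a
  letter never occurs) or the proteome has no valid window, the bias is
  *undefined* and the genome is dropped from clade means/medians/ECDFs
  for that pattern.  When the pattern is expected but absent, the bias
  is a real observation of 0 (the "genomes completely lacking the
  motif" fraction tracks exactly these).
* A terminal `*` in downloaded translations is stripped on read; it
  would otherwise fabricate impossible 4-mers.

Clade aggregation: genomes are grouped by phylum (class for
Pseudomonadota); clades larger than 1000 genomes are reduced by a
seeded uniform draw without replacement (default seed 214).  The
underrepresentation ranking orders patterns by the *unweighted* mean of
clade means — each clade votes equally regardless of genome count — and
breaks ties lexicographically.

## Motif census and localization

Occurrences are reported per protein with 1-based inclusive
coordinates; distance to the C-terminus is length − end (0 when the
motif ends the protein).  Per-protein summaries use the C-terminal-most
occurrence; the per-occurrence table is kept for positional plots.  The
small-protein filter is strict (< 300 aa).

Localization (SP/TM/CP) is a pluggable predictor interface.  The
default is a transparent hydropathy heuristic: each residue is scored
with the mean Kyte–Doolittle hydropathy of the 19-residue window
centered on it; maximal runs of residues scoring ≥ 1.6 are
membrane-like segments.  A segment lying fully within residues 1–35
and preceded by at least one K/R is a signal-peptide H-region; the call
is SP if such a segment exists and no membrane segment extends past
residue 35, TM if one does, else CP.  Proteins shorter than the window
are CP with a warning flag.  One documented quirk follows from the
stated rules: a hydrophobic segment inside residues 1–35 *without* a
preceding positive charge yields CP.  An adapter ingests the 3-line
output format of DeepTMHMM for users who run that predictor externally;
the heuristic is not a re-implementation of it and should not be
expected to match its accuracy.

## uORF/downstream pairing and enrichment

The downstream partner of a uORF is the nearest CDS on the same contig
and strand whose translation-direction start lies beyond the uORF's
stop (minimal start > end on +, maximal end < start on −).  There is no
distance cap by default (`max_gap` configurable), and a configurable
`allow_overlap` bound admits slightly overlapping genes.  uORFs must be
< 300 aa and annotated only as unknown/hypothetical/uncharacterized;
downstream genes must have a non-empty annotation not containing
"unknown".  Groups are exact normalized strings (lowercased, whitespace
collapsed, trailing punctuation stripped) — deliberately no fuzzy
matching, so "TonB-dependent receptor" and "TonB dependent receptor"
are distinct; curated super-groups are a user-supplied mapping concern.

Fold enrichment is proportion-normalized, (a/(a+b)) / (c/(c+d)), so
target and control cohorts of different sizes are comparable; groups
with c = 0 are kept and flagged infinite rather than dropped or
pseudocounted.  The Fisher exact test is computed from hypergeometric
log-probabilities (gammaln); the two-sided p-value uses the
minimum-likelihood rule — sum the probabilities of all tables with the
observed margins that are no more probable than the observed one, with
1e-7 relative slack against floating-point ties — matching the
convention of R's `fisher.test`.  Benjamini–Hochberg is the step-up
q(i) = min_{j≥i} p(j)·m/j, capped at 1, adjusted within one
target/control comparison (all its groups form the family), with
significance declared at adjusted p < 0.01.

## Synthetic data: what it emulates, and what it does not

`generate_proteome` draws residues iid from a specified composition
with lognormal lengths truncated to [50, 2000] (defaults μ = 5.5,
σ = 0.45: median ~245 aa, a realistic bacterial protein-length scale).
Motifs are planted per protein with probability p, uniformly or with
the motif end within w residues of the C-terminus.  Depletion is
post-hoc thinning: each *background* (non-planted) occurrence is, with
probability 1 − d, destroyed by resampling one of its residues from the
composition conditioned on differing from the motif letter at that
position — so each occurrence survives with probability exactly d,
giving a provable target bias.  (Unconditioned resampling would leave a
residual retention probability and bias the target upward.)  Thinning
is a single left-to-right pass; a replacement can in principle create a
new occurrence downstream, a second-order effect that is negligible at
the occurrence densities used.

`generate_annotated_genome` lays uORF/downstream pairs on one contig:
the uORF (60–250 aa, product "hypothetical protein", motif within the
last ~14 residues) is followed in translation direction by a CDS whose
annotation is drawn from a group multinomial, with a per-(motif, group)
weight factor applied before renormalization.  Note the estimand: a
weight factor f on one of g equal-weight groups implies a true
proportion ratio r = (f/(g−1+f))·g — e.g. f = 5 over 20 groups gives
r ≈ 4.17 — and r, not f, is what fold enrichment estimates; recovery
studies judge against r.  Decoy genes are interleaved on the opposite
strand, so pairing recovers every planted pair by construction.
Nucleotide content is arbitrary (CDS length 3×(aa+1)); only coordinates
and annotations matter downstream.  All generators take mandatory
seeds and are byte-identical for a fixed seed.

What the generators deliberately omit: codon usage, GC structure,
dipeptide correlations within proteins, and phylogenetic correlation
between genomes.  Passing tests therefore demonstrate the estimators'
statistical correctness under a known model, not that real proteomes
satisfy that model; on real data the composition-independence null is
only an approximation, which is precisely why the bias statistic is
interpreted comparatively across patterns and clades.

## Study problem sizes and numerical choices

* Null calibration uses one unplanted proteome of ~4×10⁵ windows and
  20 probe patterns drawn letter-by-letter from the composition (so
  their expected counts are resolvable); each bias is checked within 4
  binomial standard errors of 1.
* Depletion recovery (d = 0.1, 0.5) uses a motif-letter-rich
  composition (R/A/P/L at 0.20) and ~1.2×10⁶ windows, leaving ~200
  surviving occurrences at d = 0.1 — enough to resolve a 20% relative
  error with margin.
* Enrichment recovery pools 2×2 counts over 6 replicate toy genomes of
  500 uORFs per motif (20 groups, f = 5); top-group rank and
  significance are taken from a single replicate.
* The cross-clade ranking analog uses 3 clades × 3 genomes of 1200
  proteins with a *uniform* composition, so all 160,000 patterns share
  one expected frequency and the planted 10×-depleted pattern must beat
  every null pattern's sampling noise to rank first.
* The null-FDR study runs 200 replicate comparisons of 100 + 100 uORFs
  over 20 groups drawn from the same multinomial.

Fisher p-values cache the hypergeometric log-pmf per margin triple
(lru_cache), making the exhaustive small-table verification cheap.
ECDFs are right-continuous step functions ending at 1; quantile
dominance checks evaluate both ECDFs at the uniform cohort's deciles.

## Known limitations

* The full-scale census numbers from tens of thousands of genomes
  (e.g. genome counts of motif-bearing proteins across a whole
  taxonomy release) require the corresponding downloads; this package
  validates the machinery on synthetic ground truth and single
  genomes, and `analysis/05_refseq_worked_values.py` reproduces the
  real-genome worked values when network is available.
* The hydropathy heuristic is a coarse stand-in for a trained
  topology predictor and is best used comparatively across motif
  cohorts, not as a per-protein annotation.
* Annotation grouping is string-exact; synonymous annotations split
  groups unless a mapping file merges them.
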