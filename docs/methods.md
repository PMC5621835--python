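# Methods

## Problem setting

Zygotic injection of Cas9 with a single gRNA mutagenizes an embryo during
its early cell divisions. Error-prone repair writes a different indel into
each affected cell, so every indel allele labels a cell lineage, and the
spectrum of allele frequencies in a dissected limb is a readout of that
limb's clonal composition. Comparing the composition of a limb before
amputation with the regenerated limb that replaces it quantifies how
faithfully regeneration reconstitutes the original lineages. `indeltrace`
implements the full analysis path from pooled amplicon reads to these
fidelity statistics, plus a generative model of the experiment for
end-to-end validation.

## Allele calling

Reads are demultiplexed by exact match of an inline 4–6 nt sample tag
followed by the forward primer; no mismatch rescue is attempted because tag
bleed-through directly corrupts the composition comparison downstream.

A read containing a perfect protospacer+PAM substring is counted as the
non-mutant (INTACT) class regardless of substitutions elsewhere. Remaining
reads are aligned globally to the reference amplicon with affine gap
penalties (match +2, mismatch −3, gap open −8, gap extend −1; any single
gap may span up to 100 bases). Alignment columns are scanned for maximal
runs of non-match columns: a run containing at least one gap column becomes
a single indel event whose deletion span is the reference consumed by the
run and whose insertion is the read bases consumed. Folding gap-adjacent
mismatches into the event is what recovers combined deletion+insertion
alleles — under affine scoring the optimizer otherwise prefers to absorb a
short insertion as mismatches flanking a shorter deletion, which would
leave such alleles without a consistent representative. Pure mismatch runs
remain substitutions and never become alleles.

Indels are left-aligned (deletions slid, insertions rotated through
repeats) so equivalent placements share one canonical name: `D{start}-{end}`
for deletions, `I{after}+{bases}` for insertions, `D{start}-{end}+{bases}`
for combinations, all 1-based on the reference amplicon. An indel qualifies
as an allele only if its footprint touches the cut window — the PAM plus
the three PAM-proximal protospacer bases, where Cas9 cleaves; indels
elsewhere are set aside as PCR/sequencing artifacts. Each allele is
represented by a junction sequence (insertion plus symmetric reference
flanks, trimmed to a fixed per-target length of 27–36 nt, deficits near
amplicon ends compensated on the other side), so that read-to-allele
assignment is an exact substring test and each read matches at most one
allele; ties are broken toward the largest indel footprint, then the
lexicographically smallest name.

Discovery iterates: tally qualifying indels among unexplained reads,
promote the best-supported one (minimum support `min_discovery_reads = 2`),
remove all reads containing its representative, repeat. Well-supported
unique sequences are processed before singleton (mostly error-bearing)
reads; this ordering only affects speed, not the result. Per-animal lists
are consolidated across animals per target by canonical name, and alleles
whose representatives are identical are merged under the leftmost name.

## Quantification

An allele row from a mutant sample survives only if its raw count is at
least 2× the count of the same allele in the pool's non-mutant control
(ties kept; strictness switchable) **and** at least 4 reads. INTACT is
never filtered. Surviving counts are scaled to reads per million (RPM) of
the sample's assigned total (INTACT + surviving alleles); unassigned error
reads do not enter the denominator. Log scores are log10(RPM + 1).

## Fidelity statistics

The percent change in allelic identity between two samples is
`Σ_classes |RPM_a − RPM_b| / 2 / 10⁶ × 100` over the union of classes with
INTACT included (a flag excludes it) — the total-variation distance between
the two compositions on a 0–100 scale. It is a metric; the implementation
rejects inputs whose totals deviate from 10⁶ by more than 0.1%.

Pooled regressions fit log10(RPM+1) of the later limb on the earlier limb
across all alleles and animals, excluding points zero in both, via ordinary
least squares; r² is the squared Pearson correlation (base-invariant) and
the p-value is the standard slope test. Frequency bins split alleles at
1.6% (low) and 6.5% (high) of reads. Fold-change categories use factor-2
boundaries: lost (after = 0), decreased (after ≤ before/2), retained
(before/2 < after ≤ before), increased (after > before); "less than a
one-fold decrease" is read as after > before/2. Lost/recovered accounting
flags alleles present in one limb but absent from the next, and counts them
recovered if they reappear in any later limb or tissue sample; the pooled
summary restricts to animals with at least three limb stages, since
recovery is undefined without later compartments.

## Tissue analysis

An allele is single-tissue enriched when its abundance in one of the six
dissected tissues exceeds 16× the maximum of the other five, and
double-tissue enriched when the top two each exceed 16× the maximum of the
remaining four without qualifying singly. Ratios are computed on RPM+1 to
guard zeros, consistent with the log convention, which also makes the calls
scale-invariant for abundances well above 1 RPM. Fisher's exact test
(two-tailed) asks per tissue whether enriched alleles are over-represented
among alleles in a fold-change category; it is computed by exact integer
hypergeometric enumeration (summing point probabilities not exceeding the
observed table's), so tie handling needs no floating-point fudge factor.
The tissue–tissue similarity matrix is the pairwise r² of log10(RPM+1)
across the six tissues plus the hand, pooled over animals with both-zero
alleles excluded.

## The generative model

The simulator encodes the study design as its defaults: 19 animals split
2–4 per gRNA across 6 synthetic targets; allele count per animal drawn as
round(N(27.3, 10.2)); all animals followed through a secondary limb, 12
through a tertiary limb and 4 through a quaternary limb dissected into six
tissues plus the hand; 50,000 reads per sample (within the lower range of
real runs) at a 5·10⁻⁴ per-base substitution error rate.

* **Indel spectrum.** Deletion length ~ geometric(mean 6, capped at 40)
  positioned to overlap the cut window; insertion length ~ geometric(mean
  2, possibly 0); 15% of events are pure cut-site insertions. Candidates
  are rejection-sampled until the left-aligned indel still qualifies, the
  mutant amplicon has lost its protospacer+PAM match, and re-aligning the
  mutant recovers the same canonical name — this discards events that are
  indistinguishable from substitutions (equal-length del+ins) or that
  canonicalize to a different placement, so truth and caller always agree
  on names. The true per-gRNA spectrum is unknown; this one reproduces a
  many-rare/few-common allele distribution without modeling repair pathway
  choice.
* **Hotspots.** Each editing event draws from a small per-target pool of
  recurrent indels with probability 0.2, reproducing the observation that
  high-frequency alleles recur across animals while rare alleles are
  mostly private.
* **Composition.** Limb composition ~ Dirichlet with concentration 3.0 for
  INTACT and 0.3 per allele, giving a skewed spectrum (few alleles above
  6.5% of reads, many below 1.6%) and a substantial intact fraction.
* **Regeneration.** The next limb ~ Dirichlet(previous × 25). The
  concentration 25 was chosen from the Dirichlet variance formula so that
  expected identity change lands in the 10–25% band regarded as faithful
  regeneration; a copy flag implements the concentration→∞ limit exactly.
  Each lineage below 1.6% in the source limb is independently dropped with
  probability 0.1.
* **Tissues.** Each allele lineage splits across the six tissues with a
  sparse Dirichlet(0.3), so some lineages are effectively single-tissue;
  INTACT uses concentration 5.0 (unedited cells occur everywhere). Tissue
  composition is the hand composition reweighted by these splits.
* **Reads.** Per-sample counts are multinomial at the configured depth;
  reads are tag + mutant amplicon with i.i.d. substitution errors and fixed
  quality "I" (single-ended; paired-end merging is assumed upstream).
  Sample tags are generated at pairwise Hamming distance ≥ 2 so a single
  sequencing error cannot reassign a read to another sample — with
  distance-1 tags, tag bleed-through dominates the error budget of the
  identity-change statistic.

All randomness flows from one seed through fixed-offset substreams, so a
fixed seed gives byte-identical FASTQ and truth tables. The read-sampling
stream for a compartment is keyed on the compartment's *composition*
rather than its label: compartments with identical true composition
receive identical reads. This makes the perfect-copy limit exact end to
end (identity change 0.0, pooled r² = 1.0) while leaving ordinary runs
unaffected, since resampled compositions are almost surely distinct.

## What the simulation does and does not show

Passing the round-trip suite shows the pipeline recovers allele identities
and counts exactly on error-free reads, and recovers true identity change
within a fraction of a percentage point at realistic depth and error rates
(multinomial sampling alone contributes ~0.3–0.8 points at depth 50,000).
The generator does not model PCR amplification bias or chimeras, recurrent
artifacts shared with the non-mutant control (so the control-fold filter is
exercised only against sporadic errors), indel-generating sequencing
errors, depth variation between samples, or lineage selection during
regeneration. Recovery rates of "lost" alleles are lower in simulation
than in real data because most simulated losses are lineages permanently
below the detection threshold, whereas real losses are often marginal
sampling dropouts that reappear in deeper samples.

## Numerical and degenerate-input choices

Coordinates are 1-based inclusive on the reference amplicon; insertions
anchor to the base they follow (0 = before base 1). Reads shorter than 30
nt are counted unalignable. Alleles whose junction cannot yield a
full-length representative (deletions removing nearly the whole amplicon)
are skipped at discovery and their reads counted as error. Zero-total
samples are dropped from normalization with a warning; no-template
controls never enter normalization. Regression requires ≥3 retained
points; the tissue r² leaves cells NaN when fewer than 3 informative pairs
exist or either vector is constant. Fisher tables must be non-negative
integers; the all-zero-margin table has p = 1.

## Problem sizes

The test suite simulates cohorts of 2–20 animals at depths of 300–50,000
reads per sample; the reproduction script runs the full 19-animal design at
50,000 reads per sample (about 4 million reads end to end), completing in
well under a minute on one core.
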