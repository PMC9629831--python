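# Methods

This note documents the models behind each `moltmap` stage, the defaults and
why they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions that matter for reproducing results.

## Temporal model and phase fitting

Oscillating expression is modelled as a single harmonic on the log2 scale:

    y(t) = baseline + A · cos(2π (t − t_peak) / T) + ε,   ε ~ N(0, σ²)

with period T = 8 h sampled hourly for 16 h (two full cycles). The fit is
ordinary least squares on the design [1, cos ωt, sin ωt]; the peak phase is
φ = atan2(b, a) expressed in degrees, the amplitude is √(a²+b²), and the
oscillation call combines the F-test of the two harmonic coefficients
(p < 0.001, matching the threshold the upstream time-course study used) with
an amplitude floor (default 0.1 log2 units). The floor exists because at low
noise the F-test flags biologically negligible wobbles; 0.1 log2 units
(≈ 7% peak-to-trough) is far below the planted amplitude range (0.5–2.0) and
far above fitting noise, so the call is insensitive to its exact value.

Hourly bins are half-open: [45°(k−1), 45°k) → hour k, k = 1..8. Half-open
intervals partition the circle exactly, so no gene can fall in two bins; hour
labels are 1-based so the molt overlay peaks "in the sixth hour". A constant
expression row returns amplitude 0 and p = 1 — not an error, since real
tables contain silent genes. Rows with fewer than four timepoints are
errors (the three-parameter model would be saturated).

Ties in the molt-overlay argmax return the earliest tied bin with a logged
warning; an all-zero overlay is an error. Ingested tables that already carry
phases (pass-through mode) skip fitting entirely; peak hours are re-derived
from the phases so the bin convention is uniform either way.

## Enrichment, secretome and binned statistics

Tissue enrichment follows the published filter: TPM in the target tissue
strictly greater than 1.5× the reference and at least 25 TPM. "Relative to
all other tissues" is read strictly — the reference is the *maximum* of the
other tissues — because that reading is reproducible and at least as
conservative as any alternative; a mean-of-others mode (`mode="mean"`) is
provided for comparison. The secretome cutoff is an inclusive signal-peptide
score ≥ 0.45 (the SignalP v4.1 convention); genes without a score fall in
the non-secreted class with a warning rather than erroring, since score
tables routinely lack retired or non-coding entries.

Binned abundance profiles report mean ± SEM per hourly bin with a two-tailed
one-sample Student's t-test of the bin's values against the global average
transcript number. The global average is, by default, the mean over the
supplied gene set; the pipeline passes the genome-wide mean of the target
tissue column instead (≈ 10⁶/n genes after TPM normalization, ≈ 49 at the
20,330-gene scale), because the ~30-fold molt-hour burst of the secreted
pharynx set is defined against that genome-wide reference, not against the
already-elevated subset mean. The lagged cluster test compares bin b against
bin b−2 with a one-sided two-sample Student's t-test at p < 0.01; bins 1–2
have no comparator and bins with fewer than two genes are never flagged. No
multiple-testing correction is applied anywhere, matching the source
analysis; equal-variance (classic Student) forms are used throughout.

## SEG low-complexity detection

The detector is a faithful two-stage windowed-entropy scan:

1. **Trigger/extend.** Every 12-residue window's Shannon entropy
   K2 = −Σ (nᵢ/12) log2(nᵢ/12) is computed by a rolling count update.
   Windows with K2 ≤ 2.2 bits trigger; each trigger extends to the maximal
   contiguous run of windows with K2 ≤ 2.5 bits, and overlapping residue
   spans merge into candidate regions.
2. **Refinement.** Within each candidate region the reported segment is the
   subsequence minimizing the compositional probability
   P₀ = Ω·F / 20^L, Ω = L!/∏nᵢ!, F = 20!/∏ r_k! (r_k = number of residue
   types occurring exactly k times, k = 0 included). P₀ is evaluated in log
   space with log-gamma to avoid overflow; candidates within 10⁻⁹ in log P₀
   are ties, broken by longest then leftmost. Distinct compositions differ
   in log P₀ by far more than 10⁻⁹ at these lengths, so the tolerance only
   absorbs floating-point noise.

Sequences shorter than the window return no segments (warned), avoiding an
invented short-window variant. Non-canonical letters are an error by
default; `on_noncanonical="skip"` excludes them from windows and segments
instead, mirroring the canonical-alphabet filtering used upstream. The test
suite checks the scan against an exhaustive brute-force enumeration with
exact rational arithmetic on hundreds of short sequences.

%LCR is the fraction of residues covered by segments; %IDR reduces a
per-residue disorder-probability track to maximal runs of ≥ 30 residues at
probability ≥ 0.5 (the predictor's own binary convention — the 30-residue
rule is the analysis's, the 0.5 threshold the tool's) — both exposed as
parameters. Residue compositions are averaged per protein (each protein one
percentage vector, unweighted), so rows sum to 100 regardless of length
distribution; a pooled length-weighted mode exists behind a flag. PLAAC
scores are shifted by +60 for display (the algorithm's floor is −60), and
raw scores below the floor are rejected as corrupt input.

## Family discovery

Percent identity comes from global alignment with BLOSUM62, gap open 10,
gap extend 0.5 (Biopython's `PairwiseAligner`). The denominator is the
**full alignment length** including gap columns. Two alternatives were
evaluated and rejected as defaults after direct failure analysis on
low-complexity sets: a gap-excluded denominator lets unrelated
biased-composition pairs score 30–60% through a short chance-aligned core,
and a shorter-sequence denominator lets a short sequence scatter-match (an
LCS effect, cheap under 0.5-per-column gap extension) inside a much longer
one at 30–36%. Either failure bridges families under single linkage. Both
modes remain selectable (`denominator="aligned"` / `"shorter"`).

Families are single-linkage connected components at identity ≥ 30% with at
least 3 members; smaller components are singletons. Labels are assigned by
descending size, then lexicographically smallest member, making the
assignment invariant under input order. The 30% threshold is a package
default (the original family boxes were drawn by eye); the discovered family
count on real data is threshold-dependent and the threshold is recorded in
the output provenance. Multiple alignment is center-star (the member with
maximal summed identity is the center; "once a gap, always a gap" merging),
which is adequate for tight intra-family similarity and guarantees that
degapping any row recovers its input sequence — it is not a general MSA
tool. Position frequency matrices divide residue counts by the row count,
so residue frequencies plus gap fraction sum to 1 per column and the column
occupancy is the logo stack width.

## Synthetic data: what it emulates, what it does not

The generator's defaults reproduce the mapped dataset's composition: 20,330
genes, 2716 oscillating, 602 molt-upregulated among them (planted phases
wrapped-normal around the hour-6 bin center, SD 25°, so the overlay
concentrates with realistic spill into adjacent bins), per-tissue enriched
counts of 470/326/426/832/411/781/965 (pharynx through neurons, scaled
proportionally for smaller genomes) with 367/470 of the pharynx set
oscillating, 4-fold planted enrichment, and signal-peptide incidence of
62% / 39% / 17% in the oscillating-enriched / other-oscillating /
non-oscillating strata (Bernoulli per gene, so realized fractions vary
binomially). Secreted pharynx-enriched genes peaking in the molt hour carry
a transcript burst planted at exactly 30× the post-burst genome-wide mean
(the planted value is solved from that self-consistency condition, and
column normalization to 10⁶ preserves the ratio). Amplitudes are uniform on
0.5–2.0 log2 units — the upstream study does not publish its amplitude
distribution, so the range is a parameter, not a fixed claim.

Families are built from six consensus sequences drawn from biased residue
frequencies (0.50 dominant + 0.25 secondary over background), with disjoint
dominant/secondary pairs (Q/P, C/S, G/A, N/D, T/V, H/R) mirroring the
composition contrasts of the real families; members are consensus copies
with independent per-residue substitution at rate 0.15 (default plan
12/10/8/6/5/5 members, shrunk gracefully when a small simulated genome
cannot host it, strict when sizes are given explicitly). Secreted proteins
get a 20-residue hydrophobic leader ("M" + L/A/V/I/F) and a score ≥ 0.45;
family bodies carry disorder probability 0.9 and a background fraction of
proteins receives a random ≥30-residue disordered run.

Not emulated: read-count noise and dropout of real single-cell data,
sequence evolution by indels (family members differ only by substitutions,
which is why center-star suffices), 3′UTR/intron structure, real WormBase
identifiers, tempo changes between larval stages, and any wet-lab
observable. Consequently, passing recovery tests shows the pipeline's logic
is correct under the stated noise model — it does not certify performance
on real single-cell matrices, where enrichment calls are sensitive to
normalization choices that the pipeline deliberately leaves to the user
(TPM columns are used as provided; re-normalization is opt-in).

## Problem sizes and determinism

Every random draw flows from a single integer seed through per-stage
independent streams, so any subset of generator stages is bit-reproducible
in any call order. The test suite and the acceptance script use scaled
problem sizes chosen to exercise every code path with comfortable margins:
genome-scale (20,330 genes) runs for map statistics and 100-replicate
molt-hour stability, 6000 genes where the full six-family plan must fit,
1200 noise-free genes for exactness checks, 200 genes for phase-accuracy
measurement, and ≤ 40-residue sequences where exhaustive SEG enumeration is
feasible. Output tables are deterministically ordered (phase, then gene id)
so diffs are meaningful.

## Known limitations

* The oscillation model is a single harmonic; genes with strongly
  non-sinusoidal waveforms get a best-fit phase whose bin may differ from
  the argmax hour.
* SEG refinement reports one minimal-P₀ segment per merged candidate
  region; the classic recursive re-splitting of very long mixed regions is
  not performed (segments here are short enough that the difference does
  not arise).
* Identity-threshold family counts on real proteomes are
  threshold-dependent; the package reports the threshold with the output
  rather than asserting a count.
* The %IDR-based "disordered protein" classification depends on a cutoff
  that the source analyses never fixed numerically; it is exposed as a
  parameter and no default classification of whole proteins is made.
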