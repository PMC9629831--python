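# moltmap

Phase-resolved mapping of the *Caenorhabditis elegans* pharyngeal-cuticle
secretome over the molting cycle.

At 25 °C, *C. elegans* larvae molt about every 8 hours, shedding and rebuilding
both the body cuticle and the chitinous cuticle that lines the pharynx.
Thousands of genes oscillate in expression with this period; the subset that
is enriched in pharyngeal cells and carries a predicted signal peptide is the
candidate raw material of the pharyngeal cuticle — and it is strikingly rich
in low-complexity, intrinsically disordered proteins that fall into a handful
of nematode-specific families. `moltmap` implements the informatic side of
that analysis as a reusable, tested pipeline for anyone mapping oscillating
secretomes from expression time courses, single-cell tissue summaries and
protein sequence:

* **Temporal map** — each gene's expression row y(t) is fit by harmonic
  (cosinor) regression, y ~ β₀ + a·cos(ωt) + b·sin(ωt) with ω = 2π/8 h⁻¹.
  The peak phase φ = atan2(b, a) (degrees in [0, 360)) maps to an hourly bin
  k = ⌊φ/45°⌋ + 1; a gene is called oscillating when the F-test of the
  harmonic terms gives p < 0.001 and amplitude √(a²+b²) clears a floor.
  Overlaying a molt-upregulated gene set on the binned map locates the
  reference molting hour (hour 6).
* **Enrichment and secretome** — a gene is tissue-enriched when its TPM in
  the target tissue exceeds 1.5× that of every other tissue and is ≥ 25 TPM;
  the secretome is the set with signal-peptide score ≥ 0.45. Binned
  abundance profiles are tested per bin against the global average transcript
  number with one-sample Student's t-tests.
* **Sequence properties** — a native SEG implementation (window 12, trigger
  K2 ≤ 2.2 bits, extension K2 ≤ 2.5 bits, minimal-P₀ refinement) yields %LCR;
  disorder tracks are reduced to IDRs (runs of ≥ 30 residues at probability
  ≥ 0.5); external predictor scores (PLAAC with the +60 display offset,
  PSPredictor, LLPhyScore, …) are aggregated per group, and property values
  are transcript-weighted into temporal waves.
* **Family discovery** — all-vs-all global-alignment percent identity
  (BLOSUM62, gap open 10 / extend 0.5), single-linkage clustering at an
  identity threshold, center-star multiple alignment and position frequency
  matrices (the numeric substrate of sequence logos) per family.
* **Synthetic data** — a generator that plants all of the above (cosine
  oscillations with an 8-h period, a molt-concentrated subset, pharynx
  enrichment with a molt-hour transcript burst, stratified signal peptides,
  biased-composition low-complexity families), so every stage is testable
  against known truth.

## Worked example

```python
from moltmap.synthetic_data import SimConfig
from moltmap.pipeline import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(sim=SimConfig(n_genes=6000, seed=3)))
print(bundle.summary)
```

prints (reformatted):

```json
{
  "n_genes": 6000,
  "n_oscillating": 798,
  "n_enriched_target": 139,
  "n_oscillating_enriched": 108,
  "n_secreted_enriched": 62,
  "molt_hour": 6,
  "global_mean_tpm": 166.67,
  "secretome_fractions": {
    "oscillating_enriched": 0.574,
    "oscillating_other": 0.390,
    "non_oscillating": 0.172
  },
  "n_family_candidates": 45,
  "n_families": 6
}
```

Reading this: of 6000 simulated genes, 798 are called oscillating (harmonic
F-test p < 0.001); 108 of them are pharynx-enriched and 62 of those carry a
signal peptide — 57% of the enriched oscillators versus 39% of the remaining
oscillators and 17% of the silent genome, the stratification that marks the
molting secretome. The molt overlay peaks in hour 6, and among the secreted
pharynx-enriched low-complexity proteins the pipeline recovers the six
planted families. `bundle.write(outdir)` emits every table (map, strata,
bin profiles, property table, identity matrix, families, PFMs) as TSV plus a
JSON provenance block.

The same stages are scriptable from the shell:

```sh
moltmap simulate --seed 3 --n-genes 6000 --out sim/
moltmap map --timecourse sim/timecourse.tsv --molt sim/molt_genes.txt --out map.tsv
moltmap enrich --tissue-matrix sim/tissue_tpm.tsv --signalp sim/signalp_scores.tsv --out enriched.tsv
moltmap seg --fasta sim/proteome.fasta --out segments.tsv
moltmap families --fasta sim/proteome.fasta --trim-signal --out families/
moltmap all --seed 3 --n-genes 6000 --out report/
```

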