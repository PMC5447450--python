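# wgsdx

Clinical whole-genome diagnostic analysis as a tested, reusable pipeline:

- **`wgsdx.prioritize`** — tiered prioritization of small variants (quality,
  frequency, impact/conservation, disease association), zygosity vs. gene
  mode-of-inheritance sorting (including unphased compound-het candidates), a
  simplified deterministic pathogenic/likely-pathogenic/VUS rule table, and
  reproducible candidate ranking.
- **`wgsdx.cnv`** — read-depth CNV and junction SV filtering (non-diploid,
  hypervariable/chrY exclusion, mate-pair support ≥ 20), fragment merging,
  control-cohort/common-variant frequency annotation, gene/exon overlap,
  CNV classification, and the microarray-vs-sequencing concordance procedure
  (segdup ≥ 70% and ≥ 3% frequency exclusions, 50% reciprocal-overlap
  matching, probe-boundary breakpoint concordance).
- **`wgsdx.secondary`** — secondary-findings screen against the packaged
  56-gene medically actionable panel, honouring per-case consent.
- **`wgsdx.stats`** — diagnostic yield, Yates-corrected two-proportion χ²,
  Wilson/Clopper–Pearson binomial CIs, phenotype-subgroup yields via ontology
  closure, multi-locus and combined-actionable counts, origin summaries.
- **`wgsdx.simulate`** — a fully self-contained synthetic cohort generator
  (reduced genome, gene models, tracks, control CNVs, VCF + annotation +
  CNV/SV/CMA files, phenotypes, consent) with planted causal scenarios and a
  ground-truth manifest; per-genome intensities calibrated to a clinical WGS
  profile (~20k exonic/splicing variants, ~500 rare damaging events, ~248
  CNVs / ~1,604 SVs per genome at full scale).
- **`wgsdx.io` / `wgsdx.cli`** — VCF 4.2, BED and headered-TSV readers/writers
  with strict validation, YAML threshold config, and a staged CLI.
- **`wgsdx.fixtures`** — packaged transcriptions of the worked-example
  diagnosis and secondary-finding tables used by the acceptance tests.

All thresholds live in `wgsdx.ThresholdConfig` and are overridable from YAML.
Interval records are 0-based half-open; VCF positions are 1-based.

## CLI

```bash
# generate a seeded synthetic cohort (VCFs, CNV/SV/CMA TSVs, manifest)
wgsdx simulate --seed 7 --cohort-n 30 --scale 0.1 --out runs/cohort

# run the full pipeline (prioritize -> cnv -> secondary -> stats)
wgsdx -v all --cohort runs/cohort --out runs/results

# or individual stages
wgsdx prioritize --cohort runs/cohort --out runs/results
wgsdx cnv --cohort runs/cohort --out runs/results --config thresholds.yaml
```

Outputs: `candidates.tsv` (ranked per-case diagnostic candidates),
`cnv_annotated.tsv`, `secondary.tsv`, `concordance.json`, `summary.json`
(yield, 95% CI, χ², multi-locus and secondary-finding blocks). `-v` prints
per-stage record counts to stderr.

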