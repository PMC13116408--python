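# twinsnv

Replicate-concordant SNV genotype comparison for distinguishing monozygotic
twins from sequencing data, plus a seeded twin-pair simulator that makes the
whole pipeline testable without any external data.

The pipeline:

1. **Ingest** per-replicate single-sample VCFs (GT/AD/DP/GQ) for a trace
   sample and a reference sample, two or more replicates each.
2. **Filter** each replicate call: depth floor, genotype-quality floor, a
   heterozygote-balance (Hb) window for hets — Hb is the alternate-allele
   fraction `alt / (ref + alt)` — and optionally a homozygote-noise ceiling.
   Only genotypes accepted identically in every replicate of a sample
   survive (replicate concordance).
3. **Compare** trace and reference consensus genotypes over the domain of
   loci accepted in both samples with a variant in at least one; report
   discordant loci with full per-replicate evidence.
4. **Sweep** Hb stringency over a list of windows (default:
   `none, 0.2:0.8, 0.4:0.6, 0.45:0.55`) to show the sensitivity/specificity
   trade-off: skewed tissue-specific somatic variants (alt fraction
   typically 5–20%) leak through permissive windows and are excluded by
   stringent ones.
5. **Validate** candidates on targeted-panel VCFs under a stricter regime
   (default DP ≥ 100, GQ ≥ 10, Hb 0.3–0.7, noise < 0.05) and fold per-locus
   verdicts into a case outcome (`distinguishable` vs
   `no_detectable_difference`).

The simulator generates germline genotypes shared by both twins,
twin-specific post-zygotic heterozygous mutations, tissue-specific somatic
variants with skewed alt fractions, Poisson depth, binomial read sampling
with sequencing error, and a binomial-likelihood genotype caller — emitting
valid VCFs plus a ground-truth table.

## CLI

```sh
# synthetic case: four replicate VCFs + truth.tsv + config echo
twinsnv simulate --config config.json --out-dir sim/

# trace vs reference comparison under the shotgun regime
twinsnv compare \
    --trace-vcf sim/trace_rep1.vcf --trace-vcf sim/trace_rep2.vcf \
    --reference-vcf sim/reference_rep1.vcf --reference-vcf sim/reference_rep2.vcf \
    --dp-min 8 --gq-min 10 --hb 0.4:0.6 --out-dir cmp/

# Hb stringency sweep (same inputs)
twinsnv sweep --trace-vcf ... --reference-vcf ... --out-dir swp/

# regenerate the case with panel VCFs for the candidates found above
twinsnv simulate --config config.json --out-dir panel/ \
    --candidates cmp/candidates.tsv --n-controls 54

# targeted-panel confirmation
twinsnv validate --candidates cmp/candidates.tsv \
    --design panel/panel_design.tsv \
    --trace-vcf panel/panel_trace_rep1.vcf --trace-vcf panel/panel_trace_rep2.vcf \
    --reference-vcf panel/panel_reference_rep1.vcf \
    --reference-vcf panel/panel_reference_rep2.vcf \
    --out-dir val/
```

Every command writes a `manifest.json` (parameters, input digests, version,
timestamp). Result TSV/JSON files are byte-deterministic for fixed inputs
and seed. Exit codes: 0 success, 1 data error, 2 usage error.

`--hb` takes `LO:HI` or `none`; `--schemes` takes a comma-separated list of
the same tokens. Filter presets `shotgun` (8, 10, 0.4–0.6, no noise filter)
and `targeted` (100, 10, 0.3–0.7, noise < 0.05) are available from
`twinsnv.filtering`.

## Library entry points

- `twinsnv.core` — `Locus`, `ReadSupport`, `GenotypeCall`, `FilterConfig`,
  `heterozygote_balance`, `noise_fraction`
- `twinsnv.filtering` — `accept_genotype`, `replicate_consensus`,
  `consensus_map`, presets
- `twinsnv.discordance` — `comparison_domain`, `find_discordances`,
  `compare_samples`, `hb_sweep`, `coverage_summary`
- `twinsnv.panel` — `validate_candidates`, `validate_panel`, `case_verdict`
- `twinsnv.simulate` — `SimulationConfig`, `simulate_twin_pair`,
  `simulate_panel`, `write_simulation`
- `twinsnv.vcf_io` — `read_sample_calls`, `write_vcf`, `write_candidates`
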