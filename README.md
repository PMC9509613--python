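# wgspred

Genomic prediction with GWAS-preselected whole-genome-sequence variants in
pedigreed livestock populations: does augmenting a marker array with
sequence variants preselected by association tests improve prediction
accuracy? The full study design is implemented as a tested, reusable
pipeline and exercised entirely on synthetic populations.

The pipeline covers:

- **simpop** — multi-line pedigree simulation (discrete generations,
  full-sib litters), founder haplotypes with distance-decaying LD,
  gene-dropping with Haldane recombination, a nested "chip" marker panel,
  and additive traits with configurable heritability and QTN count.
- **relmat** — pedigree numerator relationship matrix (tabular method) and
  genomic relationship matrix (VanRaden method 1).
- **traitprep** — single-record animal-model BLUP (Henderson's MME) and
  deregression of EBV (parent average removed, Mendelian-sampling part
  unshrunk), plus a bypass that feeds simulated phenotypes through.
- **gwas** — single-variant linear mixed model: spectral REML for the null
  variance components, then a fixed-variance GLS scan with Wald p-values.
  The polygenic covariance uses chip variants only.
- **preselect** — QC filters (MAF, call rate, HWE), 55-kb window index,
  Top-k-per-window sets, ChipPlusSign (chip plus one significant proxy per
  window at p ≤ 1e-6), and multi-line variant universes.
- **bayesr** — from-scratch Gibbs sampler for the four-component mixture
  prior (variances 0, 1e-4, 1e-3, 1e-2 × σg², re-estimated every
  iteration), optional line fixed effect, and GEBV prediction.
- **evaluate** — full-sib-family test sets, relationship-pruned training
  sets, training-set reduction, family-exclusive replicate splits,
  accuracy (correlation) and bias (regression slope) metrics, and the
  accuracy-difference-vs-training-size regression.
- **io / pipeline / cli** — TSV and VCF formats, YAML run configs, and a
  one-command deterministic pipeline runner.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (relationship
oracles, REML/GWAS calibration, preselection brute-force equivalence,
BayesR recovery, study-design identities, the directional
simple-vs-polygenic architecture result, and pipeline determinism). The
heavy criteria take several minutes each; the whole suite runs in roughly
20 minutes on one CPU. One assertion — zero-class mixture dominance on
pure-noise traits — fails by design at desk-scale sample sizes and is
documented as such in its docstring.

## CLI

```bash
wgspred pipeline --config configs/example.yaml --out out/
```

runs simulate → QC → GWAS → preselect (Chip / Top-k / ChipPlusSign) →
BayesR → evaluate → compare, persisting every intermediate as TSV with the
config hash and seed in a header comment, plus a `manifest.json` of
content hashes. Re-running the same config and seed reproduces every file
bit-for-bit.

Individual stages are exposed as subcommands operating on TSV/VCF files:

```bash
wgspred simulate  --config configs/example.yaml --out sim/
wgspred qc        --genotypes sim/dosages.tsv --panel wgs --out mask.tsv
wgspred traitprep --phenotypes phen.tsv --pedigree sim/pedigree.tsv --h2 0.3 --out resp.tsv
wgspred gwas      --genotypes sim/dosages.tsv --trait resp.tsv --k-panel chip --out scan.tsv
wgspred preselect top          --gwas scan.tsv --target 40000 --out top.tsv
wgspred preselect chipplussign --gwas scan.tsv --genotypes sim/dosages.tsv --p 1e-6 --out cps.tsv
wgspred fit       --genotypes sim/dosages.tsv --trait resp.tsv --variants cps.tsv --seed 7 --out fit/
wgspred predict   --fit fit/ --genotypes sim/dosages.tsv --out gebv.tsv
wgspred evaluate  --gebv gebv.tsv --response resp.tsv --out eval.tsv
wgspred compare   --reports report.tsv --out comparison.tsv
```

## Configuration

See `configs/example.yaml` for a commented, minute-scale example. All
randomness is controlled by the single global `seed`; every stage derives
its own stream deterministically from it.
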