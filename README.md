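# adaptscan

Inference of local adaptation from replicated evolve-and-resequence (E&R)
experiments, modelled on a greenhouse selection design with outcrossing
*Brassica*-type annuals: two soil types (limestone / tuff), aphid herbivory
present or absent, and bumblebee- versus hand-pollination — eight treatment
groups, two replicate lines of 49 plants each, eight generations of selection
followed by two hand-pollinated wash-out generations, with generations 1 and
10 resequenced and a reciprocal-transplant assay at the end.

The package is aimed at researchers who want to ask, from such a design:

1. **Which loci changed frequency more than drift allows?** A
   replicate-stratified Cochran–Mantel–Haenszel (CMH) test on per-marker
   2×2 allele-count tables (generation 1 vs 10 × alt vs ref), with a
   *drift-aware* variance that inflates the null by the binomial variance a
   Wright–Fisher population of effective size *Ne* accumulates over *t*
   transmissions, Benjamini–Hochberg FDR, and 2-kb window pruning.
2. **Which of those loci matter for fitness?** Ridge-regression BLUP of
   marker effects (*y* = μ + **X**g + e, g ~ N(0, σ²_g **I**)) for the
   fitness-proxy trait "number of open flowers", with REML variance
   components, −1/0/+1 genotype coding, mean imputation, a 50% missingness
   cap and a 60% training split; markers lacking an effect in either
   replicate are discarded.
3. **Trade-off or conditional advantage?** Significant, effect-bearing
   markers are classified as antagonistic pleiotropy (AP: |Δp| > 0.1 in
   both soils, opposite directions, in both replicates), conditional
   neutrality (CN: |Δp| > 0.2 in one soil, < 0.1 in the other), or other;
   markers are annotated to genes within ±1 kb and AP prevalence is
   compared between treatments with a binomial-GLM likelihood ratio.
4. **Is the population phenotypically locally adapted?** A linear mixed
   model of the transplant data (soil line × growing soil, replicate random
   intercept); the verdict requires a significant G×E interaction *and* a
   significant, positive "local vs foreign" contrast.

A forward-time simulator of the full design (fecundity selection,
pollen-limited bee pollination, seed-share reproduction quotas, Mendelian
transmission, known AP/CN/neutral ground truth) makes every stage testable
without external data. Real data in standard formats (VCF, 012 dosage
matrices, phenotype CSV, GFF3) are read through `adaptscan.io_formats` with
the usual variant filters (biallelic SNPs, QUAL > 20, DP 6–100, maf ≥ 0.01).

## Worked example

```python
import numpy as np
from adaptscan.synthetic_experiment import (
    ExperimentConfig, TraitModel, run_experiment, strong_selection_architecture)
from adaptscan import pipeline
from adaptscan import phenotype_adaptation as pa

cfg = ExperimentConfig(rng_seed=1)            # 8 treatments x 2 reps x 49 plants
arch = strong_selection_architecture()        # 20 AP, 30 CN, 300 neutral loci
result = run_experiment(cfg, arch, TraitModel(gxe_effect=0.5))

analysis = pipeline.analyze_group(result, herbivory=True, pollination="bee",
                                  rng=np.random.default_rng(1))
print("significant markers:", analysis.n_significant)
print(analysis.calls["class"].value_counts().to_dict())
print(pipeline.evaluate_against_truth(analysis, result.truth))

hb = result.transplant.query("biotic_group == 'HB' and generation == 10")
model = pa.fit_gxe(hb)
cons = pa.contrasts(model)
print(pa.assess_local_adaptation(model, cons).adapted)
```

prints

```
significant markers: {'LHB': 97, 'THB': 99, 'HB': 196}
{'OTHER': 128, 'AP': 28, 'CN': 2}
{'n_true_ap': 20, 'n_true_ap_significant': 15, 'ap_recovery': 1.0,
 'n_neutral': 300, 'neutral_mislabel_rate': 0.04}
True
```

Of the 350 markers under selection, 196 window representatives survive the
drift-aware CMH + FDR + replicate-consistency filter in the
herbivory/bee-pollination group; all 15 antagonistic loci that reach
significance in both soils are classified AP, 4% of neutral loci pick up a
spurious AP/CN label, and the built-in 0.5-trait-unit local advantage yields
a positive local-adaptation verdict (G×E χ²₁ = 9.26, p = 0.002; local vs
foreign +0.45, p = 0.003).

The same stages are scriptable from a shell:

```bash
adaptscan simulate --out demo --seed 4
adaptscan scan --dir demo --treatment LHB
adaptscan classify --dir demo
adaptscan phenotest --phenotypes demo/phenotypes_transplant.csv
```

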