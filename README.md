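# secophen

Association testing and effect estimation for **secondary phenotypes** in
case-control genetic studies, where ascertainment on disease status distorts
the joint distribution of genotype and any trait correlated with disease.

The package implements a two-step workflow:

1. **Screen** every SNP with a fast proportional-odds (cumulative-logit)
   likelihood-ratio test of the ordinal genotype on the secondary phenotype,
   conditioning on disease status. Both component models condition on
   case-control status, so the test is valid under ascertainment without
   modelling the sampling, and there is no flat likelihood surface to
   maximize — the test runs in milliseconds per SNP.
2. **Estimate** effect sizes for the significant SNPs with a retrospective
   likelihood that models the case-control sampling explicitly
   (logistic disease model × normal trait model × genotype-frequency
   simplex, normalized by the population disease probability). The surface
   of this likelihood can be nearly flat in the disease-model intercept
   direction; the fitter supports multi-start quasi-Newton iteration with an
   analytic gradient, an optional fixed-disease-rate constraint that
   profiles the intercept out, and explicit flat-surface/non-convergence
   flags.

Also included: a calibrated ascertainment simulator (Hardy–Weinberg
genotypes, normal trait, logistic disease model, quota sampling of cases and
controls, Gauss–Hermite-calibrated disease intercept) and a simulation-study
harness for type-I-error and power comparisons against the naive case-only,
control-only and combined regressions.

## Python API

```python
import numpy as np
from secophen import SimulationParams, calibrate_gamma0, simulate_case_control
from secophen.assoc_tests import proposed_lrt
from secophen.linzeng import fit_retrospective, wald_test_beta1

params = SimulationParams(
    beta0=1.0, beta1=-0.12, sigma2=1.0,
    gamma1=np.log(1.5), gamma2=np.log(2.0),
    maf=0.3, n_cases=500, n_controls=500,
    target_rate=0.05, seed=1,
)
dataset = simulate_case_control(params.with_gamma0(calibrate_gamma0(params)))

screen = proposed_lrt(dataset)           # step 1: 1-df chi-squared LRT
fit = fit_retrospective(dataset, fixed_rate=0.05)  # step 2: effect estimate
wald = wald_test_beta1(fit)
print(screen.p_value, fit.beta1, fit.se("beta1"), wald.p_value)
```

Real data enter through `secophen.data_io`: delimited phenotype tables
(`read_phenotype_table`), genotype matrices (`read_genotype_matrix`) or VCF
GT/DS fields (`read_vcf_genotypes`), combined by `attach_genotypes`
(allele counts or imputed dosages; dosage values become ordinal levels, with
quantization when there are many distinct values).

## Command line

```sh
secophen simulate --params params.txt --out sim          # writes sim.{pheno,geno}.tsv
secophen test     --pheno sim.pheno.tsv --geno sim.geno.tsv \
                  --methods proposed,combined --out results.tsv
secophen estimate --pheno sim.pheno.tsv --geno sim.geno.tsv \
                  --disease-rate 0.05 --out estimates.tsv
secophen study    --grid grid.txt --out study            # rejection-rate grid
secophen surface  --pheno sim.pheno.tsv --geno sim.geno.tsv \
                  --pair beta0,beta1 --grid 0.5:1.5:21,-0.5:0.5:21 \
                  --fixed sigma2=1,gamma0=-4.1,gamma1=0.405,gamma2=0.693 \
                  --out surface.tsv
```

Parameter and grid files are plain `key = value` text; see
`secophen <cmd> --help` for options.

## Layout

| module | contents |
| --- | --- |
| `secophen.data_io` | dataset model, table/VCF readers, results writer |
| `secophen.simulate` | generative model, prevalence quadrature, γ₀ calibration, quota sampler |
| `secophen.ordinal` | proportional-odds cumulative-logit ML fit |
| `secophen.assoc_tests` | proposed LRT + case-only/control-only/combined comparators |
| `secophen.linzeng` | retrospective likelihood: fit, Wald/LRT, surface evaluation |
| `secophen.study` | power-study harness, Wilson intervals, reports/plots |
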