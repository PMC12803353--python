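# ratiomap

Ratio-phenotype association scanning for metabolomic fine-mapping:
all-pairs log-ratio association scans of genetic variants against a trait
panel, the p-gain statistic with exact Bonferroni threshold arithmetic,
per-locus-normalized p-gain clustering, replication power by subsampling,
and fixed-horizon incident-event risk — exercised end to end on a
synthetic cohort generator with known ground truth.

## Modules

| module | what it does |
| --- | --- |
| `ratiomap.synthdata` | HWE genotypes, lognormal trait panels with planted *opposed* / *confounded* / *null* variant scenarios, a shared non-genetic confounder, missingness injection, and outcome tables — all with a `TruthTable` of every generative coefficient |
| `ratiomap.preprocess` | zeros-to-missing, natural-log scaling, rank-based inverse-normal transform (Blom offset, configurable), log-ratio construction (`log A − log B`), test enumeration (`m(m+1)/2`) |
| `ratiomap.assoc` | OLS association engine with covariates and conditional variants; a Frisch–Waugh–Lovell fast path that exactly reproduces naive per-test fits; negative-log10 p-values computed in log space, accurate far below floating-point underflow (`neglog10_p_from_t`) |
| `ratiomap.pgain` | p-gain records (exact neglog10 arithmetic), threshold sets (`p_ref`, `p_NMR`, `p_NightRatios`, `p_AllRatios`, p-gain threshold), LD-r² variant curation, lead selection, discovery counting |
| `ratiomap.cluster` | lead-ratio × locus p-gain matrix, per-locus max normalization, hierarchical clustering (Newick export), effect-profile correlation, directionality panels |
| `ratiomap.repsurv` | replication testing at `0.05 / n_discovered`, replication power by repeated subsampling without replacement, incident/prevalent event flags, median-split groups, Kaplan–Meier fixed-horizon risk with Greenwood CIs |
| `ratiomap.pipeline` / `ratiomap.cli` | end-to-end orchestration from one YAML config with per-stage seeds and a checksummed run manifest |

## CLI

```bash
ratiomap run --config run.yaml        # full pipeline into an output dir
ratiomap validate --config run.yaml   # report all config issues
ratiomap preprocess --traits raw.tsv --out int.tsv --int-offset blom
ratiomap assoc --geno g.tsv --traits t.tsv --covar c.tsv --tests all --out assoc.tsv
ratiomap pgain --assoc assoc.tsv --m-traits 168 --out pgain.tsv
ratiomap cluster --matrix pgain_matrix.tsv --metric euclidean --linkage average --out out.tsv
ratiomap survive --outcomes outcomes.tsv --traits t.tsv --trait T1 --horizon 10 --out risk.tsv
```

A minimal `run.yaml`:

```yaml
outdir: demo_run
master_seed: 7
n_samples: 2000
n_traits: 20
n_variants: 50
theta: 0.3
```

Every stochastic stage derives its seed from `master_seed`, and re-running
the same config reproduces identical output checksums (recorded in
`manifest.json`).

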