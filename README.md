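# relictabc

Coalescent ABC demographic inference and climate-niche statistics for
two-refugium phylogeography.

Many East Asian Tertiary relict trees persist in two disjunct refugial
regions — a southern/southwestern one (SEA) and a northeastern one (NEA)
— and three origin histories compete to explain that disjunction: a
low-latitude origin (the northern populations founded from the south), a
high-latitude origin (the reverse), and vicariance (an ancestral range
split in two). `relictabc` is a library and command-line tool for testing
these hypotheses from multilocus phased sequence data: it simulates the
competing demographic scenarios under the structured coalescent, compares
them to the data by approximate Bayesian computation (ABC), estimates the
demographic parameters of the preferred scenario, and quantifies
climate-niche differences and isolation by environment between the
regions.

## The model in brief

Sequence data are L unlinked nuclear loci with 2 phased haplotypes per
diploid individual, sampled from populations assigned to the two regions.
Genealogies follow the structured coalescent with time in units of
4·N_ref generations: k lineages in a population of relative size x
coalesce at rate k(k−1)/x, lineages migrate at rate 4·N_ref·m, and
demographic events (merges, size changes) apply at scheduled times.
Mutations are infinite-sites with per-locus rate θ = 4·N_ref·µ·k·g.

The scenario catalogue holds 6 *split* models (one region founded from a
fraction f of the other, ancestral size equal to the origin's) and 9
*vicariance* models (ancestral size equal to the sum of the daughters'),
with optional bidirectional gene flow and post-divergence bottlenecks.
For model choice, each scenario's prior predictive distribution is
tabulated as (parameter draw, summary-statistic vector) rows; features
are MAD-standardized, the tolerance-quantile nearest rows to the observed
vector are accepted, and posterior model probabilities come from a
multinomial logistic regression of model label on features (or the
accepted-row shares). Parameters of the winning model are estimated by
local-linear regression adjustment and reported as posterior medians with
95% HPD intervals.

Summary statistics: nucleotide diversity π, haplotype diversity H_d,
segregating sites S, Watterson's θ, Tajima's D, Fu's F_S (Ewens sampling
formula), the Ewens–Watterson test, rarefied allelic richness, and
Hudson-type multilocus F_ST. Niche statistics: correlation PCA of climate
variables, Mantel and partial-Mantel IBE tests (genetic vs climate
distance controlling ln-geographic distance), Schoener's D and Hellinger
I overlap on suitability rasters, and a background randomization test
with a pluggable suitability model. Substitution-rate calibration scales
a chloroplast rate to the nuclear genome by an exact integer ratio
(default 3:16) and converts between coalescent units and ka.

See `docs/methods.md` for assumptions, defaults, numerical choices and
limitations.

## Worked example

Generate a study-shaped synthetic world (24 populations in two regions,
90 individuals, 27 loci, vicariance history with post-divergence
bottlenecks) and summarize it:

```python
from relictabc.synthetic_data import WorldConfig, generate_sequence_world
from relictabc.sumstats import summary_vector

ds, truth = generate_sequence_world(WorldConfig(seed=0))
v = summary_vector(ds).to_series()
print(f"loci: {len(ds.loci)}  individuals: {len(ds.sample_map.individuals)}  "
      f"populations: {len(ds.sample_map.populations)}")
print(f"pi (SEA): {v['SEA_pi_mean']:.2e}   pi (NEA): {v['NEA_pi_mean']:.2e}   "
      f"ratio: {v['SEA_pi_mean']/v['NEA_pi_mean']:.2f}")
print(f"inter-region Fst: {v['fst_regions']:.2f}")
print(f"true divergence: {truth['params']['T']} ka   "
      f"true sizes: {truth['params']['N_SEA']:.0f} / {truth['params']['N_NEA']:.0f}")
```

prints

```
loci: 27  individuals: 90  populations: 24
pi (SEA): 2.40e-03   pi (NEA): 1.17e-03   ratio: 2.05
inter-region Fst: 0.78
true divergence: 583.0 ka   true sizes: 32000 / 16000
```

— the generated world reproduces the qualitative structure the method is
built for: roughly twice the nucleotide diversity in the southern region
and strong inter-region differentiation under a deep (583 ka) divergence.

The same pipeline runs from the shell: `relictabc synth` writes a fixture
bundle, `relictabc sumstats` computes the statistics table and feature
vector, `relictabc simulate` builds per-scenario reference tables,
`relictabc select` and `relictabc estimate` perform model choice and
parameter estimation, and

```sh
relictabc calibrate --cp-rate 8.59e-10 --cp-hpd 3.12e-10 23.80e-10
```

reports the nuclear substitution rate 4.58e-09 (95% HPD 1.66e-09 to
1.27e-08) per site per year implied by the 3:16 cpDNA:nDNA ratio. Every
output gets a JSON sidecar recording the seed and configuration so any
artifact can be regenerated exactly.

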