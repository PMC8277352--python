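# fosmap

Brain-wide c-Fos activity mapping for the rat helping-behavior test (HBT):
a tested, reusable implementation of the full analysis chain used to ask
which brain regions underlie ingroup-biased prosocial behavior — from raw
c-Fos⁺ count tables and tracking records to task-PLS contrasts,
co-activation networks with principled threshold selection, an ensemble
eigen-region classification of condition-specific regions, fiber-photometry
ΔF/F event analysis, and the accompanying behavioral statistics.

It is written for systems-neuroscience labs that quantify immediate-early-gene
expression across many regions in grouped designs and want the whole chain —
cleaning rules included — to be scripted, seeded and testable. A synthetic-data
module generates cohorts with the same statistical structure (block-correlated
region modules, condition effects, acquisition curves, two-channel traces with
shared motion artifact), so every stage can be exercised without any animal
data.

## The analyses

**Task PLS.** For conditions *c* and regions *r*, the condition-mean matrix
**M** (column-centered by the unweighted grand mean of condition means) is
decomposed as **M** = **U S V**ᵀ. Each latent variable (LV) pairs a condition
contrast **u**ₖ with a region salience profile **v**ₖ. LV significance comes
from permutation of subject→condition labels (group sizes fixed, add-one
p-value); salience reliability from a within-condition subject bootstrap with
Procrustes alignment, and the bootstrap ratio salience/SE is thresholded at
2.57 (the 99% two-sided normal quantile).

**Co-activation networks.** Pairwise Pearson correlations of c-Fos counts
across the subjects of one condition; the top 10% of |r| pairs become
unit-weight edges (sign kept as an attribute). The retention fraction is
chosen by sweeping thresholds for a positive scale-free topology index
(log–log degree-distribution fit, R²·sign(−slope)) without sacrificing
percent connectivity or small-worldness σ = (C/C_rand)/(L/L_rand). Hubs are
regions in the top 20% of both degree and betweenness; communities come from
seeded Louvain modularity.

**Ensemble eigen-region classification.** Because a single network depends on
arbitrary choices, 40 configurations (5 thresholds × {Louvain, dynamic tree
cut} × {binary, soft power} × {baseline-only, broad reference}) are each run
end-to-end: cluster regions → take each cluster's first principal component
across subjects (its "eigen region") → multinomial logistic regression of
condition (ingroup / outgroup / reference) on that score → Bonferroni-corrected
per-contrast tests classify each cluster as ingroup-only, outgroup-only, both
or none, and every region inherits its cluster's label. A region's
ingroup-only occurrence ratio over the 40 runs measures how uniquely it marks
the ingroup condition.

**Photometry.** The isosbestic 405 nm control is fit to the 470 nm calcium
signal by OLS over the session; ΔF/F = (s470 − fit)/median(s470).
Event-triggered averages align ΔF/F at zone-entry times (±10 s), and the
second before each entry is compared with the second after by Wilcoxon
signed-rank.

**Behavior, cleaning and tracing.** Cochran's Q and Friedman tests for
acquisition curves; the 30 cm/s velocity filter and zone-entry/time-in-zone
metrics; the two-clause outlier rule (>2 group SD *and* outside the pooled
range of the other conditions); per-condition mean imputation; Fluoro-Gold
co-label fractions and their Pearson correlation with door-opening.

## Worked example

```sh
fosmap simulate --seed 3 --out demo/
fosmap clean --counts demo/counts.csv --out demo/clean.csv
fosmap pls --counts demo/clean.csv --seed 3 --out demo/pls.json
fosmap network --counts demo/clean.csv --condition HBT_ingroup \
    --threshold 0.10 --seed 3 --out-prefix demo/ingroup
fosmap ensemble --counts demo/clean.csv --seed 3 --out demo/tally.tsv
```

prints (seed 3):

```
wrote 72 subjects x 84 regions
removed 45 outliers; wrote demo/clean.csv
LV1 p = 0.001996
hubs: HIP31, HYP11, HYP32, LS, NacSh, OTH41, STR16
top ingroup-only region: NacC (92.5% of configs)
```

Reading: the simulated cohort carries a global HBT elevation plus an
ingroup-specific accumbens effect. The cleaning pass removes 45 extreme
counts by the two-clause rule; task PLS finds a significant LV1 contrast
(permutation p ≈ 0.002, the minimum attainable at 500 permutations); the
accumbens shell and lateral septum emerge among the degree/betweenness hubs
of the ingroup network; and across the 40 ensemble configurations the
accumbens core is classified ingroup-only most often (92.5% of runs) — the
planted accumbens structure, recovered.

Every command is a thin wrapper over `fosmap.*` library functions;
`fosmap run --config run.yaml` executes the whole chain with one seed and
writes a manifest sufficient to reproduce every table byte-for-byte.

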