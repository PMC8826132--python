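# isoniche

Analysis of **individual dietary specialization** from serially sampled
tooth-enamel stable carbon isotopes (δ13C, ‰ VPDB). Herbivore teeth grow
incrementally, so a transect of enamel samples along a tooth's growth axis
records an individual's diet over the months-to-years of tooth
mineralization. Comparing each individual's isotopic breadth with the
breadth of its species answers a classic niche-variation question: are
generalist species made of generalist individuals, or of specialists that
subdivide the species niche?

The package is written for stable-isotope (paleo)ecologists working with
flat serial-sample tables (one row per enamel sample, with individual,
taxon, dietary category, latitude, body mass, tooth, position along the
growth axis and δ13C).

## Quantities computed

- **Individual niche breadth** — min / max / range / mean / sd of each
  individual's serial δ13C values, pooled across its sampled teeth.
- **Isotopic individuality index (III)** per taxon:

  `III = (average individual δ13C range) / (total δ13C range of the taxon)`

  III → 0 when individuals are specialized within a broad species niche;
  III → 1 when each individual spans the whole species niche.
- **1‰ range bins** (right-closed: 0 < x ≤ 1, 1 < x ≤ 2, …) and cumulative
  proportions such as P(range ≤ 3‰), per dietary group.
- **Sliding-window standardization** — high-crowned teeth yield more
  serial samples, which mechanically inflates the observed range; the
  δ13C range of every block of five consecutive samples (ordered by
  distance from root) is aggregated into one standardized range per tooth.
- **Nested variance partitioning** of δ13C across three scales — between
  species, between individuals within species, within individuals — under
  the random-effects model `y_ijk = μ + S_i + I_ij + e_ijk`, estimated two
  ways: unbalanced two-level nested ANOVA (method of moments, with the
  exact unbalanced expected-mean-square multipliers n0, n0′, nb0) and
  restricted maximum likelihood (closed-form profiled likelihood).
- **Group comparisons** — tie-corrected Kruskal-Wallis plus Dunn's
  pairwise post hoc z tests (unadjusted and Holm-adjusted p side by side).
- **Synthetic data** with known hierarchical structure (diet-level means
  following C3/C4 endmember logic, species / individual / within variance
  components, optional seasonal sinusoid along the growth axis), so every
  stage is testable against ground truth.

## Worked example

```sh
python analysis/01_simulate.py        # synthetic datasets -> results/sim/
python analysis/03_individuality_index.py
```

prints, among other rows:

```
   dataset        scope         diet  mean_iii  sd_iii  n_species
specialist       global      browser     0.099   0.020          5
specialist       global       grazer     0.116   0.042          5
generalist       global      browser     0.772   0.049          5
generalist       global       grazer     0.749   0.026          5

scenario contrast (global): specialist mean III 0.113 vs generalist 0.757
```

The *specialist* preset (individuals differ strongly but each is nearly
constant along the tooth) yields mean III ≈ 0.11: every individual uses a
small slice of its species' isotopic niche. The *generalist* preset
(interchangeable individuals, each sweeping the niche seasonally) yields
III ≈ 0.76. On the study-like default dataset,
`analysis/04_window_standardization.py` shows the raw range grows with
samples per tooth (slope ≈ 0.084 ‰/sample on i.i.d. teeth) while the
window-standardized range does not (slope ≈ −0.004), and
`analysis/05_variance_partitioning.py` reports that only ~0.6% of total
δ13C variance lies within individuals — individuals are far narrower than
their species.

Equivalent one-command runs on your own table:

```sh
isoniche validate --input data.csv
isoniche run --input data.csv --out results/ --seed 0
isoniche simulate --scenario specialist --seed 42 --out sim/
```

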