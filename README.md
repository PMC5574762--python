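# divergenome

How fast does the "divergent genome" grow during speciation?  Genome scans
routinely report that the fraction of the genome lying in high-F_ST outlier
regions increases faster than linearly with divergence time, a pattern often
read as a signature of selection interacting with gene flow ("genomewide
congealing").  `divergenome` is a simulation and genome-scan toolkit for
asking whether purely neutral histories produce the same pattern.

It simulates sister-species pairs under two-deme isolation(-with-migration)
models — eight pairs of ages 2N..16N generations, constant diploid size N,
with gene flow confined to the first 2N generations after divergence
("early": speciation with gene flow) or the most recent 2N generations
("recent": secondary contact), optionally with a linked divergently selected
locus — evolves finite-sites Jukes–Cantor sequences along the resulting
genealogies, scans nonoverlapping 500-bp windows for Hudson's

    F_ST = 1 − H_w / H_b

(H_w, H_b: mean within-/between-species pairwise differences over the
window's polymorphic sites), calls outlier windows against percentile
thresholds of the F_ST distribution **pooled across all pairs** (default:
95th percentile, with runs between outliers bridged when every intervening
window exceeds the 75th percentile), and fits two growth models of
divergent-genome size y (outlier-window count) versus divergence time x in
units of N generations, both forced through the origin:

    linear:       y = c·x
    exponential:  y = a·(1 − e^{b·x})

ΔAIC = AIC_linear − AIC_exponential decides between them (ΔAIC > 0 favors
the exponential; with a < 0, b > 0 it grows faster than linearly).  The
coefficient b is compared across gene-flow scenarios with one-way ANOVA,
Tukey's HSD (with significance letters) and BCa bootstrap intervals.

## Worked example

```python
import divergenome as dg

# neutral secondary contact, 4Nm = 0.1, at desk scale c = 100
spec = dg.paper_scenario("recent", 0.1, n_replicates=5,
                         seq_length_bp=50_000).rescaled(100)
res = dg.run_scenario(spec, master_seed=11)
for rep in res.replicates:
    print(rep.y, round(rep.fit_exponential.params["b"], 3))
print("mean b:", round(res.b_values.mean(), 3))
```

prints the per-replicate outlier-window counts for the eight pair ages
(2N..16N) and the fitted exponential coefficients:

```
[ 0.  0.  0.  1.  4.  5. 21. 22.] 0.261
[ 0.  0.  0.  0.  2.  6. 19. 25.] 0.311
[ 0.  0.  0.  0.  2.  7. 11. 46.] 0.626
[ 0.  0.  0.  0.  5.  1. 26. 30.] 0.325
[ 0.  0.  0.  0.  2.  1. 20. 37.] 0.453
mean b: 0.395
```

Counts stay near zero for young pairs and rise steeply for old ones — the
pooled threshold sits in the upper tail of the oldest pairs' F_ST
distributions, so the divergent genome grows superlinearly even though this
history is entirely neutral.  The same machinery is exposed stage by stage
(`simulate_pair`, `evolve_sequences`, `window_table`, `pooled_thresholds`,
`call_outliers`, `fit_exponential_origin`, `anova_coefficients`, ...) and
as a CLI:

```sh
divergenome replicate-paper --scenario none --seed 1 --out runs/none
divergenome scan --fasta alignment.fasta --out windows.tsv
```

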