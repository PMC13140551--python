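# gillsym

Symbiont community assembly analysis for shipworm gill metagenomes.

Shipworms (wood-boring bivalves of the family Teredinidae) digest wood with
the help of intracellular bacterial endosymbionts housed in their gills.
Individual hosts carry small communities — one to five symbiont species
drawn from a modest candidate pool — and which species end up together is a
tractable model for microbial community assembly.  `gillsym` implements the
statistical pipeline for asking whether those communities are assembled at
random or shaped by symbiont function, starting from a per-specimen table
of symbiont read counts:

* **Relative abundance and occupancy.**  Read counts are normalised to
  percent abundance per specimen (`100 × reads in MAG / total MAG reads`),
  thresholded into a presence/absence matrix over a declared pool of `S`
  candidate species, and summarised as per-host richness `k_i`, per-species
  prevalence, and distinct co-occurrence patterns.
* **Richness-preserving null models.**  The null hypothesis is that each
  host acquires a uniformly random `k_i`-subset of the `S`-species pool —
  richness is preserved, species identity carries no signal.  Against it:
  - Monte Carlo randomization (default 10 000 replicates) tabulates null
    frequencies for every species combination, with 95% empirical envelopes,
    two-sided p-values, and Benjamini–Hochberg / Holm corrections;
  - pairs never observed together get an exact Poisson–binomial absence
    test: the probability that a specific pair is drawn by a host of
    richness `k` is `C(S−2, k−2)/C(S, k) = k(k−1)/(S(S−1))` (zero for
    `k < 2`), and `P(no co-occurrence anywhere) = ∏_i (1 − p_i)`;
  - the *guarantee probability* that **every** host draws at least one of
    `m` designated species (e.g. the nitrogen fixers) is
    `∏_i [1 − C(S−m, k_i)/C(S, k_i)]`.
* **Gene-content constraints.**  Nitrogen fixation is predicted from the
  essential core *nif* classes (*nifH, D, K, E, N, B*); any community
  observed in a living host is treated as sufficient, the inclusion-minimal
  observed communities are the binding constraints, and the intersection of
  their union gene sets bounds the core CAZyme / *nif* repertoire hosts
  require.  Lignocellulose-active CAZyme subfamily diversity is compared
  across richness classes with Kruskal–Wallis and Dunn–Holm tests.
* **Species delimitation.**  Genome bins are clustered into species from
  pairwise gANI/AF records (gANI > 95%, AF > 0.60, connected components),
  keeping the best CheckM-quality bin per species.
* **Synthetic data.**  A generator draws cohorts with the study's design
  (36 specimens in two host-species groups, 7-species pool, 3 fixers,
  Dirichlet-multinomial read counts, optional enrichment of particular
  combinations), so the whole pipeline is testable without sequencing data.

## Worked example

```python
import gillsym as g

ds = g.simulate_dataset(g.SimulationConfig(seed=42))   # 36-specimen cohort
pct = g.relative_abundance(ds.counts)
pm = g.derive_presence(pct)                            # threshold 0: any reads

rich_tb = g.richness_vector(pm, "Tb")
rich_lp = g.richness_vector(pm, "Lp")
print(f"richness: Tb {rich_tb.mean:.1f} +/- {rich_tb.sd:.1f} (n=22), "
      f"Lp {rich_lp.mean:.1f} +/- {rich_lp.sd:.1f} (n=14)")

report = g.cooccurrence_report(
    pm, g.NullTestConfig(replicates=10_000, seed=42),
    fixers=["sp1", "sp2", "sp4"])
top = report.per_group["combined"][0]
print(f"top combined pattern {top.label()}: observed {top.observed}, "
      f"null mean {top.null_mean:.2f} [{top.env_low}, {top.env_high}], "
      f"Holm p = {top.p_holm:.3f}")
print(f"P(every host draws >= 1 fixer | null) = "
      f"{report.guarantee.probability:.2e}")

core = g.core_gene_set(ds.cazyme_catalog, [{"sp1"}, {"sp4"}, {"sp2", "sp7"}])
print(f"core CAZyme subfamilies: {len(core.core)}; "
      f"lignocellulose-active core: {len(core.lignocellulose_core)}")
```

prints

```
richness: Tb 2.5 +/- 1.0 (n=22), Lp 2.4 +/- 0.8 (n=14)
top combined pattern sp1: observed 2, null mean 0.86 [0, 3], Holm p = 1.000
P(every host draws >= 1 fixer | null) = 2.34e-05
core CAZyme subfamilies: 58; lignocellulose-active core: 23
```

Read: this seed's cohort has group mean richness 2.5 and 2.4 symbionts per
host; the most frequent community (`sp1` alone, 2 specimens) sits inside
its null envelope, so no combination is enriched — as expected with no
planted enrichment.  The guarantee probability says that, were symbiont
choice random, seeing a nitrogen fixer in *every one* of 36 hosts would
happen about twice in 10⁵ cohorts; observing it therefore argues that
fixation is required.  The core constraint recovers the planted 58 shared
CAZyme subfamilies, 23 of them lignocellulose-active.

The same pipeline runs from the shell:

```bash
gillsym simulate --seed 42 --out sim/
gillsym all --counts sim/counts.tsv --metadata sim/metadata.tsv \
    --catalog sim/catalog.tsv --seed 42 --reps 10000 --out run/
```

Subcommands `simulate`, `abundance`, `cooccur`, `prevalence`,
`genecontent`, `dereplicate`, `all`; every output file records the package
version, seed, and a hash of the effective configuration, and identical
configuration reproduces identical bytes.

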