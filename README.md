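# famflux

Cross-species **gene-family abundance fluctuations** as a window on
horizontal gene transfer dynamics in prokaryotes.

Bacterial gene families expand and contract through inter-species
horizontal transfer (HGT), intra-species duplication, and loss. Beyond
presence/absence, each family has an *abundance profile*: the histogram of
its copy number `V` across sequenced genomes. `famflux` implements, end to
end, an analysis that connects the width of that profile to the underlying
evolutionary moves:

* a **collisional stochastic model**: `N` species genomes meet pairwise and
  exchange family members by per-copy Bernoulli trials of probability
  `p_h`, while own copies are lost (`p_l`) or duplicated (`p_d`);
  stationarity requires `p_h + p_d = p_l`. Without duplication the
  stationary profile is Poisson(λ); with duplication it is overdispersed,
  with

  `Var(V) = λ (1 + p_d / (p_h (1 − p_h)))`,

  approaching a negative binomial of mean λ and variance
  `λ (p_d + p_h)/p_h` in the grazing-collision limit, and relaxing
  exponentially at a rate set by `p_h` alone (see `docs/methods.md` for the
  exact sweep-based relaxation constant);
* **fluctuation statistics** on a family-by-genome count matrix, computed
  in sliding genome-size bins (width 390 domains): a sampling weight
  `w_f = Σ_b n_b n_b⁺ / Σ_b n_b²`, an L1 distance `L_f` to the
  equal-mean Poisson, the log inverse Fano factor
  `Q_f = Σ_b w_fb ln(⟨v⟩_b / Var_b(v))`, the occurrence `O_f`, and the mean
  scored-transfer fraction `H_f = ⟨H_fg / V_fg⟩` over genomes carrying the
  family;
* **classification** of well-sampled families (`w_f ≥ 0.38`) into
  *overdispersed* (`Q_f < −0.43`), *Poisson-like* (`−0.43 ≤ Q_f ≤ 1`) and
  *peaked* (`Q_f > 1`) profiles, with Fisher exact functional-category
  enrichment, plasmid log-ratio scores, and class-restricted genome
  distances compared to a reference phylogeny by Spearman correlation;
* a **synthetic-data generator** that plants all of this structure
  (classes, genome-size heterogeneity, clades, class-correlated transfers,
  annotations, a reference distance matrix), so the whole chain is testable
  without any external database.

It is aimed at researchers in comparative genomics and genome evolution who
want to simulate the model, reproduce its stationary predictions, or run
the fluctuation analysis on their own pre-tabulated count matrices.
See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate one family under pure transfer–loss dynamics (`p_d = 0`) and check
the stationary profile:

```sh
$ famflux simulate --p-h 0.01 -n 1000 --init 30 --sweeps 1500 \
    --record-interval 50 --seed 1 --out-prefix sim/fig
final mean=29.4600 variance=29.2424 fano=0.9926
```

The mean stays at the initial 30 (up to finite-`N` diffusion), and the Fano
factor `variance/mean ≈ 1` identifies the Poisson stationary state; the
emitted `sim/fig_histogram.tsv` matches the `famflux theory --lam 30`
profile. Adding duplication (`--p-d 0.009 --p-h 0.001`) drives the Fano
factor toward `1 + p_d/(p_h(1 − p_h)) ≈ 10` instead.

Generate a synthetic study and run the full analysis:

```sh
$ famflux synth --seed 7 --outdir data
wrote synthetic ensemble (300 families x 500 genomes) to data
$ famflux stats --matrix data/matrix.tsv --transfers data/transfers.tsv \
    --out stats.tsv
wrote statistics for 300 families to stats.tsv
$ famflux classify --stats stats.tsv --out labels.tsv
class
overdispersed    108
peaked           100
poisson_like      92
```

The classifier recovers the three planted classes of 100 families each
(97.3% of families correctly at this seed; the 8 misses are Poisson
families whose sporadic absences read as mild overdispersion) purely from
the count matrix. Downstream:

```sh
$ famflux enrich --labels labels.tsv --annotations data/annotations.tsv \
    --out enrich.tsv
6 significant tests at alpha=0.01
$ famflux distance --matrix data/matrix.tsv --labels labels.tsv \
    --cls peaked --reference data/reference_distances.tsv --out dpk.tsv
spearman_rho_vs_reference=0.9265
$ famflux distance --matrix data/matrix.tsv --labels labels.tsv \
    --cls poisson_like --reference data/reference_distances.tsv --out dpo.tsv
spearman_rho_vs_reference=0.0023
```

The enrichment table contains the planted metabolism association with
Poisson-like families (overrepresented, `P < 0.01`), and the
class-restricted distances show that peaked-family content tracks the
reference phylogeny while Poisson-like content does not — the mobile part
of the genome "scrambles" the phylogenetic signal. A single
`famflux pipeline --config cfg.yaml --outdir run` performs all stages with
a reproducible manifest.

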