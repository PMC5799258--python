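# coralmicro

Community comparison and co-occurrence network analysis for coral
microbiome OTU tables.

Reef-building corals host dense bacterial and archaeal communities, and a
recurring question in coral microbial ecology is which community members
form a host's "core" microbiome — not merely the prevalent taxa, but the
set of species whose abundances rise and fall together across replicate
colonies, suggesting interaction. `coralmicro` implements the standard
analysis chain used to answer that question from a 16S OTU count table:

1. **Table handling** — QIIME-classic OTU tables, sample metadata (host,
   location, replicate role), taxonomy with a best-hit annotation rule
   (< 94% identity or an ambiguous genus match ⇒ unknown species);
   relative abundances, rank aggregation (Proteobacteria at class level,
   Archaea pooled at domain level), and the 0.1% mean-relative-abundance
   filter applied per host dataset.
2. **Alpha diversity** — observed species and the Shannon index
   H = −Σ pᵢ log pᵢ (log base configurable and always labelled).
3. **Beta comparison** — Bray–Curtis distance d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ);
   one-way PERMANOVA with the Anderson pseudo-F
   F = ((SS_T − SS_W)/(a−1)) / (SS_W/(N−a)) and seeded label permutations
   (p = (b+1)/(m+1)); pairwise PERMANOVA over host-by-location groups;
   non-metric MDS minimizing Kruskal stress-1 with monotone regression;
   UPGMA dendrograms in Newick.
4. **Co-occurrence networks** — all-pairs Spearman ρ (average-tie ranks,
   two-sided p from the t approximation); an edge wherever ρ > 0.6 and
   P < 0.01; topology summaries (mean degree 2E/N, mean shortest-path
   length, diameter, clustering coefficient, Louvain modularity with the
   Q > 0.40 "modular structure" call) and a per-OTU permutation null model
   for non-random co-occurrence.
5. **Network comparison** — shared vs host-specific co-occurring species,
   per-taxon breakdowns, and classification of each network OTU's
   abundance profile against seawater and location (seawater-similar,
   coral-enriched, location-variable) with a log10 heat-map matrix.

Because raw survey data are rarely at hand, the package ships a
first-class synthetic study generator (`coralmicro.synthetic`): a
log-linear latent model with host and location effects, seawater
references, technical replicates, multinomial counting at Poisson read
depth, and planted co-occurring guilds whose membership is recorded as
ground truth — so every stage of the pipeline can be exercised and scored
against a known answer.

## Worked example

Run the analysis scripts in order (they share `results/run/` and a seed):

```sh
python analysis/01_simulate.py --seed 0
python analysis/03_beta_comparison.py --seed 0
python analysis/04_cooccurrence_networks.py --seed 0
```

Output of the network step at seed 0:

```
Galaxea: 70 OTUs pass the 0.1% filter; network has 20 nodes / 29 edges
  mean degree 2.90, mean distance 1.12 edges, diameter 2, clustering 0.45
  modularity Q = 0.50 (modular; threshold Q > 0.40)
  non-randomness: observed 29 edges vs null mean 2.7, P = 0.005 (199 permutations)
Montipora: 72 OTUs pass the 0.1% filter; network has 33 nodes / 53 edges
  mean degree 3.21, mean distance 3.25 edges, diameter 8, clustering 0.36
  modularity Q = 0.62 (modular; threshold Q > 0.40)
  non-randomness: observed 53 edges vs null mean 4.8, P = 0.005 (199 permutations)
```

Reading: of the ~300 simulated OTUs, 70/72 clear the per-host abundance
filter; only OTUs with at least one strong, significant positive
correlation become network nodes. Both host networks are sparse (mean
degree ≈ 3), modular (Q > 0.40, so each decomposes into sub-networks —
the planted guilds), and their edge counts far exceed the permutation
null (P = 0.005), i.e. co-occurrence is non-random. The beta step prints
the companion community-level result — host identity explains composition
(pseudo-F = 23.4, P = 0.001) while the two coral hosts' locations do not,
with a 2-D NMDS at stress 0.133.

The same pipeline runs from the shell (`coral-cooc run-all --seed 0
--outdir out/`) or from Python via `coralmicro.RunConfig` /
`run_pipeline`; real data enter through the three TSV inputs
(`otu_table_path`, `metadata_path`, `taxonomy_path`).

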