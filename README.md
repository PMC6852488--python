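# seedweb

Quantitative food-web analysis for plants and their internally feeding
insect seed predators.

Endophagous seed predators (weevils, bruchine beetles, micro-moths, seed
wasps) develop inside a single seed and kill it, so their host links can
be established by rearing: collect seeds, wait, identify what emerges,
then dissect every seed for evidence of attack. `seedweb` turns such
long-format rearing records — together with seed-trap densities, a plant
trait table and a dated plant phylogeny — into the standard quantitative
descriptions used in community ecology:

- **Web assembly.** Per-plant response variables (incidence of seed
  predators, seed-predator richness, seed predation rate), and a
  bipartite web whose link weights α\_ik estimate the seeds of plant *i*
  killed by predator *k* per m² of seed rain,
  α\_ik = density\_i · attacked\_ik ⁄ sampled\_i, with the field-protocol
  exclusion rules (species absent from traps, Hymenoptera, multi-seeded
  fruit feeders, missing seeds-per-fruit metadata) applied and logged.
- **Specialisation.** Blüthgen's species-level d′ (standardised
  Kullback–Leibler deviation of a consumer's host use from host
  availability) and the network-level H2′ (standardised two-dimensional
  Shannon entropy), connectance, per-predator diet richness, and Chao1
  interaction coverage from singleton/doubleton association counts.
  The marginal-constrained entropy extrema behind d′ and H2′ are found
  *exactly* (dynamic programming over integer tables) whenever feasible
  and by the conventional greedy/proportional integer fills otherwise.
- **Apparent competition.** The PAC matrix
  d\_ij = Σ\_k (α\_ik ⁄ Σ\_l α\_il)(α\_jk ⁄ Σ\_m α\_mk), the probability
  that a seed predator attacking plant *i* developed on plant *j*; rows
  sum to one. Summaries: the fraction of ordered plant pairs with
  d\_ij > 0.1, and the Spearman correlation of positive PAC with
  patristic distance.
- **Phylogenetic signal.** Fritz–Purvis *D* for binary incidence
  (≈ 1 under random tip arrangement, ≈ 0 under a Brownian threshold
  model) and Blomberg's *K* for richness and predation rate (= 1 under
  Brownian evolution), plus tree utilities: patristic distances and
  grafting of missing species at the stem of their genus.
- **Trait models.** An out-of-bag-evaluated ensemble of randomised
  decision trees predicting the three responses from a mixed trait
  table, scored by Cohen's κ (incidence) and pseudo-R² (richness,
  predation rate) with permutation variable importances.
- **Synthetic communities.** A fully seeded generator with lognormal
  seed rain, strongly right-skewed host ranges (capped at 7),
  phylogenetically clustered host choice, per-seed binomial attack and
  effort-limited sampling — with complete ground truth for
  parameter-recovery tests.

## Worked example

```python
import numpy as np
import seedweb as sw

cfg = sw.SyntheticConfig(n_plants=120, n_predators=100, seed=1)
dataset, community = sw.simulate_dataset(cfg)

web = sw.build_web(dataset)
print(f"web: {web.n_plants} plants x {web.n_predators} predators, "
      f"{int((web.alpha > 0).sum())} links")
print(f"connectance = {sw.connectance(web):.4f}")
print(f"H2' = {sw.H2_prime(web):.3f}")
print(f"median d' = {np.median(sw.d_prime_all(web)):.3f}")

assoc = sw.list_associations(dataset)
chao = sw.chao1_coverage(assoc["n_individuals"])
print(f"Chao1 coverage = {chao.coverage:.3f}  (S_obs={chao.S_obs}, S_est={chao.S_est:.1f})")

pac = sw.pac_matrix(web)
ex = sw.pac_exceedance(pac, threshold=0.1)
print(f"PAC > 0.1: {ex['n_exceed']} of {ex['n_pairs']} ordered pairs "
      f"({100 * ex['fraction']:.2f}%)")

summaries = sw.summarise_plants(dataset)
well = summaries[summaries.well_sampled]
D = sw.fritz_purvis_D(dataset.phylogeny,
                      well["predator_incidence"].astype(int),
                      n_perm=1000, seed=1)
print(f"incidence D = {D.D:.3f} (P_D<1 = {D.p_D_less_1:.3f})")
K = sw.blomberg_K(dataset.phylogeny,
                  well["predator_richness"].astype(float),
                  n_rand=999, seed=1)
print(f"richness K = {K.K:.3g} (P = {K.p:.3f})")
```

prints

```
web: 53 plants x 63 predators, 80 links
connectance = 0.0240
H2' = 0.978
median d' = 0.963
Chao1 coverage = 0.965  (S_obs=123, S_est=127.5)
PAC > 0.1: 26 of 2756 ordered pairs (0.94%)
incidence D = 0.960 (P_D<1 = 0.376)
richness K = 2.1e-06 (P = 0.698)
```

Reading the output: the community is extremely specialised — H2′ near
its maximum of 1, a median d′ of 0.96 and only 80 realised links of the
3 339 possible (connectance 0.024). Because predators rarely share
hosts, fewer than 1% of ordered plant pairs have any appreciable
potential for predator-mediated apparent competition (PAC > 0.1), and
incidence shows no more phylogenetic structure than a random tip
shuffle (D ≈ 1). Chao1 judges the sampling to have recovered ~96% of
the interactions that deeper sampling would reveal.

## Command line

```sh
seedweb simulate --seed 1 --outdir data/          # CSV + Newick + ground truth
seedweb build-web --rearing data/rearing.csv \
    --emergence data/emergence.csv --traps data/traps.csv --out web.csv
seedweb metrics --web web.csv --out report.json
seedweb pac --web web.csv --tree data/tree.nwk --out pac.csv
seedweb run-all --seed 1 --outdir out/            # everything, one report.json
```

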