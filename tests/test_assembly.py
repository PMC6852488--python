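import numpy as np
import pandas as pd
import pytest

from seedweb.assembly import (
    build_web,
    detection_curve,
    list_associations,
    summarise_plants,
)
from seedweb.simulate import SyntheticConfig, simulate_dataset

from conftest import make_dataset


class TestSummaries:
    def test_counts_and_well_sampled_boundary(self, tiny_dataset):
        s = summarise_plants(tiny_dataset)
        virola = s.loc["Virola sp1"]
        assert virola["total_seeds"] == 350
        assert virola["predator_richness"] == 2
        assert virola["predator_incidence"]
        assert virola["well_sampled"]
        # 199 seeds is below the >= 200 cut
        assert not s.loc["Ficus sp2", "well_sampled"]
        assert s.loc["Cecropia sp3", "well_sampled"]
        assert s.loc["Virola sp1", "predation_rate"] == pytest.approx(30 / 350)

    def test_non_predator_emergences_ignored(self, tiny_dataset):
        s = summarise_plants(tiny_dataset)
        # the Hymenoptera parasitoid on Ficus is not a seed predator
        assert s.loc["Ficus sp2", "predator_richness"] == 1

    def test_synthetic_bookkeeping_matches_ground_truth(self):
        cfg = SyntheticConfig(n_plants=40, n_predators=30, seed=5)
        ds, com = simulate_dataset(cfg)
        s = summarise_plants(ds)
        # totals per plant match the generated rearing table exactly
        expect = ds.rearing.groupby("plant_species")["n_seeds"].sum()
        pd.testing.assert_series_equal(
            s["total_seeds"].astype(int), expect, check_names=False
        )
        # richness counts realised (sampled) links, never latent ones
        em = ds.emergences.merge(
            ds.rearing[["sample_id", "plant_species"]], on="sample_id"
        )
        realised = em.groupby("plant_species")["insect_species"].nunique()
        for plant, r in realised.items():
            assert s.loc[plant, "predator_richness"] == r
        latent = com.links.groupby("plant_species")["insect_species"].nunique()
        assert (
            s["predator_richness"].reindex(latent.index).fillna(0) <= latent
        ).all()


class TestAssociations:
    def test_emergence_per_attacked_seed_arithmetic(self):
        # 10 individuals from 10 predated seeds -> 1.0; 12 from 6 -> 2.0
        rearing = [
            ("a1", "plantA", "2011-01-01", "island", "mature", 100, 0, 100, 10),
            ("b1", "plantB", "2011-01-01", "island", "mature", 100, 0, 100, 6),
        ]
        emergences = [
            ("a1", "k1", "Coleoptera", "f", "adult", 10, True),
            ("b1", "k2", "Coleoptera", "f", "adult", 12, True),
        ]
        ds = make_dataset(rearing, emergences)
        assoc = list_associations(ds).set_index("insect_species")
        assert assoc.loc["k1", "emergence_per_attacked_seed"] == pytest.approx(1.0)
        assert assoc.loc["k2", "emergence_per_attacked_seed"] == pytest.approx(2.0)

    def test_fallback_when_no_seed_scored_predated(self):
        rearing = [("a1", "plantA", "2011-01-01", "island", "mature", 100, 0, 100, 0)]
        emergences = [("a1", "k1", "Coleoptera", "f", "adult", 4, True)]
        ds = make_dataset(rearing, emergences)
        assoc = list_associations(ds)
        assert assoc["fallback"].iloc[0]
        assert assoc["emergence_per_attacked_seed"].iloc[0] == 1.0
        assert assoc["attributed_seeds"].iloc[0] == 4

    def test_unit_brood_synthetic_ratios(self):
        ds, _ = simulate_dataset(SyntheticConfig(n_plants=40, n_predators=30, seed=2))
        assoc = list_associations(ds)
        # brood size 1 and full dissection sensitivity: within a plant the
        # apportionment returns ratios of 1 wherever one predator dominates
        single = assoc.groupby("plant_species").filter(lambda g: len(g) == 1)
        ok = ~single["fallback"]
        assert np.allclose(single.loc[ok, "emergence_per_attacked_seed"], 1.0)


class TestBuildWeb:
    def test_exclusions_logged(self, tiny_dataset):
        web = build_web(tiny_dataset)
        assert set(web.plants) == {"Virola sp1", "Ficus sp2"}
        reasons = dict(web.exclusion_log)
        assert reasons.get("Cecropia sp3") == "absent_from_traps"

    def test_hymenoptera_always_excluded(self):
        rearing = [("a1", "plantA", "2011-01-01", "island", "mature", 100, 0, 100, 2)]
        emergences = [("a1", "wasp", "Hymenoptera", "Eurytomidae", "adult", 2, True)]
        traps = [("plantA", 50, 100.0, 1.0, False)]
        ds = make_dataset(rearing, emergences, traps)
        with pytest.raises(ValueError, match="empty"):
            build_web(ds, orders={"Coleoptera", "Lepidoptera", "Hymenoptera"})

    def test_multiseed_and_missing_metadata_excluded(self):
        rearing = [
            ("a1", "plantA", "2011-01-01", "island", "mature", 100, 0, 100, 5),
            ("b1", "plantB", "2011-01-01", "island", "mature", 100, 0, 100, 5),
            ("c1", "plantC", "2011-01-01", "island", "mature", 100, 0, 100, 5),
        ]
        emergences = [
            ("a1", "k1", "Coleoptera", "f", "adult", 5, True),
            ("b1", "k2", "Coleoptera", "f", "adult", 5, True),
            ("c1", "k3", "Coleoptera", "f", "adult", 5, True),
        ]
        traps = [
            ("plantA", 50, 100.0, 1.0, False),
            ("plantB", 50, 100.0, np.nan, False),
            ("plantC", 50, 100.0, 4.0, True),
        ]
        ds = make_dataset(rearing, emergences, traps)
        web = build_web(ds)
        assert web.plants == ["plantA"]
        reasons = dict(web.exclusion_log)
        assert reasons["plantB"] == "missing_seeds_per_fruit"
        assert reasons["plantC"] == "multiseeded_fruit_excluded"

    def test_alpha_bounded_by_seed_rain(self, tiny_dataset):
        web = build_web(tiny_dataset)
        killed = web.alpha.sum(axis=1)
        assert (killed <= web.plant_density + 1e-12).all()

    def test_row_permutation_invariance(self, tiny_dataset):
        web1 = build_web(tiny_dataset)
        shuffled = make_shuffled(tiny_dataset)
        web2 = build_web(shuffled)
        assert web1.plants == web2.plants
        assert web1.predators == web2.predators
        np.testing.assert_allclose(web1.alpha, web2.alpha)

    def test_drop_singletons_monotone(self):
        ds, _ = simulate_dataset(SyntheticConfig(n_plants=60, n_predators=50, seed=9))
        full = build_web(ds)
        reduced = build_web(ds, drop_singletons=True)
        assert (reduced.alpha > 0).sum() <= (full.alpha > 0).sum()

    def test_alpha_recovers_true_kill_density_deep_sampling(self):
        cfg = SyntheticConfig(
            n_plants=25,
            n_predators=20,
            seed=11,
            sampling_effort=10_000,
            undersample_quantile=0.0,
            zero_trap_fraction=0.0,
            missing_spf_fraction=0.0,
            multiseed_fraction=0.0,
            trap_overdispersion=np.inf,
        )
        ds, com = simulate_dataset(cfg)
        web = build_web(ds, orders={"Coleoptera", "Lepidoptera", "Hymenoptera"} - {"Hymenoptera"})
        true = com.true_alpha
        checked = 0
        for i, plant in enumerate(web.plants):
            dens_true = float(
                com.plants.set_index("plant_species").loc[plant, "density"]
            )
            dens_est = web.plant_density[i]
            for k, pred in enumerate(web.predators):
                t = true.loc[plant, pred]
                est = web.alpha[i, k]
                if t == 0:
                    continue
                # per-seed kill probability, freeing the check from trap noise
                p_true = t / dens_true
                p_est = est / dens_est
                se = np.sqrt(p_true * (1 - p_true) / 10_000)
                assert abs(p_est - p_true) < max(4 * se, 0.01)
                checked += 1
        assert checked > 10


def make_shuffled(ds):
    from seedweb.io import Dataset

    rng = np.random.default_rng(0)
    return Dataset(
        ds.rearing.sample(frac=1, random_state=1).reset_index(drop=True),
        ds.emergences.sample(frac=1, random_state=2).reset_index(drop=True),
        ds.traps.sample(frac=1, random_state=3).reset_index(drop=True),
        ds.traits,
        ds.phylogeny,
    )


class TestDetectionCurve:
    def test_true_detection_gives_positive_slope(self, rng):
        n_species = 200
        seeds = np.round(10 ** rng.uniform(1, 3.5, n_species)).astype(int)
        a = 0.01
        incidence = rng.random(n_species) < 1 - (1 - a) ** seeds
        summaries = pd.DataFrame(
            {
                "total_seeds": seeds,
                "predator_incidence": incidence,
                "well_sampled": seeds >= 200,
            }
        )
        fit = detection_curve(summaries)
        assert not fit.degenerate
        assert fit.slope > 0
        assert fit.p_value < 0.05

    def test_independent_incidence_slope_near_zero(self, rng):
        rejections = 0
        for _ in range(60):
            seeds = np.round(10 ** rng.uniform(1, 3.5, 150)).astype(int)
            incidence = rng.random(150) < 0.5
            summaries = pd.DataFrame(
                {
                    "total_seeds": seeds,
                    "predator_incidence": incidence,
                    "well_sampled": seeds >= 200,
                }
            )
            fit = detection_curve(summaries)
            if fit.p_value < 0.05:
                rejections += 1
        assert rejections <= 10  # ~5% nominal, generous bound

    def test_single_species_degenerate(self):
        summaries = pd.DataFrame(
            {"total_seeds": [300], "predator_incidence": [True], "well_sampled": [True]}
        )
        assert detection_curve(summaries).degenerate
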