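import numpy as np
import pytest

from oribatida import (
    NicheParams,
    ScenarioConfig,
    SpeciesParams,
    ValidationError,
    awm,
    build_community_matrix,
    generate_abundances,
    generate_dataset,
    generate_design,
    preset_scenarios,
)


class TestDesign:
    def test_full_default_design(self):
        cfg = preset_scenarios("field_like")
        plots = generate_design(cfg)
        assert len(plots) == 60
        assert sum(p.n_subsamples for p in plots) == 300
        sides = {p.habitat: p.sample_side_cm for p in plots}
        assert sides == {"forest": 15.0, "grassland": 20.0}

    def test_small_design_counts(self):
        cfg = ScenarioConfig(
            regions=("ALB",),
            habitats=("forest",),
            plots_per_region_habitat=3,
            subsamples_per_plot=2,
        )
        plots = generate_design(cfg)
        assert len(plots) == 3
        assert sum(p.n_subsamples for p in plots) == 6

    def test_even_gradient_spacing(self):
        cfg = ScenarioConfig(regions=("ALB",), habitats=("forest",))
        values = sorted(p.landuse["Formi"] for p in generate_design(cfg))
        diffs = np.diff(values)
        assert np.allclose(diffs, 1 / 14)


class TestAbundances:
    def _single_species_cfg(self, niche):
        cfg = ScenarioConfig(regions=("ALB",), habitats=("forest",))
        cfg.species = [
            SpeciesParams(
                name="sp", mode="sexual", body_size_um=300.0,
                niches={("ALB", "forest"): niche},
            )
        ]
        return cfg

    def test_zero_peak_abundance_means_absent(self):
        cfg = self._single_species_cfg(NicheParams(mu=0.5, sigma=0.2, lam_max=0.0))
        assert generate_abundances(generate_design(cfg), cfg, seed=1) == []

    def test_flat_species_fills_gradient_evenly(self, rng):
        niche = NicheParams(mu=0.0, sigma=None, lam_max=30.0)
        cfg = self._single_species_cfg(niche)
        design = generate_design(cfg)
        specs = generate_abundances(design, cfg, seed=2)
        counts = {p.plot_id: 0 for p in design}
        for s in specs:
            counts[s.plot_id] += 1
        per_plot = np.array(list(counts.values()))
        # Poisson(30) per plot: each within 5 SD, overall mean close to 30
        assert np.all(np.abs(per_plot - 30) < 5 * np.sqrt(30))
        assert per_plot.mean() == pytest.approx(30, abs=3 * np.sqrt(30 / 15))

    def test_peaked_species_recovers_its_optimum(self):
        niche = NicheParams(mu=1.0, sigma=0.08, lam_max=60.0)
        cfg = self._single_species_cfg(niche)
        design = generate_design(cfg)
        awms = []
        for seed in range(8):
            specs = generate_abundances(design, cfg, seed=seed)
            m = build_community_matrix(specs, design)
            L = np.array([p.landuse["Formi"] for p in design])
            awms.append(awm(m.row("sp"), L))
        assert np.mean(awms) == pytest.approx(0.95, abs=0.05)

    def test_subsamples_within_design_range(self):
        cfg = self._single_species_cfg(NicheParams(mu=0.0, sigma=None, lam_max=20.0))
        specs = generate_abundances(generate_design(cfg), cfg, seed=3)
        subs = {s.subsample_id for s in specs}
        assert subs <= {1, 2, 3, 4, 5}

    def test_negative_binomial_overdisperses(self):
        niche = NicheParams(mu=0.0, sigma=None, lam_max=20.0)
        cfg = self._single_species_cfg(niche)
        cfg.noise, cfg.dispersion = "negative_binomial", 1.0
        design = generate_design(cfg)
        counts = []
        for seed in range(30):
            specs = generate_abundances(design, cfg, seed=seed)
            per = {p.plot_id: 0 for p in design}
            for s in specs:
                per[s.plot_id] += 1
            counts += list(per.values())
        counts = np.array(counts)
        # variance m + m^2/k = 20 + 400 = 420 >> Poisson's 20
        assert counts.var() > 5 * counts.mean()


class TestSpecimenTraits:
    def test_all_female_when_fraction_one(self):
        cfg = preset_scenarios("null_community", n_species=4)
        cfg.species = [
            SpeciesParams(
                name=s.name, mode="sexual", body_size_um=300.0, niches=s.niches,
                female_fraction=1.0,
            )
            for s in cfg.species
        ]
        _, specs, _ = generate_dataset(cfg, seed=5)
        assert all(s.sex == "female" for s in specs)

    def test_zero_gravidity_means_no_eggs(self):
        cfg = preset_scenarios("null_community", n_species=4)
        cfg.species = [
            SpeciesParams(
                name=s.name, mode="parthenogenetic", body_size_um=300.0,
                niches=s.niches, gravidity_prob=0.0,
            )
            for s in cfg.species
        ]
        _, specs, _ = generate_dataset(cfg, seed=6)
        assert all(not s.gravid and s.egg_count == 0 for s in specs)

    def test_truncated_egg_distribution_mean(self):
        cfg = preset_scenarios("null_community", n_species=12)
        cfg.species = [
            SpeciesParams(
                name=s.name, mode="parthenogenetic", body_size_um=300.0,
                niches={k: NicheParams(0.0, None, 60.0) for k in s.niches},
                gravidity_prob=1.0, mean_eggs=2.0,
            )
            for s in cfg.species
        ]
        _, specs, _ = generate_dataset(cfg, seed=7)
        eggs = np.array([s.egg_count for s in specs if s.gravid])
        assert len(eggs) > 5000
        assert eggs.min() >= 1
        assert eggs.mean() == pytest.approx(2.0, abs=3 * eggs.std() / np.sqrt(len(eggs)))


class TestPresets:
    def test_generation_is_bit_reproducible(self):
        cfg = preset_scenarios("winners_and_losers", n_species=20)
        p1, s1, t1 = generate_dataset(cfg, seed=9)
        p2, s2, t2 = generate_dataset(cfg, seed=9)
        assert p1 == p2 and s1 == s2 and t1.equals(t2)
        _, s3, _ = generate_dataset(cfg, seed=10)
        assert s1 != s3

    def test_winner_loser_bookkeeping(self):
        cfg = preset_scenarios("winners_and_losers", n_species=30)
        roles = [s.role for s in cfg.species]
        assert roles.count("winner") == 3 and roles.count("loser") == 3
        _, _, truth = generate_dataset(cfg, seed=1)
        assert set(truth.columns) >= {"species", "mode", "role"}

    def test_null_community_is_flat_and_even(self):
        cfg = preset_scenarios("null_community", n_species=10)
        assert all(
            n.sigma is None and n.lam_max == 20.0
            for s in cfg.species
            for n in s.niches.values()
        )

    def test_field_like_shape(self):
        cfg = preset_scenarios("field_like")
        assert len(cfg.species) == 100
        assert cfg.regions == ("ALB", "SCH") and cfg.habitats == ("forest", "grassland")
        parth = sum(s.mode == "parthenogenetic" for s in cfg.species)
        assert parth == 30

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValidationError, match="null_community"):
            preset_scenarios("bogus")
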