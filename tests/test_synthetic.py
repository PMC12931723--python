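"""Synthetic-trial generator: determinism, schema, moments, OTU tables."""

import numpy as np
import pandas as pd
import pytest

from gutpkpd import presets
from gutpkpd.data import Dataset
from gutpkpd.diversity import shannon_index
from gutpkpd.errmodels import ErrorModel
from gutpkpd.saem import PopulationModel
from gutpkpd.synthetic import (default_design, generate_otu_counts,
                               generate_otu_tables, generate_trial,
                               geometric_abundances)


class TestGenerateTrial:
    def test_fixed_seed_gives_byte_identical_csv(self, tmp_path):
        design = default_design(("CZA",), 4, 2)
        for name in ("a.csv", "b.csv"):
            data, _ = generate_trial(design, seed=123)
            data.to_csv(tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == \
            (tmp_path / "b.csv").read_bytes()

    def test_round_trips_through_the_reader(self, tmp_path):
        design = default_design(("CRO",), 3, 2)
        data, _ = generate_trial(design, seed=5)
        path = tmp_path / "trial.csv"
        data.to_csv(path)
        back = Dataset.from_csv(path)
        assert back.subject_ids == data.subject_ids
        assert back.n_obs == data.n_obs
        assert set(back.responses) == {"plasma", "fecal", "shannon"}

    def test_noise_free_generation_equals_model_predictions(self):
        quiet = {
            "CZA_ceftazidime": PopulationModel(
                presets.pk_population_model("CZA_ceftazidime").mu,
                {k: 0.0 for k in presets.pk_population_model(
                    "CZA_ceftazidime").mu},
                {"plasma": ErrorModel("combined", 1e-9, 1e-9),
                 "fecal": ErrorModel("combined", 1e-9, 1e-9)}),
        }
        quiet_pd = {
            "CZA": PopulationModel(
                {"SI0": 4.0, "kout": 0.1, "Emax": 0.58, "EC50": 10.9},
                {"SI0": 0.0, "kout": 0.0, "Emax": 0.0, "EC50": 0.0},
                {"shannon": ErrorModel("constant", 1e-9)}),
        }
        design = default_design(("CZA",), 3, 1)
        d1, _ = generate_trial(design, seed=1, pk_truth=quiet,
                               pd_truth=quiet_pd)
        d2, _ = generate_trial(design, seed=999, pk_truth=quiet,
                               pd_truth=quiet_pd)
        # different seeds, but sigma ~ 0 and omega = 0: identical values
        for s1, s2 in zip(d1.subjects, d2.subjects):
            if s1.arm == "control":
                continue
            for r in s1.observations:
                np.testing.assert_allclose(s1.observations[r].values,
                                           s2.observations[r].values,
                                           rtol=1e-5)

    def test_lloq_above_everything_censors_every_concentration(self):
        lo = {
            "CRO": PopulationModel(
                {**presets.pk_population_model("CRO").mu, "f_gut": 1e-12},
                presets.pk_population_model("CRO").omega,
                presets.pk_population_model("CRO").errors),
        }
        design = default_design(("CRO",), 2, 1)
        data, _ = generate_trial(design, seed=3, pk_truth=lo)
        for s in data.subset(arms=["CRO"]).subjects:
            fec = s.observations["fecal"]
            assert fec.cens.all()
            assert np.allclose(fec.values, presets.FECAL_LLOQ)

    def test_control_arm_has_no_doses_and_stable_diversity(self):
        design = default_design((), n_control=30)
        data, truth = generate_trial(design, seed=8)
        assert all(not s.doses for s in data.subjects)
        si = np.concatenate([s.observations["shannon"].values
                             for s in data.subjects])
        assert si.mean() == pytest.approx(4.0, rel=0.05)

    def test_theta_moments_match_mu_omega(self):
        design = default_design(("TZP",), 500, 1)
        _, truth = generate_trial(design, seed=21)
        theta = truth.pk_theta[("TZP", "TZP_piperacillin")]
        pkm = presets.pk_population_model("TZP_piperacillin")
        names = tuple(pkm.mu)
        logs = np.log(theta)
        for j, n in enumerate(names):
            assert logs[:, j].mean() == pytest.approx(
                np.log(pkm.mu[n]), abs=3.5 * pkm.omega[n] / np.sqrt(500))
            assert logs[:, j].std() == pytest.approx(pkm.omega[n], rel=0.15)


class TestOTUGeneration:
    def test_uniform_target_recovers_uniform_abundances(self):
        p = geometric_abundances(np.log2(64), 64)
        assert np.allclose(p, 1.0 / 64)

    def test_two_otu_target_inverts_shannon(self):
        p = geometric_abundances(0.8112781, 2)
        assert sorted(np.round(p, 4)) == pytest.approx([0.25, 0.75], abs=1e-3)

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError):
            geometric_abundances(8.0, 100)  # log2(100) < 8

    def test_realized_shannon_tracks_target(self):
        # concentration of the multinomial at 50k reads: realized Shannon
        # (with singleton suppression) within 0.05 of target in >= 95%
        rng = np.random.default_rng(2)
        hits = 0
        targets = np.linspace(1.5, 5.5, 40)
        for tgt in targets:
            counts = generate_otu_counts(tgt, 100, 50_000, rng)
            ids = tuple(map(str, range(100)))
            from gutpkpd.diversity import OTUProfile
            si = shannon_index(OTUProfile(ids, counts), suppress=True).value
            hits += abs(si - tgt) <= 0.05
        assert hits >= 0.95 * len(targets)

    def test_tables_round_trip_sample_ids(self):
        df = pd.DataFrame({"sample_id": ["x_d0", "x_d3"],
                           "shannon": [4.0, 3.2]})
        profiles = generate_otu_tables(df, n_otus=50, n_reads=2000, seed=1)
        assert [p.sample_id for p in profiles] == ["x_d0", "x_d3"]
        assert all(p.counts.sum() == 2000 for p in profiles)
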