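"""Synthetic cohort generator: distributions, mechanisms, determinism, I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morbinet.etl import build_event_stream
from morbinet.synthetic import (
    ConfigError,
    GeneratorConfig,
    generate_cohort,
    generate_episodes,
    make_disease_model,
    read_cohort,
    read_ground_truth,
    write_cohort,
    write_ground_truth,
)


class TestGenerateCohort:
    def test_f20_split_within_binomial_band(self):
        # central 99.9% band of Binomial(2000, 0.6): ppf(5e-4)..ppf(1-5e-4)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 2000, 0.6)
        patients = generate_cohort(GeneratorConfig(n_patients=2000, seed=7))
        n_f20 = (patients["first_smi_code"] == "F20").sum()
        assert lo <= n_f20 <= hi

    def test_age_at_index_matches_configured_mean(self):
        patients = generate_cohort(GeneratorConfig(n_patients=5000, seed=1))
        age = (patients["first_smi_date"] - patients["dob"]).dt.days / 365.25
        assert abs(age.mean() - 39.5) < 1.0
        lo, hi = GeneratorConfig(n_patients=1, seed=0).age_at_smi_bounds
        assert age.between(lo, hi).all()

    def test_seed_determinism(self):
        a = generate_cohort(GeneratorConfig(n_patients=300, seed=5))
        b = generate_cohort(GeneratorConfig(n_patients=300, seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_row_count_and_date_ordering(self):
        patients = generate_cohort(GeneratorConfig(n_patients=150, seed=2))
        assert len(patients) == 150
        assert (patients["first_smi_date"] > patients["dob"]).all()

    @pytest.mark.parametrize(
        "bad", [{"p_f20": 1.5}, {"episode_rate_pre": -1.0}, {"n_patients": 0},
                {"age_at_smi_bounds": (50, 20)},
                {"ethnicity_probs": {"White": 0.4, "Black": 0.4}}]
    )
    def test_invalid_config_names_offending_field(self, bad):
        kwargs = {"n_patients": 10, "seed": 0, **bad}
        with pytest.raises(ConfigError) as err:
            GeneratorConfig(**kwargs)
        field = next(iter(bad))
        assert field in str(err.value)


class TestDiseaseModel:
    def test_prevalence_is_rank_power_law(self):
        config = GeneratorConfig(n_patients=10, seed=3)
        model = make_disease_model(config)
        w = model.prevalence
        assert len(w) == config.n_diseases
        ratio = w[0] / w[1]
        assert ratio == pytest.approx(2.0 ** config.prevalence_exponent)

    def test_progression_matrix_nonnegative_zero_diagonal(self):
        model = make_disease_model(GeneratorConfig(n_patients=10, seed=3))
        assert (model.progression >= 0).all()
        assert np.diag(model.progression).sum() == 0

    def test_codes_are_disease_chapter_categories(self):
        model = make_disease_model(GeneratorConfig(n_patients=10, seed=4))
        assert "F20" not in model.codes and "F31" not in model.codes
        assert all(c[0] in "ABCDEFGHIJKLMN" for c in model.codes)


class TestGenerateEpisodes:
    def test_every_patient_has_index_event(self, small_cohort):
        _, patients, _, _, events = small_cohort
        merged = events.merge(patients, on="patient_id")
        index_events = merged[
            (merged["code3"] == merged["first_smi_code"])
            & (merged["timestamp"] == merged["first_smi_date"])
        ]
        assert set(index_events["patient_id"]) == set(patients["patient_id"])

    def test_smi_code_appears_only_at_index_date(self, small_cohort):
        _, patients, _, _, events = small_cohort
        merged = events.merge(patients, on="patient_id")
        own = merged[merged["code3"] == merged["first_smi_code"]]
        assert (own["timestamp"] == own["first_smi_date"]).all()

    def test_seed_determinism(self):
        config = GeneratorConfig(n_patients=50, seed=9)
        patients = generate_cohort(config)
        model = make_disease_model(config)
        a = generate_episodes(patients, config, model)
        b = generate_episodes(patients, config, model)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_patients_rejected(self):
        config = GeneratorConfig(n_patients=5, seed=0)
        with pytest.raises(ValueError):
            generate_episodes(pd.DataFrame(), config)

    def test_diagnosis_lists_within_bounds(self, small_cohort):
        _, _, _, episodes, _ = small_cohort
        lengths = episodes["diagnoses"].str.split(";").str.len()
        assert lengths.between(1, 20).all()

    def test_certain_recurrence_repeats_chronic_code(self):
        """recurrence_prob=1: an acquired chronic condition re-appears in
        every subsequent episode of that patient."""
        config = GeneratorConfig(
            n_patients=30, seed=21, recurrence_prob=1.0,
            selection_strength=0.0, progression_strength=0.0,
            episode_rate_pre=0.5, episode_rate_post=0.5,
            obs_years_pre=6.0, obs_years_post=4.0, mean_extra_diagnoses=0.8,
        )
        patients = generate_cohort(config)
        model = make_disease_model(config)
        episodes = generate_episodes(patients, config, model)
        chronic = {model.codes[i] for i in np.flatnonzero(model.chronic)}
        for _, group in episodes.groupby("patient_id"):
            seen: set[str] = set()
            for diags in group.sort_values("admission_date")["diagnoses"]:
                codes = diags.split(";")
                assert seen <= set(codes)  # all chronic history re-recorded
                seen |= chronic & set(codes)

    def test_independence_when_all_mechanisms_off(self):
        """With selection/progression/recurrence off, disease identity is
        independent of patient age (chi-square over age terciles)."""
        pvals = []
        for seed in range(1, 6):
            config = GeneratorConfig(
                n_patients=500, seed=seed, selection_strength=0.0,
                progression_strength=0.0, recurrence_prob=0.0,
            )
            patients = generate_cohort(config)
            model = make_disease_model(config)
            episodes = generate_episodes(patients, config, model)
            events = build_event_stream(episodes, patients)
            events = events[~events["code3"].isin(("F20", "F31"))]
            merged = events.merge(patients, on="patient_id")
            age = (merged["first_smi_date"] - merged["dob"]).dt.days / 365.25
            tercile = pd.qcut(age, 3, labels=False)
            top = merged["code3"].value_counts().head(30).index
            mask = merged["code3"].isin(top)
            table = pd.crosstab(merged.loc[mask, "code3"], tercile[mask])
            pvals.append(stats.chi2_contingency(table).pvalue)
        assert all(p > 0.001 for p in pvals)

    def test_planted_prevalence_recovered_by_rank(self):
        """Empirical code frequencies track the planted heavy-tail weights
        (mechanisms off, so the base prevalence acts unmodulated)."""
        config = GeneratorConfig(n_patients=1000, seed=13,
                                 selection_strength=0.0,
                                 progression_strength=0.0,
                                 recurrence_prob=0.0)
        patients = generate_cohort(config)
        model = make_disease_model(config)
        episodes = generate_episodes(patients, config, model)
        events = build_event_stream(episodes, patients)
        freq = events["code3"].value_counts()
        planted = pd.Series(model.prevalence, index=model.codes)
        common = freq.index.intersection(planted.index)
        rho = stats.spearmanr(freq[common], planted[common]).statistic
        assert rho > 0.8

    def test_selection_raises_age_disease_dependence(self):
        """Age-band/disease mutual information exceeds the mechanism-off
        baseline on every seed (selection separability)."""

        def mutual_information(sel, seed):
            config = GeneratorConfig(
                n_patients=300, seed=seed, selection_strength=sel,
                progression_strength=0.0, recurrence_prob=0.0,
            )
            patients = generate_cohort(config)
            episodes = generate_episodes(patients, config,
                                         make_disease_model(config))
            events = build_event_stream(episodes, patients)
            events = events[~events["code3"].isin(("F20", "F31"))]
            merged = events.merge(patients, on="patient_id")
            age = (merged["first_smi_date"] - merged["dob"]).dt.days / 365.25
            band = pd.qcut(age, 4, labels=False)
            joint = pd.crosstab(band, merged["code3"]).to_numpy() + 0.0
            pxy = joint / joint.sum()
            px = pxy.sum(1, keepdims=True)
            py = pxy.sum(0, keepdims=True)
            nz = pxy > 0
            return (pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum()

        for seed in range(1, 6):
            assert mutual_information(1.0, seed) > mutual_information(0.0, seed)

    def test_progression_lifts_successor_rates(self):
        """The rate at which new codes land in the planted successor sets
        of the patient's prior conditions is far higher with the
        progression mechanism on than off (progression separability)."""

        def successor_hit_rate(strength, seed):
            config = GeneratorConfig(
                n_patients=200, seed=seed, selection_strength=0.0,
                progression_strength=strength, recurrence_prob=0.0,
            )
            patients = generate_cohort(config)
            model = make_disease_model(config)
            episodes = generate_episodes(patients, config, model)
            events = build_event_stream(episodes, patients)
            events = events[~events["code3"].isin(("F20", "F31"))]
            succ_of = {
                model.codes[i]: {model.codes[j]
                                 for j in np.flatnonzero(model.progression[i])}
                for i in range(len(model.codes))
            }
            hits = total = 0
            for _, group in events.groupby("patient_id"):
                prior: set[str] = set()
                for c in group.sort_values("timestamp")["code3"]:
                    if prior:
                        candidates = set().union(*(succ_of[p] for p in prior))
                        total += 1
                        hits += c in candidates - prior
                    prior.add(c)
            return hits / max(total, 1)

        for seed in range(1, 6):
            assert successor_hit_rate(150.0, seed) > 3 * successor_hit_rate(0.0, seed)


class TestCohortIO:
    def test_round_trip_preserves_all_fields(self, small_cohort, tmp_path):
        _, patients, model, episodes, _ = small_cohort
        write_cohort(patients, episodes, tmp_path)
        p2, e2 = read_cohort(tmp_path)
        pd.testing.assert_frame_equal(patients, p2)
        pd.testing.assert_frame_equal(episodes, e2)

    def test_ground_truth_round_trip(self, small_cohort, tmp_path):
        _, _, model, _, _ = small_cohort
        write_ground_truth(model, tmp_path / "gt.json")
        m2 = read_ground_truth(tmp_path / "gt.json")
        assert m2.codes == model.codes
        np.testing.assert_allclose(m2.prevalence, model.prevalence)
        np.testing.assert_allclose(m2.progression, model.progression)
        assert (m2.chronic == model.chronic).all()

    def test_empty_episode_table_round_trips(self, tmp_path):
        patients = generate_cohort(GeneratorConfig(n_patients=3, seed=1))
        empty = pd.DataFrame(
            columns=["episode_id", "patient_id", "admission_date",
                     "discharge_date", "diagnoses"]
        )
        empty["admission_date"] = pd.to_datetime(empty["admission_date"])
        empty["discharge_date"] = pd.to_datetime(empty["discharge_date"])
        write_cohort(patients, empty, tmp_path)
        _, e2 = read_cohort(tmp_path)
        assert len(e2) == 0

    def test_diagnoses_cell_uses_semicolon_dialect(self, small_cohort, tmp_path):
        _, patients, _, episodes, _ = small_cohort
        write_cohort(patients, episodes, tmp_path)
        raw = (tmp_path / "episodes.csv").read_text().splitlines()
        multi = [l for l in raw[1:] if ";" in l]
        assert multi, "expected at least one multi-diagnosis episode"
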