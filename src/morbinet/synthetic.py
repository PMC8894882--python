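"""Synthetic patient cohort and admission-episode generator.

Emulates the statistical structure of a linked mental-health / hospital
admission dataset for a cohort of patients with a severe mental illness
(SMI) index diagnosis (schizophrenia F20 or bipolar disorder F31):

* ~60/40 F20/F31 split, age at first SMI diagnosis ~ truncated Normal;
* heavy-tailed (rank ~ power-law) prevalence over a vocabulary of
  3-character ICD-10 disease categories;
* admission episodes as Poisson processes before and after the index
  date, each carrying an ordered list of up to 20 diagnosis codes;
* three independently switchable generative mechanisms:
  - "selection": attribute homophily — each disease has a latent age
    center and patients are preferentially diagnosed with conditions
    typical of their age;
  - "progression": condition-conditional progression — a patient's
    existing conditions boost a latent set of successor conditions;
  - "recurrence": chronic conditions re-appear in later episodes.

The generator is seed-reproducible and dumps its latent ground truth so
parameter-recovery tests can check that each mechanism leaves its
intended statistical fingerprint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "DiseaseModel",
    "make_disease_model",
    "generate_cohort",
    "generate_episodes",
    "write_cohort",
    "read_cohort",
    "write_ground_truth",
    "read_ground_truth",
    "DIAGNOSIS_DELIMITER",
    "SELECTION_ON",
    "PROGRESSION_ON",
]

#: delimiter used to join an episode's ordered diagnosis list in one CSV cell
DIAGNOSIS_DELIMITER = ";"

#: age scale (years) of the homophily kernel exp(-s * |age - center| / scale)
AGE_KERNEL_SCALE = 10.0

#: reference "on" levels for mechanism-recovery experiments: selection or
#: progression at its on-level with the other at zero (recurrence stays at
#: the study default) leaves a detectable fingerprint at cohort sizes of a
#: few hundred patients; the selection on-level coincides with the study
#: default, progression needs a much stronger boost than the default to
#: dominate the heavy-tailed base prevalence
SELECTION_ON = 1.0
PROGRESSION_ON = 150.0

_SMI_CODES = ("F20", "F31")


class ConfigError(ValueError):
    """Raised when a GeneratorConfig field is invalid; names the field."""


def _default_ethnicity() -> dict[str, float]:
    # broad inner-city catchment mix
    return {"White": 0.52, "Black": 0.28, "Asian": 0.08, "Mixed": 0.06, "Other": 0.06}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, with study-condition defaults."""

    n_patients: int
    seed: int = 0
    p_f20: float = 0.6
    age_at_smi_mean: float = 39.5
    age_at_smi_sd: float = 16.5
    age_at_smi_bounds: tuple[float, float] = (16.0, 90.0)
    n_diseases: int = 900
    prevalence_exponent: float = 0.8
    episode_rate_pre: float = 0.7
    episode_rate_post: float = 1.4
    obs_years_pre: float = 10.0
    obs_years_post: float = 8.0
    selection_strength: float = 1.0
    progression_strength: float = 5.0
    recurrence_prob: float = 0.2
    p_female: float = 0.5
    ethnicity_probs: dict[str, float] = field(default_factory=_default_ethnicity)
    censor_date: str = "2018-03-31"
    first_smi_start: str = "2008-04-01"
    first_smi_end: str = "2018-03-31"
    #: admission rate multiplier (age/40)^gamma — admission rates rise with age
    age_rate_exponent: float = 1.5
    #: each episode carries 1 + Poisson(mean_extra_diagnoses) codes (<= 20)
    mean_extra_diagnoses: float = 1.2
    #: probability per post-SMI year of death; 0 keeps everyone censored alive
    annual_death_prob: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        errors = []
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients > 0):
            errors.append("n_patients must be a positive integer")
        if not (isinstance(self.n_diseases, (int, np.integer)) and self.n_diseases > 0):
            errors.append("n_diseases must be a positive integer")
        for name in ("p_f20", "recurrence_prob", "p_female", "annual_death_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must be a probability in [0, 1]")
        for name in (
            "episode_rate_pre",
            "episode_rate_post",
            "obs_years_pre",
            "obs_years_post",
            "selection_strength",
            "progression_strength",
            "age_rate_exponent",
            "mean_extra_diagnoses",
        ):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be nonnegative")
        if self.age_at_smi_sd <= 0:
            errors.append("age_at_smi_sd must be positive")
        if self.prevalence_exponent <= 0:
            errors.append("prevalence_exponent must be positive")
        lo, hi = self.age_at_smi_bounds
        if not lo < hi:
            errors.append("age_at_smi_bounds must satisfy min < max")
        probs = np.asarray(list(self.ethnicity_probs.values()), dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-6:
            errors.append("ethnicity_probs must be nonnegative and sum to 1")
        if pd.Timestamp(self.censor_date) <= pd.Timestamp(self.first_smi_start):
            errors.append("censor_date must fall after first_smi_start")
        if errors:
            raise ConfigError("; ".join(errors))

    def _seed_streams(self) -> dict[str, np.random.Generator]:
        ss = np.random.SeedSequence(self.seed)
        names = ("model", "cohort", "episodes")
        return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


# --------------------------------------------------------------------------
# latent disease model


def _code_pool() -> list[str]:
    """Valid 3-character categories in disease chapters I-XIV.

    Chapters XV-XXII (obstetric, perinatal, congenital, symptom, injury,
    external-cause and administrative codes) are deliberately absent: the
    analysis excludes them, and the generator emulates disease diagnoses.
    The index codes F20/F31 are reserved for the SMI event itself.
    """
    pool: list[str] = []
    for letter in "ABCDEFGHIJKLMN":
        if letter == "D":
            numbers = [*range(0, 49), *range(50, 90)]
        elif letter == "H":
            numbers = range(0, 96)
        elif letter == "K":
            numbers = range(0, 94)
        else:
            numbers = range(0, 100)
        for num in numbers:
            code = f"{letter}{num:02d}"
            if code not in _SMI_CODES:
                pool.append(code)
    return pool


@dataclass
class DiseaseModel:
    """Latent ground truth behind the episode stream.

    prevalence[i] is the normalized base weight of codes[i] (assigned by
    rank^-exponent over a random permutation of the vocabulary);
    age_center[i] is the age (years) at which the homophily kernel for
    codes[i] peaks; chronic[i] flags conditions eligible for recurrence;
    progression[i, j] >= 0 is the boost that a prior diagnosis of codes[i]
    gives to a later diagnosis of codes[j] (zero diagonal).
    """

    codes: list[str]
    prevalence: np.ndarray
    age_center: np.ndarray
    chronic: np.ndarray
    progression: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.codes)
        if not (self.prevalence > 0).all():
            raise ValueError("prevalence weights must be positive")
        if self.progression.shape != (n, n):
            raise ValueError("progression matrix must be n_diseases x n_diseases")
        if (self.progression < 0).any() or np.diag(self.progression).any():
            raise ValueError("progression weights must be nonnegative with zero diagonal")

    def index_of(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.codes)}


def make_disease_model(config: GeneratorConfig) -> DiseaseModel:
    """Draw the latent disease model implied by ``config`` (seed-determined)."""
    rng = config._seed_streams()["model"]
    pool = _code_pool()
    if config.n_diseases > len(pool):
        raise ConfigError(f"n_diseases must be <= {len(pool)} (3-character vocabulary)")
    codes = list(rng.choice(pool, size=config.n_diseases, replace=False))
    ranks = np.arange(1, config.n_diseases + 1, dtype=float)
    weights = ranks ** (-config.prevalence_exponent)
    prevalence = weights / weights.sum()
    # age profiles shift with rarity: the common acute categories of a
    # working-age admission cohort peak in young adulthood, while the
    # long tail of specific conditions accumulates at older ages — so
    # under homophily the few high-prevalence conditions concentrate on
    # young low-usage patients while older heavy users spread across
    # many rare conditions (the disassortative placement the mixing
    # analysis is designed to detect)
    rarity = (ranks - 1) / max(config.n_diseases - 1, 1)
    age_center = np.clip(
        25.0 + 40.0 * rarity + rng.normal(0.0, 8.0, size=config.n_diseases),
        15.0, 85.0,
    )
    chronic = rng.random(config.n_diseases) < 0.35
    n = config.n_diseases
    progression = np.zeros((n, n))
    n_successors = min(6, n - 1)
    for i in range(n):
        succ = rng.choice(n - 1, size=n_successors, replace=False)
        succ = np.where(succ >= i, succ + 1, succ)  # skip the diagonal
        # normalize by successor prevalence: the boost encodes the
        # specific prior->next relationship, not the successor's
        # background popularity (that factor enters multiplicatively
        # through the prevalence term at sampling time)
        progression[i, succ] = rng.uniform(0.5, 1.5, size=n_successors) / (
            n * prevalence[succ]
        )
    return DiseaseModel(codes, prevalence, age_center, chronic, progression)


# --------------------------------------------------------------------------
# patients


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the patient table: one row per patient, seed-reproducible."""
    config.validate()
    rng = config._seed_streams()["cohort"]
    n = config.n_patients
    ids = [f"P{i:05d}" for i in range(n)]
    gender = np.where(rng.random(n) < config.p_female, "F", "M")
    eth_names = list(config.ethnicity_probs)
    eth_p = np.asarray([config.ethnicity_probs[k] for k in eth_names], dtype=float)
    ethnicity = rng.choice(eth_names, size=n, p=eth_p / eth_p.sum())
    smi_code = np.where(rng.random(n) < config.p_f20, "F20", "F31")

    lo, hi = config.age_at_smi_bounds
    mu, sd = config.age_at_smi_mean, config.age_at_smi_sd
    # asymmetric truncation shifts the mean; solve for the latent location
    # so the truncated distribution's mean equals the configured mean
    loc = optimize.brentq(
        lambda m: stats.truncnorm.mean((lo - m) / sd, (hi - m) / sd, loc=m, scale=sd)
        - mu,
        lo, hi,
    )
    ages = stats.truncnorm.rvs(
        (lo - loc) / sd, (hi - loc) / sd, loc=loc, scale=sd, size=n, random_state=rng
    )

    start = pd.Timestamp(config.first_smi_start)
    end = pd.Timestamp(config.first_smi_end)
    span_days = (end - start).days
    smi_date = start + pd.to_timedelta(rng.integers(0, span_days + 1, size=n), unit="D")
    dob = smi_date - pd.to_timedelta(np.round(ages * 365.25).astype(int), unit="D")

    death = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    if config.annual_death_prob > 0:
        censor = pd.Timestamp(config.censor_date)
        yrs = rng.exponential(1.0 / config.annual_death_prob, size=n)
        cand = smi_date + pd.to_timedelta(np.round(yrs * 365.25).astype(int), unit="D")
        death = pd.Series(np.where(cand <= censor, cand, pd.NaT))

    return pd.DataFrame(
        {
            "patient_id": ids,
            "gender": gender,
            "ethnicity": ethnicity,
            "dob": dob,
            "first_smi_code": smi_code,
            "first_smi_date": smi_date,
            "death_date": death.values,
        }
    )


# --------------------------------------------------------------------------
# episodes


def _sample_codes(
    rng: np.random.Generator,
    model: DiseaseModel,
    config: GeneratorConfig,
    age_now: float,
    history_idx: list[int],
    n_draws: int,
    taken: set[int],
) -> list[int]:
    """Draw ``n_draws`` distinct disease indices from the mechanism mixture."""
    w = model.prevalence.copy()
    if config.selection_strength > 0:
        w = w * np.exp(
            -config.selection_strength
            * np.abs(age_now - model.age_center)
            / AGE_KERNEL_SCALE
        )
    if config.progression_strength > 0 and history_idx:
        boost = model.progression[history_idx].sum(axis=0)
        w = w * (1.0 + config.progression_strength * boost)
    if taken:
        w[list(taken)] = 0.0
    picks: list[int] = []
    for _ in range(n_draws):
        total = w.sum()
        if total <= 0:
            break
        j = int(rng.choice(len(w), p=w / total))
        picks.append(j)
        w[j] = 0.0
    return picks


def generate_episodes(
    patients: pd.DataFrame, config: GeneratorConfig, model: DiseaseModel | None = None
) -> pd.DataFrame:
    """Generate the admission-episode table for ``patients``.

    Admission times follow per-patient Poisson processes (episode_rate_pre
    before, episode_rate_post after the index date, both scaled by the
    age multiplier (age/40)^age_rate_exponent); each episode's diagnosis
    list is drawn from the selection/progression/recurrence mixture; every
    patient gets exactly one index episode carrying their first SMI code
    on the index date.
    """
    if len(patients) == 0:
        raise ValueError("patients table is empty")
    if model is None:
        model = make_disease_model(config)
    if len(model.codes) != config.n_diseases:
        raise ValueError("model dimensions inconsistent with config")
    rng = config._seed_streams()["episodes"]
    censor = pd.Timestamp(config.censor_date)
    chronic_idx = set(np.flatnonzero(model.chronic))

    rows: list[tuple[str, pd.Timestamp, pd.Timestamp, str]] = []
    for patient in patients.sort_values("patient_id").itertuples(index=False):
        smi = patient.first_smi_date
        age_smi = (smi - patient.dob).days / 365.25
        mult = (age_smi / 40.0) ** config.age_rate_exponent if age_smi > 0 else 1.0
        span_post = min(config.obs_years_post, (censor - smi).days / 365.25)
        if pd.notna(patient.death_date):
            span_post = min(span_post, (patient.death_date - smi).days / 365.25)
        span_post = max(span_post, 0.0)

        n_pre = rng.poisson(config.episode_rate_pre * config.obs_years_pre * mult)
        pre_off = -rng.uniform(0.0, config.obs_years_pre, size=n_pre)
        n_post = rng.poisson(config.episode_rate_post * span_post * mult)
        post_off = rng.uniform(0.0, span_post, size=n_post)

        offsets_days = np.concatenate(
            [
                np.minimum(np.round(pre_off * 365.25), -1),
                np.maximum(np.round(post_off * 365.25), 1),
            ]
        ).astype(int)
        offsets_days.sort()

        # chronological pass, threading the index episode in at offset 0
        history: list[int] = []
        history_set: set[int] = set()
        all_offsets = np.concatenate([offsets_days[offsets_days < 0], [0],
                                      offsets_days[offsets_days > 0]])
        for off in all_offsets:
            date = smi + pd.Timedelta(days=int(off))
            age_now = age_smi + off / 365.25
            episode: list[str] = []
            taken: set[int] = set()
            if off == 0:
                episode.append(patient.first_smi_code)
            # chronic recurrence re-draws
            if config.recurrence_prob > 0:
                for j in history:
                    if j in chronic_idx and rng.random() < config.recurrence_prob:
                        if len(episode) < 20:
                            episode.append(model.codes[j])
                            taken.add(j)
            # recurrent chronic codes and the index code are recorded on
            # top of the fresh presenting diagnoses (cap 20 still holds)
            n_new = min(1 + rng.poisson(config.mean_extra_diagnoses),
                        20 - len(episode))
            for j in _sample_codes(
                rng, model, config, age_now, history, max(n_new, 0), taken
            ):
                episode.append(model.codes[j])
                taken.add(j)
            for j in taken:
                if j not in history_set:
                    history_set.add(j)
                    history.append(j)
            if episode:
                discharge = date + pd.Timedelta(days=int(rng.poisson(4)))
                rows.append(
                    (patient.patient_id, date, discharge,
                     DIAGNOSIS_DELIMITER.join(episode[:20]))
                )

    out = pd.DataFrame(
        rows, columns=["patient_id", "admission_date", "discharge_date", "diagnoses"]
    )
    out = out.sort_values(["patient_id", "admission_date"], kind="stable").reset_index(
        drop=True
    )
    out.insert(0, "episode_id", [f"E{i:06d}" for i in range(len(out))])
    return out


# --------------------------------------------------------------------------
# I/O


def write_cohort(patients: pd.DataFrame, episodes: pd.DataFrame, directory) -> None:
    """Write patients.csv and episodes.csv (ISO-8601 dates, ';' diagnoses)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p = patients.copy()
    for col in ("dob", "first_smi_date", "death_date"):
        p[col] = pd.to_datetime(p[col]).dt.strftime("%Y-%m-%d")
    p.to_csv(directory / "patients.csv", index=False)
    e = episodes.copy()
    for col in ("admission_date", "discharge_date"):
        e[col] = pd.to_datetime(e[col]).dt.strftime("%Y-%m-%d")
    e.to_csv(directory / "episodes.csv", index=False)


def read_cohort(directory) -> tuple[pd.DataFrame, pd.DataFrame]:
    directory = Path(directory)
    patients = pd.read_csv(
        directory / "patients.csv",
        parse_dates=["dob", "first_smi_date", "death_date"],
        dtype={"patient_id": str},
    )
    episodes = pd.read_csv(
        directory / "episodes.csv",
        parse_dates=["admission_date", "discharge_date"],
        dtype={"episode_id": str, "patient_id": str, "diagnoses": str},
    )
    return patients, episodes


def write_ground_truth(model: DiseaseModel, path) -> None:
    """Dump the latent DiseaseModel as JSON for recovery tests."""
    i, j = np.nonzero(model.progression)
    payload = {
        "codes": list(model.codes),
        "prevalence": model.prevalence.tolist(),
        "age_center": model.age_center.tolist(),
        "chronic": model.chronic.astype(bool).tolist(),
        "progression": [
            [int(a), int(b), float(model.progression[a, b])] for a, b in zip(i, j)
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path) -> DiseaseModel:
    payload = json.loads(Path(path).read_text())
    n = len(payload["codes"])
    prog = np.zeros((n, n))
    for a, b, w in payload["progression"]:
        prog[a, b] = w
    return DiseaseModel(
        codes=list(payload["codes"]),
        prevalence=np.asarray(payload["prevalence"], dtype=float),
        age_center=np.asarray(payload["age_center"], dtype=float),
        chronic=np.asarray(payload["chronic"], dtype=bool),
        progression=prog,
    )
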