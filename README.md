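# morbinet

Temporal bipartite patient–diagnosis networks for studying how
multimorbidity — the co-occurrence of two or more health conditions —
unfolds around an index severe-mental-illness (SMI) diagnosis
(schizophrenia, ICD-10 F20, or bipolar disorder, F31).

The package is aimed at epidemiologists and network scientists working
with hospital admission records.  Real linked mental-health/admissions
data cannot be redistributed, so `morbinet` ships a seed-reproducible
synthetic cohort generator with planted, independently switchable
generative mechanisms; every analysis stage is exercisable — and its
statistical behaviour testable — at desk scale.

## The model

Admission episodes yield a stream of diagnosis events
(patient *u*, 3-character ICD-10 category *v*, date *t*), after dropping
codes in the non-disease chapters XV–XXII.  Over a time window the
stream aggregates into a weighted bipartite graph *G = (U, V, E)*:
patients on one side, disease categories on the other, edge weight *w* =
number of diagnoses of the pair in the window.  Key statistics:

- **New-condition ratio** per patient: with *N₁(u)* the pre-index and
  *N₂(u)* the post-index condition sets,
  `|N₂∖N₁| / |N₁∪N₂|`.
- **Average efficiency** of a node subset *S*:
  `E = 1/(|S|(|S|−1)) · Σ_{i≠j} 1/d_ij`,
  with shortest-path distances on the full bipartite graph and
  unreachable pairs contributing zero.
- **Degree mixing**: Kendall τ-b between a node's degree *k* and its mean
  neighbour degree ⟨k_nn⟩; negative values mean disassortative mixing.
- **Temporal graphlets**: strictly ordered event pairs (t₁ < t₂,
  t₂ − t₁ ≤ Δt) sharing a node — D1 (same pair repeated), D2 (one
  patient, two diseases: progression-like) and D3 (one disease, two
  patients: selection-like).
- **Null model**: degree-preserving double-edge swaps (A–X, B–Y →
  A–Y, B–X); significance of any scalar statistic φ via
  `z = (φ_o − ⟨φ_r⟩)/σ(φ_r)` with a two-tailed normal p-value.

## Worked example

```python
from morbinet.synthetic import GeneratorConfig, generate_cohort, \
    generate_episodes, make_disease_model
from morbinet.etl import build_event_stream, split_cohort, splits_to_frame
from morbinet.networks import build_pre_post, build_network, summarize
from morbinet.graphlets import count_2edge
from morbinet.metrics import mixing_profile
from morbinet.nulls import null_test

config = GeneratorConfig(n_patients=500, seed=42)
patients = generate_cohort(config)
episodes = generate_episodes(patients, config, make_disease_model(config))
events = build_event_stream(episodes, patients)

pre, post = build_pre_post(events, patients)
full = build_network(events, patients, label="ALL")
ratios = splits_to_frame(split_cohort(events, patients))["new_ratio"]
counts = count_2edge(events, delta_t=5.0, scope="PRE")
res = null_test(full, lambda n: mixing_profile(n, "patients").kendall_tau,
                n_replicates=100, seed=0)
```

This prints (summaries via `summarize`):

```
500 patients, 7821 episodes, 29857 diagnosis events
label  n_patients  n_diseases  n_edges  mean_patient_degree  mean_disease_degree  density     gcr
  PRE         498         893     8084               16.233                9.053    0.018 100.000
 POST         500         898    10266               20.532               11.432    0.023 100.000
  ALL         500         900    15757               31.514               17.508    0.035 100.000
mean new-condition ratio: 0.475
pre-index 2-edge graphlet fractions: {'D1': 0.016, 'D2': 0.473, 'D3': 0.512}
patient-side tau(k,knn) = -0.565, null -0.182 +/- 0.032, z = -12.1
```

Reading the numbers: patients acquire clearly more distinct conditions
after the index diagnosis (mean patient degree 16.2 pre vs 20.5 post;
on average 47.5% of a patient's conditions are new post-index); the
disease-centred wedge D3 is the most common 2-edge temporal graphlet
even in pre-index episodes (patients tend to be diagnosed with the same
conditions); and the k vs ⟨k_nn⟩ correlation is strongly negative and
far below its degree-preserving null (z ≈ −12): high-degree patients
preferentially carry rare conditions — genuine disassortative mixing,
not a degree-sequence artifact.

The same analysis runs end to end from a YAML config:

```bash
morbinet run config.yaml --out results/
# config.yaml: {seed: 5, generator: {n_patients: 500}, n_replicates: 100}
```

producing tidy CSVs (network summaries, degree profiles, condition
splits, chapter-lift matrix, mixing and peer-attribute null tests,
efficiency-vs-window series with null ribbons, graphlet counts) plus a
JSON run log; reruns with the same seed are byte-identical.

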