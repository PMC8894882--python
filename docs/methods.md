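# Methods

## Scope and data model

`morbinet` analyses hospital admission histories of a cohort defined by
an index severe-mental-illness (SMI) diagnosis: schizophrenia (ICD-10
F20) or bipolar disorder (F31).  Two tables drive everything:

* **patients** — identifier, gender, ethnicity, date of birth, index
  code (F20/F31), index date, optional death date;
* **episodes** — identifier, patient, admission and discharge dates, and
  an ordered list of up to 20 ICD-10 codes (3 or 4 characters).

ETL rounds every code to its 3-character category (anything not
matching letter–digit–digit is rejected and logged), drops the
non-disease chapters XV–XXII (obstetric, perinatal, congenital,
symptom, injury, external-cause, administrative), and timestamps each
retained diagnosis with the episode's **admission** date.  Time is
measured as signed years to the index date (day difference / 365.25);
events dated exactly on the index date count as post-index, since the
index diagnosis itself happens that day.  When a patient appears in
several record sources, the earliest SMI mention wins, with date ties
resolved in favour of the mental-health register and then the
lexicographically smaller code.

Within one episode, duplicate categories collapse to a single event at
the smallest list position; repeats across episodes are kept — they
carry edge weights and the repeated-pair graphlet D1.  Whether a real
coding pipeline would deduplicate within episodes is unknowable from
code lists alone; deduplication is this package's convention.

## Networks

A window of the event stream aggregates to a weighted bipartite graph:
patient nodes (gender, ethnicity, index code, age at index as
attributes), disease nodes (category, chapter), edges weighted by the
diagnosis count for the pair, with the patient's age at the first
diagnosis of the pair (floored to whole years) as an edge attribute.  A
patient's own index code never forms an edge, and a patient with no
other retained diagnoses is absent from the networks (but not from the
graphlet stream, which keeps index events).

Window boundaries are half-open `[t, t+Δt)` except the last window of a
sliding sequence, which is closed: a closed–closed convention would
double-count events sitting exactly on interior boundaries.  Snapshot
sequences default to Δt = 5 years and a 1-year step; cumulative mode
aggregates everything up to each yearly boundary.

## Statistics

* **Average efficiency** `E = 1/(|S|(|S|−1)) Σ 1/d_ij` over ordered
  pairs of the chosen subset (all nodes, patients, diseases), distances
  always measured on the full bipartite graph; unreachable pairs add 0.
  Restricting only the pair set (rather than re-computing distances on
  a one-mode projection) keeps patient- and disease-side efficiencies
  on the same metric space; this is a deliberate reading of an
  ambiguous convention, flagged here.
* **Degree mixing** uses unweighted degrees and the tie-corrected
  Kendall τ-b: degrees are small integers, so ties are everywhere.
  Weights are likewise ignored in all efficiency computations, because
  the null model (below) does not preserve them.
* **Second-order neighbourhoods** are nodes at distance exactly 2
  (always the same parity in a bipartite graph); peer-attribute
  statistics average an attribute (by default age at index) over those
  distance-2 patients, implemented with sparse matrix products.
* **Chapter lift** is patient-level presence/absence:
  `P(pre∈A, post∈B) / (P(pre∈A)·P(post∈B))`, NaN when a marginal is
  empty.
* **Modularity** of attribute partitions is computed on the shared-
  neighbour-weighted one-mode projections (standard weighted Newman Q).
* Group means (degree profiles) carry normal-approximation 95% CIs;
  single-member groups get zero-width intervals.

## Null model

Degree-preserving randomization by double-edge swaps: pick two edges
A–X and B–Y; replace with A–Y and B–X unless endpoints coincide or an
edge would be duplicated.  A replicate applies 10·|E| accepted swaps
(a standard mixing heuristic; the package exposes the count).  Both
degree sequences, the node sets and the edge count are conserved
exactly; weights reset to 1, so only weight-free statistics may be
z-scored against this ensemble.  Saturated networks (no admissible
swap, e.g. complete bipartite) return an identical copy with a warning.
Significance is `z = (φ_o − ⟨φ_r⟩)/σ(φ_r)` with a two-tailed
standard-normal p-value; the empirical percentile of the observed value
within the ensemble is reported alongside as a diagnostic.

## Temporal graphlets

Catalogues are enumerated exhaustively, not hard-coded: static classes
are connected parity-labelled bipartite graphs on 2–4 nodes, canonical
under parity-preserving relabelling (7 classes: edge, two wedges, two
stars, path, cycle), with automorphism orbits computed on topology
alone, ignoring parity.  Temporal classes are strictly ordered edge
sequences (m ≤ 3) in first-appearance normal form whose final static
graph is connected; the three 2-edge classes D1/D2/D3 are the repeated
pair, the patient-centred wedge and the disease-centred wedge.  The
D-index assignment follows the mechanism logic (D2 ↔ within-patient
progression, D3 ↔ cross-patient selection); the catalogue dump records
the canonical forms so the convention is auditable.

Counting scans the time-sorted stream once, keeping per-patient,
per-disease and per-pair counts of events inside the active Δt window,
so cost is O(events × window occupancy).  **Events sharing a timestamp
never pair**: the ordering t₁ < t₂ is strict, and codes within one
admission episode share the admission date.  This is the single largest
unstated convention in this analysis family and it is deliberate — an
episode's code list has no internal temporal order.  A brute-force
all-pairs twin of the counter exists solely as its oracle in tests.
Scope restrictions (pre-/post-index) are applied per event; a pair
straddling the boundary is counted in neither restricted scope.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with latent ground truth dumped to JSON for recovery tests:

| parameter | default | meaning / rationale |
|---|---|---|
| `p_f20` | 0.6 | F20/F31 split of the index diagnosis |
| `age_at_smi_mean`, `sd`, bounds | 39.5, 16.5, (16, 90) | truncated-normal age at index; the latent location is solved so the *truncated* mean equals the configured mean |
| `n_diseases` | 900 | close to the full 3-character vocabulary of disease chapters I–XIV; hospital cohorts realise most of it |
| `prevalence_exponent` | 0.8 | rank^(−0.8) heavy-tailed base prevalence |
| `episode_rate_pre/post` | 0.7 / 1.4 per yr | admissions intensify after the index diagnosis |
| `obs_years_pre/post` | 10 / 8 | observation span around the index date (post clipped at censoring) |
| `age_rate_exponent` | 1.5 | admission rate × (age/40)^1.5 — admission rates rise with age |
| `mean_extra_diagnoses` | 1.2 | episodes carry 1 + Poisson(1.2) codes (≤ 20) |
| `selection_strength` | 1.0 | homophily kernel exp(−s·|age − centre|/10y) |
| `progression_strength` | 5.0 | boost 1 + λ·Σ progression weights of prior conditions |
| `recurrence_prob` | 0.2 | chance per episode that an acquired chronic condition is re-recorded |

Each disease carries a latent age centre, a chronic flag (35%), and six
random successor conditions.  Two design elements matter and were fixed
after exploratory experiments, before any thresholds were set:

* **Age centres shift with rarity** — common categories peak in young
  adulthood, the long tail of specific conditions at older ages.
  Combined with age-graded admission rates this places the few
  high-prevalence conditions on young low-usage patients while older
  heavy users spread across many rare conditions: exactly the
  disassortative, efficiency-raising placement the mixing and null-
  model analyses are designed to detect.  With selection switched off
  the kernel is inert and the structure disappears.
* **Progression weights are normalized by successor prevalence**, so
  the boost encodes a specific prior→next relationship.  Unnormalized
  weights would make the progression mechanism reproduce the base
  prevalence profile and be statistically indistinguishable from it.

Every patient gets exactly one index episode carrying their index code
on the index date; recurrent chronic codes are recorded on top of the
fresh presenting diagnoses.  Episode times are uniform within the
observation spans given Poisson counts; diagnosis draws are sequential
without replacement within an episode.

Reference "on" levels for mechanism-recovery experiments are
`SELECTION_ON = 1.0` (the study default — the homophily fingerprint is
already detectable there) and `PROGRESSION_ON = 150` (progression must
overwhelm the heavy-tailed base prevalence to dominate disease choice).
Mechanism-recovery experiments measure graphlet orderings on
**pre-index** episodes: the materialized index event is shared by the
entire cohort and would otherwise inject a large mechanism-independent
D3 contribution — the same artifact control used when analysing real
cohorts.

What the generator does **not** emulate: true ICD-10 semantics beyond
chapter membership, seasonal or secular admission trends, correlated
admission bursts, mortality (optional and off by default), coding error
modes, or care-pathway effects.  Passing recovery tests therefore shows
the analysis machinery detects planted structure of the stated kinds at
realistic scale — not that real cohorts contain that structure.

## Numerical conventions and degenerate inputs

* Undefined quantities are NaN markers, never exceptions: the
  new-condition ratio of a patient with no retained conditions, τ on a
  degenerate (tie-only) margin, z when the null ensemble has zero
  variance, lift cells with empty marginals, the giant-component ratio
  of an empty network.
* Kendall τ via `scipy.stats.kendalltau` (τ-b); shortest paths via
  `scipy.sparse.csgraph` BFS; truncated normals via
  `scipy.stats.truncnorm` with the location solved by Brent's method.
* All randomness flows from named `numpy` `SeedSequence` streams; the
  pipeline expands one master seed into per-stage streams so stages can
  be re-run in isolation.  Identical config + seed ⇒ byte-identical CSV
  output.
* Problem sizes in the test-suite and in `scripts/acceptance.py` —
  500-patient cohorts (300 for the homophily runs), 100-replicate null
  ensembles, 5-year windows, 5 seeds — are the package's chosen
  desk-scale study conditions: large enough that every planted
  fingerprint is detectable with margin, small enough to iterate on.

## Known limitations

* The 2-edge counter is exact but the 3-edge temporal classes are
  catalogued only, not counted at scale.
* The swap-chain null is a heuristic sampler of the configuration
  ensemble; 10·|E| accepted swaps is a burn-in convention, not a
  guarantee of uniform mixing on adversarial degree sequences.
* The normal-approximation p-value for z is exact only asymptotically;
  the empirical percentile is reported for small ensembles.
* Patient-side and disease-side efficiencies restrict the pair set but
  keep full-bipartite distances (see above); projection-metric variants
  would differ.
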