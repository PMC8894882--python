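"""End-to-end analysis pipeline: cohort -> ETL -> networks -> metrics ->
null tests -> temporal graphlets, driven by one YAML config.

The report bundle is a directory of tidy CSV tables (plus a JSON run
log); figures are optional and CSV is canonical.  A single master seed
expands into independent per-stage seed streams so any stage can be
re-run in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import etl as etl_mod
from . import metrics as metrics_mod
from . import nulls as nulls_mod
from .graphlets import count_2edge
from .networks import build_network, build_pre_post, build_snapshots, summarize
from .synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_episodes,
    make_disease_model,
    read_cohort,
    write_cohort,
    write_ground_truth,
)

__all__ = ["RunConfig", "validate_config", "run"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated, fully defaulted pipeline configuration."""

    seed: int = 0
    input_dir: str | None = None
    generator: dict | None = None
    exclude_mental: bool = False
    window_years: float | None = None
    censor_date: str = "2018-03-31"
    snapshot_delta_t: float = 5.0
    snapshot_step: float = 1.0
    snapshot_mode: str = "sliding"
    n_replicates: int = 1000
    n_swaps: int | None = None
    graphlet_delta_t: list[float] = field(default_factory=lambda: [5.0])
    graphlet_scopes: list[str] = field(default_factory=lambda: ["ALL", "PRE", "POST"])
    figures: bool = False

    def validate(self) -> list[str]:
        errors = []
        if self.input_dir is not None and self.generator is not None:
            errors.append("give either input_dir or generator, not both")
        if self.input_dir is None and self.generator is None:
            errors.append("one of input_dir or generator is required")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            errors.append(f"input_dir does not exist: {self.input_dir}")
        if self.snapshot_delta_t <= 0:
            errors.append("snapshot_delta_t must be positive")
        if self.snapshot_step <= 0:
            errors.append("snapshot_step must be positive")
        if self.snapshot_mode not in ("sliding", "cumulative"):
            errors.append("snapshot_mode must be 'sliding' or 'cumulative'")
        if self.n_replicates <= 0:
            errors.append("n_replicates must be positive")
        if self.n_swaps is not None and self.n_swaps <= 0:
            errors.append("n_swaps must be positive when given")
        if any(dt <= 0 for dt in self.graphlet_delta_t):
            errors.append("graphlet_delta_t entries must be positive")
        if any(s not in ("ALL", "PRE", "POST") for s in self.graphlet_scopes):
            errors.append("graphlet_scopes entries must be ALL, PRE or POST")
        if self.window_years is not None and self.window_years <= 0:
            errors.append("window_years must be positive when given")
        return errors


def validate_config(path) -> RunConfig:
    """Parse a YAML config, fill defaults, and list every violation at once."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    config = RunConfig(**{k: v for k, v in raw.items() if k in known})
    errors = [f"unknown config key: {k}" for k in sorted(unknown)]
    errors += config.validate()
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return config


def _stage_seed(master: int, stage: str) -> int:
    """Stable derived seed < 2^31 for one named stage."""
    child = np.random.SeedSequence([master, abs(hash(stage)) % (2**31)])
    return int(child.generate_state(1)[0] % (2**31))


def run(config: RunConfig, outdir) -> dict:
    """Execute all stages; returns a dict of the bundle's file paths."""
    errors = config.validate()
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, str] = {}

    def save(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        frame.to_csv(path, index=False)
        bundle[name] = str(path)

    # ---- stage: data -----------------------------------------------------
    if config.generator is not None:
        gen = GeneratorConfig(**{**config.generator,
                                 "seed": config.generator.get("seed", config.seed)})
        patients = generate_cohort(gen)
        model = make_disease_model(gen)
        episodes = generate_episodes(patients, gen, model)
        datadir = outdir / "data"
        write_cohort(patients, episodes, datadir)
        write_ground_truth(model, datadir / "ground_truth.json")
        censor = gen.censor_date
    else:
        patients, episodes = read_cohort(config.input_dir)
        censor = config.censor_date
    logger.info("data: %d patients, %d episodes", len(patients), len(episodes))

    # ---- stage: etl ------------------------------------------------------
    events = etl_mod.build_event_stream(
        episodes, patients,
        exclude_mental=config.exclude_mental,
        window_years=config.window_years,
    )
    ev_out = events.copy()
    ev_out["timestamp"] = ev_out["timestamp"].dt.strftime("%Y-%m-%d")
    save(ev_out, "events.csv")
    splits = etl_mod.split_cohort(events, patients)
    split_frame = etl_mod.splits_to_frame(splits)
    save(split_frame, "condition_splits.csv")

    meta = patients.set_index("patient_id")
    npy_rows = []
    for s in splits:
        m = meta.loc[s.patient_id]
        rates = etl_mod.new_per_year(
            s, m["first_smi_date"],
            m["death_date"] if pd.notna(m["death_date"]) else None,
            pd.Timestamp(censor),
        )
        npy_rows.append({"patient_id": s.patient_id, **rates})
    save(pd.DataFrame(npy_rows), "new_per_year.csv")

    # ---- stage: networks -------------------------------------------------
    pre, post = build_pre_post(events, patients)
    everything = build_network(events, patients, label="ALL")
    summaries = pd.DataFrame(
        [dataclasses.asdict(summarize(n)) for n in (pre, post, everything)]
    )
    save(summaries, "network_summaries.csv")

    # ---- stage: metrics --------------------------------------------------
    profiles = []
    for net in (pre, post, everything):
        for key in ("side", "chapter", "age_band"):
            prof = metrics_mod.degree_profile(net, key)
            prof.insert(0, "group_by", key)
            prof.insert(0, "window", net.label)
            profiles.append(prof)
    save(pd.concat(profiles, ignore_index=True), "degree_profiles.csv")

    lift = metrics_mod.chapter_lift(splits)
    save(lift.lift.reset_index(names="pre_chapter"), "chapter_lift.csv")

    seed_nulls = _stage_seed(config.seed, "nulls")
    null_rows = []

    def phi_tau(side):
        return lambda net: metrics_mod.mixing_profile(net, side).kendall_tau

    mixing_rows = []
    for net in (pre, post, everything):
        for side in ("patients", "diseases"):
            mix = metrics_mod.mixing_profile(net, side)
            mixing_rows.append(
                {"window": net.label, "side": side, "kendall_tau": mix.kendall_tau}
            )
            res = nulls_mod.null_test(
                net, phi_tau(side), n_replicates=config.n_replicates,
                n_swaps=config.n_swaps, seed=seed_nulls,
                name=f"tau_k_knn/{side}/{net.label}",
            )
            null_rows.append(_null_row(res, net.label))
        taus, _ = metrics_mod.second_order_correlations(net, "diseases")
        mixing_rows.append(
            {"window": net.label, "side": "diseases", **taus}
        )
    save(pd.DataFrame(mixing_rows), "mixing.csv")

    peer_table, peer_tau = metrics_mod.peer_attribute(everything, "age_at_smi")
    save(peer_table, "peer_age.csv")
    res = nulls_mod.null_test(
        everything, lambda n: metrics_mod.peer_attribute(n, "age_at_smi")[1],
        n_replicates=config.n_replicates, n_swaps=config.n_swaps,
        seed=seed_nulls, name="tau_age_peer_age/ALL",
    )
    null_rows.append(_null_row(res, "ALL"))

    # ---- stage: efficiency over snapshots --------------------------------
    snaps = build_snapshots(
        events, patients, delta_t=config.snapshot_delta_t,
        step=config.snapshot_step, mode=config.snapshot_mode,
    )
    eff_rows = []
    for snap in snaps:
        if snap.graph.number_of_edges() < 2:
            continue
        row = {"window": snap.label, "midpoint": snap.midpoint}
        for subset in ("all", "patients", "diseases"):
            if len(metrics_mod._side_nodes(snap, subset)) < 2:
                continue
            res = nulls_mod.null_test(
                snap, lambda n, s=subset: metrics_mod.efficiency(n, s).value,
                n_replicates=config.n_replicates, n_swaps=config.n_swaps,
                seed=seed_nulls, name=f"efficiency/{subset}/{snap.label}",
            )
            row[f"E_{subset}"] = res.observed
            row[f"E_{subset}_null_mean"] = res.null_mean
            row[f"E_{subset}_null_sd"] = res.null_sd
            row[f"E_{subset}_z"] = res.z
            row[f"E_{subset}_ratio"] = (
                res.observed / res.null_mean if res.null_mean else np.nan
            )
            null_rows.append(_null_row(res, snap.label))
        eff_rows.append(row)
    save(pd.DataFrame(eff_rows), "efficiency_series.csv")
    save(pd.DataFrame(null_rows), "null_tests.csv")

    # ---- stage: graphlets ------------------------------------------------
    gl_rows = []
    for dt in config.graphlet_delta_t:
        for scope in config.graphlet_scopes:
            counts = count_2edge(events, dt, scope)
            gl_rows.append(
                {"scope": scope, "delta_t": dt, **counts.counts,
                 **{f"frac_{k}": v for k, v in counts.fractions.items()}}
            )
    save(pd.DataFrame(gl_rows), "graphlet_counts.csv")

    if config.figures:
        from . import plotting

        eff_frame = pd.DataFrame(eff_rows)
        if not eff_frame.empty and "E_all" in eff_frame:
            bundle["efficiency_series.png"] = str(
                plotting.plot_efficiency_series(
                    eff_frame, outdir / "efficiency_series.png"
                )
            )
        gl_frame = pd.DataFrame(gl_rows)
        bundle["graphlet_fractions.png"] = str(
            plotting.plot_graphlet_fractions(
                gl_frame[gl_frame["delta_t"] == config.graphlet_delta_t[0]],
                outdir / "graphlet_fractions.png",
            )
        )
        chap = metrics_mod.degree_profile(everything, "chapter")
        bundle["degree_profile.png"] = str(
            plotting.plot_degree_profile(chap, outdir / "degree_profile.png")
        )

    log = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_patients": int(len(patients)),
        "n_episodes": int(len(episodes)),
        "n_events": int(len(events)),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    bundle["run_log.json"] = str(outdir / "run_log.json")
    return bundle


def _null_row(res: nulls_mod.NullTestResult, window: str) -> dict:
    return {
        "statistic": res.name, "window": window, "observed": res.observed,
        "null_mean": res.null_mean, "null_sd": res.null_sd, "z": res.z,
        "p_two_tailed": res.p_two_tailed, "n_replicates": res.n_replicates,
        "seed": res.seed, "empirical_percentile": res.empirical_percentile,
    }
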