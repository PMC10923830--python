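"""End-to-end orchestration: simulate -> bin -> effect sizes -> population
comparisons -> report bundle, with reproducible seeding and a config-hash
manifest.

Each epoch has its own factorial design: reward probability alone in the cue
epoch; reward probability x direction in the motion epoch; reward
probability x direction x reward outcome in the outcome epoch — always with
all interactions, and with time as an additional factor for whole-epoch
quantities.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anova
from .anova import FactorialDesign, Type2Solver
from .binning import bin_spikes
from .resampling import permutation_welch_anova, permutation_welch_t
from .simulate import SimConfig, generate_session

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_pipeline", "filter_neurons", "epoch_design"]

EPOCH_FACTORS = {
    "cue": ["reward_prob"],
    "motion": ["reward_prob", "direction"],
    "outcome": ["reward_prob", "direction", "outcome"],
}
FACTOR_COLUMNS = {
    "reward_prob": "reward_prob",
    "direction": "direction_deg",
    "outcome": "outcome",
}


@dataclass
class AnalysisConfig:
    """Analysis settings plus one simulated population per entry in
    ``populations`` (population name -> SimConfig field overrides)."""

    populations: dict[str, dict] = field(default_factory=lambda: {"sim": {}})
    n_neurons: int = 20
    epochs: list[str] = field(default_factory=lambda: ["cue", "motion", "outcome"])
    window_ms: tuple[float, float] = (0, 800)
    bin_ms: int = 50
    alpha: float = 0.05
    n_resamples: int = 10_000
    min_trials: int = 55
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "window_ms" in raw:
            raw["window_ms"] = tuple(raw["window_ms"])
        return cls(**raw)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # purely I/O; identical analyses hash identically
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def epoch_design(trial_table: pd.DataFrame, epoch: str) -> FactorialDesign:
    """Factorial design (without time) for one epoch from a trial table."""
    if epoch not in EPOCH_FACTORS:
        raise ValueError(f"unknown epoch {epoch!r}")
    factors = {
        name: trial_table[FACTOR_COLUMNS[name]].to_numpy()
        for name in EPOCH_FACTORS[epoch]
    }
    return FactorialDesign(factors)


def filter_neurons(
    neuron_table: pd.DataFrame,
    min_trials: int = 55,
    time_varying_only: bool = False,
) -> pd.DataFrame:
    """Apply the inclusion rules to a per-(neuron, task) record table.

    Requires columns neuron_id, task, n_trials and (if ``time_varying_only``)
    a boolean ``time_varying`` column.  Neurons need at least ``min_trials``
    successful trials; a neuron recorded on both tasks keeps the task with
    more trials.
    """
    t = neuron_table[neuron_table["n_trials"] >= min_trials]
    t = t.sort_values(["neuron_id", "n_trials"], ascending=[True, False])
    t = t.drop_duplicates(subset="neuron_id", keep="first")
    if time_varying_only:
        t = t[t["time_varying"].astype(bool)]
    return t.reset_index(drop=True)


def _csv_with_hash(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis on simulated populations; returns the report bundle.

    Writes per-neuron effect-size tables (per-bin and whole-epoch, all terms
    including interactions), per-population bin-wise summaries (mean and SEM
    across neurons), cross-population permutation comparisons of whole-epoch
    effect sizes, and a manifest with the config hash and seeds.  Neurons
    whose design degenerates (e.g. a factor losing a level by chance) are
    skipped and logged in the manifest's skip ledger.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    rows_epoch, rows_bin, rows_sig, skips = [], [], [], []
    epoch_values: dict[tuple[str, str, str], dict[str, list[float]]] = {}

    for p_i, (pop, overrides) in enumerate(sorted(config.populations.items())):
        sim = SimConfig(**{
            "seed": config.seed + 1000 * (p_i + 1),
            "bin_ms": config.bin_ms,
            "epoch_duration_ms": int(config.window_ms[1] - config.window_ms[0]),
            **overrides,
        })
        session = generate_session(sim, n_neurons=config.n_neurons)
        for epoch in config.epochs:
            try:
                design = epoch_design(session.trial_table, epoch)
                solver = Type2Solver(design.with_time(sim.n_bins))
                bin_solver = Type2Solver(design)
            except ValueError as exc:
                skips.append({"population": pop, "epoch": epoch, "reason": str(exc)})
                continue
            for nrn in session.neurons:
                binned = bin_spikes(
                    nrn.spike_times_ms, session.trial_table, epoch,
                    config.window_ms, config.bin_ms,
                )
                decomp = solver.decompose(binned.counts.astype(float).ravel())
                for term in decomp.ss:
                    if "time" in term:
                        continue
                    label = anova.term_label(term)
                    ss_t, df_t = anova._pooled_term_ss(decomp, term)
                    omega = anova._omega_from_ss(
                        ss_t, df_t, decomp.ss_error, decomp.df_error, decomp.n_obs
                    )
                    eta = ss_t / (ss_t + decomp.ss_error) if ss_t + decomp.ss_error else 0.0
                    p, flag = anova.neuron_significance(
                        binned, design, term, config.alpha, solver=solver
                    )
                    rows_epoch.append(
                        dict(neuron_id=nrn.neuron_id, population=pop, epoch=epoch,
                             term=label, scope="epoch", omega_p2=omega, eta_p2=eta)
                    )
                    rows_sig.append(
                        dict(neuron_id=nrn.neuron_id, population=pop, epoch=epoch,
                             term=label, p_value=p, significant=flag)
                    )
                    epoch_values.setdefault((epoch, label, "omega_p2"), {}) \
                        .setdefault(pop, []).append(omega)
                p_time, tv = anova.time_varying_flag(binned, design, config.alpha,
                                                     solver=solver)
                rows_sig.append(
                    dict(neuron_id=nrn.neuron_id, population=pop, epoch=epoch,
                         term="time", p_value=p_time, significant=tv)
                )
                bins = bin_solver.decompose_many(binned.counts.astype(float))
                for j, d in enumerate(bins):
                    for term in d.ss:
                        rows_bin.append(
                            dict(neuron_id=nrn.neuron_id, population=pop, epoch=epoch,
                                 term=anova.term_label(term), scope=f"bin:{j}",
                                 omega_p2=anova.omega_partial(d, term),
                                 eta_p2=anova.eta_partial(d, term))
                        )

    effect_epoch = pd.DataFrame(rows_epoch)
    effect_bin = pd.DataFrame(rows_bin)
    significance = pd.DataFrame(rows_sig)
    summary = (
        effect_bin.groupby(["population", "epoch", "term", "scope"])["omega_p2"]
        .agg(mean_omega_p2="mean", sem_omega_p2=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
             n_neurons="count")
        .reset_index()
    )

    comparisons = {}
    rng = np.random.default_rng(config.seed + 77)
    for (epoch, term, metric), groups in sorted(epoch_values.items()):
        if len(groups) < 2:
            continue
        names = sorted(groups)
        arrays = [np.asarray(groups[g]) for g in names]
        seed_a = int(rng.integers(2**31))
        res = permutation_welch_anova(arrays, config.n_resamples, seed=seed_a)
        pairwise = {}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                seed_t = int(rng.integers(2**31))
                r = permutation_welch_t(arrays[i], arrays[j], config.n_resamples,
                                        seed=seed_t)
                pairwise[f"{names[i]}_vs_{names[j]}"] = {
                    "t": r.statistic, "p": r.p_value, "seed": seed_t
                }
        comparisons[f"{epoch}:{term}:{metric}"] = {
            "groups": names,
            "n": [len(a) for a in arrays],
            "welch_F": res.statistic,
            "p": res.p_value,
            "seed": seed_a,
            "pairwise": pairwise,
        }

    _csv_with_hash(effect_epoch, out / "effectsizes_epoch.csv", cfg_hash)
    _csv_with_hash(effect_bin, out / "effectsizes_bins.csv", cfg_hash)
    _csv_with_hash(significance, out / "significance.csv", cfg_hash)
    _csv_with_hash(summary, out / "population_summary.csv", cfg_hash)
    with open(out / "comparisons.json", "w") as fh:
        json.dump(comparisons, fh, indent=1)
    manifest = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "skips": skips,
        "tables": [
            "effectsizes_epoch.csv", "effectsizes_bins.csv", "significance.csv",
            "population_summary.csv", "comparisons.json",
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return {
        "effectsizes_epoch": effect_epoch,
        "effectsizes_bins": effect_bin,
        "significance": significance,
        "population_summary": summary,
        "comparisons": comparisons,
        "manifest": manifest,
    }
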