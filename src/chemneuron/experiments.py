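"""Reproducible experiment runs: configuration, fixtures, artifact bundles.

An :class:`ExperimentConfig` ties a neuron specification, an input task and
engine/analysis settings together; :func:`run_experiment` realizes it into a
bundle of CSV artifacts (schedule, trajectory, weight summary) plus a JSON
run log.  Every random draw is traceable to the config seed, and every
output file carries a config-hash header line so bundles can be matched to
the exact configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .analysis import steady_state_weights
from .engine import HillParams, simulate_hill, simulate_ode, simulate_ssa
from .inputs import TaskSpec, generate_schedule
from .models import NeuronSpec, build_ccn, build_cn, default_spec

__all__ = ["ExperimentConfig", "ConfigError", "run_experiment",
           "make_fixture", "FIXTURES"]

log = logging.getLogger("chemneuron")


class ConfigError(ValueError):
    """Invalid experiment configuration; lists every violation found."""


@dataclass
class ExperimentConfig:
    neuron: NeuronSpec
    task: TaskSpec
    model: str = "cn"                 # "cn" | "ccn" | "cn-hill"
    mode: str = "ssa"                 # "ssa" | "ode"
    seed: int = 0
    grid: float = 0.1
    transient: float = 700.0
    window: float = 300.0
    outdir: str = "experiment-out"

    def validate(self) -> None:
        problems = []
        if self.task.N != self.neuron.N:
            problems.append(
                f"task.N ({self.task.N}) != neuron.N ({self.neuron.N})")
        if self.model not in ("cn", "ccn", "cn-hill"):
            problems.append(f"unknown model {self.model!r}")
        if self.mode not in ("ssa", "ode"):
            problems.append(f"unknown mode {self.mode!r}")
        if self.grid <= 0:
            problems.append("grid must be > 0")
        if self.transient + self.window > self.task.horizon:
            problems.append(
                "analysis window (transient + window) exceeds task.horizon")
        if problems:
            raise ConfigError("; ".join(problems))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["neuron"] = self.neuron.to_dict()
        d["task"] = asdict(self.task)
        d["task"]["frequencies"] = list(self.task.frequencies)
        d["task"]["correlation_chain"] = list(self.task.correlation_chain)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["neuron"] = NeuronSpec.from_dict(d["neuron"])
        t = dict(d["task"])
        t["frequencies"] = tuple(t["frequencies"])
        t["correlation_chain"] = tuple(t.get("correlation_chain", ()))
        d["task"] = TaskSpec(**t)
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output paths excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        text = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _write_with_header(path: Path, header: str, write_body) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        write_body(fh)


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one configured experiment end to end.

    Writes ``schedule.csv``, ``trajectory.csv``, ``weights.csv`` and
    ``run.json`` into ``config.outdir`` and returns a result dict with the
    weight summary and artifact paths.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    header = f"# chemneuron {__version__} config {chash}\n"
    t_start = time.time()

    task = TaskSpec(config.task.N, config.task.frequencies,
                    config.task.correlation_chain, config.task.delta,
                    config.task.jitter_var, config.task.horizon, config.seed)
    schedule = generate_schedule(task, config.neuron.beta, config.neuron.kappa)
    log.info("phase=schedule events=%d horizon=%g", len(schedule), task.horizon)

    hill = None
    if config.model == "cn":
        net = build_cn(config.neuron)
    elif config.model == "ccn":
        net = build_ccn(config.neuron)
    else:  # cn-hill
        net = build_cn(config.neuron, activation="hill")
        hill = HillParams(config.neuron.m, config.neuron.threshold,
                          config.neuron.E_total)
    log.info("phase=build model=%s species=%d reactions=%d", config.model,
             len(net.species), len(net.reactions))

    if config.mode == "ssa":
        traj = simulate_ssa(net, schedule, task.horizon, config.seed,
                            config.grid, hill=hill)
    else:
        traj = simulate_ode(net, schedule, task.horizon, config.grid,
                            hill=hill)
    log.info("phase=simulate mode=%s samples=%d", config.mode, traj.times.size)

    summary = steady_state_weights(traj, config.transient, config.window)
    log.info("phase=analyze dispersion=%s", summary.dispersion)

    paths = {}
    p = outdir / "schedule.csv"
    _write_with_header(p, header, lambda fh: schedule.to_frame().to_csv(fh, index=False))
    paths["schedule"] = str(p)
    p = outdir / "trajectory.csv"
    _write_with_header(p, header, lambda fh: traj.to_frame().to_csv(fh, index=False))
    paths["trajectory"] = str(p)
    p = outdir / "weights.csv"
    _write_with_header(p, header, lambda fh: summary.to_frame().to_csv(fh, index=False))
    paths["weights"] = str(p)

    run_log = {
        "version": __version__,
        "config_hash": chash,
        "seed": config.seed,
        "n_events": len(schedule),
        "n_species": len(net.species),
        "n_reactions": len(net.reactions),
        "dispersion": None if summary.degenerate else summary.dispersion,
        "raw_weights": [float(w) for w in summary.raw],
        "elapsed_s": round(time.time() - t_start, 3),
        "config": config.to_dict(),
    }
    p = outdir / "run.json"
    with open(p, "w") as fh:
        json.dump(run_log, fh, indent=1)
    paths["log"] = str(p)
    return {"summary": summary, "paths": paths, "config_hash": chash}


# ---------------------------------------------------------------------------
# fixtures: small, fast configs implementing the in-article protocols
# ---------------------------------------------------------------------------

def _fixture_assoc(seed: int) -> ExperimentConfig:
    # two channels, strong first weight, weak second; correlated boli
    neuron = default_spec(N=2, m=5, H_init=(100, 0))
    task = TaskSpec(N=2, frequencies=(2.0, 2.0), correlation_chain=(1, 2),
                    delta=0.0047, jitter_var=0.0001, horizon=60.0, seed=seed)
    return ExperimentConfig(neuron, task, seed=seed, grid=0.01,
                            transient=40.0, window=20.0,
                            outdir="fixture-assoc")


def _fixture_fb2(seed: int) -> ExperimentConfig:
    from .inputs import make_fb_task

    neuron = default_spec(N=5, m=1)
    task = make_fb_task(2, 4.0, 2.0, 5, horizon=1000.0, seed=seed)
    return ExperimentConfig(neuron, task, seed=seed, outdir="fixture-fb2")


def _fixture_tc2(seed: int) -> ExperimentConfig:
    from .inputs import make_tc_task

    neuron = default_spec(N=5, m=5)
    task = make_tc_task(2, 2.0, 0.0047, 0.0001, 5, horizon=1000.0, seed=seed)
    return ExperimentConfig(neuron, task, seed=seed, outdir="fixture-tc2")


def _fixture_fig6(seed: int) -> ExperimentConfig:
    # two-bolus coincidence protocol; feed to differential_weight_fraction
    neuron = default_spec(N=2, m=4)
    task = TaskSpec(N=2, frequencies=(2.0, 2.0), correlation_chain=(1, 2),
                    delta=0.0, jitter_var=0.0, horizon=0.2, seed=seed)
    return ExperimentConfig(neuron, task, seed=seed, grid=0.01,
                            transient=0.0, window=0.2, outdir="fixture-fig6")


FIXTURES = {
    "assoc": _fixture_assoc,
    "fb2": _fixture_fb2,
    "tc2": _fixture_tc2,
    "fig6": _fixture_fig6,
    "dcn-min": None,  # handled in make_fixture
}


def make_fixture(name: str, seed: int = 0):
    """Return a ready-to-run configuration for a named protocol.

    ``"dcn-min"`` returns ``(circuit, network, schedule)`` for a small
    three-channel DNA neuron compiled to its reaction network, instead of an
    :class:`ExperimentConfig`.
    """
    if name == "dcn-min":
        from .dsd import build_dcn, compile_to_crn, dcn_input_schedule

        circuit = build_dcn(3, 1)
        net = compile_to_crn(circuit)
        task = TaskSpec(N=3, frequencies=(0.0001, 0.0001, 0.0002),
                        horizon=100000.0, seed=seed)
        schedule = dcn_input_schedule(circuit, task)
        return circuit, net, schedule
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return factory(seed)
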