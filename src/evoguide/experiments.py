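"""Experiment orchestration: single-step and guided (step-wise) evolution.

A :class:`Schedule` is an ordered list of stages, each naming an environment
gate, an epoch budget, an advance criterion (fitness threshold reached, or a
fixed number of epochs) and a population source — continue from the previous
stage, start from founders, or mix two previously completed stages 50/50
(optionally with horizontal gene transfer enabled during the stage).

Replicates are seeded deterministically from the master seed so that a whole
experiment grid is reproducible bit for bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import environment as env_mod
from .cell_model import CellParams
from .environment import EnvironmentSpec, environment_trace
from .evolution import HGTConfig, MutationConfig, Population, mix_populations, run_epoch
from .fitness_rate import FitnessTrajectory, summarize_replicates

__all__ = [
    "Stage",
    "Schedule",
    "ExperimentConfig",
    "StageResult",
    "RunRecord",
    "run_schedule",
    "run_grid",
    "desk_profile",
    "paper_profile",
]


@dataclass(frozen=True)
class Stage:
    """One leg of a guided-evolution path."""

    gate: str
    budget_epochs: int
    threshold: float | None = 0.75   # advance when population-mean w reaches it
    fixed_epochs: int | None = None  # alternative: advance after n epochs
    source: object = "continue"      # "continue" | "founders" | ("mix", i, j)
    hgt: bool = False

    def __post_init__(self) -> None:
        if self.gate not in env_mod.GATES:
            raise ValueError(f"unknown gate {self.gate!r}")
        if self.threshold is None and self.fixed_epochs is None:
            raise ValueError("stage needs a threshold or a fixed epoch count")
        if isinstance(self.source, (tuple, list)):
            tag = self.source[0]
            if tag != "mix" or len(self.source) != 3:
                raise ValueError("mix source must be ('mix', i, j)")


@dataclass(frozen=True)
class Schedule:
    """An ordered sequence of stages; stage 0 starts from founders."""

    stages: tuple
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValueError("a schedule needs at least one stage")
        for idx, st in enumerate(self.stages):
            if isinstance(st.source, (tuple, list)):
                _, i, j = st.source
                if not (0 <= i < idx and 0 <= j < idx):
                    raise ValueError("mix sources must reference completed stages")

    @classmethod
    def single(cls, gate: str, budget: int, threshold: float = 0.75,
               **kw) -> "Schedule":
        return cls(stages=(Stage(gate=gate, budget_epochs=budget,
                                 threshold=threshold, source="founders", **kw),),
                   name=f"un-evolved->{gate}")

    @classmethod
    def path(cls, gates, budgets, threshold: float = 0.75,
             hgt_last: bool = False) -> "Schedule":
        stages = []
        for i, (g, b) in enumerate(zip(gates, budgets)):
            stages.append(Stage(gate=g, budget_epochs=b, threshold=threshold,
                                source="founders" if i == 0 else "continue",
                                hgt=hgt_last and i == len(gates) - 1))
        return cls(stages=tuple(stages), name="->".join(gates))


@dataclass
class ExperimentConfig:
    """Everything an experiment needs besides the schedule itself."""

    population_size: int = 128
    replicates: int = 8
    master_seed: int = 0
    delay: int = env_mod.DEFAULT_DELAY
    cell_params: CellParams = field(default_factory=CellParams)
    mutation: MutationConfig = field(default_factory=MutationConfig)
    hgt: HGTConfig = field(default_factory=lambda: HGTConfig(enabled=True))
    threshold: float = 0.75

    def trace_for(self, gate: str):
        return environment_trace(EnvironmentSpec(gate=gate, delay=self.delay))


@dataclass
class StageResult:
    gate: str
    epochs_run: int
    time_to_threshold: int | None
    success: bool
    final_mean_w: float
    mean_w: np.ndarray  # per-epoch population mean fitness


@dataclass
class RunRecord:
    """Result of one replicate of one schedule."""

    schedule_name: str
    replicate: int
    master_seed: int
    stages: list
    elapsed_s: float = 0.0

    @property
    def trajectory(self) -> FitnessTrajectory:
        mean_w = np.concatenate([s.mean_w for s in self.stages])
        labels = sum(([s.gate] * len(s.mean_w) for s in self.stages), [])
        return FitnessTrajectory(mean_w=mean_w, environment=labels)

    @property
    def success(self) -> bool:
        return all(s.success for s in self.stages)

    @property
    def total_epochs(self) -> int | None:
        """Total epochs to traverse the path (last stage up to its
        threshold crossing); None if any stage failed."""
        if not self.success:
            return None
        total = 0
        for s in self.stages[:-1]:
            total += s.epochs_run
        last = self.stages[-1]
        total += (last.time_to_threshold + 1
                  if last.time_to_threshold is not None else last.epochs_run)
        return total

    def to_dict(self) -> dict:
        return {
            "schedule": self.schedule_name,
            "replicate": self.replicate,
            "master_seed": self.master_seed,
            "success": bool(self.success),
            "total_epochs": self.total_epochs,
            "stages": [
                {
                    "gate": s.gate,
                    "epochs_run": s.epochs_run,
                    "time_to_threshold": s.time_to_threshold,
                    "success": bool(s.success),
                    "final_mean_w": float(s.final_mean_w),
                }
                for s in self.stages
            ],
        }


def _stage_seed(master: int, replicate: int, stage: int, epoch: int) -> int:
    ss = np.random.SeedSequence([master, replicate, stage, epoch])
    return int(ss.generate_state(1)[0] % (2**31))


def _run_stage(pop: Population, stage: Stage, cfg: ExperimentConfig,
               replicate: int, stage_idx: int) -> StageResult:
    trace = cfg.trace_for(stage.gate)
    hgt = cfg.hgt if stage.hgt else HGTConfig(enabled=False)
    hgt_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.master_seed, replicate, stage_idx, 7**5]))
    means = []
    t_hit = None
    for ep in range(stage.budget_epochs):
        seed = _stage_seed(cfg.master_seed, replicate, stage_idx, ep)
        f = run_epoch(pop, trace, cfg.mutation, seed, hgt=hgt, hgt_rng=hgt_rng)
        m = float(np.nanmean(f)) if np.any(np.isfinite(f)) else 0.0
        means.append(m)
        if stage.threshold is not None and t_hit is None and m >= stage.threshold:
            t_hit = ep
            if stage.fixed_epochs is None:
                break
        if stage.fixed_epochs is not None and ep + 1 >= stage.fixed_epochs:
            break
    mean_w = np.asarray(means)
    success = (t_hit is not None) if stage.threshold is not None else True
    return StageResult(gate=stage.gate, epochs_run=len(mean_w),
                       time_to_threshold=t_hit, success=success,
                       final_mean_w=float(mean_w[-1]) if len(mean_w) else 0.0,
                       mean_w=mean_w)


def run_schedule(cfg: ExperimentConfig, schedule: Schedule,
                 replicate: int = 0) -> RunRecord:
    """Execute one replicate of a schedule and return its RunRecord.

    Populations are carried over unchanged across ``continue`` transitions
    (the fitness discontinuity at an environment switch is expected);
    ``mix`` stages draw 50/50 from two completed stages' final populations.
    """
    t_start = time.time()
    results: list[StageResult] = []
    finals: list[Population] = []
    pop: Population | None = None
    for idx, stage in enumerate(schedule.stages):
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.master_seed, replicate, idx, 11]))
        if stage.source == "founders" or (stage.source == "continue" and pop is None):
            pop = Population.founders(cfg.population_size, rng, cfg.cell_params)
        elif stage.source == "continue":
            pass  # carry the evolved population over unchanged
        else:
            _, i, j = stage.source
            pop = mix_populations(finals[i], finals[j], rng)
        res = _run_stage(pop, stage, cfg, replicate, idx)
        results.append(res)
        finals.append(pop.copy())
        if not res.success and idx + 1 < len(schedule.stages):
            # budget exhausted: remaining stages are recorded as failures
            for later in schedule.stages[idx + 1:]:
                results.append(StageResult(gate=later.gate, epochs_run=0,
                                           time_to_threshold=None,
                                           success=False, final_mean_w=0.0,
                                           mean_w=np.zeros(0)))
            break
    return RunRecord(schedule_name=schedule.name, replicate=replicate,
                     master_seed=cfg.master_seed, stages=results,
                     elapsed_s=time.time() - t_start)


def run_grid(cfg: ExperimentConfig, schedules) -> tuple[pd.DataFrame, list]:
    """Run every schedule for every replicate; returns (summary, records).

    The summary has one row per schedule: mean epochs among successful
    replicates (``"> budget"`` when none succeeded), success counts, and the
    average total path time of complete traversals.
    """
    schedules = list(schedules)
    if not schedules:
        raise ValueError("need at least one schedule")
    records = []
    rows = []
    for sched in schedules:
        recs = [run_schedule(cfg, sched, r) for r in range(cfg.replicates)]
        records.extend(recs)
        budget = sched.stages[-1].budget_epochs
        last_stage = sched.stages[-1]
        # for threshold stages, "time" is the first crossing; for
        # fixed-epoch stages, the (fixed) number of epochs run
        last_times = []
        for r in recs:
            s = r.stages[-1]
            if not s.success:
                last_times.append(None)
            elif last_stage.threshold is not None:
                last_times.append(s.time_to_threshold)
            else:
                last_times.append(s.epochs_run)
        mean_t, n_succ, n_tot = summarize_replicates(last_times, budget)
        totals = [r.total_epochs for r in recs if r.total_epochs is not None]
        rows.append({
            "schedule": sched.name,
            "final_gate": sched.stages[-1].gate,
            "mean_epochs": mean_t,
            "median_epochs": (float(np.median([t for t in last_times
                                               if t is not None]))
                              if n_succ else f"> {budget}"),
            "success": f"{n_succ}/{n_tot}",
            "success_rate": n_succ / n_tot,
            "mean_total_epochs": float(np.mean(totals)) if totals else None,
        })
    return pd.DataFrame(rows), records


def desk_profile(master_seed: int = 0, **overrides) -> ExperimentConfig:
    """Desk-scale profile: small population and budget, minutes per run."""
    kw = dict(population_size=128, replicates=8, master_seed=master_seed)
    kw.update(overrides)
    return ExperimentConfig(**kw)


def paper_profile(master_seed: int = 0, **overrides) -> ExperimentConfig:
    """Full-scale profile (1024 cells, 64 replicates, ~10^7 time units).

    Cluster-scale: a single run takes hours on one CPU.
    """
    kw = dict(population_size=1024, replicates=64, master_seed=master_seed)
    kw.update(overrides)
    return ExperimentConfig(**kw)


def save_records(records, path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in records], fh, indent=1)
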