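"""Pre-packaged desk-scale evolution studies.

These are the standard experiments the package ships with: direct evolution
of founder populations in each single environment, guided (step-wise)
evolution into XOR via OR, and complementary A/B pre-evolution mixed with
and without horizontal gene transfer.  The same protocol backs the test
suite and the reproduction script, so the numbers they report come from one
implementation.

Desk-scale defaults (128 cells, budgets of a few hundred epochs, a couple
of replicates) are sized for minutes of runtime on one CPU; threshold
crossings in the harder environments are routinely censored at the budget
at this scale (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .experiments import ExperimentConfig, Schedule, Stage, run_grid

__all__ = [
    "DESK_GATES",
    "censored_median",
    "direct_study",
    "guided_or_study",
    "mix_study",
    "run_desk_study",
]

DESK_GATES = ("AND", "OR", "A", "XOR")


def censored_median(times, budget: int) -> float:
    """Median adaptation time with unfinished runs counted as budget + 1."""
    vals = [budget + 1 if t is None else t for t in times]
    return float(np.median(vals))


def _config(population_size, replicates, master_seed, threshold):
    return ExperimentConfig(population_size=population_size,
                            replicates=replicates, master_seed=master_seed,
                            threshold=threshold)


def direct_study(gates=DESK_GATES, population_size=128, replicates=2,
                 budget=500, master_seed=0, threshold=0.75):
    """Un-evolved founders → each environment; per-replicate outcomes.

    Returns ``{gate: {"times": [...], "final_w": [...], "mean_w": 2-D}}``
    where ``times`` holds the first epoch the population mean reached the
    threshold (None if censored at the budget).
    """
    cfg = _config(population_size, replicates, master_seed, threshold)
    out = {}
    for gate in gates:
        sched = Schedule.single(gate, budget, threshold=threshold)
        _, records = run_grid(cfg, [sched])
        out[gate] = {
            "times": [r.stages[0].time_to_threshold for r in records],
            "final_w": [r.stages[0].final_mean_w for r in records],
            "trajectories": [r.stages[0].mean_w for r in records],
        }
    return out


def guided_or_study(population_size=128, replicates=2, pre_epochs=60,
                    budget=500, master_seed=0, threshold=0.75):
    """OR pre-evolution (fixed epochs) followed by evolution in XOR.

    Returns per-replicate XOR-stage threshold-crossing times and total path
    epochs (pre-evolution included; None when censored).
    """
    cfg = _config(population_size, replicates, master_seed, threshold)
    sched = Schedule(stages=(
        Stage(gate="OR", budget_epochs=pre_epochs, threshold=None,
              fixed_epochs=pre_epochs, source="founders"),
        Stage(gate="XOR", budget_epochs=budget, threshold=threshold),
    ), name="OR->XOR")
    _, records = run_grid(cfg, [sched])
    return {
        "xor_stage_times": [r.stages[1].time_to_threshold for r in records],
        "total_epochs": [r.total_epochs for r in records],
        "final_w": [r.stages[1].final_mean_w for r in records],
    }


def mix_study(population_size=128, replicates=2, pre_epochs=60, budget=100,
              master_seed=0, threshold=0.75, p_transfer=0.05):
    """A- and B-evolved populations mixed 50/50 into XOR, ± HGT.

    Returns per-arm XOR-stage crossing times and attained fitness.
    """
    from .evolution import HGTConfig

    out = {}
    for label, hgt_on in (("hgt", True), ("no_hgt", False)):
        cfg = _config(population_size, replicates, master_seed, threshold)
        cfg.hgt = HGTConfig(enabled=True, p_transfer=p_transfer)
        sched = Schedule(stages=(
            Stage(gate="A", budget_epochs=pre_epochs, threshold=None,
                  fixed_epochs=pre_epochs, source="founders"),
            Stage(gate="B", budget_epochs=pre_epochs, threshold=None,
                  fixed_epochs=pre_epochs, source="founders"),
            Stage(gate="XOR", budget_epochs=budget, threshold=threshold,
                  source=("mix", 0, 1), hgt=hgt_on),
        ), name=f"A&B->XOR ({label})")
        _, records = run_grid(cfg, [sched])
        out[label] = {
            "xor_stage_times": [r.stages[2].time_to_threshold for r in records],
            "final_w": [r.stages[2].final_mean_w for r in records],
        }
    return out


def run_desk_study(master_seed=0, population_size=128, replicates=2,
                   budget=500, threshold=0.75):
    """The full desk-scale study: direct envs + guided paths."""
    direct = direct_study(population_size=population_size,
                          replicates=replicates, budget=budget,
                          master_seed=master_seed, threshold=threshold)
    guided = guided_or_study(population_size=population_size,
                             replicates=replicates, budget=budget,
                             master_seed=master_seed, threshold=threshold)
    mixes = mix_study(population_size=population_size,
                      replicates=replicates, master_seed=master_seed,
                      threshold=threshold)
    return {"direct": direct, "guided_or": guided, "mix": mixes,
            "budget": budget, "replicates": replicates,
            "population_size": population_size,
            "guided_pre_epochs": 60, "mix_budget": 100}
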