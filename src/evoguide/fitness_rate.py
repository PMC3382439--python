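"""Fitness, adaptation-time and evolutionary-rate statistics.

A cell's fitness over one epoch is the Pearson correlation between its
response-protein expression trace and the nutrient-presence trace; it is a
reporting proxy only and never feeds back into selection.  Population
trajectories of the per-epoch mean fitness w are summarised by the first
epoch at which w reaches a threshold (adaptation speed) and, for averaged
trajectories, by the time constant τ of the exponential fit

    w(t) = A0 − α · exp(−t / τ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FitnessTrajectory",
    "ExponentialFit",
    "epoch_fitness",
    "time_to_threshold",
    "fit_exponential",
    "summarize_replicates",
]


@dataclass
class FitnessTrajectory:
    """Per-epoch population-average fitness with environment labels."""

    mean_w: np.ndarray
    environment: list = field(default_factory=list)
    sd_w: np.ndarray | None = None
    frac_above: np.ndarray | None = None  # fraction of cells with w > 0.75

    def __len__(self) -> int:
        return len(self.mean_w)


@dataclass(frozen=True)
class ExponentialFit:
    """Parameters of w(t) = A0 − α·exp(−t/τ)."""

    a0: float
    alpha: float
    tau: float
    rss: float


def epoch_fitness(response_trace, nutrient_trace, return_flag: bool = False):
    """Pearson correlation between response expression and nutrient presence.

    Defined as 0.0 when either trace has zero variance (an all-silent cell
    has no tracking behaviour, not undefined behaviour); set
    ``return_flag=True`` to also receive that degeneracy flag.
    """
    r = np.asarray(response_trace, dtype=float)
    n = np.asarray(nutrient_trace, dtype=float)
    if r.shape != n.shape or r.ndim != 1:
        raise ValueError("response and nutrient traces must be 1-D and equally long")
    degenerate = r.std() == 0 or n.std() == 0
    value = 0.0 if degenerate else float(np.corrcoef(r, n)[0, 1])
    if return_flag:
        return value, degenerate
    return value


def time_to_threshold(traj, threshold: float):
    """First epoch index with population-average w ≥ threshold, else None.

    Later dips below the threshold do not change the result: adaptation
    speed is the *first* crossing.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    w = np.asarray(getattr(traj, "mean_w", traj), dtype=float)
    hits = np.nonzero(w >= threshold)[0]
    return int(hits[0]) if hits.size else None


def _exp_model(params, t):
    a0, alpha, log_tau = params
    return a0 - alpha * np.exp(-t / math.exp(log_tau))


def fit_exponential(mean_w, n_starts: int = 8) -> ExponentialFit:
    """Nonlinear least-squares fit of w(t) = A0 − α·exp(−t/τ).

    τ is optimised on a log scale to keep it positive, with multiple
    initialisations spread over plausible time constants; the best-RSS
    solution is returned.  Raises on constant trajectories (unidentifiable)
    and if no start converges.
    """
    w = np.asarray(getattr(mean_w, "mean_w", mean_w), dtype=float)
    if w.ndim != 1 or len(w) < 10:
        raise ValueError("need a 1-D trajectory of at least 10 epochs")
    if np.ptp(w) == 0:
        raise ValueError("constant trajectory: exponential rate is unidentifiable")
    t = np.arange(len(w), dtype=float)

    best = None
    taus = np.geomspace(max(len(w) / 50, 1.0), len(w) * 2.0, n_starts)
    a0_guess = float(w[-max(1, len(w) // 10):].mean())
    alpha_guess = a0_guess - float(w[0])
    if alpha_guess == 0:
        alpha_guess = float(np.ptp(w))
    for tau0 in taus:
        x0 = np.array([a0_guess, alpha_guess, math.log(tau0)])
        try:
            res = least_squares(
                lambda p: _exp_model(p, t) - w, x0, method="lm", max_nfev=2000
            )
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(res.fun @ res.fun)
        if best is None or rss < best[1]:
            best = (res.x, rss)
    if best is None:
        raise RuntimeError(
            "exponential fit failed to converge from any initialisation "
            f"(tried τ starts {taus.round(2).tolist()})"
        )
    (a0, alpha, log_tau), rss = best
    return ExponentialFit(a0=float(a0), alpha=float(alpha), tau=math.exp(log_tau), rss=rss)


def summarize_replicates(times, budget: int):
    """Summarise replicate adaptation times.

    ``times`` holds one ``time_to_threshold`` result per replicate (int or
    None).  A replicate succeeds if it reached the threshold within
    ``budget`` epochs.  Returns ``(mean_epochs, n_success, n_total)`` where
    ``mean_epochs`` is the mean over successful replicates only, or the
    string ``"> {budget}"`` if no replicate succeeded.
    """
    times = list(times)
    if not times:
        raise ValueError("need at least one replicate")
    successes = [t for t in times if t is not None and t <= budget]
    n_total = len(times)
    if not successes:
        return f"> {budget}", 0, n_total
    return float(np.mean(successes)), len(successes), n_total
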