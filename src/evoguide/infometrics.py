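"""Information-theoretic environmental-complexity metrics.

All metrics operate on the plug-in (maximum-likelihood) joint distribution of
the binary triple ``(s1, s2, n)`` sampled per time step from an environment
trace.  The nutrient variable may be realigned with its causes by shifting it
back by the environment delay before pairing (``N_shifted``); metrics are
reported both for the raw nutrient ``N`` and for ``N_shifted``.

The headline complexity measure is the interaction information

    I(S1; S2; N) = I(S1; S2) - I(S1; S2 | N)

which is negative for synergistic relationships (XOR being the canonical
example), so environments are ranked by its magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import EnvironmentTrace

__all__ = [
    "JointDistribution",
    "empirical_joint",
    "entropy",
    "mutual_information",
    "conditional_mi",
    "multivariate_mi",
    "marginal",
    "kl_divergence",
    "metric_rate_regression",
    "complexity_report",
]

_VARS = {"s1": 0, "s2": 1, "n": 2}


@dataclass(frozen=True)
class JointDistribution:
    """Plug-in distribution over the 8 outcomes of ``(s1, s2, n)``.

    ``shift`` records the lag applied to the nutrient sequence before
    pairing: ``0`` pairs ``n[t]`` with the signals at ``t``; ``-delay``
    pairs ``n[t + delay]`` (i.e. shifts the nutrient *back*, recovering the
    undelayed gate output ``N_shifted``).
    """

    probs: np.ndarray  # shape (2, 2, 2)
    sample_count: int
    shift: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (2, 2, 2):
            raise ValueError("probs must have shape (2, 2, 2)")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


def empirical_joint(trace: EnvironmentTrace, shift: int = 0) -> JointDistribution:
    """Estimate the joint distribution of ``(s1[t], s2[t], n[t - shift])``.

    With ``shift = -delay`` the nutrient is shifted back by the delay, so the
    signals at time ``t`` are paired with the gate output they caused.  Only
    time steps where both ends of the pairing are defined contribute, so
    ``sample_count = epoch_length - |shift|``.
    """
    n_steps = trace.epoch_length
    if abs(shift) >= n_steps:
        raise ValueError("|shift| must be smaller than the epoch length")
    s1 = np.asarray(trace.s1, dtype=np.intp)
    s2 = np.asarray(trace.s2, dtype=np.intp)
    nut = np.asarray(trace.nutrient, dtype=np.intp)
    if shift <= 0:
        # pair signals at t with nutrient at t + |shift|
        lag = -shift
        s1p, s2p, np_ = s1[: n_steps - lag], s2[: n_steps - lag], nut[lag:]
    else:
        s1p, s2p, np_ = s1[shift:], s2[shift:], nut[: n_steps - shift]
    counts = np.zeros((2, 2, 2), dtype=float)
    np.add.at(counts, (s1p, s2p, np_), 1.0)
    total = counts.sum()
    return JointDistribution(probs=counts / total, sample_count=int(total), shift=shift)


def _axes_for(variables) -> tuple[int, ...]:
    if isinstance(variables, str):
        variables = (variables,)
    axes = []
    for v in variables:
        if v not in _VARS:
            raise ValueError(f"unknown variable {v!r}; expected subset of {set(_VARS)}")
        axes.append(_VARS[v])
    if not axes:
        raise ValueError("variable set must be non-empty")
    if len(set(axes)) != len(axes):
        raise ValueError("duplicate variables")
    return tuple(sorted(axes))


def _marginal_array(dist: JointDistribution, variables) -> np.ndarray:
    keep = _axes_for(variables)
    drop = tuple(ax for ax in range(3) if ax not in keep)
    return dist.probs.sum(axis=drop) if drop else dist.probs


def _plogp_entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def marginal(dist: JointDistribution, variable: str) -> np.ndarray:
    """Binary marginal distribution ``[P(v=0), P(v=1)]`` of one variable."""
    return _marginal_array(dist, variable)


def entropy(dist: JointDistribution, variables) -> float:
    """Shannon entropy (bits) of the marginal over ``variables``; 0·log 0 = 0."""
    return _plogp_entropy(_marginal_array(dist, variables).ravel())


def mutual_information(dist: JointDistribution, x: str, y: str) -> float:
    """Plug-in mutual information I(X; Y) in bits."""
    return entropy(dist, x) + entropy(dist, y) - entropy(dist, (x, y))


def conditional_mi(dist: JointDistribution, x: str, y: str, given: str) -> float:
    """Conditional mutual information I(X; Y | Z) in bits (non-negative)."""
    z = given
    value = (
        entropy(dist, (x, z))
        + entropy(dist, (y, z))
        - entropy(dist, (x, y, z))
        - entropy(dist, z)
    )
    # plug-in CMI is mathematically >= 0; clamp float dust
    return max(value, 0.0) if value > -1e-12 else value


def multivariate_mi(dist: JointDistribution) -> float:
    """Interaction information I(S1; S2; N) = I(S1;S2) − I(S1;S2|N), in bits.

    Negative values indicate synergy: the nutrient is informative about the
    signal pair jointly but not about either signal alone (e.g. XOR).
    """
    return mutual_information(dist, "s1", "s2") - conditional_mi(
        dist, "s1", "s2", given="n"
    )


def kl_divergence(p, q) -> float:
    """Kullback–Leibler divergence D(p || q) in bits for binary marginals.

    Raises if ``q`` assigns zero mass where ``p`` does not (the divergence
    would be infinite); this is surfaced rather than silently returned.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same shape")
    if abs(p.sum() - 1) > 1e-9 or abs(q.sum() - 1) > 1e-9:
        raise ValueError("p and q must be probability distributions")
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("q must give nonzero mass wherever p does (D would be infinite)")
    return float((p[mask] * np.log2(p[mask] / q[mask])).sum())


def metric_rate_regression(metric_values, rates) -> float:
    """Adjusted R² of a simple OLS regression of evolutionary rate on a metric.

    ``rates`` are the per-environment time constants τ; ``metric_values`` the
    corresponding complexity-metric values.  Requires at least 3 environments
    and a non-constant metric.  Adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2) and
    may be negative for uninformative metrics.
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(rates, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("metric values and rates must be 1-D and equally long")
    n = len(x)
    if n < 3:
        raise ValueError("regression needs at least 3 environments")
    if np.ptp(x) == 0:
        raise ValueError("metric is constant across environments; R² undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    beta = (xc @ yc) / (xc @ xc)
    resid = yc - beta * xc
    ss_tot = float(yc @ yc)
    if ss_tot == 0:
        r2 = 1.0
    else:
        r2 = 1.0 - float(resid @ resid) / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def complexity_report(traces: dict[str, EnvironmentTrace]):
    """Per-environment complexity metrics as a pandas DataFrame.

    Rows are environments; columns: interaction information with the
    back-shifted nutrient (``mi_s1_s2_nshift``) and with the raw nutrient
    (``mi_s1_s2_n``), conditional MI ``I(S1;S2|N_shifted)``, joint entropy
    ``H(S1,S2,N_shifted)``, the mean signal–nutrient Pearson correlation and
    the mean K-L divergence between each signal's marginal and the nutrient
    marginal.
    """
    import pandas as pd

    rows = {}
    for name, trace in traces.items():
        d_shift = empirical_joint(trace, shift=-trace.delay)
        d_raw = empirical_joint(trace, shift=0)
        s1 = np.asarray(trace.s1, float)
        s2 = np.asarray(trace.s2, float)
        lag = trace.delay
        nsh = np.asarray(trace.nutrient, float)[lag:]
        c1 = _safe_corr(s1[: len(nsh)], nsh)
        c2 = _safe_corr(s2[: len(nsh)], nsh)
        kl1 = kl_divergence(marginal(d_shift, "s1"), marginal(d_shift, "n"))
        kl2 = kl_divergence(marginal(d_shift, "s2"), marginal(d_shift, "n"))
        rows[name] = {
            "mi_s1_s2_nshift": multivariate_mi(d_shift),
            "cmi_s1_s2_given_nshift": conditional_mi(d_shift, "s1", "s2", given="n"),
            "joint_entropy_nshift": entropy(d_shift, ("s1", "s2", "n")),
            "mi_s1_s2_n": multivariate_mi(d_raw),
            "mean_signal_nutrient_corr": 0.5 * (c1 + c2),
            "mean_kl_signal_nutrient": 0.5 * (kl1 + kl2),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
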