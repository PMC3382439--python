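"""Numba kernels for the population dynamics.

The population lives in packed per-cell arrays so that one compiled call
advances every cell through a whole epoch.  Node layout within a cell:
index 0 and 1 are the read-only sensor nodes for s1 and s2; triplet ``i``
occupies indices ``2+3i`` (gene/mRNA), ``3+3i`` (protein) and ``4+3i``
(modified protein).  Triplet 0 is the metabolic triplet T0 and node 3 is
the response protein RP0.

All stochasticity inside a kernel call is driven by ``np.random`` seeded at
entry, so a (state, seed) pair fully determines the outcome.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# -- physics/energy parameter vector indices ---------------------------------
P_AMPLITUDE = 0     # sensor molecule count when its signal is high
P_INNER_K = 1       # half-saturation of the per-regulator inner sigmoid
P_OUTER_K = 2       # steepness of the outer logistic on summed regulation
P_PMAX = 3          # maximum per-step production probability
P_CAP = 4           # molecule-count cap per node
P_RP_THRESH = 5     # RP0 count needed for nutrient metabolism
P_COST_PROD = 6     # energy cost per molecule produced
P_COST_DEG = 7      # energy cost per molecule degraded
P_MAINT = 8         # energy cost per non-sensor node per step
P_GAIN = 9          # energy gained per step of successful metabolism
P_DIV_THRESH = 10   # energy level triggering division (inclusive)
P_EPS = 11          # epsilon in 1/(energy+eps) replacement weights
P_SUB_K = 12        # half-saturation of the substrate availability factor
P_COST_EXPR = 13    # energy cost per step while the metabolic pathway runs
P_UPTAKE_CAP = 14   # max energy harvestable per epoch (uptake saturation)
P_FIT_SMOOTH = 15   # time constant (steps) of the expression-level smoother
N_PARAMS = 16

# -- mutation parameter vector indices ---------------------------------------
M_RATE = 0          # P(rate/weight perturbation) per division
M_ADD = 1           # P(edge addition) per division
M_DEL = 2           # P(edge deletion) per division
M_DUP = 3           # P(triplet duplication) per division
M_DELTRIP = 4       # P(triplet deletion) per division
M_SCALE = 5         # s.d. of additive weight noise / log-scale rate noise
N_MPARAMS = 6

BASAL_MIN = 1e-4
DEG_MIN = 1e-4
DEG_MAX = 0.5


@njit(cache=False)
def _mutate_cell(n_trip, counts, basal, degr, n_edges, esrc, edst, ew, c,
                 mparams, pmax):
    """Apply the per-division mutation operators to cell ``c`` in place.

    Each operator fires independently with its configured probability.
    T0 is never deleted; node and edge caps are enforced by skipping
    operations that would exceed them.
    """
    maxn = counts.shape[1]
    maxe = esrc.shape[1]
    maxtrip = (maxn - 2) // 3
    scale = mparams[M_SCALE]

    # rate / weight perturbation (includes transcription-rate changes);
    # perturbations are heavy-tailed: mostly fine adjustments, occasionally
    # large jumps (lets evolution both refine and restructure kinetics)
    if np.random.random() < mparams[M_RATE]:
        s = scale if np.random.random() < 0.75 else 3.0 * scale
        if np.random.random() < 0.5 and n_edges[c] > 0:
            e = np.random.randint(n_edges[c])
            ew[c, e] += np.random.normal(0.0, 2.0 * s)
        else:
            j = 2 + np.random.randint(3 * n_trip[c])
            factor = np.exp(np.random.normal(0.0, s))
            if np.random.random() < 0.5:
                b = basal[c, j] * factor
                if b < BASAL_MIN:
                    b = BASAL_MIN
                if b > pmax * 0.999:
                    b = pmax * 0.999
                basal[c, j] = b
            else:
                d = degr[c, j] * factor
                if d < DEG_MIN:
                    d = DEG_MIN
                if d > DEG_MAX:
                    d = DEG_MAX
                degr[c, j] = d

    # edge addition: source is a sensor, protein or modified protein;
    # target any non-sensor node — except that sensors may not regulate the
    # metabolic triplet T0 directly (the metabolic operon responds only to
    # transcription-factor proteins); parallel edges are not created
    if np.random.random() < mparams[M_ADD] and n_edges[c] < maxe:
        n_src = 2 + 2 * n_trip[c]
        k = np.random.randint(n_src)
        if k < 2:
            src = k
        else:
            k -= 2
            src = 2 + 3 * (k // 2) + 1 + (k % 2)
        dst = 2 + np.random.randint(3 * n_trip[c])
        exists = src < 2 and dst < 5  # forbidden sensor->T0 regulation
        for e in range(n_edges[c]):
            if esrc[c, e] == src and edst[c, e] == dst:
                exists = True
                break
        if not exists:
            e = n_edges[c]
            esrc[c, e] = src
            edst[c, e] = dst
            ew[c, e] = np.random.normal(0.0, 3.0)
            n_edges[c] = e + 1

    # edge deletion
    if np.random.random() < mparams[M_DEL] and n_edges[c] > 0:
        e = np.random.randint(n_edges[c])
        last = n_edges[c] - 1
        esrc[c, e] = esrc[c, last]
        edst[c, e] = edst[c, last]
        ew[c, e] = ew[c, last]
        n_edges[c] = last

    # triplet duplication: copies the three nodes and every incident edge
    if np.random.random() < mparams[M_DUP] and n_trip[c] < maxtrip:
        k = np.random.randint(n_trip[c])
        ob = 2 + 3 * k
        nb = 2 + 3 * n_trip[c]
        for off in range(3):
            counts[c, nb + off] = counts[c, ob + off]
            basal[c, nb + off] = basal[c, ob + off]
            degr[c, nb + off] = degr[c, ob + off]
        ne0 = n_edges[c]
        for e in range(ne0):
            s = esrc[c, e]
            d = edst[c, e]
            s_in = ob <= s < ob + 3
            d_in = ob <= d < ob + 3
            if (s_in or d_in) and n_edges[c] < maxe:
                ns = s + (nb - ob) if s_in else s
                nd = d + (nb - ob) if d_in else d
                enew = n_edges[c]
                esrc[c, enew] = ns
                edst[c, enew] = nd
                ew[c, enew] = ew[c, e]
                n_edges[c] = enew + 1
        n_trip[c] += 1

    # triplet deletion: any triplet except the metabolic triplet T0
    if np.random.random() < mparams[M_DELTRIP] and n_trip[c] > 1:
        k = 1 + np.random.randint(n_trip[c] - 1)
        base = 2 + 3 * k
        w = 0
        for e in range(n_edges[c]):
            s = esrc[c, e]
            d = edst[c, e]
            if (base <= s < base + 3) or (base <= d < base + 3):
                continue
            if s >= base + 3:
                s -= 3
            if d >= base + 3:
                d -= 3
            esrc[c, w] = s
            edst[c, w] = d
            ew[c, w] = ew[c, e]
            w += 1
        n_edges[c] = w
        top = 2 + 3 * (n_trip[c] - 1)
        for j in range(base, top):
            counts[c, j] = counts[c, j + 3]
            basal[c, j] = basal[c, j + 3]
            degr[c, j] = degr[c, j + 3]
        n_trip[c] -= 1


@njit(cache=False, fastmath=True, inline="always")
def _binomial_small(n, p):
    """Binomial sample by CDF inversion; fast for n·p of order 1."""
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    u = np.random.random()
    q = 1.0 - p
    pk = np.exp(n * np.log1p(-p))    # P(0) = q**n
    if u < pk:
        return 0
    r = p / q
    acc = pk
    k = 0
    while k < n:
        pk *= r * (n - k) / (k + 1)
        acc += pk
        k += 1
        if u < acc:
            return k
    return n


@njit(cache=False)
def _copy_cell(n_trip, counts, basal, degr, n_edges, esrc, edst, ew,
               lineage, src, dst):
    maxn = counts.shape[1]
    maxe = esrc.shape[1]
    n_trip[dst] = n_trip[src]
    n_edges[dst] = n_edges[src]
    for j in range(maxn):
        counts[dst, j] = counts[src, j]
        basal[dst, j] = basal[src, j]
        degr[dst, j] = degr[src, j]
    for e in range(maxe):
        esrc[dst, e] = esrc[src, e]
        edst[dst, e] = edst[src, e]
        ew[dst, e] = ew[src, e]
    lineage[dst] = lineage[src]


@njit(cache=False)
def _choose_victim(energy, parent, eps):
    """Weighted draw over all cells except the parent, weight 1/(energy+eps)."""
    nc = energy.shape[0]
    total = 0.0
    for i in range(nc):
        if i != parent:
            total += 1.0 / (energy[i] + eps)
    r = np.random.random() * total
    acc = 0.0
    victim = -1
    for i in range(nc):
        if i == parent:
            continue
        acc += 1.0 / (energy[i] + eps)
        if r <= acc:
            victim = i
            break
    if victim == -1:  # float round-off fallback
        for i in range(nc - 1, -1, -1):
            if i != parent:
                victim = i
                break
    return victim


@njit(cache=False, fastmath=True)
def run_epoch(n_trip, counts, basal, degr, n_edges, esrc, edst, ew,
              energy, lineage, version,
              s1, s2, nut, params, mparams, seed,
              process_divisions,
              sum_r, sum_r2, sum_rn, div_counts,
              record_rp, rp_trace, uptake, reset_uptake, birth_step,
              continuous_mparams):
    """Advance every cell through ``len(s1)`` time steps, in place.

    Accumulates per-cell response-protein statistics (sum, sum of squares,
    sum over nutrient-present steps) for fitness computation, and the number
    of divisions per cell slot.  Division replaces a victim drawn with
    probability proportional to 1/(energy+eps); progeny are mutated copies
    carrying half the parent's energy.
    """
    np.random.seed(seed)
    nc = energy.shape[0]
    n_steps = s1.shape[0]

    amplitude = params[P_AMPLITUDE]
    inner_k = params[P_INNER_K]
    outer_k = params[P_OUTER_K]
    pmax = params[P_PMAX]
    cap = int(params[P_CAP])
    rp_thresh = params[P_RP_THRESH]
    cost_prod = params[P_COST_PROD]
    cost_deg = params[P_COST_DEG]
    maint = params[P_MAINT]
    gain = params[P_GAIN]
    div_thresh = params[P_DIV_THRESH]
    eps = params[P_EPS]
    sub_k = params[P_SUB_K]
    cost_expr = params[P_COST_EXPR]
    uptake_cap = params[P_UPTAKE_CAP]
    tau_fit = params[P_FIT_SMOOTH]
    beta = np.exp(-1.0 / tau_fit) if tau_fit > 0 else 0.0
    ema = np.zeros(nc)

    maxn = counts.shape[1]
    reg = np.zeros(maxn)
    dividers = np.empty(nc, dtype=np.int64)
    div_version = np.empty(nc, dtype=np.int64)
    if reset_uptake:
        for c in range(nc):
            uptake[c] = 0.0

    # lookup tables for the saturation functions on integer counts
    tab_max = cap if cap > int(amplitude) else int(amplitude)
    inner_tab = np.empty(tab_max + 1)
    sub_tab = np.empty(tab_max + 1)
    for i in range(tab_max + 1):
        inner_tab[i] = i / (inner_k + i)
        sub_tab[i] = i / (sub_k + i)

    for t in range(n_steps):
        ia1 = int(amplitude) if s1[t] > 0 else 0
        ia2 = int(amplitude) if s2[t] > 0 else 0
        nut_t = nut[t] > 0
        for c in range(nc):
            counts[c, 0] = ia1
            counts[c, 1] = ia2
            nn = 2 + 3 * n_trip[c]
            for j in range(2, nn):
                reg[j] = 0.0
            for e in range(n_edges[c]):
                reg[edst[c, e]] += ew[c, e] * inner_tab[counts[c, esrc[c, e]]]
            en = energy[c]
            for j in range(2, nn):
                role = (j - 2) % 3
                if role == 0:
                    fsub = 1.0
                else:
                    fsub = sub_tab[counts[c, j - 1]]
                # production must be paid for: starved cells cannot express
                if fsub > 0.0 and en >= cost_prod:
                    b = basal[c, j]
                    r = reg[j]
                    if r == 0.0:
                        p = b * fsub
                    else:
                        p = pmax * fsub / (1.0 + ((pmax - b) / b) * np.exp(-outer_k * r))
                    if np.random.random() < p and counts[c, j] < cap:
                        counts[c, j] += 1
                        en -= cost_prod
                cj = counts[c, j]
                if cj > 0:
                    dg = _binomial_small(cj, degr[c, j])
                    if dg > 0:
                        counts[c, j] -= dg
                        en -= cost_deg * dg
            en -= maint * (nn - 2)
            rp = counts[c, 3]
            if rp >= rp_thresh and en >= cost_expr:
                # the metabolic pathway is running: pay its per-step cost,
                # and harvest energy if nutrient is present, up to the
                # per-epoch uptake saturation
                en -= cost_expr
                if nut_t and uptake[c] < uptake_cap:
                    en += gain
                    uptake[c] += gain
            if en < 0.0:
                en = 0.0
            energy[c] = en
            # fitness statistics use the smoothed expression level
            fr = beta * ema[c] + (1.0 - beta) * float(rp)
            ema[c] = fr
            sum_r[c] += fr
            sum_r2[c] += fr * fr
            if nut_t:
                sum_rn[c] += fr
            if record_rp:
                rp_trace[t, c] = rp
            if continuous_mparams.shape[0] == N_MPARAMS:
                # continuous mutation mode: operators fire at any time
                # point, on the cell itself (per-step probabilities)
                _mutate_cell(n_trip, counts, basal, degr, n_edges,
                             esrc, edst, ew, c, continuous_mparams, pmax)

        if process_divisions:
            nd = 0
            for c in range(nc):
                if energy[c] >= div_thresh:
                    dividers[nd] = c
                    div_version[nd] = version[c]
                    nd += 1
            if nd > 0:
                # process in random order (Fisher–Yates)
                for i in range(nd - 1, 0, -1):
                    j = np.random.randint(i + 1)
                    tmp = dividers[i]
                    dividers[i] = dividers[j]
                    dividers[j] = tmp
                    tmpv = div_version[i]
                    div_version[i] = div_version[j]
                    div_version[j] = tmpv
                for i in range(nd):
                    p = dividers[i]
                    if version[p] != div_version[i]:
                        continue  # overwritten by an earlier division
                    if energy[p] < div_thresh:
                        continue
                    half = energy[p] * 0.5
                    energy[p] = half
                    victim = _choose_victim(energy, p, eps)
                    _copy_cell(n_trip, counts, basal, degr, n_edges,
                               esrc, edst, ew, lineage, p, victim)
                    energy[victim] = half
                    uptake[victim] = uptake[p]
                    version[victim] += 1
                    # the slot now holds a new individual: its fitness
                    # statistics start from the next time step
                    birth_step[victim] = t + 1
                    sum_r[victim] = 0.0
                    sum_r2[victim] = 0.0
                    sum_rn[victim] = 0.0
                    ema[victim] = 0.0
                    _mutate_cell(n_trip, counts, basal, degr, n_edges,
                                 esrc, edst, ew, victim, mparams, pmax)
                    div_counts[p] += 1


@njit(cache=False)
def mutate_one(n_trip, counts, basal, degr, n_edges, esrc, edst, ew,
               mparams, pmax, seed):
    """Seeded single-cell mutation entry point (cell index 0)."""
    np.random.seed(seed)
    _mutate_cell(n_trip, counts, basal, degr, n_edges, esrc, edst, ew, 0,
                 mparams, pmax)


@njit(cache=False)
def mutate_at(n_trip, counts, basal, degr, n_edges, esrc, edst, ew, c,
              mparams, pmax, seed):
    """Seeded mutation of cell ``c`` within full population arrays."""
    np.random.seed(seed)
    _mutate_cell(n_trip, counts, basal, degr, n_edges, esrc, edst, ew, c,
                 mparams, pmax)


@njit(cache=False)
def choose_victim_seeded(energy, parent, eps, seed):
    np.random.seed(seed)
    return _choose_victim(energy, parent, eps)
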