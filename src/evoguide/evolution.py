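"""Population dynamics: selection, mutation and horizontal gene transfer.

The population has a fixed size; when a cell's energy reaches the division
threshold it divides, and the progeny — a mutated copy carrying half the
parent's energy — replaces a victim drawn with probability proportional to
``1/(energy + eps)``.  Mutations are applied to progeny at division.  HGT,
when enabled, fires at epoch boundaries and copies one donor triplet with
its incident edges into a recipient of a (possibly) different lineage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine, cell_model
from ._engine import (
    M_ADD,
    M_DEL,
    M_DELTRIP,
    M_DUP,
    M_RATE,
    M_SCALE,
    N_MPARAMS,
)  # noqa: F401 (mutation indices are part of the engine interface)
from .cell_model import CellNetwork, CellParams, pack_cells, unpack_cells

__all__ = [
    "MutationConfig",
    "HGTConfig",
    "Population",
    "mutate",
    "sample_victim",
    "replace_on_division",
    "hgt_step",
    "step_population",
    "run_epoch",
    "mix_populations",
]


@dataclass(frozen=True)
class MutationConfig:
    """Per-division mutation probabilities and the perturbation scale."""

    p_rate_perturbation: float = 0.3   # edge weight / basal / degradation tweak
    p_edge_addition: float = 0.04
    p_edge_deletion: float = 0.06      # deletion-biased, mirroring microbial
    p_triplet_duplication: float = 0.004   # deletion bias (genomes stay lean)
    p_triplet_deletion: float = 0.008
    weight_noise_scale: float = 0.25
    #: if False, operators fire continuously (per step, probabilities are
    #: spread over the epoch) instead of on progeny at division
    at_division: bool = True

    def __post_init__(self) -> None:
        for name in ("p_rate_perturbation", "p_edge_addition", "p_edge_deletion",
                     "p_triplet_duplication", "p_triplet_deletion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")

    def to_array(self) -> np.ndarray:
        m = np.zeros(N_MPARAMS)
        m[M_RATE] = self.p_rate_perturbation
        m[M_ADD] = self.p_edge_addition
        m[M_DEL] = self.p_edge_deletion
        m[M_DUP] = self.p_triplet_duplication
        m[M_DELTRIP] = self.p_triplet_deletion
        m[M_SCALE] = self.weight_noise_scale
        return m

    @classmethod
    def zero(cls) -> "MutationConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    _NO_CONTINUOUS = np.zeros(1)

    def kernel_arrays(self, n_steps: int):
        """(division mparams, continuous mparams) for an engine call."""
        if self.at_division:
            return self.to_array(), self._NO_CONTINUOUS
        return np.zeros(N_MPARAMS), self.to_array() / max(n_steps, 1)


@dataclass(frozen=True)
class HGTConfig:
    """Horizontal gene transfer settings (applied at epoch boundaries)."""

    enabled: bool = False
    p_transfer: float = 0.05  # per-cell per-epoch probability of receiving

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_transfer <= 1.0:
            raise ValueError("p_transfer must be a probability")


class Population:
    """Fixed-size collection of cells stored in packed engine arrays."""

    def __init__(self, packed, params: CellParams):
        self._p = packed
        self.params = params

    # -- construction -------------------------------------------------------
    @classmethod
    def from_cells(cls, cells, params: CellParams | None = None) -> "Population":
        params = params or CellParams()
        if len(cells) < 2:
            raise ValueError("a population needs at least 2 cells")
        packed = pack_cells(cells, params)
        packed.lineage[:] = np.arange(len(cells))
        for i, c in enumerate(cells):
            if c.lineage:
                packed.lineage[i] = c.lineage
        return cls(packed, params)

    @classmethod
    def founders(cls, size: int, rng: np.random.Generator,
                 params: CellParams | None = None,
                 screen: bool = True, **cell_kw) -> "Population":
        """A founder population of random cells with distinct lineage ids.

        Founders are screened for viability in rich medium (candidates are
        simulated in one batch under constant nutrient and kept only if they
        gain energy — the in-silico analogue of pre-culturing), so founder
        populations are always alive, if untuned, in any environment.
        """
        params = params or CellParams()
        if not screen:
            cells = [cell_model.random_cell(rng, params, screen=False,
                                            **cell_kw) for _ in range(size)]
            return cls.from_cells(cells, params)
        kept: list = []
        n_steps = 1200
        zeros = np.zeros(n_steps, dtype=np.int8)
        ones = np.ones(n_steps, dtype=np.int8)
        for _ in range(30):  # batches of candidates until enough survive
            batch = [cell_model.random_cell(rng, params, screen=False,
                                            **cell_kw)
                     for _ in range(max(2 * size, 16))]
            for c in batch:
                c.energy = 10_000.0
            probe = cls.from_cells(batch, params)
            sr = np.zeros(probe.size)
            _engine.run_epoch(
                probe._p.n_trip, probe._p.counts, probe._p.basal,
                probe._p.degr, probe._p.n_edges, probe._p.esrc,
                probe._p.edst, probe._p.ew, probe._p.energy,
                probe._p.lineage, probe._p.version,
                zeros, zeros, ones, params.to_array(),
                MutationConfig.zero().to_array(), _seed_from(rng),
                False, sr, sr.copy(), sr.copy(),
                np.zeros(probe.size, dtype=np.int64),
                False, np.zeros((1, 1), dtype=np.int64),
                probe._p.uptake, True, np.zeros(probe.size, dtype=np.int64),
                MutationConfig._NO_CONTINUOUS,
            )
            for i in np.nonzero(probe._p.energy > 10_000.0)[0]:
                kept.append(batch[int(i)])
                if len(kept) >= size:
                    break
            if len(kept) >= size:
                break
        while len(kept) < size:  # pathological parameters: fill unscreened
            kept.append(cell_model.random_cell(rng, params, screen=False,
                                               **cell_kw))
        for c in kept:
            c.energy = params.initial_energy
        return cls.from_cells(kept[:size], params)

    @property
    def size(self) -> int:
        return len(self._p.energy)

    @property
    def energies(self) -> np.ndarray:
        return self._p.energy

    @property
    def lineages(self) -> np.ndarray:
        return self._p.lineage

    def to_cells(self):
        return unpack_cells(self._p)

    def cell(self, i: int) -> CellNetwork:
        return unpack_cells(self._sub(i))[0]

    def _sub(self, i: int):
        sub = cell_model._Packed(1, self.params.max_triplets, self.params.max_edges)
        _copy_into(self._p, i, sub, 0)
        return sub

    def copy(self) -> "Population":
        new = cell_model._Packed(self.size, self.params.max_triplets,
                                 self.params.max_edges)
        for name in new.__slots__:
            getattr(new, name)[:] = getattr(self._p, name)
        return Population(new, self.params)

    def reset_uptake(self) -> None:
        """Zero the per-epoch nutrient-uptake counters (epoch boundary)."""
        self._p.uptake[:] = 0.0

    def save_snapshot(self, directory, fitness=None) -> None:
        """Write per-cell JSON networks plus a TSV manifest to a directory."""
        from pathlib import Path

        path = Path(directory)
        path.mkdir(parents=True, exist_ok=True)
        cells = self.to_cells()
        with open(path / "manifest.tsv", "w") as fh:
            fh.write("cell_id\tlineage\tenergy\tfitness\tn_triplets\tn_edges\n")
            for i, c in enumerate(cells):
                (path / f"cell_{i:04d}.json").write_text(c.to_json(indent=1))
                w = "" if fitness is None else f"{float(fitness[i]):.4f}"
                fh.write(f"{i}\t{c.lineage}\t{c.energy:.3f}\t{w}\t"
                         f"{len(c.triplets)}\t{len(c.edges)}\n")

    def genotype_fingerprint(self) -> bytes:
        """Hashable digest of all genotype arrays (counts/energy excluded)."""
        import hashlib

        h = hashlib.sha256()
        p = self._p
        for a in (p.n_trip, p.basal, p.degr, p.n_edges, p.esrc, p.edst, p.ew):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.digest()


def _copy_into(src_packed, i, dst_packed, j) -> None:
    for name in ("n_trip", "counts", "basal", "degr", "n_edges",
                 "esrc", "edst", "ew", "energy", "lineage", "version"):
        getattr(dst_packed, name)[j] = getattr(src_packed, name)[i]


def _seed_from(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def mutate(cell: CellNetwork, config: MutationConfig,
           rng: np.random.Generator,
           params: CellParams | None = None) -> CellNetwork:
    """Apply the per-division mutation operators to a copy of ``cell``.

    Runs the same compiled mutation routine as the population kernel.
    """
    params = params or CellParams()
    packed = pack_cells([cell], params)
    _engine.mutate_one(packed.n_trip, packed.counts, packed.basal, packed.degr,
                       packed.n_edges, packed.esrc, packed.edst, packed.ew,
                       config.to_array(), params.p_max, _seed_from(rng))
    return unpack_cells(packed)[0]


def sample_victim(energies, parent_index: int, eps: float,
                  rng: np.random.Generator) -> int:
    """Draw the cell to be replaced: weight 1/(energy+eps), parent excluded."""
    e = np.asarray(energies, dtype=float)
    if not 0 <= parent_index < len(e):
        raise IndexError("parent index out of range")
    w = 1.0 / (e + eps)
    w[parent_index] = 0.0
    return int(rng.choice(len(e), p=w / w.sum()))


def replace_on_division(pop: Population, parent_index: int,
                        config: MutationConfig,
                        rng: np.random.Generator) -> int:
    """Divide cell ``parent_index``: progeny replaces a weighted victim.

    The parent must be ready to divide.  Parent and progeny each get half
    the parent's energy; the progeny is mutated.  Returns the victim index.
    """
    p = pop._p
    if p.energy[parent_index] < pop.params.division_threshold:
        raise ValueError("parent is not ready to divide")
    half = p.energy[parent_index] * 0.5
    p.energy[parent_index] = half
    victim = sample_victim(p.energy, parent_index, pop.params.replacement_eps, rng)
    _copy_into(p, parent_index, p, victim)
    p.energy[victim] = half
    p.version[victim] += 1
    _engine.mutate_at(p.n_trip, p.counts, p.basal, p.degr,
                      p.n_edges, p.esrc, p.edst, p.ew, victim,
                      config.to_array(), pop.params.p_max, _seed_from(rng))
    return victim


def hgt_step(pop: Population, config: HGTConfig,
             rng: np.random.Generator) -> int:
    """One round of horizontal gene transfer; returns the number of transfers.

    Each cell independently receives, with probability ``p_transfer``, one
    randomly chosen triplet (plus incident edges) from a random donor cell.
    Edges whose other endpoint is neither a sensor nor inside the transferred
    triplet are dropped; recipients at the triplet cap are skipped.
    """
    if not config.enabled:
        return 0
    p = pop._p
    nc = pop.size
    maxtrip = pop.params.max_triplets
    maxe = pop.params.max_edges
    n_transfers = 0
    receivers = np.nonzero(rng.random(nc) < config.p_transfer)[0]
    for r in receivers:
        if p.n_trip[r] >= maxtrip:
            continue
        donor = int(rng.integers(nc - 1))
        if donor >= r:
            donor += 1
        k = int(rng.integers(p.n_trip[donor]))
        ob = 2 + 3 * k
        nb = 2 + 3 * int(p.n_trip[r])
        for off in range(3):
            p.counts[r, nb + off] = p.counts[donor, ob + off]
            p.basal[r, nb + off] = p.basal[donor, ob + off]
            p.degr[r, nb + off] = p.degr[donor, ob + off]
        for e in range(int(p.n_edges[donor])):
            s = int(p.esrc[donor, e])
            d = int(p.edst[donor, e])
            s_in = ob <= s < ob + 3
            d_in = ob <= d < ob + 3
            if not (s_in or d_in):
                continue
            # the other endpoint must exist in the recipient: sensors and
            # the metabolic triplet T0 (nodes 0..4) are universal — present
            # in every cell — so edges to them transfer; edges touching any
            # other donor node are dropped
            if not s_in and s >= 5:
                continue
            if not d_in and d >= 5:
                continue
            if p.n_edges[r] >= maxe:
                break
            ns = s + (nb - ob) if s_in else s
            nd = d + (nb - ob) if d_in else d
            enew = int(p.n_edges[r])
            p.esrc[r, enew] = ns
            p.edst[r, enew] = nd
            p.ew[r, enew] = p.ew[donor, e]
            p.n_edges[r] = enew + 1
        p.n_trip[r] += 1
        p.version[r] += 1
        n_transfers += 1
    return n_transfers


def step_population(pop: Population, s1_t: int, s2_t: int, nutrient_t: int,
                    mutation: MutationConfig, rng: np.random.Generator) -> None:
    """Advance the whole population one time step, processing divisions.

    The per-epoch uptake counters are left running; callers advancing an
    epoch step by step should reset them at epoch boundaries via
    ``pop.reset_uptake()``.
    """
    _run_trace(pop, np.array([s1_t], np.int8), np.array([s2_t], np.int8),
               np.array([nutrient_t], np.int8), mutation, _seed_from(rng),
               reset_uptake=False)


def run_epoch(pop: Population, trace, mutation: MutationConfig, seed: int,
              hgt: HGTConfig | None = None,
              hgt_rng: np.random.Generator | None = None) -> np.ndarray:
    """Run one epoch in place and return the per-cell fitness array.

    Fitness is the Pearson correlation between each cell's RP0 count trace
    and the nutrient trace over the epoch (0 for constant traces).  If an
    HGT config is given and enabled, one transfer round fires at the end of
    the epoch.
    """
    sr, sr2, srn, _, birth = _run_trace(pop, trace.s1, trace.s2,
                                        trace.nutrient, mutation, seed)
    nut = np.asarray(trace.nutrient, dtype=float)
    # cells born mid-epoch (replacement) are scored over their own lifetime;
    # cells alive for less than half the epoch are not scored this epoch
    # (NaN) — they are measured over their first full(er) epoch instead
    cum = np.concatenate([[0.0], np.cumsum(nut)])
    n = len(nut) - birth
    sn = cum[-1] - cum[birth]
    fitness = np.zeros(pop.size)
    cov = srn - sr * sn / np.maximum(n, 1)
    var_r = sr2 - sr * sr / np.maximum(n, 1)
    var_n = sn - sn * sn / np.maximum(n, 1)
    ok = (var_r > 0) & (var_n > 0) & (n > 1)
    fitness[ok] = cov[ok] / np.sqrt(var_r[ok] * var_n[ok])
    fitness[n < len(nut) // 2] = np.nan
    if hgt is not None and hgt.enabled:
        if hgt_rng is None:
            hgt_rng = np.random.default_rng(seed ^ 0x5DEECE66D % (2**31))
        hgt_step(pop, hgt, hgt_rng)
    return fitness


def _run_trace(pop: Population, s1, s2, nut, mutation: MutationConfig,
               seed: int, reset_uptake: bool = True):
    p = pop._p
    nc = pop.size
    sr = np.zeros(nc)
    sr2 = np.zeros(nc)
    srn = np.zeros(nc)
    div_counts = np.zeros(nc, dtype=np.int64)
    birth = np.zeros(nc, dtype=np.int64)
    div_m, cont_m = mutation.kernel_arrays(len(s1))
    _engine.run_epoch(
        p.n_trip, p.counts, p.basal, p.degr, p.n_edges, p.esrc, p.edst, p.ew,
        p.energy, p.lineage, p.version,
        np.asarray(s1, np.int8), np.asarray(s2, np.int8),
        np.asarray(nut, np.int8),
        pop.params.to_array(), div_m, int(seed) % (2**31),
        True, sr, sr2, srn, div_counts,
        False, np.zeros((1, 1), dtype=np.int64),
        p.uptake, reset_uptake, birth, cont_m,
    )
    return sr, sr2, srn, div_counts, birth


def mix_populations(pop_a: Population, pop_b: Population,
                    rng: np.random.Generator) -> Population:
    """50/50 mix of two equally sized populations, size preserved.

    Samples half of the slots from each source population without
    replacement; lineage ids are carried over unchanged.
    """
    if pop_a.size != pop_b.size:
        raise ValueError("populations must have equal size to be mixed")
    if pop_a.params != pop_b.params:
        raise ValueError("populations must share cell parameters")
    n = pop_a.size
    take_a = rng.choice(n, size=n // 2, replace=False)
    take_b = rng.choice(n, size=n - n // 2, replace=False)
    mixed = cell_model._Packed(n, pop_a.params.max_triplets, pop_a.params.max_edges)
    j = 0
    for i in take_a:
        _copy_into(pop_a._p, int(i), mixed, j)
        j += 1
    for i in take_b:
        _copy_into(pop_b._p, int(i), mixed, j)
        j += 1
    return Population(mixed, pop_a.params)
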