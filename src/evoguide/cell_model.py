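"""Single-cell gene regulatory / biochemical network model.

Each cell's genome is a set of *triplets* — gene/mRNA, protein and modified
protein nodes capturing transcription, translation and post-translational
modification — wired by weighted signed regulatory edges.  Two read-only
sensor nodes expose the environmental signals s1 and s2 as molecule counts;
they can act as regulators but are never regulated.  Triplet 0 is the
metabolic triplet T0; its protein node RP0 is the response protein whose
expression (count at or above a threshold) is required for nutrient uptake.

Per time step, each node creates at most one molecule with probability given
by a two-level sigmoid — an inner per-regulator saturation ``c/(K + c)`` on
the regulator's molecule count, summed with signed weights, then an outer
logistic on the total regulation calibrated so that zero regulation yields
the node's basal rate — scaled by the availability of the substrate molecule
(the upstream node in the triplet chain).  Each existing molecule then
degrades independently with the node's degradation probability.  Production,
degradation and node maintenance all cost energy; metabolising nutrient
(RP0 expressed while nutrient is present) earns energy; a cell divides once
its energy reaches a threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _engine
from ._engine import (
    N_MPARAMS,
    N_PARAMS,
    P_AMPLITUDE,
    P_CAP,
    P_COST_DEG,
    P_COST_PROD,
    P_DIV_THRESH,
    P_EPS,
    P_GAIN,
    P_INNER_K,
    P_MAINT,
    P_OUTER_K,
    P_PMAX,
    P_RP_THRESH,
    P_SUB_K,
    P_COST_EXPR,
    P_UPTAKE_CAP,
    P_FIT_SMOOTH,
)

__all__ = [
    "Triplet",
    "RegulatoryEdge",
    "CellNetwork",
    "CellParams",
    "SENSOR_IDS",
    "node_id",
    "node_index",
    "regulatory_input",
    "production_probability",
    "step_cell",
    "ready_to_divide",
    "random_cell",
    "constitutive_cell",
    "gate_cell",
]

SENSOR_IDS = ("S1", "S2")
_ROLE_LETTER = ("G", "P", "M")


@dataclass
class Triplet:
    """One gene/mRNA → protein → modified-protein unit.

    ``counts``, ``basal`` and ``degradation`` are ordered (gene, protein,
    modified protein).  Basal rates are per-step creation probabilities at
    zero regulation; degradation rates are per-molecule per-step.
    """

    counts: tuple = (0, 0, 0)
    basal: tuple = (0.03, 0.03, 0.03)
    degradation: tuple = (0.01, 0.01, 0.01)


@dataclass
class RegulatoryEdge:
    """Signed weighted regulation; positive = activation, negative = inhibition."""

    source: str
    target: str
    weight: float


@dataclass
class CellNetwork:
    """A cell's genome plus its physiological state (molecule counts, energy)."""

    triplets: list = field(default_factory=lambda: [Triplet()])
    edges: list = field(default_factory=list)
    energy: float = 0.0
    lineage: int = 0

    def __post_init__(self) -> None:
        if len(self.triplets) < 1:
            raise ValueError("a cell always contains the metabolic triplet T0")
        n = len(self.triplets)
        for e in self.edges:
            node_index(e.source, n)  # validates
            tgt = node_index(e.target, n)
            if tgt < 2:
                raise ValueError(f"sensor {e.target} cannot be a regulation target")

    @property
    def n_nodes(self) -> int:
        """Non-sensor node count."""
        return 3 * len(self.triplets)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "triplets": [asdict(t) for t in self.triplets],
            "edges": [asdict(e) for e in self.edges],
            "energy": self.energy,
            "lineage": self.lineage,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellNetwork":
        return cls(
            triplets=[Triplet(tuple(t["counts"]), tuple(t["basal"]),
                              tuple(t["degradation"]))
                      for t in d["triplets"]],
            edges=[RegulatoryEdge(e["source"], e["target"], float(e["weight"]))
                   for e in d["edges"]],
            energy=float(d.get("energy", 0.0)),
            lineage=int(d.get("lineage", 0)),
        )

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, s: str) -> "CellNetwork":
        return cls.from_dict(json.loads(s))

    def to_graph(self):
        """networkx DiGraph of sensors, nodes and weighted edges."""
        import networkx as nx

        g = nx.DiGraph()
        for s in SENSOR_IDS:
            g.add_node(s, kind="sensor")
        for i, t in enumerate(self.triplets):
            for r, letter in enumerate(_ROLE_LETTER):
                g.add_node(
                    f"{letter}{i}",
                    kind=("gene", "protein", "modified_protein")[r],
                    triplet=i,
                    count=int(t.counts[r]),
                    basal=float(t.basal[r]),
                    degradation=float(t.degradation[r]),
                )
        for e in self.edges:
            g.add_edge(e.source, e.target, weight=float(e.weight))
        return g

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_graph(), path)


def node_id(index: int) -> str:
    """Packed node index → symbolic id (S1, S2, G0, P0, M0, G1, ...)."""
    if index < 0:
        raise ValueError("negative node index")
    if index < 2:
        return SENSOR_IDS[index]
    trip, role = divmod(index - 2, 3)
    return f"{_ROLE_LETTER[role]}{trip}"


def node_index(ident: str, n_triplets: int | None = None) -> int:
    """Symbolic node id → packed index; validates against the triplet count."""
    if ident in SENSOR_IDS:
        return SENSOR_IDS.index(ident)
    letter, num = ident[0], ident[1:]
    if letter not in _ROLE_LETTER or not num.isdigit():
        raise ValueError(f"malformed node id {ident!r}")
    trip = int(num)
    if n_triplets is not None and trip >= n_triplets:
        raise ValueError(f"node {ident!r} refers to a missing triplet")
    return 2 + 3 * trip + _ROLE_LETTER.index(letter)


@dataclass(frozen=True)
class CellParams:
    """Kinetic and energy parameters shared by every cell.

    Defaults are calibrated so that a network expressing RP0 only while
    nutrient is present out-competes a constitutive expresser (the selective
    gradient that makes gate logic evolvable), see the package methods note.
    """

    sensor_amplitude: float = 50.0   # sensor molecule count when signal high
    inner_k: float = 10.0            # regulator half-saturation (molecules)
    outer_steepness: float = 2.0     # outer logistic steepness
    p_max: float = 0.5               # max creation probability per step
    count_cap: int = 60              # molecule cap per node
    rp_threshold: float = 10.0       # RP0 count required for metabolism
    cost_production: float = 0.1     # energy per molecule created
    cost_degradation: float = 0.0    # energy per molecule degraded
    cost_expression: float = 0.3     # energy per step while RP0 is expressed
    maintenance: float = 0.005       # energy per non-sensor node per step
    metabolism_gain: float = 4.0     # energy per step of nutrient uptake
    uptake_cap: float = 2000.0       # per-epoch uptake saturation
    division_threshold: float = 2000.0
    initial_energy: float = 2000.0
    replacement_eps: float = 0.01    # epsilon in 1/(energy+eps) weights
    substrate_k: float = 5.0         # substrate half-saturation (molecules)
    fitness_smoothing: float = 50.0  # expression-level smoother τ (steps)
    max_triplets: int = 8
    max_edges: int = 48

    def to_array(self) -> np.ndarray:
        p = np.zeros(N_PARAMS)
        p[P_AMPLITUDE] = self.sensor_amplitude
        p[P_INNER_K] = self.inner_k
        p[P_OUTER_K] = self.outer_steepness
        p[P_PMAX] = self.p_max
        p[P_CAP] = self.count_cap
        p[P_RP_THRESH] = self.rp_threshold
        p[P_COST_PROD] = self.cost_production
        p[P_COST_DEG] = self.cost_degradation
        p[P_MAINT] = self.maintenance
        p[P_GAIN] = self.metabolism_gain
        p[P_DIV_THRESH] = self.division_threshold
        p[P_EPS] = self.replacement_eps
        p[P_SUB_K] = self.substrate_k
        p[P_COST_EXPR] = self.cost_expression
        p[P_UPTAKE_CAP] = self.uptake_cap
        p[P_FIT_SMOOTH] = self.fitness_smoothing
        return p


def regulatory_input(cell: CellNetwork, target: str,
                     s1: float = 0.0, s2: float = 0.0,
                     params: CellParams | None = None) -> float:
    """Total signed regulation arriving at ``target``.

    Sum over incoming edges of weight × inner-sigmoid of the source node's
    molecule count, where the inner sigmoid is ``c / (K + c)``.  Sensor
    counts are ``amplitude × signal level``.
    """
    params = params or CellParams()
    n = len(cell.triplets)
    node_index(target, n)

    def count_of(ident: str) -> float:
        if ident == "S1":
            return params.sensor_amplitude * s1
        if ident == "S2":
            return params.sensor_amplitude * s2
        idx = node_index(ident, n) - 2
        trip, role = divmod(idx, 3)
        return float(cell.triplets[trip].counts[role])

    total = 0.0
    for e in cell.edges:
        if e.target == target:
            c = count_of(e.source)
            total += e.weight * c / (params.inner_k + c)
    return total


def production_probability(regulation: float, basal: float,
                           substrate_count: float | None = None,
                           params: CellParams | None = None) -> float:
    """Per-step molecule creation probability.

    Outer logistic on total regulation, calibrated so that zero regulation
    gives the basal rate and strong activation saturates at ``p_max``,
    multiplied by a substrate-availability factor ``c/(K_s + c)`` (1 for
    gene nodes, whose substrate — the DNA template — is always present;
    exactly 0 when the substrate is absent).
    """
    params = params or CellParams()
    pmax = params.p_max
    b = min(max(basal, _engine.BASAL_MIN), pmax * 0.999)
    if substrate_count is None:
        fsub = 1.0
    elif substrate_count <= 0:
        return 0.0
    else:
        fsub = substrate_count / (params.substrate_k + substrate_count)
    return pmax * fsub / (1.0 + ((pmax - b) / b) * math.exp(-params.outer_steepness * regulation))


def ready_to_divide(cell: CellNetwork, params: CellParams | None = None) -> bool:
    """True iff the cell's energy has reached the division threshold (inclusive)."""
    params = params or CellParams()
    return cell.energy >= params.division_threshold


# -- packing to/from engine arrays ------------------------------------------

class _Packed:
    """Packed array views of one or more cells (see _engine for layout)."""

    __slots__ = ("n_trip", "counts", "basal", "degr", "n_edges",
                 "esrc", "edst", "ew", "energy", "lineage", "version",
                 "uptake")

    def __init__(self, ncells: int, max_triplets: int, max_edges: int):
        maxn = 2 + 3 * max_triplets
        self.n_trip = np.zeros(ncells, dtype=np.int64)
        self.counts = np.zeros((ncells, maxn), dtype=np.int64)
        self.basal = np.full((ncells, maxn), _engine.BASAL_MIN)
        self.degr = np.full((ncells, maxn), _engine.DEG_MIN)
        self.n_edges = np.zeros(ncells, dtype=np.int64)
        self.esrc = np.zeros((ncells, max_edges), dtype=np.int64)
        self.edst = np.zeros((ncells, max_edges), dtype=np.int64)
        self.ew = np.zeros((ncells, max_edges))
        self.energy = np.zeros(ncells)
        self.lineage = np.zeros(ncells, dtype=np.int64)
        self.version = np.zeros(ncells, dtype=np.int64)
        self.uptake = np.zeros(ncells)


def pack_cells(cells, params: CellParams) -> _Packed:
    packed = _Packed(len(cells), params.max_triplets, params.max_edges)
    for c, cell in enumerate(cells):
        nt = len(cell.triplets)
        if nt > params.max_triplets:
            raise ValueError(f"cell has {nt} triplets; cap is {params.max_triplets}")
        if len(cell.edges) > params.max_edges:
            raise ValueError("cell exceeds the edge cap")
        packed.n_trip[c] = nt
        for i, t in enumerate(cell.triplets):
            for r in range(3):
                j = 2 + 3 * i + r
                packed.counts[c, j] = int(t.counts[r])
                packed.basal[c, j] = float(t.basal[r])
                packed.degr[c, j] = float(t.degradation[r])
        packed.n_edges[c] = len(cell.edges)
        for e, edge in enumerate(cell.edges):
            packed.esrc[c, e] = node_index(edge.source, nt)
            packed.edst[c, e] = node_index(edge.target, nt)
            packed.ew[c, e] = float(edge.weight)
        packed.energy[c] = float(cell.energy)
        packed.lineage[c] = int(cell.lineage)
    return packed


def unpack_cells(packed: _Packed) -> list:
    cells = []
    for c in range(len(packed.energy)):
        nt = int(packed.n_trip[c])
        triplets = []
        for i in range(nt):
            j = 2 + 3 * i
            triplets.append(Triplet(
                counts=tuple(int(packed.counts[c, j + r]) for r in range(3)),
                basal=tuple(float(packed.basal[c, j + r]) for r in range(3)),
                degradation=tuple(float(packed.degr[c, j + r]) for r in range(3)),
            ))
        edges = [
            RegulatoryEdge(node_id(int(packed.esrc[c, e])),
                           node_id(int(packed.edst[c, e])),
                           float(packed.ew[c, e]))
            for e in range(int(packed.n_edges[c]))
        ]
        cells.append(CellNetwork(triplets=triplets, edges=edges,
                                 energy=float(packed.energy[c]),
                                 lineage=int(packed.lineage[c])))
    return cells


def _seed_from(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def step_cell(cell: CellNetwork, s1_t: int, s2_t: int, nutrient_t: int,
              rng: np.random.Generator,
              params: CellParams | None = None) -> CellNetwork:
    """Advance one cell by one time step; returns the updated cell.

    Runs the same compiled kernel as the population simulation on a
    single-cell state (division and mutation are population-level events
    and are not processed here).
    """
    params = params or CellParams()
    packed = pack_cells([cell], params)
    zeros = np.zeros(1)
    _engine.run_epoch(
        packed.n_trip, packed.counts, packed.basal, packed.degr,
        packed.n_edges, packed.esrc, packed.edst, packed.ew,
        packed.energy, packed.lineage, packed.version,
        np.array([s1_t], dtype=np.int8), np.array([s2_t], dtype=np.int8),
        np.array([nutrient_t], dtype=np.int8),
        params.to_array(), np.zeros(N_MPARAMS), _seed_from(rng),
        False, zeros.copy(), zeros.copy(), zeros.copy(),
        np.zeros(1, dtype=np.int64),
        False, np.zeros((1, 1), dtype=np.int64),
        packed.uptake, False, np.zeros(1, dtype=np.int64),
        np.zeros(1),
    )
    return unpack_cells(packed)[0]


def simulate_cell(cell: CellNetwork, s1, s2, nutrient,
                  rng: np.random.Generator,
                  params: CellParams | None = None,
                  record_rp: bool = False):
    """Run one cell (no division/mutation) over arbitrary signal traces.

    Returns ``(updated_cell, fitness)`` where fitness is the Pearson
    correlation of the RP0 count trace with the nutrient trace over the run
    (0 when either is constant).  With ``record_rp=True`` the per-step RP0
    count trace is returned as a third element (expression profile).
    """
    params = params or CellParams()
    packed = pack_cells([cell], params)
    sr = np.zeros(1)
    sr2 = np.zeros(1)
    srn = np.zeros(1)
    nut = np.asarray(nutrient, dtype=np.int8)
    n_steps = len(nut)
    rp_trace = np.zeros((n_steps if record_rp else 1, 1), dtype=np.int64)
    _engine.run_epoch(
        packed.n_trip, packed.counts, packed.basal, packed.degr,
        packed.n_edges, packed.esrc, packed.edst, packed.ew,
        packed.energy, packed.lineage, packed.version,
        np.asarray(s1, dtype=np.int8), np.asarray(s2, dtype=np.int8),
        nut, params.to_array(), np.zeros(N_MPARAMS), _seed_from(rng),
        False, sr, sr2, srn, np.zeros(1, dtype=np.int64),
        record_rp, rp_trace,
        packed.uptake, True, np.zeros(1, dtype=np.int64),
        np.zeros(1),
    )
    fitness = _fitness_from_sums(sr[0], sr2[0], srn[0], nut)
    cell_out = unpack_cells(packed)[0]
    if record_rp:
        return cell_out, fitness, rp_trace[:, 0]
    return cell_out, fitness


def _fitness_from_sums(sr: float, sr2: float, srn: float, nutrient) -> float:
    n = len(nutrient)
    sn = float(np.sum(nutrient))
    cov = srn - sr * sn / n
    var_r = sr2 - sr * sr / n
    var_n = sn - sn * sn / n
    if var_r <= 0 or var_n <= 0:
        return 0.0
    return float(cov / math.sqrt(var_r * var_n))


# -- builders ----------------------------------------------------------------

def viable_in_rich_medium(cell: CellNetwork,
                          params: CellParams,
                          rng: np.random.Generator,
                          n_steps: int = 1200) -> bool:
    """Can this cell grow when nutrient is always present?

    Emulates pre-culturing founders in rich medium: a genotype that cannot
    express its response protein enough to feed even with nutrient constantly
    available never makes it into a founder population.
    """
    probe = CellNetwork.from_dict(cell.to_dict())
    probe.energy = 10_000.0
    zeros = np.zeros(n_steps, dtype=np.int8)
    ones = np.ones(n_steps, dtype=np.int8)
    out, _ = simulate_cell(probe, zeros, zeros, ones, rng, params)
    return out.energy > probe.energy


def random_cell(rng: np.random.Generator,
                params: CellParams | None = None,
                n_extra_triplets: int = 1,
                n_random_edges: int = 4,
                screen: bool = True,
                max_tries: int = 200) -> CellNetwork:
    """A random founder cell: T0 plus extra triplets and random wiring.

    By default candidates are screened for viability in rich medium (see
    :func:`viable_in_rich_medium`), mirroring the pre-culture step that
    precedes any evolution experiment; the returned genotype is still
    untuned for any *temporal* structure (epoch fitness near 0).
    """
    params = params or CellParams()
    if screen:
        for _ in range(max_tries):
            cand = random_cell(rng, params, n_extra_triplets, n_random_edges,
                               screen=False)
            if viable_in_rich_medium(cand, params, rng):
                return cand
        return cand  # extremely unlikely; fall back to the last draw

    def rand_triplet() -> Triplet:
        return Triplet(
            counts=(0, 0, 0),
            basal=(float(10 ** rng.uniform(-3.5, -0.6)),  # gene (log-uniform:
                   # spans leaky to sharply threshold-gated transcription)
                   float(rng.uniform(0.15, 0.45)),        # protein
                   float(rng.uniform(0.05, 0.45))),       # modified protein
            degradation=(float(rng.uniform(0.008, 0.05)),
                         float(rng.uniform(0.008, 0.05)),
                         # modified proteins span slow time scales: raw
                         # material for delay lines
                         float(10 ** rng.uniform(-2.7, -1.3))),
        )

    nt = 1 + n_extra_triplets
    triplets = [rand_triplet() for _ in range(nt)]
    sources = list(SENSOR_IDS) + [f"{l}{i}" for i in range(nt) for l in ("P", "M")]
    targets = [f"{l}{i}" for i in range(nt) for l in ("G", "P", "M")]
    # founders share a sensing scaffold with randomised parameters: the
    # sensors regulate the auxiliary triplet's gene, whose protein tracks
    # the signals quickly and whose modified protein is a slow store; both
    # feed back onto the metabolic gene.  Sensors never regulate the
    # metabolic triplet directly — the metabolic operon responds only to
    # transcription-factor proteins — so sensing logic lives in (HGT-
    # transferable) auxiliary triplets.  Signs, strengths and rates — hence
    # the logic and its timing — are left for evolution, and structural
    # mutations can still rewire the topology.
    edges = []
    if nt > 1:
        edges += [
            RegulatoryEdge("S1", "G1", float(rng.normal(1.5, 2.0))),
            RegulatoryEdge("S2", "G1", float(rng.normal(1.5, 2.0))),
            RegulatoryEdge("M1", "G0", float(rng.normal(2.5, 2.5))),
            RegulatoryEdge("P1", "G0", float(rng.normal(-1.0, 2.5))),
        ]
    seen = {(e.source, e.target) for e in edges}
    for _ in range(n_random_edges):
        s = sources[rng.integers(len(sources))]
        t = targets[rng.integers(len(targets))]
        if (s, t) in seen:
            continue
        if s in SENSOR_IDS and t in ("G0", "P0", "M0"):
            continue  # sensors do not regulate the metabolic triplet
        seen.add((s, t))
        edges.append(RegulatoryEdge(s, t, float(rng.normal(0.0, 1.5))))
    return CellNetwork(triplets=triplets, edges=edges,
                       energy=params.initial_energy)


def constitutive_cell(params: CellParams | None = None,
                      basal: float = 0.25) -> CellNetwork:
    """A cell expressing RP0 constitutively, ignoring both signals."""
    params = params or CellParams()
    t0 = Triplet(counts=(10, 10, 0), basal=(basal, 0.45, 0.001),
                 degradation=(0.02, 0.02, 0.02))
    return CellNetwork(triplets=[t0], edges=[],
                       energy=params.initial_energy)


def gate_cell(gate: str, params: CellParams | None = None) -> CellNetwork:
    """A hand-designed network that tracks the delayed gate output.

    The designs implement the signal-to-nutrient delay with a store/inhibitor
    pair inside one auxiliary triplet: the gene G1 computes the gate condition
    on the sensors (a low gene basal rate makes the outer logistic a sharp
    threshold), its protein P1 tracks the signal window quickly, and the
    modified protein M1 is a slow store that outlasts the window.  RP0 is
    activated by the store but repressed by the fast inhibitor, so it fires
    only *after* the signal window ends — approximately the 500-step delayed
    nutrient window.  XOR adds a second (AND-detector) triplet whose store
    represses RP0, cancelling the response to the both-signals window.
    """
    params = params or CellParams()
    bg = 1e-4  # gene basal: sharp threshold
    if gate in ("AND", "OR", "A", "B"):
        w1, w2, d_p1, d_m1, w_store, w_inh, d_p0, w_p = {
            "AND": (2.0, 2.0, 0.024, 0.0045, 7.6, -7.1, 0.016, 0.0),
            "OR": (5.9, 5.9, 0.038, 0.0051, 7.7, -6.3, 0.013, 1.2),
            "A": (5.0, -8.1, 0.05, 0.0042, 8.7, -11.2, 0.009, 0.0),
            "B": (-4.5, 3.5, 0.011, 0.0057, 10.3, -5.2, 0.010, 2.0),
        }[gate]
        t0 = Triplet(counts=(0, 0, 0), basal=(bg, 0.45, 0.001),
                     degradation=(0.05, d_p0, 0.02))
        t1 = Triplet(counts=(0, 0, 0), basal=(bg, 0.45, 0.45),
                     degradation=(0.05, d_p1, d_m1))
        edges = [
            RegulatoryEdge("S1", "G1", w1),
            RegulatoryEdge("S2", "G1", w2),
            RegulatoryEdge("M1", "G0", w_store),
            RegulatoryEdge("P1", "G0", w_inh),
        ]
        if w_p:
            edges.append(RegulatoryEdge("M1", "P0", w_p))
        return CellNetwork(triplets=[t0, t1], edges=edges,
                           energy=params.initial_energy)
    if gate == "XOR":
        t0 = Triplet(counts=(0, 0, 0), basal=(bg, 0.45, 0.001),
                     degradation=(0.05, 0.0084, 0.02))
        # OR-condition delay line
        t1 = Triplet(counts=(0, 0, 0), basal=(bg, 0.45, 0.45),
                     degradation=(0.05, 0.0243, 0.0063))
        # AND-detector delay line (represses the both-signals response)
        t2 = Triplet(counts=(0, 0, 0), basal=(bg, 0.45, 0.45),
                     degradation=(0.05, 0.0243, 0.0063))
        edges = [
            RegulatoryEdge("S1", "G1", 5.6),
            RegulatoryEdge("S2", "G1", 5.6),
            RegulatoryEdge("S1", "G2", 1.85),
            RegulatoryEdge("S2", "G2", 1.85),
            RegulatoryEdge("M1", "G0", 10.8),
            RegulatoryEdge("P1", "G0", -10.0),
            RegulatoryEdge("M2", "G0", -19.9),
            RegulatoryEdge("M1", "P0", 1.4),
            RegulatoryEdge("M2", "P0", -1.4),
        ]
        return CellNetwork(triplets=[t0, t1, t2], edges=edges,
                           energy=params.initial_energy)
    raise ValueError(f"unknown gate {gate!r}")
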