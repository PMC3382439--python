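# Methods

`evoguide` simulates fixed-size populations of digital microbes whose
genomes are small gene regulatory/biochemical networks, evolving under
temporally structured environments in which nutrient availability is a
*delayed* boolean function of two external signals.  This note describes the
model, its parameters and their defaults, the design decisions that were
genuinely open, and what the desk-scale experiments shipped with the package
do and do not demonstrate.

## Environments

Two binary signals `s1`, `s2` are emitted as square pulses inside a
4,500-step epoch that repeats identically.  The default waveform has three
pulses of width 500 with signal levels (1,0), (0,1) and (1,1) starting at
steps 500, 1,750 and 3,000.  Nutrient presence is a logic gate applied
pointwise to the signals — one of AND, OR, A (= s1 AND NOT s2), B
(= NOT s1 AND s2), XOR — then shifted forward by a fixed delay of 500 steps,
zero-padding the epoch start (no wrap-around).  Under the default waveform
the five gates produce 1/3/1/1/2 nutrient pulses per epoch.  Cells never
sense nutrient directly; anticipating it requires processing the signals
through a network with appropriate temporal structure, and the 500-step
delay means a purely reactive response earns almost nothing.

Environmental *similarity* is the Pearson correlation between two
environments' nutrient traces over one epoch.  Environmental *complexity*
is measured with plug-in information metrics on the per-step joint
distribution of `(s1, s2, n)`, where the nutrient sequence is shifted back
by the delay (`N_shifted`) so causes and effects are aligned.  The headline
metric is the interaction information
`I(S1;S2;N) = I(S1;S2) − I(S1;S2|N)`, which is negative for synergistic
environments; XOR — the only non-linearly-separable gate — has the largest
magnitude (−1 bit in the ideal case), and environments are ranked by that
magnitude.  All estimators are maximum-likelihood (no bias correction):
sequences contribute 4,000+ samples over 8 bins, so the plug-in bias is
negligible and results are exactly reproducible.

## Cells

A genome is a list of *triplets* — gene/mRNA, protein, and modified-protein
nodes, capturing transcription, translation and post-translational
modification — plus weighted signed regulatory edges.  Triplet 0 (T0) is
the metabolic triplet; its protein RP0 is the response protein whose
expression (count ≥ `rp_threshold`, default 10) is required for nutrient
uptake.  Two read-only sensor nodes expose `s1` and `s2` as molecule counts
(amplitude 50 when high).

Per time step each node creates at most one molecule with probability given
by a two-level sigmoid: an inner per-regulator saturation `c/(K+c)` (K = 10)
of the regulator's molecule count, summed with signed edge weights into a
total regulation `r`, then an outer logistic
`p = p_max / (1 + ((p_max−b)/b)·exp(−k·r))` with steepness k = 2 and
`p_max = 0.5`, calibrated so that `r = 0` yields the node's basal rate `b`.
The probability is scaled by substrate availability `c_sub/(K_s+c_sub)`
(K_s = 5): proteins need their gene's mRNA, modified proteins their
protein; genes use the DNA template (always available).  Low gene basal
rates make the outer logistic a sharp threshold — the ingredient that lets
single genes compute gate-like functions of their regulators.  Each
molecule independently degrades with its node's degradation probability.
Counts are capped at 60.

Regulatory grammar: sensors and protein-level nodes can be regulators;
genes cannot.  Sensors never regulate the metabolic triplet directly — the
metabolic operon responds only to transcription-factor proteins.  This
keeps evolved sensing logic in auxiliary triplets, i.e. in transferable
"gene clusters", which is what makes horizontal gene transfer meaningful.

## Energy and selection

Selection acts on energy alone; the fitness statistic below is never read
by the simulator.  Per step a cell pays:

- production, 0.1 per molecule created (creation requires the energy to pay
  for it — a starved cell cannot express);
- maintenance, 0.005 per non-sensor node;
- a metabolic-pathway running cost of 0.3 per step while RP0 is expressed
  (the pathway is costly to operate whether or not food is present).

While RP0 is expressed *and* nutrient is present the cell harvests 4.0
energy per step, up to a per-epoch uptake saturation of 2,000 (storage and
metabolic capacity are finite; 2,000 = one full 500-step pulse).  The
saturation equalises the attainable income across environments whose
nutrient durations differ (OR offers 3× the nutrient of AND) and makes
*timing*, not expression quantity, the only way to raise net energy: a
constitutive expresser nets roughly zero in AND and is beaten severalfold
by a delayed-gate network, which is the selective gradient that makes gate
logic evolvable.  At energy ≥ 2,000 a cell divides: the progeny is a
mutated copy, parent and progeny each keep half the energy, and the progeny
replaces a victim drawn with probability ∝ 1/(energy + 0.01) among all
other cells, so population size is constant and the poor are replaced
preferentially.

## Mutation and HGT

Mutations are applied to progeny at division (a per-step mode exists behind
a config flag).  Operators and default per-division probabilities:
rate/weight perturbation 0.3 (half on a random edge weight, half
multiplicative on a random node's basal or degradation rate; perturbations
are heavy-tailed — 75% small, 25% 3× larger — so kinetics can be both
refined and restructured), edge addition 0.04, edge deletion 0.06, triplet
duplication 0.004, triplet deletion 0.008 (T0 is never deletable).
Structural deletion bias matters: with symmetric rates the add/delete
random walk reflects at zero and saturates the genome-size caps, and the
resulting maintenance load can drive whole populations extinct.

HGT, when enabled, fires at epoch boundaries: each cell receives, with
probability 0.05, one randomly chosen triplet from a random donor together
with its incident edges.  Sensors and the metabolic triplet T0 exist in
every cell, so edges linking the transferred cluster to them are remapped
onto the recipient's own sensors/T0; edges touching any other donor node
are dropped.  A cluster that activated metabolism in the donor therefore
still activates metabolism in the recipient — an A-evolved cell receiving a
B-evolved cluster acquires an XOR-like response in a single event.

## Fitness

A cell's fitness over an epoch is the Pearson correlation between its RP0
expression level and the nutrient trace, where "expression level" is the
RP0 count smoothed with an exponential moving average (τ = 50 steps, small
against the 500-step delay); the smoothing removes single-molecule shot
noise from the *measurement* without touching the dynamics or selection.
Cells replaced mid-epoch are scored over their own lifetime, and cells
alive for less than half an epoch are omitted from that epoch's population
average (they are measured over their first full epoch instead).  Constant
traces score 0, so unevolved populations start near w = 0.  Adaptation
speed is the first epoch at which the population-average w reaches a
threshold (0.75 by default); the evolutionary rate of an averaged
trajectory is the time constant τ of the nonlinear least-squares fit
`w(t) = A0 − α·exp(−t/τ)` (multi-start on a log-τ grid).

## Founders

Founder cells carry T0 plus one auxiliary triplet wired as a sensing
scaffold — sensors → auxiliary gene; the auxiliary protein (fast) and
modified protein (slow store) → metabolic gene — with random signs,
strengths, basal and degradation rates (modified-protein lifetimes span
~50–500 steps, the raw material for delay lines), plus a few fully random
edges.  Candidates are screened in batch for viability in rich medium
(constant nutrient): only genotypes that can feed at all become founders,
the in-silico analogue of pre-culturing, which removes founder-lottery
extinctions in small populations.  Founders are diverse and viable but
temporally untuned: initial epoch fitness is ≈ 0 in every environment.

## Scales, and what the desk experiments show

The reference experiments behind the phenomena this package explores used
1024-cell populations, ~10⁷ time units and 64 replicates per condition —
cluster-scale work.  The shipped desk profile uses 64–128 cells, epoch
budgets of a few hundred, and a handful of replicates, sized to run in
minutes on one CPU (`experiments.desk_profile`; `paper_profile` exposes the
full-scale settings with a runtime warning).  At desk scale the qualitative
phenomena are reproduced — AND adapts fastest and can reach w ≥ 0.75 within
a few hundred epochs; A, OR and XOR are progressively slower, XOR clearly
slowest, in line with its maximal interaction-information magnitude — but
absolute adaptation times are far larger relative to the epoch budget than
at full scale, success rates are lower, and threshold crossings for the
hard environments are often censored at the budget.  Statements about
guided evolution at desk scale therefore compare censored time-to-threshold
medians and attained fitness levels rather than the cleanly separated epoch
counts observable at full scale.

Known limitations: environments are binary and purely temporal; nutrient is
non-depleting (no competition through a shared resource pool); mutation is
division-coupled by default; the modified-protein node participates in
regulation only (metabolism is gated by RP0 alone); and the energy model —
pathway running cost, uptake saturation, pay-to-produce — is a calibrated
behavioural model, not a fit to measured rate constants.
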