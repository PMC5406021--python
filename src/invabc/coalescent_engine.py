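"""Serial-sample structured coalescent simulation with microsatellite (GSM)
and sequence (HKY) mutation models.

The genealogy is simulated backward in time under the continuous-time
(Kingman) approximation: within a population of size Ne the pair-coalescence
rate for k lineages is k(k-1)/2 x 1/(ploidy x Ne) per generation.  Timed
events move lineages between populations (splits, admixture) or change Ne
(epochs); serial samples enter as tips at their sampling times.  mtDNA is
simulated as a haploid locus with effective size Ne/4 by default (maternal,
haploid), configurable via ``ne_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .genotype_io import GenotypeMatrix, LocusDef
from .mtdna_stats import SequenceAlignment
from .scenario_model import Scenario, generations_to_year

MIN_REPEATS = 2  # reflecting lower bound for microsatellite repeat counts

#: AT-rich base frequencies typical of insect mitochondrial protein genes (ACGT)
DEFAULT_BASE_FREQS = (0.29, 0.16, 0.15, 0.40)


@dataclass(frozen=True)
class MutationModelMsat:
    """Generalized stepwise model: step size geometric with parameter
    ``p_gsm`` (P(step = 1) = p_gsm), sign symmetric."""

    mean_rate: float
    p_gsm: float = 0.7
    rate_shape: float = 2.0  # gamma shape for per-locus rate dispersion

    def __post_init__(self) -> None:
        if self.mean_rate < 0:
            raise ValueError("mean_rate must be >= 0")
        if not 0 < self.p_gsm <= 1:
            raise ValueError("p_gsm must be in (0, 1]")


@dataclass(frozen=True)
class MutationModelSeq:
    """HKY substitution model: transition/transversion parameter kappa and
    stationary base frequencies; ``rate`` is per site per generation."""

    rate: float
    kappa: float = 10.0
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")


@dataclass
class GeneTree:
    """A coalescent genealogy: parent pointers, node times (generations bp),
    and per-tip sample metadata."""

    parent: np.ndarray  # (n_nodes,), -1 at the root
    time: np.ndarray  # (n_nodes,)
    n_tips: int
    tip_population: list[str]
    tip_time: np.ndarray
    tip_label: list[str]  # sample-group label per tip
    tip_individual: np.ndarray  # individual index within the sample group

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (generations)."""
        lens = np.zeros(self.n_nodes)
        nr = self.parent >= 0
        lens[nr] = self.time[self.parent[nr]] - self.time[nr]
        return lens

    def tmrca(self) -> float:
        return float(self.time.max())


class ScenarioError(RuntimeError):
    pass


def simulate_gene_tree(
    scenario: Scenario,
    draws: dict[str, float],
    ploidy: int = 2,
    seed=None,
    ne_scale: float = 1.0,
    samples: list[tuple[str, float, int, str]] | None = None,
) -> GeneTree:
    """One genealogy for the scenario's sample design.

    ``samples`` is ``(population, time, n_gene_copies, label)`` per sampling
    event; by default it is derived from the scenario's sample events with
    ``ploidy`` gene copies per individual.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if samples is None:
        samples = [
            (pop, t, ploidy * n_dip, label) for pop, t, n_dip, label in scenario.bound_samples()
        ]
    ne = {p: v * ne_scale for p, v in scenario.initial_ne(draws).items()}

    n_tips = sum(s[2] for s in samples)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    tip_population: list[str] = []
    tip_label: list[str] = []
    tip_individual = np.empty(n_tips, dtype=np.int64)
    tip_time = np.empty(n_tips)

    # event queue: samples plus demographic events, ascending in time
    queue: list[tuple] = []
    tid = 0
    for pop, t, n_copies, label in samples:
        ids = list(range(tid, tid + n_copies))
        for c in range(n_copies):
            tip_population.append(pop)
            tip_label.append(label)
            tip_individual[tid + c] = c // ploidy
            tip_time[tid + c] = t
            time[tid + c] = t
        queue.append((t, 0, "sample", pop, ids))
        tid += n_copies
    for ev in scenario.bound_events(draws):
        queue.append((ev[0], 1, *ev[1:]))
    queue.sort(key=lambda e: (e[0], e[1]))

    lineages: dict[str, list[int]] = {}
    t = 0.0
    next_node = n_tips

    def coalesce_pop(pop: str, at: float) -> None:
        nonlocal next_node
        lin = lineages[pop]
        k = len(lin)
        i = int(rng.random() * k)
        j = int(rng.random() * (k - 1))
        if j >= i:
            j += 1
        a, b = lin[i], lin[j]
        node = next_node
        next_node += 1
        parent[a] = node
        parent[b] = node
        time[node] = at
        if i < j:
            i, j = j, i
        del lin[i]
        del lin[j]
        lin.append(node)

    def run_until(t_stop: float) -> float:
        """Coalesce within populations from the current time up to t_stop."""
        nonlocal t
        while True:
            rates = []
            pops = []
            total = 0.0
            for p, lin in lineages.items():
                k = len(lin)
                if k >= 2:
                    rate = k * (k - 1) / (2.0 * ploidy * ne[p])
                    pops.append(p)
                    rates.append(rate)
                    total += rate
            if total == 0.0:
                t = t_stop
                return t
            dt = rng.exponential(1.0 / total)
            if t + dt >= t_stop:
                t = t_stop
                return t
            t += dt
            u = rng.random() * total
            acc = 0.0
            target = pops[-1]
            for p, rate in zip(pops, rates):
                acc += rate
                if u < acc:
                    target = p
                    break
            coalesce_pop(target, t)

    for item in queue:
        run_until(item[0])
        kind = item[2]
        if kind == "sample":
            lineages.setdefault(item[3], []).extend(item[4])
        elif kind == "split":
            _, _, _, derived, par = item
            if par not in ne:
                raise ScenarioError(f"split into unknown population {par}")
            if derived in lineages:
                lineages.setdefault(par, []).extend(lineages.pop(derived))
            ne.pop(derived, None)  # derived population ceases to exist
        elif kind == "admixture":
            _, _, _, derived, par, alt, ra = item
            moved = lineages.pop(derived, [])
            for lin in moved:
                dest = alt if rng.random() < ra else par
                lineages.setdefault(dest, []).append(lin)
            ne.pop(derived, None)
        elif kind == "ne_change":
            _, _, _, pop, value = item
            ne[pop] = value * ne_scale

    # all events processed: remaining lineages must sit in one population
    active = {p: lin for p, lin in lineages.items() if lin}
    if len(active) > 1:
        raise ScenarioError(
            f"lineages stranded in multiple populations with no ancestral path: {sorted(active)}"
        )
    (pop, lin), = active.items()
    # final vectorized Kingman pass in the root population
    while len(lin) > 1:
        k = len(lin)
        dt = rng.exponential(2.0 * ploidy * ne[pop] / (k * (k - 1)))
        t += dt
        coalesce_pop(pop, t)

    return GeneTree(
        parent=parent,
        time=time,
        n_tips=n_tips,
        tip_population=tip_population,
        tip_time=tip_time,
        tip_label=tip_label,
        tip_individual=tip_individual,
    )


# -- mutation -----------------------------------------------------------------


def mutate_microsat(
    tree: GeneTree,
    model: MutationModelMsat,
    ancestral_state: int = 25,
    seed=None,
    rate: float | None = None,
) -> np.ndarray:
    """Tip repeat counts under the generalized stepwise model.

    Mutation counts are Poisson(branch length x rate); each mutation steps
    +-s with s ~ Geometric(p_gsm).  Tip states are reflected at the
    ``MIN_REPEATS`` lower bound (applied once to final states).
    """
    if ancestral_state <= MIN_REPEATS:
        raise ValueError(f"ancestral_state must exceed the lower bound {MIN_REPEATS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = model.mean_rate if rate is None else rate
    lens = tree.branch_lengths()
    total = lens.sum()
    disp = np.zeros(tree.n_nodes)
    n_mut = rng.poisson(mu * total)
    if n_mut:
        cum = np.cumsum(lens)
        branch = np.searchsorted(cum, rng.random(n_mut) * total)
        steps = rng.geometric(model.p_gsm, n_mut) if model.p_gsm < 1 else np.ones(n_mut, dtype=np.int64)
        signs = rng.integers(0, 2, n_mut) * 2 - 1
        np.add.at(disp, branch, signs * steps)
    states = np.zeros(tree.n_nodes)
    parent = tree.parent
    # nodes are created in backward-time order, so parent index > child index
    for v in range(tree.n_nodes - 2, -1, -1):
        states[v] = states[parent[v]] + disp[v]
    tips = ancestral_state + states[: tree.n_tips]
    low = tips < MIN_REPEATS
    tips[low] = 2 * MIN_REPEATS - tips[low]
    return np.maximum(tips, MIN_REPEATS).astype(np.int64)


def hky_rate_matrix(kappa: float, base_freqs) -> np.ndarray:
    """HKY Q matrix (ACGT order) normalized to one expected substitution per
    unit time at stationarity."""
    pi = np.asarray(base_freqs, dtype=float)
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -float(np.sum(pi * np.diag(q)))
    return q / scale


def mutate_sequence(
    tree: GeneTree,
    model: MutationModelSeq,
    L: int = 445,
    seed=None,
) -> np.ndarray:
    """Tip sequences as an (n_tips, L) uint8 ASCII array under HKY.

    The root sequence is drawn from the stationary frequencies; each branch
    uses the exact matrix-exponential transition probabilities for its length
    (in expected substitutions: rate x generations).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = hky_rate_matrix(model.kappa, model.base_freqs)
    pi = np.asarray(model.base_freqs)
    lens = tree.branch_lengths() * model.rate
    states = np.empty((tree.n_nodes, L), dtype=np.int8)
    # node index order is backward-time order: the root is the last node
    states[tree.n_nodes - 1] = rng.choice(4, size=L, p=pi)
    for v in range(tree.n_nodes - 2, -1, -1):
        p_mat = expm(q * lens[v]) if lens[v] > 0 else np.eye(4)
        cum = np.cumsum(p_mat, axis=1)
        parent_seq = states[tree.parent[v]]
        u = rng.random(L)
        child = np.empty(L, dtype=np.int8)
        for b in range(4):
            sel = parent_seq == b
            if np.any(sel):
                child[sel] = np.searchsorted(cum[b], u[sel])
        states[v] = np.minimum(child, 3)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bases[states[: tree.n_tips].astype(np.int64)]


# -- dataset-level simulation -------------------------------------------------


_META_CACHE: dict[tuple, pd.DataFrame] = {}


def _sample_metadata(scenario: Scenario, bound: tuple) -> pd.DataFrame:
    """Individual metadata for a sample design (memoised: it is deterministic)."""
    key = (scenario.present, scenario.g_per_year, bound)
    if key not in _META_CACHE:
        ids, pops, years = [], [], []
        for pop, t, n_dip, label in bound:
            year = int(round(generations_to_year(t, scenario.present, scenario.g_per_year)))
            for i in range(n_dip):
                ids.append(f"{label}_i{i:03d}")
                pops.append(label)
                years.append(year)
        _META_CACHE[key] = pd.DataFrame({"id": ids, "population": pops, "year": years})
    return _META_CACHE[key].copy()


@dataclass
class SimOptions:
    ancestral_repeats: int = 25
    size_offset_bp: int = 100  # cosmetic bp offset so allele sizes look assay-like
    mt_ne_scale: float = 0.25  # haploid, maternally inherited
    seq_length: int = 445
    p_gsm: float = 0.7
    rate_shape: float = 2.0
    simulate_sequence: bool = True
    base_freqs: tuple = DEFAULT_BASE_FREQS


def simulate_dataset(
    scenario: Scenario,
    draws: dict[str, float],
    panel: list[LocusDef],
    seed=None,
    options: SimOptions = SimOptions(),
) -> tuple[GenotypeMatrix, SequenceAlignment | None]:
    """Simulate one full dataset under a scenario and parameter vector.

    Each microsatellite locus gets an independent diploid gene tree; per-locus
    rates are gamma-dispersed around the motif-class mean (``mu_di`` /
    ``mu_tri`` in ``draws``).  The sequence locus is a single haploid tree
    with effective size scaled by ``mt_ne_scale`` and HKY mutations at rate
    ``mu_seq`` with transition/transversion parameter ``kappa``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bound = scenario.bound_samples()

    calls_cols = []
    for locus in panel:
        mean_mu = draws["mu_di"] if locus.motif_length == 2 else draws["mu_tri"]
        rate = rng.gamma(options.rate_shape, mean_mu / options.rate_shape) if options.rate_shape else mean_mu
        tree = simulate_gene_tree(scenario, draws, ploidy=2, seed=rng)
        model = MutationModelMsat(mean_mu, p_gsm=options.p_gsm, rate_shape=options.rate_shape)
        repeats = mutate_microsat(tree, model, options.ancestral_repeats, seed=rng, rate=rate)
        sizes = options.size_offset_bp + repeats * locus.motif_length
        calls_cols.append(sizes.reshape(-1, 2))  # consecutive copies pair per individual

    meta = _sample_metadata(scenario, tuple(bound))
    calls = np.stack(calls_cols, axis=1).astype(np.int32)  # (n_ind, n_loci, 2)
    g = GenotypeMatrix(meta, list(panel), calls)

    aln = None
    if options.simulate_sequence:
        samples_hap = [(pop, t, n_dip, label) for pop, t, n_dip, label in bound]
        tree = simulate_gene_tree(
            scenario, draws, ploidy=1, seed=rng, ne_scale=options.mt_ne_scale,
            samples=samples_hap,
        )
        seq_model = MutationModelSeq(
            rate=draws.get("mu_seq", 0.0), kappa=draws.get("kappa", 10.0),
            base_freqs=options.base_freqs,
        )
        seqs = mutate_sequence(tree, seq_model, L=options.seq_length, seed=rng)
        meta_seq = pd.DataFrame(
            {
                "id": [f"{lab}_s{i:03d}" for lab, i in zip(tree.tip_label, tree.tip_individual)],
                "population": tree.tip_label,
                "year": [
                    int(round(generations_to_year(t, scenario.present, scenario.g_per_year)))
                    for t in tree.tip_time
                ],
            }
        )
        aln = SequenceAlignment(meta_seq, seqs)
    return g, aln
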