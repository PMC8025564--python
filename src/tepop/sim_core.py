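"""Per-generation update cycle for an asexual host population carrying TEs.

Each host is haploid and clonal: a genome is an ordered sequence of loci,
each coding, non-coding, an active TE copy, or a dead (degraded) TE copy.
One generation applies, in fixed order:

1. **transposition** — each active TE fires with probability
   ``transposition_rate``; a firing retains the original copy and inserts
   ``progeny`` new active copies, each at a fresh locus adjacent to a target
   chosen non-coding (dead TEs included) with the insertion-bias
   probability, otherwise coding; each new insertion draws a fitness effect
   (lethal / deleterious / neutral / beneficial) and multiplies host fitness;
2. **excision** — each active TE's locus is deleted with probability
   ``excision_rate`` (no fitness change);
3. **TE death** — each active TE degrades into a permanently inactive dead
   copy with probability ``death_rate``; dead copies count as non-coding for
   future targeting;
4. **host mutation** — each locus mutates with probability
   ``mutation_rate``: a coding mutation multiplies fitness by
   ``1 - mutation_effect``, a mutation in an active TE inactivates it, and
   mutations of non-coding or dead-TE loci are silent;
5. **reproduction** — ``carrying_capacity`` offspring are drawn by sampling
   parents with replacement, probability proportional to fitness
   (Wright–Fisher with selection).  Offspring are exact clonal copies — no
   recombination and no horizontal TE transfer.  If every fitness is zero
   the host population goes extinct.

Selection runs last so that every event of a generation is visible to it.
Fitness is a heritable scalar: the product of all effect multipliers applied
along the lineage since the founder (starting at 1.0); excision does not
restore fitness.  The insertion-bias value is a constant of the run — TEs
cannot evolve site preferences — and TE copies pass only from parent to
offspring, never between lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .effects import EffectClass
from .parameters import SimulationParams

__all__ = [
    "LocusClass",
    "Genome",
    "Host",
    "Population",
    "GenerationRecord",
    "init_population",
    "transpose",
    "excise",
    "te_death",
    "mutate_hosts",
    "reproduce",
    "step_generation",
]


class LocusClass(IntEnum):
    CODING = 0
    NONCODING = 1
    ACTIVE_TE = 2
    DEAD_TE = 3


_N_CLASSES = len(LocusClass)


class Genome:
    """An ordered sequence of loci with a cached per-class tally.

    The locus array may grow (insertions add loci) and shrink (excisions
    delete loci).  The counts cache is updated incrementally by every
    mutating method; :meth:`tally` recomputes it from scratch for
    integrity checks.
    """

    __slots__ = ("loci", "_counts")

    def __init__(self, loci: np.ndarray) -> None:
        self.loci = np.asarray(loci, dtype=np.uint8)
        self._counts = np.bincount(self.loci, minlength=_N_CLASSES).astype(np.int64)

    # -- counts ----------------------------------------------------------
    @property
    def counts(self) -> np.ndarray:
        """Cached per-class locus counts in :class:`LocusClass` order."""
        return self._counts

    @property
    def n_coding(self) -> int:
        return int(self._counts[LocusClass.CODING])

    @property
    def n_noncoding(self) -> int:
        return int(self._counts[LocusClass.NONCODING])

    @property
    def n_active_te(self) -> int:
        return int(self._counts[LocusClass.ACTIVE_TE])

    @property
    def n_dead_te(self) -> int:
        return int(self._counts[LocusClass.DEAD_TE])

    def __len__(self) -> int:
        return self.loci.size

    def tally(self) -> np.ndarray:
        """Fresh per-class tally of the locus array (integrity oracle)."""
        return np.bincount(self.loci, minlength=_N_CLASSES).astype(np.int64)

    def copy(self) -> "Genome":
        clone = Genome.__new__(Genome)
        clone.loci = self.loci.copy()
        clone._counts = self._counts.copy()
        return clone

    # -- mutators --------------------------------------------------------
    def indices_of(self, *classes: LocusClass) -> np.ndarray:
        if len(classes) == 1:
            return np.flatnonzero(self.loci == classes[0])
        return np.flatnonzero(np.isin(self.loci, np.array(classes, dtype=np.uint8)))

    def insert_active(self, positions: np.ndarray) -> None:
        """Insert new ACTIVE_TE loci before the given original positions."""
        self.loci = np.insert(self.loci, positions, np.uint8(LocusClass.ACTIVE_TE))
        self._counts[LocusClass.ACTIVE_TE] += len(positions)

    def delete(self, indices: np.ndarray) -> None:
        removed = np.bincount(self.loci[indices], minlength=_N_CLASSES)
        self.loci = np.delete(self.loci, indices)
        self._counts -= removed

    def convert(self, indices: np.ndarray, new_class: LocusClass) -> None:
        removed = np.bincount(self.loci[indices], minlength=_N_CLASSES)
        self.loci[indices] = np.uint8(new_class)
        self._counts -= removed
        self._counts[new_class] += len(indices)


@dataclass
class Host:
    """One clonal individual: a genome plus a heritable fitness scalar.

    ``lineage`` is the founder host's id, inherited unchanged, which lets
    tests verify that TE copies never move between founder lineages.
    """

    genome: Genome
    fitness: float
    id: int
    lineage: int


@dataclass
class Population:
    hosts: list[Host]
    generation: int
    params: SimulationParams
    rng: np.random.Generator
    _next_id: int = 0

    @property
    def size(self) -> int:
        return len(self.hosts)

    def total_active_te(self) -> int:
        return sum(h.genome.n_active_te for h in self.hosts)

    def mean_te_per_host(self) -> float:
        return self.total_active_te() / self.size if self.hosts else 0.0

    def mean_fitness(self) -> float:
        return (
            float(np.mean([h.fitness for h in self.hosts])) if self.hosts else 0.0
        )

    def new_id(self) -> int:
        nid = self._next_id
        self._next_id += 1
        return nid


@dataclass
class GenerationRecord:
    """Per-generation summary with a balanced TE event ledger.

    The ledger identity is::

        total_active_te = previous total + insertions - excisions
                          - te_deaths - te_inactivations + te_repro_delta

    where ``te_repro_delta`` is the net change in active copies caused by
    fitness-proportional resampling of parents (lineages leaving no
    offspring lose their copies; lineages sampled more than once duplicate
    theirs).
    """

    generation: int
    total_active_te: int
    mean_te_per_host: float
    population_size: int
    mean_fitness: float
    insertions: int = 0
    excisions: int = 0
    te_deaths: int = 0
    te_inactivations: int = 0
    te_repro_delta: int = 0
    host_deaths: int = 0
    noncoding_insertions: int = 0
    coding_insertions: int = 0
    lethal_insertions: int = 0
    deleterious_insertions: int = 0
    beneficial_insertions: int = 0


def _rng_of(pop: Population, rng: np.random.Generator | None) -> np.random.Generator:
    return pop.rng if rng is None else rng


def init_population(
    params: SimulationParams, rng: np.random.Generator
) -> Population:
    """Build the founding population at carrying capacity.

    Each host gets ``genome_length`` loci of which the non-coding fraction
    are NONCODING (rest CODING, randomly interleaved), then
    ``initial_te_per_host`` active TE loci are inserted adjacent to random
    non-coding loci.  All fitnesses start at 1.
    """
    n_noncoding = int(round(params.non_coding_fraction * params.genome_length))
    n_coding = params.genome_length - n_noncoding
    if params.initial_te_per_host > 0 and n_noncoding == 0:
        raise ValueError(
            f"cannot place {params.initial_te_per_host} initial TEs: "
            "genome has no non-coding loci"
        )
    base = np.concatenate(
        [
            np.full(n_coding, LocusClass.CODING, dtype=np.uint8),
            np.full(n_noncoding, LocusClass.NONCODING, dtype=np.uint8),
        ]
    )
    pop = Population(hosts=[], generation=0, params=params, rng=rng)
    for _ in range(params.carrying_capacity):
        loci = rng.permutation(base)
        genome = Genome(loci)
        if params.initial_te_per_host:
            targets = rng.choice(
                genome.indices_of(LocusClass.NONCODING),
                size=params.initial_te_per_host,
                replace=True,
            )
            genome.insert_active(targets + 1)
        hid = pop.new_id()
        pop.hosts.append(Host(genome=genome, fitness=1.0, id=hid, lineage=hid))
    return pop


def transpose(
    pop: Population, rng: np.random.Generator | None = None
) -> dict[str, int]:
    """Copy-and-paste transposition with per-insertion effect draws.

    Returns an event log with insertion, targeting, and effect-class
    counts.  A genome with no loci of the chosen target class falls back to
    the other class (counted under ``target_fallbacks``).
    """
    rng = _rng_of(pop, rng)
    p = pop.params
    dist = p.effect_distribution
    log = {
        "firings": 0,
        "insertions": 0,
        "noncoding_insertions": 0,
        "coding_insertions": 0,
        "target_fallbacks": 0,
        "lethal_insertions": 0,
        "deleterious_insertions": 0,
        "neutral_insertions": 0,
        "beneficial_insertions": 0,
    }
    if not pop.hosts or p.transposition_rate == 0.0:
        return log
    active = np.fromiter(
        (h.genome.n_active_te for h in pop.hosts), dtype=np.int64, count=pop.size
    )
    firings = rng.binomial(active, p.transposition_rate)
    for i in np.flatnonzero(firings):
        host = pop.hosts[i]
        genome = host.genome
        n_new = int(firings[i]) * p.progeny

        # fitness consequences: one unconditional categorical draw per insertion
        k = rng.multinomial(n_new, dist.probabilities)
        if k[EffectClass.LETHAL]:
            host.fitness = 0.0
        if k[EffectClass.DELETERIOUS]:
            host.fitness *= (1.0 - dist.s_deleterious) ** int(k[EffectClass.DELETERIOUS])
        if k[EffectClass.BENEFICIAL]:
            host.fitness *= (1.0 + dist.s_beneficial) ** int(k[EffectClass.BENEFICIAL])

        # target-site choice: non-coding (incl. dead TEs) vs coding
        n_nc_pool = genome.n_noncoding + genome.n_dead_te
        n_cod_pool = genome.n_coding
        if p.insertion_bias is None:
            bias = n_nc_pool / len(genome) if len(genome) else 0.0
        else:
            bias = p.insertion_bias
        n_nc = int(rng.binomial(n_new, bias))
        if n_nc_pool == 0 and n_nc:
            log["target_fallbacks"] += n_nc
            n_nc = 0
        if n_cod_pool == 0 and n_new - n_nc:
            log["target_fallbacks"] += n_new - n_nc
            n_nc = n_new
        positions = []
        if n_nc:
            pool = genome.indices_of(LocusClass.NONCODING, LocusClass.DEAD_TE)
            positions.append(rng.choice(pool, size=n_nc, replace=True))
        if n_new - n_nc:
            pool = genome.indices_of(LocusClass.CODING)
            positions.append(rng.choice(pool, size=n_new - n_nc, replace=True))
        genome.insert_active(np.concatenate(positions) + 1)

        log["firings"] += int(firings[i])
        log["insertions"] += n_new
        log["noncoding_insertions"] += n_nc
        log["coding_insertions"] += n_new - n_nc
        log["lethal_insertions"] += int(k[EffectClass.LETHAL])
        log["deleterious_insertions"] += int(k[EffectClass.DELETERIOUS])
        log["neutral_insertions"] += int(k[EffectClass.NEUTRAL])
        log["beneficial_insertions"] += int(k[EffectClass.BENEFICIAL])
    return log


def excise(
    pop: Population, rng: np.random.Generator | None = None
) -> dict[str, int]:
    """Delete each active TE locus with probability ``excision_rate``."""
    rng = _rng_of(pop, rng)
    rate = pop.params.excision_rate
    log = {"excisions": 0}
    if not pop.hosts or rate == 0.0:
        return log
    active = np.fromiter(
        (h.genome.n_active_te for h in pop.hosts), dtype=np.int64, count=pop.size
    )
    removals = rng.binomial(active, rate)
    for i in np.flatnonzero(removals):
        genome = pop.hosts[i].genome
        idx = rng.choice(
            genome.indices_of(LocusClass.ACTIVE_TE),
            size=int(removals[i]),
            replace=False,
        )
        genome.delete(idx)
        log["excisions"] += int(removals[i])
    return log


def te_death(
    pop: Population, rng: np.random.Generator | None = None
) -> dict[str, int]:
    """Degrade each active TE to a dead copy with probability ``death_rate``."""
    rng = _rng_of(pop, rng)
    rate = pop.params.death_rate
    log = {"te_deaths": 0}
    if not pop.hosts or rate == 0.0:
        return log
    active = np.fromiter(
        (h.genome.n_active_te for h in pop.hosts), dtype=np.int64, count=pop.size
    )
    deaths = rng.binomial(active, rate)
    for i in np.flatnonzero(deaths):
        genome = pop.hosts[i].genome
        idx = rng.choice(
            genome.indices_of(LocusClass.ACTIVE_TE),
            size=int(deaths[i]),
            replace=False,
        )
        genome.convert(idx, LocusClass.DEAD_TE)
        log["te_deaths"] += int(deaths[i])
    return log


def mutate_hosts(
    pop: Population, rng: np.random.Generator | None = None
) -> dict[str, int]:
    """Per-locus host mutation.

    Coding mutations multiply fitness by ``1 - mutation_effect``; mutations
    in active TEs inactivate them (to DEAD_TE); mutations of non-coding or
    dead-TE loci are silent (logged only).
    """
    rng = _rng_of(pop, rng)
    p = pop.params
    log = {"coding_mutations": 0, "te_inactivations": 0, "silent_mutations": 0}
    if not pop.hosts or p.mutation_rate == 0.0:
        return log
    n = pop.size
    coding = np.fromiter((h.genome.n_coding for h in pop.hosts), np.int64, count=n)
    active = np.fromiter((h.genome.n_active_te for h in pop.hosts), np.int64, count=n)
    silent_pool = np.fromiter(
        (h.genome.n_noncoding + h.genome.n_dead_te for h in pop.hosts),
        np.int64,
        count=n,
    )
    k_coding = rng.binomial(coding, p.mutation_rate)
    k_active = rng.binomial(active, p.mutation_rate)
    k_silent = rng.binomial(silent_pool, p.mutation_rate)
    for i in np.flatnonzero(k_coding):
        pop.hosts[i].fitness *= (1.0 - p.mutation_effect) ** int(k_coding[i])
    for i in np.flatnonzero(k_active):
        genome = pop.hosts[i].genome
        idx = rng.choice(
            genome.indices_of(LocusClass.ACTIVE_TE),
            size=int(k_active[i]),
            replace=False,
        )
        genome.convert(idx, LocusClass.DEAD_TE)
    log["coding_mutations"] = int(k_coding.sum())
    log["te_inactivations"] = int(k_active.sum())
    log["silent_mutations"] = int(k_silent.sum())
    return log


def reproduce(
    pop: Population, rng: np.random.Generator | None = None
) -> dict[str, int]:
    """Fitness-proportional Wright–Fisher reproduction at carrying capacity.

    Samples ``carrying_capacity`` parents with replacement, probability
    proportional to fitness; offspring are exact clonal copies.  If all
    fitnesses are zero the population goes extinct (size 0).
    """
    rng = _rng_of(pop, rng)
    log = {"host_deaths": 0, "te_repro_delta": 0}
    if not pop.hosts:
        return log
    before_active = pop.total_active_te()
    weights = np.fromiter((h.fitness for h in pop.hosts), np.float64, count=pop.size)
    total = weights.sum()
    if total <= 0.0:
        log["host_deaths"] = pop.size
        log["te_repro_delta"] = -before_active
        pop.hosts = []
        return log
    counts = rng.multinomial(pop.params.carrying_capacity, weights / total)
    new_hosts: list[Host] = []
    for i in np.flatnonzero(counts):
        parent = pop.hosts[i]
        for _ in range(int(counts[i])):
            new_hosts.append(
                Host(
                    genome=parent.genome.copy(),
                    fitness=parent.fitness,
                    id=pop.new_id(),
                    lineage=parent.lineage,
                )
            )
    log["host_deaths"] = int(np.sum(counts == 0))
    pop.hosts = new_hosts
    log["te_repro_delta"] = pop.total_active_te() - before_active
    return log


def step_generation(
    pop: Population, rng: np.random.Generator | None = None
) -> GenerationRecord:
    """Advance the population one generation and return its record.

    Applies transposition → excision → TE death → host mutation →
    reproduction, in that fixed order, then increments the generation
    counter.
    """
    rng = _rng_of(pop, rng)
    t_log = transpose(pop, rng)
    e_log = excise(pop, rng)
    d_log = te_death(pop, rng)
    m_log = mutate_hosts(pop, rng)
    r_log = reproduce(pop, rng)
    pop.generation += 1
    return GenerationRecord(
        generation=pop.generation,
        total_active_te=pop.total_active_te(),
        mean_te_per_host=pop.mean_te_per_host(),
        population_size=pop.size,
        mean_fitness=pop.mean_fitness(),
        insertions=t_log["insertions"],
        excisions=e_log["excisions"],
        te_deaths=d_log["te_deaths"],
        te_inactivations=m_log["te_inactivations"],
        te_repro_delta=r_log["te_repro_delta"],
        host_deaths=r_log["host_deaths"],
        noncoding_insertions=t_log["noncoding_insertions"],
        coding_insertions=t_log["coding_insertions"],
        lethal_insertions=t_log["lethal_insertions"],
        deleterious_insertions=t_log["deleterious_insertions"],
        beneficial_insertions=t_log["beneficial_insertions"],
    )
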