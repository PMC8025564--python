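# Methods

## The model

`tepop` simulates the fate of a transposable-element (TE) population inside
a clonal (asexual) host population, under conditions in which none of the
classical explanations for TE accumulation are available: hosts never
recombine, TEs never transfer horizontally between lineages, and TEs cannot
evolve insertion-site preferences.  The only mechanism by which TE activity
can favour its own spread is the fitness effect of new insertions — which is
exactly the dial the central experiment turns.

Each host carries a genome represented as an ordered sequence of loci of
four kinds: coding, non-coding, active TE copy, and dead (degraded) TE copy.
Dead copies behave as non-coding DNA for targeting purposes, so the cycle of
TE proliferation and degradation enlarges the non-coding landscape — the
"TE engineering" idea the experiment probes.  Host fitness is a single
non-negative scalar, the product of all effect multipliers applied along the
lineage since its founder (founders start at 1).

One generation applies, in fixed order:

1. **Transposition.** Each active copy fires with probability *u*
   (`transposition_rate`).  A firing retains the original copy and inserts
   `progeny` new active copies, each at a new locus adjacent to a target
   chosen non-coding with the insertion-bias probability (otherwise coding;
   unbiased mode uses the genome's current non-coding fraction).  Each new
   insertion independently draws an effect class:

   | class       | probability           | fitness multiplier  |
   |-------------|-----------------------|---------------------|
   | lethal      | 0.20                  | 0                   |
   | deleterious | 0.30                  | 1 − s_d             |
   | neutral     | 0.50 − p_b            | 1                   |
   | beneficial  | p_b ∈ [0, 0.20]       | 1 + s_b             |

   The beneficial probability p_b is the experiment's swept variable; the
   neutral class absorbs whatever the beneficial class gives up, so the
   lethal/deleterious split never changes.  Effect class is drawn
   unconditionally per insertion — it does not depend on whether the target
   locus is coding — because the class percentages are defined over all
   insertions.  A consequence worth stating plainly: since insertion adds a
   new locus rather than disrupting the target, the insertion-bias and
   non-coding-DNA axes influence only where loci sit (and the targeting
   statistics in the event log), not fitness; under this reading those two
   axes are dynamically inert.
2. **Excision.** Each active copy's locus is deleted with probability
   `excision_rate`.  Excision carries no fitness change: the harm or benefit
   of an old insertion is treated as a property of the lineage's history,
   not of the locus, which keeps the heritable-scalar fitness consistent.
3. **TE death.** Each active copy degrades to a dead copy with probability
   `death_rate`; dead copies are permanently inactive and join the
   non-coding targeting pool.
4. **Host mutation.** Every locus mutates with probability
   `corrected_mutation_rate`.  Coding mutations multiply fitness by
   1 − `mutation_effect`; mutations in active TEs inactivate them (another
   route into the dead-copy pool); mutations of non-coding or dead loci are
   silent.
5. **Reproduction.** Wright–Fisher with selection: `carrying_capacity`
   parents are sampled with replacement, probability proportional to
   fitness, and each offspring is an exact clonal copy (genome and fitness).
   If every fitness is zero the host population is extinct.

Selection runs last so that every event of the generation is visible to it.
Generations are discrete and non-overlapping.  Offspring inherit the
parent's current fitness scalar rather than recomputing it from per-locus
annotations; the two are observationally equivalent (a lethal host never
reproduces) and the scalar form is the one consistent with fitness-free
excision.

A run ends at the first generation with zero active copies (extinction,
recorded) or at the 1,500-generation cutoff; a run still carrying at least
one active copy at the cutoff is classified as *accumulated*.

## Parameters and calibration

The eight experimental axes are two-level (High/Low); published scenario
tables print only the letters.  The numeric values behind them are a
configurable *level map*; this package's defaults are a calibration chosen
once, against the qualitative behaviour the experiment is defined by —
collapse without the beneficial class, persistence with it — and then
frozen:

| axis                    | low          | high  | meaning                                   |
|-------------------------|--------------|-------|-------------------------------------------|
| te_progeny              | 1            | 2     | new copies per firing (original retained) |
| te_excision_rate        | 0.08         | 0.16  | per-copy per-generation deletion          |
| te_death_rate           | 0.04         | 0.08  | per-copy per-generation degradation       |
| insertion_bias          | proportional | 0.9   | P(new insertion targets non-coding)       |
| corrected_mutation_rate | 1e-4         | 1e-3  | per-locus per-generation                  |
| non_coding_dna          | 0.3          | 0.7   | initial non-coding genome fraction        |
| mutation_effect         | 0.01         | 0.1   | coding-mutation selection coefficient     |
| carrying_capacity       | 100          | 500   | host population size                      |

Globals: genome of 1,000 loci; 5 initial active copies per host, placed at
random non-coding sites; transposition rate *u* = 0.05 per copy per
generation; s_d = 0.01, s_b = 0.30; cutoff 1,500 generations.

The calibration logic is worth recording.  Per active copy and generation,
transposition adds *u* · `progeny` copies (0.05 low, 0.10 high) while
excision + death mechanically remove `excision_rate` + `death_rate`
(0.12 at the low levels).  The low-level mechanical loss therefore exceeds
the mechanical gain even at high progeny, so *no* TE population can sustain
itself on copy bookkeeping alone: persistence requires lineage-level
positive selection, which only the beneficial insertion class can supply.
With s_b = 0.30, a lineage that draws a beneficial insertion expands fast
enough to amplify its TE complement before the advantage erodes, and at
p_b = 0.20 such draws arrive often enough to sustain the TE population
indefinitely; at p_b = 0 the TE population decays to extinction within a
few dozen generations, and intermediate frequencies interpolate (longer and
longer excursions, still ending in extinction).  The asymmetry between
s_b = 0.30 and s_d = 0.01 is deliberate: the deleterious class mainly
matters through its contribution to the per-insertion fitness drag, while
the beneficial class must be strong enough for single draws to establish
against drift in populations of a few hundred hosts (establishment
probability ≈ 2s under a branching approximation).  A beneficial coefficient
small enough to be called "mild" in a molecular-evolution sense (s ≈ 0.01)
cannot rescue a TE population of this size from a 7 %-per-generation decay,
whatever its frequency — with these population sizes the interesting
contrast simply does not exist at that magnitude.

## What the simulator emulates, and what it does not

The generator *is* the study system: there is no external data.  What the
defaults emulate is a desk-scale version of the published design — six
High/Low scenarios, a 0 %-vs-20 % beneficial contrast, a six-level sweep,
three replicates, a 1,500-generation cutoff.  Features of real TE biology
deliberately absent: sexual recombination and horizontal transfer (their
absence is the point of the design), TE families with distinct parameter
values, site-specific selection (every coding locus is equally mutable and
equally dispensable), dosage- or position-dependent insertion effects, and
any coupling between effect class and target-site class.  Consequently,
passing tests show that the *model's* headline contrast is reproducible and
calibration-robust — not that real genomes behave this way.

## Numerical and design choices

* **Seeds.** All randomness flows through one `numpy` Generator per
  replicate, seeded by `SHA-256(base_seed | scenario | pct | replicate)`
  truncated below 2³¹ — adding cells to a design never perturbs existing
  trajectories, and every run is bit-replayable from the JSON snapshot.
* **Event sampling.** Per-host event counts are binomial draws on cached
  per-class locus counts; affected loci are then chosen uniformly within
  their class.  Batched effect draws use a single multinomial,
  distributionally identical to per-insertion categorical draws.
* **Ledger.** Every generation records insertions, excisions, TE deaths,
  mutational inactivations, and the reproduction delta; the active-copy
  count satisfies the conservation identity exactly, which the tests check
  against fresh genome tallies.
* **Degenerate inputs.** A genome with an empty target class falls back to
  the other class (logged); zero initial TEs is immediate extinction at
  generation 0; an all-zero-fitness population reproduces to size 0 and the
  run ends.
* **Tie-breaks.** None needed: sampling is with replacement everywhere
  except the choice of which copies excise/die/inactivate, which is uniform
  without replacement within the host.
* **Problem sizes.** Unit tests run populations of 10–30 hosts with genomes
  of 100–200 loci; the sweep-monotonicity check uses carrying capacity 100,
  a 300-generation cutoff and 10 replicates per level; the headline
  contrast runs the published design at full size (K = 500, 1,500
  generations, 3 replicates).

## Known limitations

* The insertion-bias and non-coding-DNA axes are dynamically inert under
  the unconditional-effect reading (see above), so scenario differences
  here express only progeny, excision, death, carrying capacity, and
  mutation-load noise.  A model in which insertions into coding loci are
  the *mechanism* of the deleterious classes would make those axes matter;
  that is a different model than the one specified.
* The mutation-effect axis acts only through background load shared (in
  expectation) by all hosts; it perturbs selection efficacy via clonal
  interference rather than acting on TEs directly.
* Absolute fitness declines over long runs (multiplicative load); only
  relative fitness matters for reproduction, and double precision holds the
  dynamic range comfortably at these rates.
* The High/Low numeric values are a calibration, not a measurement; every
  quantitative outcome (extinction generations, copy-number plateaus)
  should be read as internal to this calibration.
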