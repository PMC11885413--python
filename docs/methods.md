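# Methods

## Model structure

The state is the vector of nine genotype densities
$N_1,\dots,N_9$ (AABB, AABb, AAbb, AaBB, AaBb, Aabb, aaBB, aaBb, aabb;
densities are real numbers per unit area, not individual counts). The
model couples three ingredients:

1. **Mating genetics.** The population is panmictic with two unlinked
   loci. Each genotype contributes gametes (AB, Ab, aB, ab) with
   per-locus drive-allele shares 1, ½, 0 for allele counts 2, 1, 0,
   multiplied across loci. Offspring densities $\nu_i$ come from random
   union of two draws from the density-weighted population gamete pool,
   scaled by total density. This construction is algebraically
   identical to summing over all 81 ordered parental pairs (kept as a
   brute-force oracle in the test suite) and conserves density exactly:
   $\sum_i \nu_i = \sum_i N_i$. Lethal genotypes are *produced* in
   $\nu$ and removed only through their zero fitness at birth, which is
   what makes the conservation identity (and hence evaluating the
   competition function on $\sum_i N_i$) exact.

2. **Fitness.** Costs act at birth, never on parental survival or
   gamete success: the birth term is $r\,\nu_i\,\psi_i$. Per locus the
   factors are $1$, $1-hs$, $1-s$; $\psi_i$ is their product over loci.
   Haplosufficiency of toxin and antidote makes AAbb, Aabb, aaBB and
   aaBb unconditionally non-viable ($\psi=0$); wild type has $\psi=1$.
   The model is single-pool (no sexes) because nothing in the dynamics
   distinguishes them under panmixia.

3. **Density dependence.** One dimensionless family evaluated at total
   density, acting multiplicatively on births ($f(0)=1$, decreasing) or
   additively on deaths ($f(0)=0$, increasing). The additive (rather
   than multiplicative) death form keeps a positive baseline death rate
   $\mu$ at vanishing density. The Bellows family applies its scaling
   as $aN^b$ — $a$ carries different units per family, so only the
   dimensionless $f$ values are ever compared across families.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| r | per-capita birth rate | 1.1 / day | Anopheles-like |
| mu | per-capita death rate | 0.1 / day | r > mu required |
| K | wild-type equilibrium | 10,000 | sets the scale |
| a | density scaling | solved | closed form per family/mode |
| b | compensation strength | 0.5 / 1 / 2 | under/perfect/over |
| s_a, s_b | homozygous construct cost | 0 | in [0, 1] |
| h_a, h_b | dominance of the cost | 0.5 | in [0, 1] |

Calibration solves $f(K) = \mu/r$ (births) or $f(K) = r-\mu$ (deaths);
all six combinations invert in closed form, e.g. MSS births
$aK = (r/\mu - 1)^{1/b}$, Hassell deaths $aK = e^{(r-\mu)/b} - 1$.
With default rates every calibrated model has per-capita growth exactly
1/day at vanishing density and 0 at $K$; under other rates (sensitivity
scenarios) $a$ is re-solved for the same $K$ and only the zero at $K$
is guaranteed.

## Release protocol and outcome metrics

Wild type starts exactly at $K$ and integrates a 10-generation burn-in
(a settling check, since $K$ is already the fixed point); AABB
homozygotes are then added instantaneously at `release_ratio` (default
1.0) times the current wild-type density; integration continues for a
200-generation horizon. One generation is fixed at 10 days — the mean
adult lifespan $1/\mu$ at default rates — and exposed as
`generation_length`. Equilibrium outcomes and establishment thresholds
are invariant to this convention; absolute return times in generations
are not, but *ratios* of return times between scenarios are.

Outcomes, read from once-per-generation samples after release:

- **final total** and **final drive-carrying** density at the horizon;
- **establishment**: drive-carrying frequency ≥ 0.99 at the horizon
  (`established`), ≤ 0.01 (`lost`), otherwise `undetermined`. The 0.99
  / 0.01 band is a robustness choice against numerical tails; borderline
  runs are reported as `undetermined`, never forced;
- **wild-type return time**: first whole generation after release at
  which wild-type density re-exceeds $0.99K$, having dipped to or below
  it earlier; 0 if it never dipped; censored (None) if it never
  recovers within the horizon — in particular whenever the drive fixes.

## Numerics

Classical fixed-step RK4 at `dt = 0.1` day (protocol validation caps
`dt` at a tenth of a generation). A fixed step keeps trajectories
bit-reproducible, which the CLI exploits to guarantee byte-identical
CSV output; there is no randomness anywhere in the model. Truncation
error can push a density that is decaying to zero slightly negative;
components are clamped to 0 and the largest clamp magnitude is recorded
on the trajectory (tests assert it stays below $10^{-6}K$). Integration
aborts with a diagnostic naming the generation and step if any density
exceeds $10^3 K$ or becomes non-finite. An empty population maps to
zero offspring and zero derivatives. The integrator broadcasts over a
batch axis of fitness vectors, so a whole scan sharing one ecology
integrates in a single pass; batched and individual runs agree to
machine precision (tested).

## Why the establishment threshold is genetics-only

Writing $p_i = N_i/N$, the frequency dynamics of the full model reduce
to the replicator-type system
$\dot p_i = q_i(p)\,\psi_i - p_i \sum_j q_j(p)\,\psi_j$
(with $q(p)$ the panmictic offspring frequencies): under death-acting
density dependence $f$ cancels exactly, and under birth-acting density
dependence $r f(N)$ is a positive factor that only rescales time.
Establishment versus loss is a basin question about this reduced
system, which is why the s- and h-thresholds are identical across all
18 density configurations and all ecological scenarios.
`frequency_dynamics_establishment` integrates the reduced system
directly and reproduces the full model's thresholds exactly (0.24/0.25
in s at h = 0.5; 0.59/0.60 in h at s = 0.23). A second, deliberately
cruder oracle (`discrete_generation_establishment`) iterates the same
genetics as a discrete-generation map; being a different dynamical
system it places the s-threshold one 0.01 grid step lower and the
h-threshold a few steps lower — useful as an independent sanity check,
not as ground truth for the continuous model.

## Design choices where the design was open

- **Gamete-pool construction** of the cross table instead of an
  explicit 81-pair mating sum: fewer terms, same algebra (the pair sum
  survives as a test oracle).
- **Release as a state jump**, not a birth pulse: a released cohort of
  adult homozygotes is an instantaneous addition to the state.
- **No adaptive stepping**: reproducibility is worth more here than
  step-size economy; the dynamics are smooth and non-stiff at the
  default scales (dt-halving changes final states by < $10^{-4}K$).
- **Near-threshold suppression readings** are evaluated at the largest
  *establishing* grid value of s (0.24 under defaults).
- At the largest establishing cost with $h = 0.5$ the final population
  is not pure AABB: because one wild-type allele at a locus costs less
  than two ($1 - hs > 1 - s$) while wild-type homozygosity at a single
  locus is lethal in a drive background, heterozygotes enjoy a marginal
  advantage and a small Aa/Bb load persists at the horizon. Final
  totals therefore sit somewhat above the pure-AABB equilibrium one
  would compute by setting $\psi_{AABB}$ in the single-genotype
  equilibrium condition.

## What the experiments assume, and limits

Scans (`scan_s`, `scan_h`, `heatmap_asymmetric`,
`sensitivity_scenarios`) run the full release protocol per grid point;
published-scale grids are 0.01-step (s, h, s_a) and 0.1-step (cost
ratio), and every experiment accepts a coarser grid and the
`FAST_PROTOCOL` (100-generation horizon) where full convergence is not
the point. The test suite and the reproduction script mostly use the
full 200-generation horizon with 0.01-step grids around thresholds and
coarser grids elsewhere; the cross-configuration threshold check probes
the two bracketing grid values (0.24, 0.25) in all 18 configurations
rather than re-running full scans.

The model is deliberately generic and omits: spatial structure and
migration (so no recolonisation or "chasing" dynamics), stochasticity
and drift (densities are real-valued; an "established" call at
frequency 0.99 says nothing about extinction risk of small real
populations), age/stage structure, time-lagged density dependence (so
overcompensating dynamics cannot oscillate), Allee effects, and
predation-shaped (concave-down) feedbacks. Sex structure is absent by
construction. Conclusions about *which* competition family a real
vector population follows are outside the model: the package's value is
exactly that it lets all six forms be swapped under one genetic system.
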