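# Methods

## Model

The simulator treats a chromosome as a 1D lattice of base pairs. `N` LEFs
(default 20 per Mbp, minimum 1 per chromosome) cycle between an inactive
pool and chromatin. An active LEF is a pair of extrusion units at positions
`rev ≤ fwd`; the interval between them is its loop. Each epoch proceeds as:
bind inactive LEFs at uniform positions (both units collapsed, loop 0);
index units in genomic order; sample contacts from a random subset of
active LEFs; draw candidate strides; advance every barrier's two-state
Markov chain; detect and resolve LEF–barrier and LEF–LEF collisions;
advance units; release LEFs by a Bernoulli trial.

**Barriers.** A barrier is (position, blocking direction, π_B, P_UU); P_BB
is derived from the stationary condition
π_B = (1−P_UU)/((1−P_UU)+(1−P_BB)). A (π_B, P_UU) pair is feasible iff
π_B ≥ (1−P_UU)/(2−P_UU). The algebra functions raise on infeasible pairs,
naming the feasible range; barrier *objects* clamp P_BB to 0 instead,
because optimizer-proposed genotypes roam the whole unit square and must
still be simulable (their realized occupancy is then higher than the
genotype requested — the optimizer sees that through the fitness, not
through an exception). Only Bound barriers block, only in their blocking
direction ('+' strand blocks reverse-moving units); Unbound barriers are
fully transparent. π_B = 0 forces Unbound forever.

**Movement and collisions.** Strides are truncated-normal, mean
`mean_stride` (default = bin size, 5 kbp), SD 5 % of the mean, rounded to
integer bp. The collision semantics are *defined* by a 1-bp micro-stepping
process: all units advance simultaneously 1 bp per tick (visited in genomic
rank order within a tick; stride budget is spent only on actual movement);
a unit never steps onto a bound blocking barrier (it ends 1 bp short), never
leaves the chromosome (ends clamp at 0 and length−1), and never passes or
lands on another LEF's unit. Consequences: two approaching units end up
adjacent, splitting the remaining gap with the odd base pair going to the
unit first in genomic order; a unit blocked by an already-stalled unit
queues behind it; the two units of one LEF never cross (loop ≥ 0). The
production resolver computes the same outcome in closed form — barrier caps
by binary search, primary meeting points for approaching pairs, then one
right-to-left sweep for forward units and one left-to-right sweep for
reverse units — and is numba-compiled. The test suite asserts exact
equivalence (positions and stall causes) against the micro-stepping oracle
on hundreds of randomized small systems.

Stall causes are tracked per unit (none / barrier / LEF–LEF / chromosome
end). A LEF whose two units are both *barrier*-stalled is hard-stalled by a
convergent bound pair and its release probability is divided by
`hard_stall_lifetime_multiplier` (default 5). Chromosome-end stalls count
as their own category and do not trigger the hard-stall bonus, since the
biology attributes extended cohesin residence to CTCF pairs, not telomeres.

**Release.** The base per-epoch release probability is
p = 2·mean_stride / processivity (default processivity 200 kbp, so p = 0.05
and the mean lifetime is 20 epochs, geometric).

**Contacts.** Each epoch every active LEF is sampled independently with
probability `contact_sampling_fraction` (default 0.025). A sampled LEF
registers one loop contact at (rev, fwd) and, on average,
`tad_to_loop_contact_ratio` (default 1.0) intra-TAD contacts at positions
drawn uniformly (with replacement) inside the loop; loop-only and tad-only
modes expose the two channels separately. The sampling fraction is not
stated by the source material for this model family; 0.025 keeps the
per-epoch sampling sparse enough that successive contacts from one LEF are
nearly independent snapshots while still terminating a default density-1
run in a few hundred epochs per cell.

**Burn-in.** Contact-free epochs with progressive binding: 1/⌈mean
lifetime⌉ of the LEFs activate per epoch until all are placed. Afterwards
the windowed mean loop size is monitored (window 16 epochs): burn-in ends
when the signed relative change between consecutive windows drops below 1 %
— a one-sided criterion, i.e. "the mean loop size has stopped growing" —
or at a hard cap of 5 000 epochs. A one-sided test is used because at
steady state the between-window difference is symmetric noise, so the
criterion fires almost immediately once growth ends, whereas a two-sided
band on noisy window means would essentially never be satisfied for
realistic LEF counts.

**Stopping.** By default a run ends when the aggregate matrix reaches a
target mean density of 1 contact per band pixel (each of the `ncells`
instances, default 512, carries an equal share of the contact budget);
alternatively a per-cell epoch budget can govern termination.

**Determinism.** Every (chromosome, cell) task derives its RNG from
`SeedSequence([master_seed, crc32(chrom_name), cell_index])`. Matrices are
merged by integer addition, so results are bit-identical for any worker
count and scheduling order.

## Contact matrix and cooler I/O

Counts are stored as a dense band `[band_rows × nbins]` of unsigned ints,
with pixel (i, j), i ≤ j, at `(j−i, i)`; memory is linear in chromosome
length. Increments beyond the band (|i−j| ≥ band_rows, half-open) are
dropped and tallied. Coolers are single-resolution, storage-mode
symmetric-upper, written and read directly through h5py following the
cooler schema (format-version 3, enum-typed bin chrom column,
chrom_offset/bin1_offset indexes); a private root attribute records the
diagonal width so round-trips restore the band geometry exactly.
Multi-resolution ("zoomify") output, balancing weights and
inter-chromosomal pixels are out of scope.

## Matrix comparison

All scoring operates on the band image, whose column *i* is exactly the
vector of pixels starting on the diagonal at bin *i* and extending along
matrix row *i* (the anti-diagonal gives matrix column *i*). The transform
is a difference of Gaussians, σ₁ = 1.0 and σ₂ = 1.6 pixels, computed with
reflect padding on the band, followed by a step function (≥ threshold → 1;
ties map to 1). Reference (experimental) matrices are conventionally
thresholded at 1.5 and simulated matrices at 0.75. The stripe end of a
vector is its last non-zero pixel; two matrices agree on a row (or column)
when the stripe ends coincide, with both-empty counting as agreement —
penalizing correctly empty regions would reward spurious stripes. Pixel
accuracy is measured over the union (deduplicated) of subdiagonal windows,
3 Mbp by default, centered on barrier bins. Per-diagonal Pearson
correlations report NaN on constant diagonals.

## Parameter optimization

**Genome-wide (uniform parameters).** The objective simulates the genome
with every barrier at the proposed (π_B, P_UU), transforms and discretizes
the result, scores it row- and column-wise against the pre-transformed
reference, intersects row scores with horizontal-stripe intervals and
column scores with vertical ones, and returns the mean mismatch (lower is
better); infeasible pairs short-circuit to the maximal score 1.0. The same
simulation seed is used for every call, so the objective is a deterministic
function of the parameters. Minimization is sequential model-based: a
Matérn-5/2 Gaussian process with a small white-noise term, expected
improvement maximized over a 512-point random candidate cloud, 10
space-filling initial points, and a 5 % random-exploration rate. Equal
lower/upper bounds pin a dimension, which is how occupancy can be fitted at
a known P_UU. Training/validation stripe splits are seeded halves; the
validation score is logged per call but never influences the search.

**Per-barrier (evolution strategy).** Genotypes are two length-N vectors
(π_B and P_UU per barrier). The mainland runs a (μ, λ) ES — μ = 256,
λ = 512 by default; offspring replace the population entirely and the top μ
survive (stable sort for ties) — with two-point crossover on the
concatenated genotype and clamped Gaussian mutation. The fitness of a
genotype is the mean over barriers of f·p(π_B), where f is the average of
the row- and column-mismatch indicators at the barrier's bin and p is a
penalty in [1, 2]:

    p(x) = min(2, 1 + exp(−(x−0.5)² / (2·0.12²)) + 0.5·exp(−(x−1)² / (2·0.02²)))

p is ≈2 at x = 0.5, falls steeply toward 1 at both extremes, and adds a
narrow bump at exactly 1 (permanently bound barriers are implausible). The
functional form is this package's own choice satisfying those qualitative
constraints; the width 0.12 makes the penalty negligible outside roughly
[0.2, 0.8], where the stripe score itself carries signal, and the 0.02 bump
penalizes only the top few percent. Stopping: 1 000 generations, < 1 % best
-fitness improvement over the last 25 generations, or mean per-gene
standard deviation below 10⁻³. After mainland convergence, m islands
(μ = 128, λ = 256) are seeded by sampling with replacement from the hall of
fame; each island masks k = round(𝒩(25, 5)) consecutive barriers (set
inactive, not mutable), except one island that instead replaces every weak
allele (π_B < 0.5) with (π_B = 0, P_UU = 1) and leaves all loci mutable.
Fitness-proportionate draws from the island populations then replace half
the mainland, and the alternation repeats until the cycle budget or
stagnation. Fitness evaluations are memoized on the rounded genotype.

## Synthetic data

The fixtures module generates chrom.sizes files, convergent '+'/'−' barrier
pairs (default spacing: pairs evenly spread, 200 kbp span — a typical
mammalian sub-TAD, and commensurate with the 200 kbp default processivity),
stripe annotations anchored at barriers ('+' → horizontal, '−' →
vertical), and self-referential reference coolers produced by the engine
itself at known parameters with a JSON sidecar. Everything is
byte-deterministic given the seed. What the generator does *not* emulate:
random-polymer background contacts, compartmentalization, distance-decay
beyond what extrusion itself produces, experimental noise, or
chromatin-state heterogeneity between cells. Tests passing on these
systems therefore demonstrate the internal correctness of the simulator and
the optimizers' ability to invert it — not that fitted parameters from real
Micro-C data are biologically accurate.

## Scaled-down experiment sizes

The test suite and the acceptance script run everything on synthetic
systems sized for a single CPU: the default-configuration stopping-rule
check uses one 5 Mbp chromosome with 4 convergent pairs and the full 512
cells; optimizer-recovery experiments use 0.8–3 Mbp systems with 4–128
cells and elevated contact densities (4–8 per pixel) so that the
discretized stripe pattern is statistically stable — the stripe-end metric
compares exact indices, so with only a handful of stripes the objective is
informative only once per-pixel noise is well below the discretization
threshold. These sizes are configuration, not code paths. In the Bayesian
recovery experiment P_UU is pinned at its generating value: the 2D problem
is genuinely degenerate (a ridge of dynamically near-equivalent
combinations trades higher occupancy against lower binding stability, as
the genome-wide optimization surface itself shows), so point recovery of
occupancy is only well-posed with the second parameter constrained.

## Known limitations

* Contacts are intra-chromosomal only; no 3D polymer mechanics, so
  long-range compartmental signal is absent and distance decay is flatter
  than experiment.
* One extrusion speed and one barrier model genome-wide; no
  chromatin-state-dependent binding.
* Counts are unsigned; subsampling a finished matrix to a lower density is
  left to external cooler tooling.
* The GA clamps infeasible (π_B, P_UU) genotypes to P_BB = 0 rather than
  repairing them; the penalty and fitness handle the consequences.
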