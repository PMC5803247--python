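# Methods

## Signal model and coordinates

PRO-seq signal is represented at single-base resolution per chromosome and
strand: the count of nascent-RNA 3′ ends (the last base incorporated by an
engaged polymerase) at each position.  All coordinates are 0-based
half-open internally and in bedGraph; GFF3 is converted from 1-based
closed on input.  Minus-strand bedGraph values are accepted as positive or
negative magnitudes and stored as magnitudes.  Gene-relative offsets
follow one convention throughout: “+n” is n bases downstream of the
anchor (TSS or CPS) along the gene's strand, intervals half-open at the
downstream edge.

Libraries are normalized by a spike-in scalar: factor = spike-in mapped
reads / 10⁵, normalized signal = raw / factor.  Replicates are combined by
summing raw counts and spike-in reads, so the combined library is the
depth-weighted pool.  Differential tests consume raw counts and receive
the factors as size factors instead.

## Two-population kinematic generator

The generator emulates transcription as a conveyor belt: initiation rate r
and elongation speed v give steady-state density ρ = r/v, so slowing
polymerases raises local PRO-seq density at constant initiation.  Under
simulated inhibition with checkpoint offset c from the TSS, the expected
density at time t is piecewise along each gene:

| segment (bp from TSS)        | density                              | population |
|------------------------------|--------------------------------------|-----------|
| [0, v_slow·t)                | ρ·v_ref/v_slow                       | slow, post-inhibition |
| [v_slow·t, c + v_slow·t)     | ρ                                    | pre-inhibition, pre-checkpoint |
| [c + v_slow·t, c + v_fast·t) | background                           | cleared zone |
| [c + v_fast·t, CPS]          | ρ                                    | fast, ahead of the clearing wave |

A promoter-proximal pause peak (height × ρ over the first
`pause_peak_width` bases) persists additively in every condition, and an
exponential termination decay past the CPS scales with the density
reaching the CPS; both choices make the t = 0 profile equal the untreated
one exactly.  Counts are Poisson per base (a gamma-Poisson
negative-binomial mode with dispersion α exists to exercise the
differential test), scaled by each library's spike-in factor.  A single
master seed feeds deterministic per-sample streams keyed by condition,
timepoint, and replicate.

Default parameters (the study conditions used by the tests and the
acceptance script): 40 genes of 6–8 kb on two 250-kb chromosomes,
v_slow = 400 bp/min, v_fast = 1200 bp/min, checkpoint c = 500 bp,
body density ρ = 0.25 reads/bp, pause peak 10× over 50 bp, background
0.01 reads/bp, termination decay 300 bp, timepoints
{0, 0.5, 1, 2.5, 5} min, two replicates at 10⁵ spike-in reads.  The
pre-inhibition reference rate v_ref = 2000 bp/min is an assumption
anchored to the canonical budding-yeast elongation-rate scale; no
measured fission-yeast pre-inhibition rate backs it, and it only sets the
5′ density elevation, not the recovered rates.  Genome-wide signature
checks use a second cohort with a genome-like length mix (1–6.5 kb,
most genes short) because those signatures genuinely depend on the length
distribution — see “What the generator does not emulate”.

`GroundTruth` records per gene and timepoint the kinematic wave front
min(v_slow·t, L) and clearing start min(c + v_fast·t, L), both
non-decreasing in t, as the recovery targets.

## Gene filtering

* **Observed TSS**: argmax of background-subtracted PRO-cap signal within
  ±250 bp of the annotated TSS, required to exceed the background by more
  than 4 normalized reads (strict inequality).  PRO-cap background is
  estimated from the same intergenic region set as the activity filter and
  scaled to the PRO-cap library — the one background concept, consistently
  library-scaled.  Argmax ties break toward the base nearest the original
  annotation, then upstream (least-change rule).
* **Activity**: p = P(X ≥ k), X ~ Poisson(λ·L), for the raw gene-body
  count k over length L (observed TSS through CPS, promoter included —
  the body is not promoter-subtracted here, a documented and configurable
  choice); λ is total raw reads in intergenic background regions divided
  by strand-bp.  Active iff p < 0.01.
* **Read-through**: normalized signal in +250..+550 must strictly exceed
  −300..TSS; equality fails.

Intergenic background regions default to the annotation complement with
500 bp buffers; a BED file can override them.

## Differential regions

Regions: promoter TSS..+100, early +150..+450, late CPS−300..CPS, counted
for genes > 800 nt so regions cannot collide.  The test is an
own-implementation negative-binomial Wald contrast — a documented stand-in
for the standard NB-GLM workflow, with spike-in size factors supplied
externally exactly as that workflow accepts them.  Per gene-region,
counts K ~ NB(mean s_j·q·2^(β·x_j), dispersion α).  α is estimated by
method of moments from *within-condition* residuals of size-factor-scaled
counts, then shrunk (geometric mean) toward a mean-dispersion trend
α(μ) = a₁/μ + a₀ fitted across all gene-regions; single-replicate designs
fall back to the trend alone.  The Wald statistic is the log fold change
of ε-stabilized scaled group means over its delta-method standard error,
with the NB variance evaluated on the scaled scale — this makes results
exactly invariant when one sample's counts and spike-in reads move
together.  The reference is normal (the dispersion is stabilized
genome-wide, so per-row degrees of freedom do not govern the statistic);
BH correction and calls at adjusted p < 0.01.  No fold-change shrinkage:
calls, not effect-size ranking, are the purpose.  Exact numerical parity
with any particular NB-GLM implementation is not claimed; null
calibration (BH-adjusted call fraction ≤ nominal on β = 0 simulations)
and directional agreement on fixtures are the tested contract.

## Wave HMMs

Observations are treated−untreated normalized signal in 50-bp windows:
from −500 bp (10 upstream windows) through the gene for the advancing
variant, from the TSS for the clearing variant.  Both variants use a
three-state strictly left-to-right chain (1→2→3, no skips, initial state
1).

* Advancing: state 1 normal (initialized from the upstream windows),
  states 2–3 gamma.  Wave front = downstream edge of the last state-2
  window, in bp from the TSS.
* Clearing: all three states gamma; state 1 initialized from the first
  1000 nt downstream of the TSS, state 2 the cleared trough, state 3 the
  unaffected tail.  The call is the state-2/3 boundary (the start of the
  clearing wave).  Window values are first clamped at |z| ≤ TSmooth = 5
  standard scores to restrain outlying windows.

Gamma emissions on differences (which can be negative) are evaluated on
values shifted by the per-gene minimum minus a small margin
(5% of the range, floor 10⁻³); the shift is fixed before fitting and
recorded, hence invertible.  Fitting is Baum–Welch with exact weighted
MLE M-steps (normal: weighted mean/variance; gamma: Newton solve of
log k − ψ(k) = log ȳ − log-bar-y from Minka's starting point), so the
log-likelihood is non-decreasing every iteration; tolerance 10⁻⁶
relative, max 200 iterations, emission variance floor 10⁻⁸.  Viterbi ties
break toward the earliest state transitions (conservative, shorter
distances); an exhaustive path-enumeration oracle (≤ 14 windows) checks
the decoder exactly.  Call quality requires EM convergence and
KL(state 2 ‖ state 3) > 1 by the gamma closed form; the same gate is
applied to both variants, the single principled criterion available.
Series filtering keeps genes with quality-passing calls at every
timepoint whose distances never decrease.  Length gates: > 4 kb
(advancing, all timepoints to 5 min), > 6 kb (clearing, timepoints
≤ 2.5 min — the cleared trough has usually run off shorter genes, and by
5 min off even the longest).

Approximate initial wave distances seed the emission split.  On real
data these are supplied per timepoint (the printed defaults of the
original analyses are RunConfig's defaults); on synthetic cohorts the
default is a cohort-level least-squares changepoint scan of the windowed
differences (two segments for advancing, three for clearing; cohort
median in bp) — the in-silico analog of eyeballing fold-change heat maps.
EM re-estimates emissions, so the init only needs to be on the right
side of the basin.

## Rates

The headline rate is the pooled OLS slope of distance (bp) on time (min)
over every retained gene×timepoint call, intercept included — forcing the
origin would bias the slope whenever the wave has a positional offset
(the clearing wave starts at the checkpoint, not the TSS; its fitted
intercept on synthetic data indeed recovers ≈ c).  A through-origin
toggle exists.  Uncertainty: (i) bootstrap — each of 1000 replicates
draws ⌈10% of genes⌉ with replacement and refits the pooled slope;
(ii) the per-gene OLS slope distribution (mean, SD).  Population
comparison reports the pooled-slope difference, a Welch t on per-gene
slopes, and a bootstrap-overlap p when both distributions are attached;
no claim is made about which single test is canonical.

## What the generator does and does not emulate

It emulates: single-base 3′-end count statistics with intergenic
background, pause peaks, plateaus and termination decay; spike-in library
scaling; the two-population kinematics with sharp fronts; replicate
structure.  It does not emulate: sequence content (no reads/FASTQ),
gene-to-gene expression variability (all genes share ρ), front
stochasticity or diffusion (fronts are deterministic given t), antisense
or bidirectional transcription, or overlapping genes.  Passing recovery
tests therefore shows the estimators are correct under the stated
kinematics and count noise — not that real data meet those assumptions.
Directional signature tests (PI shift, early-up/late-down patterns) are
length-mix dependent: on a genome-like mix the slow wave spans most of a
typical body and PIs drop genome-wide, while on a long-gene-only cohort
the promoter window's own elevation can outweigh the body's, so the
genome-wide checks run on the mixed cohort by design.

## Degenerate inputs and numerical choices

Zero-variance emission segments hit the variance floor and are flagged;
all-zero difference vectors fit but fail the KL gate (no wave).  Genes
too short for three windows, regions off the chromosome end, inverted
intervals, zero/negative spike-in counts, λ ≤ 0, and empty gene sets all
raise with the offending object named.  Windows truncated at chromosome
ends are excluded from sums and densities with a warning.  ε for log₂
fold-change bins is 0.5 normalized reads (configurable); the
termination-zone width uses fraction f = 0.25 of the CPS-proximal level
over a 1-kb window by default, both exposed because no canonical
definition exists.  The activity test's body bounds and the PI body
(+100..CPS, the non-overlapping complement of the promoter window) are
likewise configurable with these defaults.

## Problem sizes

Tests and the acceptance script run cohorts of 40–48 genes on toy
genomes of ≤ 0.5 Mb, 200-instance decoder-oracle sweeps, and
5000-gene null simulations; these sizes give stable statistics for every
check while keeping a full run in the tens of seconds.
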