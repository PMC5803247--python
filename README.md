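# polwave

Analysis of RNA polymerase II elongation dynamics from spike-in-normalized
PRO-seq time courses, built around the signatures of a kinase-dependent
early-elongation checkpoint in fission yeast: after rapid Cdk9 inhibition,
Pol II that has not yet passed a promoter-proximal checkpoint advances
slowly (an **advancing wave** of elevated signal spreading from the TSS),
while Pol II already past the checkpoint runs ahead at its normal speed
(a **clearing wave** that leaves a transient trough of depleted signal).
`polwave` turns strand-specific single-base 3′-end coverage tracks into
wave calls and elongation-rate estimates, and ships a synthetic-data
generator with known ground truth so every stage is verifiable without any
external download.

Intended users: groups analysing nascent-transcription run-on data
(PRO-seq/GRO-seq with PRO-cap TSS maps) who need pausing metrics,
spike-in-aware differential region tests, and wave-based elongation-rate
estimation in one tested Python package.

## What it computes

* **Gene set** — observed TSSs re-annotated as the argmax of
  background-subtracted PRO-cap signal within ±250 bp of the existing
  annotation (requiring > 4 normalized reads over background); activity
  filtering by a Poisson upper-tail test of gene-body counts against the
  intergenic background density λ (p < 0.01); removal of genes whose
  upstream window (−300..TSS) carries at least as much signal as
  +250..+550 (read-through).
* **Pausing index** — PI = density(TSS..+100) / density(+100..CPS) on
  normalized signal, with quartiles, log₁₀ CDFs, and a two-sample KS test.
* **Profiles and fold changes** — TSS/CPS-anchored composite profiles and
  log₂((treated+ε)/(untreated+ε)) matrices in 10-bp bins over −250..+4000.
* **Differential regions** — raw counts in promoter (TSS..+100), early
  (+150..+450) and late (CPS−300..CPS) regions for genes > 800 nt; a
  negative-binomial Wald test with spike-in size factors
  (spike-in mapped reads / 10⁵) and Benjamini–Hochberg correction, calls
  at adjusted p < 0.01.
* **Wave calls** — per-gene treated−untreated signal in 50-bp windows fed
  to three-state strictly left-to-right HMMs fitted by Baum–Welch and
  decoded by Viterbi.  Advancing variant (genes > 4 kb; normal upstream
  state, gamma wave/body states): the wave front is the downstream edge of
  the last state-2 window.  Clearing variant (genes > 6 kb, timepoints
  ≤ 2.5 min; all-gamma, TSmooth = 5 outlier clamping): the call is the
  state-2/3 boundary.  Quality requires KL(state 2 ‖ state 3) > 1 and EM
  convergence; gene series must be called at every timepoint and never
  recede toward the TSS.
* **Rates** — pooled OLS of wave distance (bp) on time (min); uncertainty
  from a 10%-of-genes × 1000-replicate bootstrap and from the per-gene
  slope distribution; Welch comparison of the two populations.

The synthetic generator implements the two-population kinematics with
conveyor-belt density ρ = r/v: at time t the expected profile is elevated
to ρ·v_ref/v_slow over [0, v_slow·t), unchanged up to the checkpoint
offset, cleared to background over [c+v_slow·t, c+v_fast·t), and
unaffected beyond, with Poisson (optionally negative-binomial) counts and
per-library spike-in scaling.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (seed 1; outputs under `results/`):

```
$ python analysis/01_simulate_timecourse.py
wrote 40 genes (6009-7966 bp) and 13 libraries to results/data
$ python analysis/02_filter_genes.py
input genes:        40
with observed TSS:  40
active (p < 0.01):  40
read-through clean: 40
final analysis set: 40
$ python analysis/05_call_waves.py
advancing: 40/40 gene series retained
clearing:  40/40 gene series retained
$ python analysis/06_estimate_rates.py
advancing: 400 bp/min (bootstrap 95% CI 400-400, n=40 genes)
clearing: 1200 bp/min (bootstrap 95% CI 1181-1213, n=40 genes)
clearing - advancing = 800 bp/min (Welch p = 5.76e-71)
```

The recovered slopes match the generator's true rates (400 and
1200 bp/min): the advancing calls land exactly on window boundaries at
this noise level, and the clearing boundary tracks checkpoint + v_fast·t.
The same stages run on real data prepared in the same layout (bedGraph
pairs + sample sheet + BED6 genes + chrom.sizes), either through the
stage functions or the `polwave` CLI (`polwave all --config run.yaml`).

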