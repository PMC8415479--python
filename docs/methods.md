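# Methods

`fcthresh` benchmarks algorithms that prune a functional connectivity matrix
(CM) estimated from spike trains down to the statistically significant links
(the functional matrix, FM).  Because real recordings never come with ground
truth, the benchmark is fully synthetic: structural networks with known
wiring are simulated, a CM is inferred from the emitted spikes, each
thresholding method prunes it, and the result is scored against the known
structure.  This note documents the models, the defaults and why they were
chosen, and what the synthetic benchmark does and does not establish.

## Structural network generators

All generators produce 500-neuron networks with 400 excitatory
(regular-spiking) and 100 inhibitory (fast-spiking) neurons and exactly
20,000 directed links (16,000 excitatory-sourced, 4,000 inhibitory-sourced)
at their defaults.  Excitatory neurons may target any other neuron;
inhibitory neurons target excitatory neurons only, so the three link blocks
are E→E, E→I and I→E.  Initial weights are drawn at generation time,
excitatory ~ N(7, 1) clipped to ≥ 0.1, inhibitory ~ N(−7, 1) clipped to
≤ −0.1 (the clip preserves the sign invariants).  Conduction delays are
integers, uniform on 1–20 ms for excitatory links and exactly 1 ms for
inhibitory links; delays are drawn independently per link (the alternative —
one delay per source neuron — is equally consistent with the model
description; per-link was chosen as the less degenerate option).

**Random (RND).** Every neuron projects to `out_degree` (default 40)
uniformly chosen distinct targets; in-degrees are then binomial,
approximately normal with mean 32 (excitatory sources) and 10 (inhibitory
sources onto excitatory targets).

**Small-world (SW).** The excitatory population forms an undirected ring
lattice with 20 neighbours per side (every link reciprocal).  Each
undirected lattice pair is rewired jointly with probability 0.3 to a
uniformly chosen partner, the standard Watts–Strogatz move applied to the
reciprocal pair rather than to each direction separately.  1,600 directed
lattice links (4 per excitatory neuron) are then *translated* onto
inhibitory targets, spread round-robin so every inhibitory neuron receives
at least one excitatory input — without this the inhibitory population can
never activate.  The inhibitory block is wired randomly.  The translation
count is a free parameter of the construction; 1,600 makes the generated
networks reproduce the published structural small-world index of the
benchmark networks (SWI ≈ 1.83; we measure 1.80 ± 0.02 over six seeds).
Fewer translations raise SWI (denser lattice), more dilute it.

**Scale-free (SF).** Out-degrees are drawn per population from a truncated
power law p(k) ∝ k^(−γ) on [`min_links_per_neuron`, k_max], with γ solved
numerically so the expected mean equals the 40-link budget; the draw is then
adjusted by unit steps to hit the total exactly.  Targets are re-drawn
uniformly per row (the "row shuffle"), which suppresses bidirectional pairs
and makes in-degrees binomial.  The result has power-law outgoing and normal
incoming degree distributions.  The default minimum of 5 links per neuron
(γ ≈ 1.8) makes the structural hub count — nodes whose total degree is at
least one SD above the mean — match the published characterization of the
benchmark's SF networks (49 ± 2; we measure 47 ± 4).  Larger minima give
lighter tails and fewer hubs.

**Modular.** Two excitatory modules of 175 neurons, one inhibitory module of
100, and 50 out-of-module excitatory neurons.  Links appear with probability
`intra_p` (default 0.25) within a module and `inter_p` (default 0.01)
elsewhere; the inhibitory module projects into the excitatory modules at
`intra_p` so inhibition remains effective.  The published source for this
configuration gives no quantitative parameters, so the defaults are a
plausible weakly-coupled regime; no quantitative claims are attached to this
generator and it carries no acceptance target.

## Spiking-network simulator

Izhikevich two-variable neurons (RS: a=0.02, b=0.2, c=−65, d=8; FS: a=0.1,
same b, c, d), integrated on a fixed 1 ms grid with the voltage equation
advanced in two 0.5 ms half-steps — the scheme of the reference
implementation of the delayed-STDP network model.  The 1 ms scheme
overestimates firing rates by O(10%) against a fine-step integration; this
bias is irrelevant here because the benchmark's claims are about structure
recovery, not exact rates.  A non-finite membrane potential aborts the run
with the failure time.

Synapses are pure delayed current pulses: a spike of i at t adds w_ij to
neuron j's input current at t + delay_ij.  Excitatory weights are plastic
(STDP: potentiation A₊ e^(−t/τ₊) with A₊=0.1, depression A₋ e^(−t/τ₋) with
A₋=0.12, τ₊=τ₋=20 ms) until `stdp_freeze_s` (default 300 s of a 900 s run)
and frozen afterwards; weights are clipped to [0, 10].  Pairing is
nearest-spike and delay-corrected: potentiation uses the last presynaptic
*arrival* before the postsynaptic spike; depression is applied when a
presynaptic spike is scheduled, against the target's most recent spike.
(The model description does not fix the pairing scheme; nearest-spike online
updates are the conventional choice.)  Under spontaneous activity the
excitatory weights settle into the expected bimodal distribution.

Noise drive, default "kick" mode: each millisecond, `noise_rate` uniformly
chosen neurons (default 1) receive a current kick of amplitude 20 — the
convention of the cited polychronization-style model.  A per-neuron Gaussian
current mode (`noise_model="gaussian"`, σ default 5) is also available; the
published description states only that the noise is seeded and
Gaussian-process-like, so the mode and amplitude are recorded in the run
metadata.  In the degree sweep the kick rate is raised for sparse networks
(`noise_rate = max(1, (40/k)²)`), mirroring the benchmark's stated practice
of tuning the model so mean firing rates do not differ across
configurations; without it, k=30 networks fire at ~2 Hz and every estimator
starves.

## Spike statistics

Mean firing rate is total spikes / duration / N.  Bursts are maximal runs of
≥ 3 spikes with consecutive ISIs ≤ 100 ms followed by a quiescent gap
> 100 ms (string-method convention; the intra-burst ISI ceiling is exposed
as a knob since only the quiescence criterion is fixed by the source).  A
qualifying run at the recording's end counts as a burst, avoiding censoring
bias.  Mean bursting rate is bursts/minute/neuron; burst duration is the
mean extent of all bursts.  Because the noise model is fixed only in form,
published point values of MFR/MBR/BD are treated as qualitative bands, not
reproduction targets.

## Connectivity estimation

The default estimator is a baseline-corrected delayed cross-correlogram.
Spike trains are binned at 1 ms; for each ordered pair the correlogram
counts C_l are computed for |l| ≤ 50 ms via sparse matrix products.  The
per-lag baseline is a partially hollow local average (mean over the
surrounding ±12 lags, central ±2 excluded).  This is the critical numerical
choice: network bursts impose broad, roughly symmetric correlation across
all lags, and any *global* baseline (total mean or median) leaves that
co-modulation in the signal — with a global baseline the brief inhibitory
suppression is invisible (we recovered ~30 of 4,000 inhibitory links; with
the hollow local baseline, ~3,000).  A monosynaptic excitatory link appears
as a sharp one-bin excess at its fixed delay; an inhibitory link as a 2–4 ms
deficit at short lags.  The summary value is the dominant signed deviation
over causal lags 1–25 ms, normalized by the geometric mean of the two spike
counts.  Lag 0 is excluded (no direction), the diagonal is zero, silent
neurons give zero rows/columns.  An `"excitation"` mode scores excesses only,
for networks known to contain no inhibitory population.  The estimator is a
front-end: the thresholding stage needs only a signed matrix, and any other
estimator (e.g. a TSPE implementation) can be substituted.

The null distribution of the statistic (independent trains) is symmetric in
sign frequency and small in magnitude when per-bin expected counts are ≳ a
few; at very low counts (< ~1 per bin) discreteness skews it positive.
Benchmarks therefore use recordings long and active enough to stay in the
calibrated regime.

## Thresholding methods

All statistics use sample SDs (n−1); both thresholds are strict
inequalities.

**Hard threshold (HT).** Keeps positive entries > μ_exc + n_exc·σ_exc and
negative entries < μ_inh − n_inh·σ_inh, statistics over the nonzero entries
of each sign.  Defaults n_exc=1, n_inh=2.

**Double threshold (DDT).** Step 1 applies HT, yielding the kept matrix
T1CM and the rejected matrix RM.  Step 2 computes, for every nonzero RM
element ij, a second threshold from the *other* nonzero entries of RM's row
i: Th = μ + m_exc·σ (excitatory candidates) or μ − m_inh·σ (inhibitory),
defaults m_exc=m_inh=3.  The row acts as a pseudo-surrogate null sample:
when most row entries are spurious, a true link stands out locally even
though it failed the global threshold.  Step 3 recovers the RM elements
beyond their row threshold (T2CM); step 4 returns FM = T1CM ∪ T2CM
(disjoint by construction).  Two open points are resolved as options:

* *Row statistics on mixed-sign rows* — `row_stats="split"` (default) pools
  only same-sign entries, keeping the null sample sign-consistent on large
  matrices; `"pooled"` uses all nonzero entries, needed when a sign-split
  row would be too short.
* *Small rows* — an element whose exclusion pool has fewer than
  `min_row_candidates` (default 5) entries is conservatively rejected; and
  when the pool has fewer than 5 entries the row SD is floored by a robust
  global scale (1.4826 × MAD of the corresponding RM entries).  A 2-sample
  SD can collapse to ~0 and both admit noise and reject signal; the MAD
  floor (robust to the few true links hiding in RM) fixes both failure
  modes on small matrices while leaving rows with ≥ 5 entries — i.e. the
  entire 500-neuron benchmark — governed by the pure row statistics.
* `signs="excitatory"` restricts both steps to the positive side for
  networks with no inhibitory population.

**Density threshold (DT).** Keeps exactly the M_e strongest positive and
M_i most-negative entries; ties at the cut resolved in row-major order for
determinism.  In benchmarks M_e/M_i are calibrated to the DDT result of the
same realization, so the two methods always return identical link counts.

**Shuffle threshold (SH).** For each ordered pair, a null distribution of
estimator values is built from `n_shuffles` surrogate copies of the target
train (times redrawn i.i.d. uniform, spike count preserved); an entry is
kept when its one-sided z-score against that null exceeds the critical
value at α (default 0.01 per sign).  The z-test inherits the stated
normality assumption; because the estimator is extremum-based its null is
not Gaussian, and the test is conservative in the adequate-count regime
(measured false-positive rate below the nominal α on independent Poisson
trains).  The surrogates are computed as whole cross-matrices per shuffle,
so the cost is `n_shuffles` × one estimation pass.

## Topology metrics

Graphs are binarized and symmetrized (edge if either direction present) for
clustering, path length and SWI — the clustering pair-count denominator is
undirected, and structural and functional graphs must be compared on the
same footing.  C_i = links among neighbours / (k_i(k_i−1)/2), with C_i = 0
for degree < 2; L is the mean shortest-path length over reachable ordered
pairs, with the unreachable fraction reported.  SWI = (C/C_rand)/(L/L_rand)
with the reference values averaged over 20 degree-preserving rewirings
(igraph edge swaps); 20 references keep the ensemble spread below the
published ±0.01 SWI resolution.  Hubs are nodes with total (in+out) degree
≥ mean + 1 SD (the degree flavour is a knob).  Degree distributions are
fitted either as scaled Gaussian densities on unit-bin histograms
(`curve_fit`, moment-based fallback if the optimizer fails) or as power laws
by linear regression of log-frequency on log-degree — on exact unit bins
when the support is dense (no binning bias), on ~10-per-decade logarithmic
bins otherwise (an empirical sparse tail of singletons otherwise flattens
the fit).  Survival-function (cumulative) fitting is available for both
families.

## Evaluation

Every ordered off-diagonal pair is classified by sign into excitatory /
absent / inhibitory in both the output and the target, giving a 3×3
confusion matrix.  Accuracy is the trace over all N²−N classified pairs.
The printed form of the accuracy formula omits the true-negative count from
the denominator, which would allow values above 1; the all-pairs denominator
is the only reading consistent with the reported accuracies and is used
throughout.  Missed links are pooled as false negatives regardless of sign,
matching the printed formula.

## Benchmark scales and what the tests show

The full published evaluation uses 15-minute recordings and up to 90
networks per topology.  The package's acceptance runs are scaled down to
run on one CPU in minutes: 360 s simulations (60 s plasticity + 300 s
frozen-weight recording), one realization per degree value in {30, 40, 50},
and six seeds for the structural ensembles.  At this scale the double
threshold maintains ≥ 0.97 three-class accuracy on random networks with the
detected excitatory fraction within a few points of the structural 80%, and
the structural generators reproduce the published SWI, hub-count and
degree-fit characterizations.

The five-neuron worked example uses static synapses at weight 7 (the mean
of the benchmark's initial weight distribution), Gaussian noise (σ=5),
900 s, the excitation-only estimator score, and DDT with n=1, m=3,
`min_row_candidates=2`.  At weight 7 synaptic transmission is probabilistic,
which keeps second-order (common-input) correlations quadratically weaker
than direct ones; saturated weights (~10) make transmission nearly
deterministic and generate spurious common-input links even in a five-node
graph.  Exact 7/7-link recovery occurs in ≳ 90% of noise seeds.

What passing does *not* show: the generators emulate homogeneous cultures
with instantaneous current synapses, without spatial embedding, conductance
dynamics, or electrode subsampling; the estimator sees every neuron
noiselessly.  Quantities that are sensitive to the estimator front-end
(absolute link counts per method) or to the unspecified noise amplitude
(MFR/MBR/BD point values) are checked only as qualitative bands, and the
16-hour-scale surrogate runs are exercised only at reduced surrogate
counts.

## Known limitations

* The simulator is fixed to the 1 ms integration grid; `step_neuron`
  supports other steps but the network kernel does not.
* SH at α=0.01 is conservative for this estimator; its published link
  counts are not reproduction targets here.
* The modular generator is parameterized plausibly but unvalidated against
  quantitative published values (none are available).
* Degree-sweep noise calibration is a fixed rule, not a closed-loop rate
  controller; extreme degrees (k ≲ 15) may still leave networks
  under-driven.
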