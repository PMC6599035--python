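# Methods

This note documents the models, statistical conventions and numerical
choices behind `sinode`, and what the synthetic benchmarks do and do not
establish about real data.

## Study design assumed throughout

Two tissues — sinus node (SN) and abutting right atrial muscle (RA) — each
with three pooled biological replicates, quantified label-free at the
protein-group level. All statistics operate on log2 intensities; input
scale must be declared explicitly (`scale="log2"` or `"linear"`), never
guessed from magnitudes, because silent auto-detection makes runs
irreproducible across instruments.

## Differential abundance

**Pre-processing.** Reverse/contaminant rows are dropped; within each
isoform group only the row with the highest summed intensity is kept.
Proteins need ≥ 3 quantified values in at least one tissue and ≥ 2
peptides. Quantile normalization maps each sample onto the across-sample
mean of order statistics; samples with missing values are mapped through
the reference quantile function at their fractional observed ranks (the
same interpolation convention as limma's `normalizeQuantiles`, against
which the implementation is cross-checked), and missing entries stay
missing.

**Imputation.** MS dropout is abundance-dependent (missing-not-at-random,
left-censored): faint proteins vanish first. Missing entries are therefore
drawn, separately per sample, from a downshifted normal
N(μ_s − d·σ_s, (w·σ_s)²) with defaults d = 1.8 and w = 0.3 in units of the
sample's observed SD — the standard left-censored imputation for label-free
data. Observed values are never modified, and the imputed mask is carried
through so downstream steps can audit which calls rest on imputation.

**Test statistic.** d = (mean_SN − mean_RA)/(se_pooled + S0) with S0 = 0.1.
S0 enters the denominator additively (the SAM convention), damping
significance for low-variance proteins with negligible fold change. The
reported p-value is the ordinary two-sided pooled-variance Student t,
kept unmoderated so it remains interpretable on its own.

**Permutation FDR.** Balanced group-label relabelings are enumerated
exhaustively whenever their number does not exceed `n_permutations`
(default 750; a 3v3 design has C(6,3) = 20 assignments) and sampled
without replacement otherwise. Two conventions deserve comment because
they decide whether a 3v3 analysis can work at all:

1. *The original labeling and its complement are excluded.* They reproduce
   the observed statistics exactly, so including them floors the estimated
   FDR at 2/20 = 0.1 and makes a 5 % cutoff unreachable in this design.
   Eighteen informative relabelings remain.
2. *A +1 pseudo-count is added to the permuted exceedance count*:
   FDR(t) = (E_perm[#{|d*| ≥ t}] + 1) / #{|d| ≥ t}. Without it, a protein
   whose |d| happens to beat all 18 relabeling maxima receives estimated
   FDR 0 no matter how weak the evidence; on simulated global nulls this
   produced a false call in ~10 % of data sets, i.e. a realized expected
   FDP of ~0.10 at nominal q = 0.05. With the guard the measured null FDP
   is 0 while sensitivity at the benchmark conditions (effect 2.0 log2
   units, σ = 0.3, 3v3) remains ~0.93. The guard is the same logic as the
   +1 in permutation p-values (never report an estimate smaller than the
   resolution of the permutation space) and can be disabled
   (`fdr_numerator_offset=0`).

The exceedance summary across permutations is the mean by default; the
median (the original SAM description) is available but is markedly
anti-conservative in an 18-relabeling space, where the median count is 0
whenever the observed extreme beats a mere majority of relabelings.

The significance set is the largest threshold-set with FDR(t) ≤ q
(q = 0.05); direction is the sign of d. Fewer than 10 permutations is
recorded as a warning on the result rather than an error.

**Post-hoc imputation check.** Every significant protein with ≤ 2
quantified values in either tissue is re-examined: if the raw-intensity
log2 ratio deviates from the post-imputation ratio by more than a factor
(default 2.0 on the log2 scale, configurable — "strongly deviated" is a
judgement call) or flips sign, the protein is flagged. Flags are reported,
never silently removed, so the exclusion list is an explicit, auditable
artifact.

## Channel copy numbers

iBAQ divides intensity by the number of theoretically observable peptides
and is treated as proportional to molar abundance. Copies per cell follow
from subunit stoichiometry and an anchor:

N_X = N_anchor · (iBAQ_X/s_X) / (iBAQ_anchor/s_anchor), anchor = HCN4,
s_anchor = 4, N_anchor = 6255.

Counts are computed per replicate against the replicate-matched anchor
intensity and then averaged; this preserves the pairing between a
replicate's channel and anchor measurements and yields the dispersion the
per-replicate design supports. The default dispersion is the SD across
replicates, with SEM as an option (the two conventions appear
interchangeably in practice; the choice is surfaced, not guessed).
Replicates missing the anchor are excluded with a logged warning; a
missing channel is reported as absent, never as zero. The shipped
stoichiometry table fixes only HCN4 = 4 and Cav1.2 = 1 by convention; the
rest (tetrameric HCN/Kir/Kv/Ryr, dimeric two-pore K⁺ channels, monomeric
Cav α-subunits, Serca2, Ncx1) follow standard channel biochemistry and are
user-overridable via a TSV.

## Single-channel Markov models

HCN1/HCN4 are two-state C ⇌ O schemes; Cav1.2, Cav3.2 and ERG are
four-state linear chains C ⇌ O ⇌ I1 ⇌ I2 with two inactive states. Rates
derive from Hodgkin–Huxley gates by α = y∞/τ, β = (1 − y∞)/τ — the unique
two-state chain whose occupancy reproduces the HH gate. The linear-chain
topology for the inactive states, and the specific Boltzmann/bell-curve
parameters in `data/markov_schemes.json`, are modelling choices of this
package; only HCN4's 1.0 pS unitary conductance is an anchor of the
analysis, and the other unitary conductances are placeholders flagged in
the data file.

**Monte Carlo.** The simulation is a discrete-time jump process at
Δt = 0.02 ms: from state i, transition i → j fires with probability
r_ij·Δt per step (enforced max total exit probability < 0.1 per step).
Within a constant-voltage segment the dwell time of this chain is
geometric, so the implementation samples dwell lengths directly — exactly
the same law as per-step Bernoulli sampling but proportional to the number
of transitions rather than steps. A literal per-step sampler and an exact
continuous-time Gillespie sampler are kept as cross-checks; tests verify
distributional agreement of all three and Kolmogorov–Smirnov consistency
of open dwell times with the exponential limit. Sweeps start from the
stationary distribution at the holding potential.

**Unitary conductance fit.** Per test voltage the open-level current is
the maximum-magnitude current observed while open across sweeps (open
levels are noiseless in this model, so the fitted slope of current vs
voltage is exact whenever each voltage saw at least one opening; voltages
with no openings are dropped). The default voltage-clamp family holds at
−30 mV and steps to −140…−70 mV for 2000 ms.

**Master equation.** dp/dt = Q(V)ᵀp is propagated with per-segment matrix
exponentials — exact for piecewise-constant voltage protocols — and
probability conservation is checked to 1e-8 at every output sample.
Channel counting from conductance is N = round(G_cell/g_u); with the
shipped node model's HCN4 whole-cell conductance of 6.255 nS and the
fitted 1.0 pS slope this gives 6255 channels.

## Cell models and phenotype conversion

The myocyte model is a Hodgkin–Huxley ensemble defined entirely by
configuration: ohmic currents g·Πy^e·(V − E) with Boltzmann steady states
and bell-shaped time constants, dV/dt = −(ΣI + I_stim)/C_m, plus a
phenomenological SR Ca²⁺ subsystem (Michaelis–Menten uptake, CICR-shaped
release) that is deliberately feed-forward — it tracks the membrane but
does not feed back on it, so rescaling SR fluxes cannot destabilize the
voltage dynamics. That makes the Ca²⁺ pools diagnostic bookkeeping, not a
Ca²⁺-clock model, and is a stated limitation.

The shipped atrial and sinus-node configurations are **synthetic minimal
parameterizations authored for this package** (filenames carry
`.synthetic.`); they are not transcriptions of published models. They were
tuned to the qualitative phenotypes the conversion procedure is tested
against: the atrial cell rests stably near −78 mV, fires exactly one AP
per stimulus at a 200 ms cycle length, and is silent unpaced; the
converted cell fires spontaneously (~9.7 Hz, maximum diastolic potential
≈ −74 mV, APD90 ≈ 43 ms, a positive diastolic depolarization rate —
plausible mouse nodal values). Conclusions from these configs are
qualitative (presence/absence of automaticity, direction of feature
changes), not quantitative reproductions of any measured AP.

**Conversion tables.** Every conversion is an ordered list of auditable
actions (set capacitance, scale conductance, set fraction, shift a gate's
half-activation, insert/remove a current, scale SR fluxes). The shipped
atrial → SN table applies: C_m 50 → 25 pF; I_Na × 0.4, I_CaL × 0.8,
I_Kr × 1.3 (stand-ins for SN/RA LFQ ratios — regenerate with
`compute_scaling_from_lfq`, which maps pooled subunit log2 fold changes to
linear ratios 2^log2fc); insertion of I_f split into HCN4 (6.255 nS, the
anchor) and HCN1 components and of I_CaT with its activation shifted
−7 mV; I_Kur to 0 % and I_to to 10 %; SR uptake ×0.9, release ×1.0
(Ca²⁺-handling proteins are essentially unchanged between the tissues).
I_K1 is left unchanged by default; a Kir3/TASK1-guided reduction can be
added to a custom table (which Kir3/TASK combination should stand in for
I_K1 is an open question; the machinery accepts any choice). Applying a
table records every pre-action value, so `invert()` restores them exactly
and an atrial → SN → atrial round trip is bit-identical. The reverse
conversion additionally installs the atrial inward rectifier, without
which the node model cannot be silenced.

**Numerics.** Adaptive stiff-capable integration (LSODA, rtol = atol =
1e-6) with output interpolated onto a fixed 0.1 ms grid; stimulus edges
bound integration segments so square pulses are exact. Runs last 20 s to
reach steady state and features are averaged over the last two APs:
cycle length between upstrokes (dV/dt > 5 V/s crossing −20 mV), MDP as
the minimum between them, APD50/90 from the dV/dt-max time to 50 %/90 %
repolarization of the peak-to-MDP amplitude, and the diastolic
depolarization rate as the slope over the middle half of the final
diastole. Automaticity requires ≥ 2 upstrokes in the final quarter of the
trace with cycle-length CV < 10 %; a window shorter than two expected
cycles returns "inconclusive" rather than a boolean. Divergence
(|V| > 200 mV) raises with the last state attached.

## Synthetic data: what it emulates and what it does not

The proteome generator draws per-protein abundances
μ_i ~ N(base_mean = 25, base_sd² = 2.5²) on the log2 scale, replicate
values N(μ_i + s_ij, noise_sd² = 0.3²), with a designated differential
subset shifted ± effect/2 per tissue (alternating direction), and censors
entries with the logistic MNAR curve p(x) = 1/(1 + exp(k(x − m)))
(midpoint 20.5, steepness 1.5 — chosen to give the few-percent missingness
typical of deep tissue proteomes). The channel-table generator builds
iBAQ values backwards from known copy numbers with multiplicative
Gaussian noise (intensities are log-normal in practice). Defaults mirror
the study design: 3 replicates per tissue, log2 effect 2.0, residual SD
0.3.

Not emulated: peptide-level inference, shared/razor peptides,
between-replicate correlation, batch effects, intensity-dependent variance,
match-between-runs artifacts, or spectra. Passing the synthetic benchmarks
therefore demonstrates correctness of the procedures (filter semantics,
imputation distribution, FDR machinery, copy-number inversion), not
robustness to every pathology of real MS data.

Problem sizes in the shipped test-and-validation runs — 500 null
simulations of 1000 × 6 matrices for FDR calibration, 10 000 imputed
values for the distributional check, up to 10 000 Monte-Carlo sweeps for
the master-equation comparison, 400 seeds for the copy-number noise study,
20 s cell-model integrations — were chosen as the smallest sizes at which
the Monte-Carlo error of each check is comfortably below the tolerance it
asserts.

## Known limitations

- The permutation space of a 3v3 design is tiny (18 informative
  relabelings); FDR estimates are coarse by nature and rest on the +1
  guard described above.
- Copy numbers inherit every systematic error of iBAQ as a molar proxy
  (peptide detectability, membrane-protein digestion bias) and assume the
  measured subunits reside in myocyte membranes.
- Cell-model conclusions are qualitative; the shipped parameterizations
  are minimal synthetic constructions, and the SR subsystem does not
  implement a Ca²⁺ clock.
- Four-state inactive-state connectivity and all non-HCN4 unitary
  conductances are placeholder modelling choices.
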