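# Methods

`micropam` is a desk-scale re-implementation of an in-silico pharmacology
pipeline: a reduced human layer-2/3 cortical microcircuit with tonic and
synaptic GABAergic inhibition, a depression condition, alpha5-selective and
non-selective positive allosteric modulator (PAM) interventions, and the
complete downstream biomarker analysis (signal-detection metrics on firing
rates, simulated EEG through a four-sphere head model, aperiodic/periodic
spectral parameterization, oscillatory-event detection, effect sizes and
dose-response fits).  This note documents the model, its assumptions, the
defaults and why they were chosen, and what the reduction does and does not
reproduce.

## Neuron and synapse models

The reference system is a morphologically detailed 1000-neuron circuit
(80% pyramidal, 5% SST, 7% PV, 8% VIP interneurons) simulated on a
cluster.  Here every neuron is an adaptive leaky integrate-and-fire point
model.  Pyramidal cells have two electrically coupled compartments — a
spiking somatic-basal compartment and a passive apical compartment — which
is the minimal structure that preserves the dendritic targeting logic the
pharmacology depends on: SST inhibition and alpha5-sensitive tonic
inhibition act apically, PV inhibition perisomatically, recurrent
excitation on both.  Interneurons are single-compartment.

Synapses are conductance-based with double-exponential waveforms
normalized to unit peak; connectivity is Bernoulli per connection class.
The SST->Pyr class targets the apical compartment, PV->Pyr the
somatic-basal compartment, and Pyr->Pyr contacts both (weight split
equally).  Short-term plasticity is not modeled (hook retained in
`SynapseParams.stp`).

Tonic GABA-A inhibition is an outwardly rectifying conductance density
`G_tonic * r(V)` with `r(V) = f_min + (1-f_min) * sigmoid((V-V_half)/k)`.
The rectification parameters of the reference model are not published; the
defaults are `V_half = -50 mV`, `k = 10 mV`, `f_min = 0.4`, all
configurable.  At a fixed clamp potential only the scalar `r(V_hold)`
matters, so the clamp fits are well defined regardless of this choice.
Densities (mS/cm^2) are folded to absolute conductances through
per-compartment areas; the areas are free parameters of the reduction
(defaults 0.5e-5 cm^2 somatic-basal, 4e-5 cm^2 apical for pyramidal cells,
4e-5 cm^2 for interneurons) and were set during calibration (below).

Integration is fixed-step exponential-Euler at `dt = 0.1 ms`, with the
rectification and conductance terms frozen over a step.  The network inner
loop is numba-compiled; `cells.step_neuron` is an independent plain-Python
single-neuron integrator used as an oracle in the tests (a disconnected
network neuron must reproduce its firing rate).

## Background drive and stimulus

Every neuron receives an excitatory Ornstein-Uhlenbeck (OU) conductance
whose mean and SD are equal and grow with relative distance from the soma,
`g * exp(X_rel)`; the inhibitory OU conductance is zero.  One process sits
at the midway point of each dendritic arbor and pyramidal apical dendrites
carry five additional processes at `X_rel = 0.1 ... 0.9`.  In the
two-compartment reduction the apical processes are summed into a single
effective OU drive with the same total mean and variance (a sum of
independent OU processes with a common correlation time is again OU).  The
correlation time defaults to 3 ms (standard for point-conductance
backgrounds; not published).  Conductances are floored at zero.  The
background magnitude multiplier `m_ou` (1x/3x/6x) scales the pyramidal
drive to emulate higher activity regimes.

The stimulus is a brief afferent volley: 55 pyramidal neurons (basal, 2-4
ms delay, 4 nS), 35 PV (2-2.5 ms, 2 nS), 65 early VIP (0.5-4.5 ms, 2.8 nS)
and 80 late VIP (7-12 ms, 2.2 nS), with an apical variant stimulating 85
pyramidal cells apically.  Counts scale with the circuit scale factor
(round half-up, minimum one).  The published conductances describe inputs
to morphologically detailed neurons that receive several synaptic contacts
each; the reduction folds the contact count into per-population gain
factors on the printed values (defaults 8x for pyramidal targets, 0.5x PV,
3x VIP), chosen so that stimulated pyramidal cells respond reliably and
the post-stimulus rate distribution separates from baseline at desk scale
— without this the signal-detection analysis is degenerate at N=200.

## Conditions

All interventions are multiplicative conductance transforms:

* **depression** — all SST->X synaptic weights x0.6; pyramidal apical
  tonic conductance x0.6 (apical only); interneuron tonic conductance
  reduced by 40% of its assumed SST-mediated fraction (default 0.18 per
  class; the fraction is an unpublished estimate and was set during
  calibration).
* **alpha5-PAM at dose delta** — apical pyramidal tonic conductance and
  SST->Pyr weights x(1 + 0.60 * delta).  The reference modulation 0.60 is
  the fitted 60% conductance increase at the experimental reference dose;
  the dose sweep covers 25-150%.
* **non-selective PAM** — x1.60 on every inhibitory synaptic weight and
  every tonic conductance.

Transforms compose only as healthy -> depression -> one PAM; re-application
raises.  Condition labels are carried on every output.

## Voltage-clamp fitting

The clamp emulates the in-vitro protocol: soma held at -75 mV, chloride
reversal shifted to -5 mV, spiking disabled, currents reported relative to
the zero-tonic (picrotoxin) condition.  The apical steady state solves the
passive balance with a bracketed root-finder (the balance is monotone in
the apical potential).  `fit_tonic_conductance` finds the uniform density
reproducing the GABA-only current (-65.9 pA) by bisection on a bracket of
ten times the analytic single-compartment estimate (residual < 0.1 pA);
`fit_pam_factor` finds the apical-only factor reproducing the target
current ratio (default 1.52, the per-cell paired increase; the ratio of
printed group means, 95.3/65.9 = 1.446, is also supported since the two
cannot be reconciled from printed data).  Because apical conductance
changes are attenuated at the somatic electrode, the fitted factor always
exceeds the current ratio and approaches it as the coupling conductance
grows — the qualitative content of the published 1.52 -> 1.60 pair.

## Signal-detection analysis

Pyramidal population rates are computed in 50 ms windows sliding by 1 ms
over a 3 s pre-stimulus period (2951 windows per circuit) and in one
5-55 ms post-stimulus window per circuit.  Pre-stimulus windows are fitted
per circuit with maximum-likelihood skew-normal distributions; the
post-stimulus distribution is fitted across randomized circuits (with a
symmetric fallback below 20 circuits, where a skewness parameter is not
identifiable).  The decision threshold is the pdf intersection between the
two modes (optimal decision theory for equal priors; with multiple sign
changes the root nearest the midpoint of the modes is used).  Failed and
false detection are the post-distribution mass below and pre-distribution
mass above the threshold; both equal brute-force quadrature of the fitted
densities to 1e-6 in the tests.  SNR is defined here as
`(mean_post - mean_pre) / SD_pre` of the window rates (the source reports
SNR without printing a formula; an alternative ratio definition can be
swapped in).  Mean pairwise spike correlations use 1 ms binary bins over
all pyramidal pairs, skipping and counting zero-variance trains.

## EEG forward model and spectra

Each pyramidal neuron's somato-apical coupling current, multiplied by the
compartment separation (default 400 um) along the depth axis, sums into a
single equivalent current dipole.  The scalp potential comes from the
quasi-static four-sphere volume conductor (radii 79/80/85/90 mm,
conductivities 0.047/1.71/0.02/0.41 S/m), with the dipole radial at 78 mm
depth and the electrode at the scalp apex (positions are not published;
both configurable).  The concentric-sphere solution expands the source in
(associated) Legendre harmonics and solves a 7x7 continuity system per
degree, truncated at 1e-12 relative; with equal conductivities it matches
the analytic homogeneous-sphere dipole potential to machine precision, and
the expansion coefficients were verified against the closed-form
infinite-medium dipole.

Spectra use Welch's method (Hann, 50% overlap) with the segment length
fixed at 3.5 s x fs so the ~0.286 Hz resolution of the reference analysis
is preserved at any sampling rate.  Band powers integrate theta (4-8),
alpha (8-12) and lower beta (12-21 Hz).  Spike-train spectra use the
population-summed binary train.  Bootstrap means and 95% CIs over seeds
use 100 percentile-bootstrap iterations, seeded.

## Spectral parameterization

PSDs are decomposed over 3-30 Hz into a 1/f aperiodic component (offset
and exponent in log10 space) plus up to three Gaussian peaks: robust
aperiodic fit (peak-masked second pass), iterative peak extraction with a
relative threshold of two residual SDs and minimum height zero, bandwidth
bounded in [2, 6] Hz, joint Gaussian refinement, aperiodic re-fit on the
peak-subtracted spectrum.  Candidates closer than one bandwidth merge
(larger survives).  The aperiodic band integral (AUC) is closed-form;
periodic band powers integrate the Gaussians in log-residual space (the
reference convention is unstated; this choice is fixed and documented).
On noisy synthetic spectra (log-normal noise, SD 0.05) the exponent bias
is below 0.05 over 100 seeds.

## Oscillatory events

A complex Morlet spectrogram (seven cycles; the reference toolbox's
wavelet settings are unpublished) on a 1-100 Hz grid with 0.5 Hz steps is
median-normalized per frequency row.  Local maxima above the median
threshold 4.0 seed events; the bounding box grows along time at the peak
frequency and along frequency at the peak time until the normalized power
falls below half the detection threshold (for a peak at threshold this
equals half the peak value; the rule is our concrete reading of the
referenced method, fixed by the requirement that a detected burst's box
cover the burst).  Boxes overlapping more than 0.5 of the smaller box are
pruned keeping the higher peak.  Features: duration, frequency span,
cycle count (duration x peak frequency), and wave height (peak-to-trough
of the band-passed signal inside the box).  Bands: delta 0.5-4, theta
4-9, alpha 9-15, beta 15-29, low gamma 30-40, gamma 40-80 Hz (half-open);
the published table's 29-30 Hz gap is preserved verbatim and peaks inside
it map to the nearer band with a flag.

## Statistics and the sweep

Cohen's d uses the pooled-SD formula
`(x_bar - y_bar) / sqrt(((Nx-1)sx^2 + (Ny-1)sy^2)/(Nx+Ny-2))` exactly as
published (the source pairs it with paired-sample t-tests; both are
provided).  Dose-response fits compare linear, exponential and sigmoid
least-squares models with their SSEs and a two-sided Pearson correlation.
The sweep runner derives per-seed-index (structure, noise) seed pairs from
one master seed via `numpy.random.SeedSequence` and shares them across
conditions, so condition contrasts are paired; results are tidy
(condition, seed, metric, value) tables with mean/SD/effect-size
summaries.

## Calibration and desk scale

The connection probabilities and synaptic weights of the reference model
are not published as a compact table.  The defaults here keep the
spec-suggested probabilities and calibrate weights and OU magnitudes so
that the healthy circuit fires at the reference operating point (pyramidal
~0.75 Hz baseline, interneurons faster), the depression condition elevates
pyramidal rates strongly, the reference PAM dose restores them, and the
dose-response is monotone.  The default scale factor is 0.2 (200 neurons);
full scale (1000) remains available.  Desk-scale problem sizes used by the
tests and the acceptance script: 3.3-3.5 s simulations for spiking/
detection metrics (3 s pre-stimulus period), 7.7-10.7 s for EEG spectra,
10-20 paired seeds per condition.

## What the reduction reproduces, and what it does not

Reproduced qualitatively (asserted in tests): depression elevates baseline
pyramidal and interneuron rates (large d); the reference alpha5-PAM dose
restores baseline rates, SNR and detection-error rates while leaving the
stimulus response unchanged; the dose-response of baseline rate is
strongly linear and negative (r < -0.9) with low doses insufficient and
high doses over-suppressing; the non-selective PAM leaves baseline rates
elevated; failed/false detection orderings healthy < depression and
PAM < depression; the clamp-fit attenuation structure (conductance factor
exceeding the current ratio).

Not reproduced, by construction of the reduction (and therefore left as
failing checks rather than weakened ones): the non-selective PAM's
*worsening* of failed detection relative to depression — in the reduced
circuit the 0.6 x 1.6 arithmetic restores apical inhibition almost exactly
while interneurons collapse under the 60% tonic boost, so the pre/post
separation improves; the published worsening requires response dampening
by morphologically distributed synaptic integration.  Likewise the
depression EEG power elevation is reproduced in the alpha and beta bands
but not uniformly at every 4-21 Hz frequency bin: in a two-compartment
dipole the depression condition depolarizes the apical compartment, which
reduces the excitatory driving force of the background and cancels part of
the impedance- and rate-driven power gain at low frequencies.  Absolute
firing rates, PSD magnitudes and detection-error percentages are
scale-dependent and are not compared to the full-scale values.

The synthetic-data generators (`micropam.synthetic`) emulate the
statistical structure each analysis stage assumes — Poisson spike trains
with optional common rate modulation, power-law spectra with Gaussian
peaks and log-normal noise, colored noise with Hann-windowed bursts,
piecewise-constant clamp traces at the experimental current levels.  They
contain none of the circuit's recurrent dynamics, so round-trip tests on
them validate the analysis stages, not the simulator; the circuit-level
claims above are tested on the simulator itself.
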