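# Methods

`ulfmri` simulates a shielding-free 0.055 T brain MRI scanner end to end —
phantom, contrast, interference environment, dual-window multichannel
acquisition, per-scan deep-learning EMI cancellation, Fourier
reconstruction, and quantitative evaluation — entirely in software, so the
cancellation method can be exercised and validated without hardware.

## The problem

At ultra-low field the MR signal sits at a 2.32 MHz carrier and is weak
enough that, without a radiofrequency shielding cage, environmental and
internal electromagnetic interference (broadband sources, swept emitters,
mains harmonics) dominates the receive chain. The cancellation scheme
samples ten small EMI sensing coils simultaneously with the MRI receive
coil. Within every TR there are two window types: the MRI acquisition
window(s), one per echo, and EMI *characterization* windows placed in the
TR's dead time where no transverse magnetization survives, so they contain
interference and receiver noise but no MRI signal. The characterization
data train, per scan, a model that predicts the receive-coil EMI from the
ten sensing channels; the prediction is subtracted from every
frequency-encoding (FE) line before averaging and reconstruction.

## Signal model

All signals are complex baseband at the 2.32 MHz carrier, default sampling
rate 50 kHz (dwell 20 µs), so frequencies are offsets within ±25 kHz.

**Phantom.** Nested ellipsoids (CSF rim, GM shell, WM core, optional
spherical lesion) on a labelled grid. Tissue parameters default to apparent
0.055 T estimates: GM T1/T2 = 330/110 ms, WM = 260/100 ms, CSF = 4000/2000 ms
(any values above 1500/1000 ms are consistent with the long-relaxation
bounds; these give clearly visible short-TR FLAIR-like suppression).
Proton densities (CSF 1.0, GM 0.9, WM 0.8) and ADCs (GM 0.8e-3, WM 0.7e-3,
CSF 3.0e-3 mm²/s) follow standard brain-phantom convention. The geometry is
analytic so per-tissue voxel counts are verifiable by brute-force
enumeration; it makes no claim to anatomical realism.

**Contrast.** Closed-form steady-state models: spoiled-GRE Ernst equation
for T1W (TR/TE 52/13 ms, FA 40°), saturation-recovery FSE
`pd·(1−e^(−TR/T1))·e^(−TE/T2)` for T2W (1500/202 ms) and the FLAIR-like
short-TR protocol (500/129 ms), and mono-exponential diffusion attenuation
for spin-echo EPI DWI (2800/102 ms, b = 0/500 s/mm², Δ/δ = 49/30 ms). T2*
is taken equal to T2 (field homogeneity < 250 ppm makes intravoxel
dephasing negligible at these voxel sizes), the GRE is assumed RF-spoiled,
and per-echo T2 modulation across the FSE echo train is not modelled — the
stated effective TE applies at the k-space center (center-out phase-encode
ordering), which keeps reconstruction round trips exact.

**EMI world.** Four source kinds, all analytic functions of absolute time
so waveforms are exactly reproducible and phase-continuous across
arbitrarily scheduled windows: a tone; a periodic linear chirp (swept
source); a mains-harmonic comb (default 50 Hz fundamental, 1/m amplitude
roll-off, seeded phases); and a broadband source synthesized as a dense
seeded comb of random tones (default 256) inside a band — spectrally
indistinguishable from filtered noise at FE-line resolution, but with exact
random access in time. Coupling into the 11 channels (1 receive + 10
sensing) is linear: a complex FIR per (source, channel). Defaults: 3 taps
into the receive coil, a single complex gain into each sensing coil, and
independent complex-Gaussian sensor noise on the sensing channels (σ = 0.01
against O(1) sensing gains, i.e. ~40 dB sensing SNR) — perfect sensors
would make cancellation trivial. Slow multiplicative gain drift per channel
is available to emulate body-antenna/posture effects, off by default. The
coupling functions are free simulation parameters; no claim is made that
they reproduce any particular physical installation.

**Acquisition.** The MRI content of an FE line is a row of the orthonormal
centered DFT of the contrast-weighted phantom (DC at index N//2, FE along
axis 0). The receive channel adds circular complex-Gaussian receiver noise
and the coupled EMI; sensing channels carry coupled EMI plus sensor noise
and never any MRI signal. Elliptic 2D phase encoding masks phase-encode
offsets outside the inscribed ellipse with semi-axes ⌊n/2⌋ (≈ π/4 of the
grid). Each record embeds a *shielded twin* — identical MRI signal and
receiver-noise realization with EMI off — which is the ground-truth
comparator a shielding cage would provide. Characterization windows default
to one FE-line duration each; their count per TR is configurable because a
64×64 single-slice scan has only 16 TRs and the training set is built
entirely from these windows (16/TR → 256 windows). They are spread evenly
across the TR's dead time after the echo train (where the unrefocused
transverse magnetization has dephased) rather than packed at the end of the
TR: when the interference spectrum drifts during the scan, end-of-TR
clustering makes the characterization data unrepresentative of the times at
which FE lines are acquired, and the canceller is then asked to extrapolate
— with a swept source this distribution shift measurably inflates the
residual on acquisition windows above the validation floor. Protocol validation
rejects TRs that cannot contain acquisition plus characterization windows,
reflecting the genuine time overhead of the scheme. Single-shot EPI is
simulated with alternating-line readout: a configurable constant + linear
odd/even phase in the hybrid (readout-space) domain injects the
Nyquist-ghost mechanism, and off-resonance from the phantom field map
accrues phase along the echo train (the distortion mechanism, displacement
−f/bw pixels along phase encode); a 3-line non-phase-encoded reference scan
is emitted per volume.

## The canceller

**CNN.** Five convolutional layers with kernels 11×11, 9×9, 5×5, 1×1, 7×7
and 128, 64, 32, 32, 2 channels; layers 1–4 are convolution + batch
normalization + ReLU, layer 5 convolution only. Input is one FE line's
sensing stack, n_x × 10 × 2 (samples × coils × real/imag); output n_x × 2.
Training uses only characterization-window pairs, an 85/15 seeded random
split, MSE loss, Adam (β1 = 0.9, β2 = 0.999, lr = 5e-4), batch 16, exactly
20 epochs, final-epoch weights returned (validation loss is recorded per
epoch, including an epoch-0 entry, but there is no early stopping).

Choices the published description leaves open, fixed here:

- *Padding and coil-axis reduction.* All convolutions use zero same-padding
  on both axes, preserving n_x × 10; the final two-channel map is averaged
  across the 10-wide coil axis to give n_x × 2. The reduction rule is a
  model field so alternatives (center crop) remain testable.
- *Normalization.* Inputs are divided by the standard deviation of the
  training-portion sensing data and targets by the standard deviation of
  the training-portion receive windows; both constants are stored in the
  model and undone at prediction. Normalizing the targets as well keeps the
  network's working scale at its He-initialization scale even when the EMI
  couples weakly into the receive coil (receive EMI can be orders of
  magnitude below sensing amplitudes); with input-only scaling the first
  epochs are spent shrinking the output range and the 20-epoch budget ends
  an order of magnitude above the receiver-noise floor.
- *Initialization* is He-normal, seeded; batch normalization uses running
  statistics (momentum 0.1) at prediction time.
- Complex data are handled as two real channels end to end; there is no
  complex arithmetic inside the network.

The network is implemented directly in NumPy (float32, im2col/
shifted-slice GEMM for the convolutions and both gradient passes), which
keeps a full per-scan training at the published hyper-parameters to a few
minutes on a single CPU core and makes training bit-reproducible for a
fixed seed under a fixed operation order.

**Linear baseline / oracle.** A regularized least-squares regression from
lagged sensing samples (10 coils × L taps, causal, zero-padded at window
starts with the first L−1 samples of each window optionally excluded from
the fit) to the receive samples over the same characterization windows. In
a noiseless world with instantaneous (1-tap) linear coupling the
sensing-to-receive map is exactly representable and the baseline restores
FE lines to the shielded twin at machine precision — the analytic
correctness surface the CNN is compared against. Note that with multi-tap
sensing couplings the exact sensing-to-receive map is rational (IIR), not
FIR; the FIR baseline is then an approximation, which is why the oracle
worlds use 1-tap sensing gains.

**Per-scan discipline.** Models carry a fingerprint of the
characterization data they were trained on and refuse to cancel a
different record (override available for deliberate transfer experiments).

## Reconstruction and metrics

Complex NEX averaging places the mean of the cleaned repeats at each
k-space coordinate (cancellation always precedes averaging); display
interpolation embeds k-space centered in a zero grid enlarged by integer
pad factors and takes the magnitude of the orthonormal inverse FFT, scaled
so values at original voxel centers are preserved (pad (2,2,2) turns
2×2×10 mm acquisition voxels into 1×1×5 mm display voxels). EPI ghost
correction fits the constant + linear odd/even phase in hybrid space from
the reference scan (slope from the mean phase increment of
odd·conj(even), then the constant) and removes it from odd lines — the
minimal standard method, chosen because the published pipeline names the
correction but not the algorithm. Distortion correction resamples along
phase encode by +f/bw pixels using the simulator's own field map
(field-map estimation from data is out of scope). The ADC pipeline floors
magnitudes, combines the three directional b1 images by geometric mean —
chosen so the ADC of the combined image is the arithmetic mean (trace/3)
of directional ADCs — and takes the b0/b1 log-ratio inside an object mask.

**Shielded equivalence** is operationalized as the relative deviation of
background-noise standard deviations: magnitude-image std over a
background mask (label-0 voxels upsampled to the display grid and dilated
by 2 voxels to exclude Gibbs ringing), cancelled arm versus shielded twin,
pass if within 5%. The same estimator is applied to both arms so
distribution-shape factors cancel; masks below ~2000 voxels are rejected
(bootstrap SE ≲ 2%, well inside the criterion). EMI-band suppression in dB
is measured on the EMI component isolated against the shielded twin
(contaminated−shielded before, cancelled−shielded after), because in raw
FE-line spectra the MRI signal dominates the band and hides the
suppression; the band power uses the mean power spectrum over lines
(mean |FFT|², matching the time-domain energy ratio) since magnitude
averaging understates interference that hits only a few lines per bin,
such as a swept ridge. The magnitude-averaged per-condition spectra are
reported alongside for display.
The EMI band comes from the world specification (known in simulation), not
from estimation.

## Study conditions and problem sizes

The standard evaluation scan is a 64×64 single-slice T2W FSE (TR/TE
1500/202 ms, ETL 8, NEX 2, full Cartesian sampling, 16 characterization
windows per TR → 256 windows). Receiver noise σ = 0.007 (single-average GM
image SNR ≈ 20). The standard interference environment is a broadband
source (2–20 kHz offsets) plus a 50 Hz mains-harmonic comb, with the
receive-coil coupling scaled so the EMI-to-receiver-noise power ratio is
20; the dynamic environment replaces these with a swept source traversing
±18 kHz every 8 s, several sweeps per scan. A single run seed fans out to
per-stage seeds (seed×10 + stage counter), so stages can be re-run in
isolation.

These sizes are deliberate desk-scale choices: they keep a full
simulate-train-cancel-evaluate cycle to a few minutes while preserving
every structural feature of the full protocols (multi-echo trains,
dual-window timing, per-scan training at the published hyper-parameters).

## What the simulation does and does not show

Passing the shielded-equivalence criterion here shows the method works
when EMI couples linearly (possibly with short memory and slow drift) into
all channels and the sensing coils see the sources at good SNR. Real
installations add effects outside this generator: nonlinear front-end
behaviour, sources visible to the receive coil but poorly sensed (the
body-antenna problem is only phenomenologically drifted), non-stationary
coupling faster than a scan, imperfect characterization-window purity, and
gradient/eddy-current interference correlated with the sequence itself.
Results on the synthetic worlds therefore validate the implementation and
the method's statistical machinery, not any specific hardware deployment.

Other known limitations: contrast models are closed-form steady-state
(no extended-phase-graph FSE, no inversion-recovery FLAIR, no B1
inhomogeneity); the phantom is geometric; EPI corrections use the
simulator's own truth (reference scan, field map); magnitude images only.

## Numerical choices

Orthonormal FFTs with DC at N//2 throughout; float32 network arithmetic
with float64 loss accumulation; Adam ε = 1e-8; batch-norm ε = 1e-5;
rank-deficient linear fits raise unless regularized; ADC magnitudes floored
at 1e-6 of the b0 peak; linear-interpolation resampling for distortion;
ties in center-out phase-encode ordering broken lexicographically.
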