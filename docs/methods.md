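# Methods

This note records the model as implemented, the parameter conventions, the
numerical choices that were genuinely open, and what the synthetic tests do
and do not demonstrate.

## Signal analysis

The analysis window is a periodic Hann window, W(x) = (1 + cos(2πx/L))/2 on
|x| < L/2, sampled with the zero endpoint included once so that
constant-overlap-add holds exactly at hop L/2 and L/4.  Frames are
transformed with a unitary DFT (1/√N scaling) and only the ω ≥ 0 bins are
stored; the ω < 0 half of the spectrum of a real signal is the Hermitian
mirror and is reconstructed on synthesis.  Synthesis uses the canonical
dual window, so `istft(stft(s))` is the identity to ~1e−15 for every
overlap-add-valid geometry (hop ≤ L/2), not just asymptotically.

Defaults: L = 62.5 ms, hop = L/4 = 15.625 ms, FFT size the next power of
two (512 at 8 kHz, frequency step 15.625 Hz).  These were chosen so that
the canonical delay δ = 0.0625 s is an exact whole number (4) of hops at
8 kHz: the evolution consumes one spectrogram frame per Euler step, and a
delay that is not a whole number of steps must be snapped (the pipeline
does this with a logged warning for other geometries, e.g. a 16 ms hop
snaps δ to 0.064 s).

The reconstructed image is inverted by extending the stored half-spectrum
Hermitianly and running a complex inverse transform; the imaginary part of
the synthesised waveform is measured before being discarded and reported
as `imag_ratio = max|Im ŝ| / max|Re ŝ|`.  This is the operational check of
the reality guarantee.

## Lift

The chirpiness of a time–frequency point is the slope that keeps |S|
stationary to first order, ν* = −∂τ|S|/∂ω|S|.  Gradients are central
differences (one-sided at borders).  Two discretisation details matter:

* **Verticality mask.**  Where |∂ω|S|| ≤ tol the level line is vertical
  and ν* → ±∞; such points are masked (dropped), not clamped.  The default
  tol is 1e−3 × sup|∂ω|S||.  Only the frequency component sets this scale:
  the two gradient components carry different units (per second vs per
  hertz) and are numerically orders of magnitude apart.
* **Band edges.**  For the DC and Nyquist rows the magnitude of a real
  signal's spectrum is an even function across the row, so its true
  frequency derivative vanishes there.  Inside `lift` the ω-gradient is
  therefore computed on the even extension, which makes those rows masked
  vertical contours.  This is what keeps the lifted input exactly
  consistent with Hermitian mirror symmetry.

Each unmasked point with ν* inside the admissible band N = [−ν_max, ν_max]
deposits its full complex value S(τ,ω) into the nearest ν bin (an exact
equality between ν* and a grid value essentially never holds in floating
point, so nearest-bin assignment realises the "Dirac on the lifted
surface" semantics while keeping projection ∘ lift the identity on kept
points).  Points outside N are dropped rather than clamped — clamping
would pile mass at the boundary bin and send it off at the wrong transport
velocity.

ν_max is data-driven by default: rank the bins with defined chirpiness by
magnitude, keep the smallest set holding 1% of that mass (at least 200
bins — the handful of bins nearest the ridge crest have a 0/0 chirpiness
ratio and cannot be used alone), take the 99th percentile of |ν*| over it,
and widen by a 1.5× margin so that the band contains not only the extreme
slopes but also the kernel's diffusion neighbourhood around them (a ridge
sitting in the boundary bin would otherwise lose roughly half of its
interaction mass to the truncation of N).  The ν grid is uniform with an
odd count (default 41) so ν = 0 is a grid point and the grid is exactly
closed under negation.

## Interaction kernel, units and scaling

The kernel is the transition density at time δ of dω = ν dt,
dν = √(2b) dW.  The noise amplitude √(2b) is fixed by requiring the
generator's diffusion term to be b∂ν², equivalently the ν-marginal of the
closed form to have variance 2bδ; the Monte-Carlo test enforces exactly
this.  The density is jointly Gaussian with mean (ω′ + δν′, ν′) and
covariance [[2bδ³/3, bδ²], [bδ², 2bδ]].

**Axis scaling.**  b in the canonical experiments is an O(0.01–0.2) number,
which is only meaningful once the frequency and chirpiness axes are
rescaled to O(1).  Both axes are divided by the *same* factor (the Nyquist
frequency by default, recorded in the config), with time left in seconds.
A common factor is the only scaling that preserves the kinematic relation
ν = dω/dt: frequencies and chirpinesses scaled by different factors would
make the kernel's drift transport mass along the frequency axis at a rate
unrelated to the ridge's own advance (a factor-4 overshoot in the default
geometry), which defeats gap bridging — the phenomenon the transport term
exists to produce.

**Truncation.**  Tables store only the compact region {k_δ ≥ ε}, whose
closed form is two inequalities (a ν band of squared half-width
C_ε = −4bδ log(ε/max k) and, inside it, an ω′ interval centred on the
transport point).  C_ε is computed from the ratio ε / max k so that
ε = max k gives exactly the degenerate single point.  Candidate lattice
offsets come from these bounds (with a 1e−9-relative slack) and are then
filtered by the exact test k ≥ ε, so the stored support coincides
bit-for-bit with brute-force thresholding.  Default ε = 1e−4 × max k keeps
row masses ≥ 0.999 on resolving lattices.

**Quadrature.**  Entries are kernel values times the (scaled) cell area —
a midpoint rule — so a row's sum ("mass") approximates the integral of a
probability density: ≈ 1 for rows whose support the lattice resolves and
contains, < 1 where the support is clipped by the band edges of N.  At the
smallest b values the kernel's ω width falls somewhat below the frequency
step and row masses wobble by a few percent; this changes the effective
interaction gain slightly but no qualitative behaviour.

**Band-edge folds.**  The lattice covers ω ≥ 0 only.  Support points with
ω′ < 0 are folded to (−ω′, −ν′) with conjugation (mirror symmetry of real
signals); support points beyond Nyquist are folded across the Nyquist row
the same way (the sampled spectrum of a real signal is even about Nyquist
too).  Because k_δ(−ω, −ν ‖ ω′, ν′) = k_δ(ω, ν ‖ −ω′, −ν′) holds
bit-for-bit in the implementation, these folds preserve the Hermitian
consistency of the DC and Nyquist rows exactly, which is what makes the
final waveform real to machine precision rather than merely approximately.

## Wilson–Cowan evolution

Forward Euler with dt equal to the STFT hop; the delay is an integer
number of steps and the zero history for t ≤ 0 is built in.  Stability of
the explicit decay term requires α·dt < 1 (0.86 at the defaults, which is
also why the step is tied to the hop rather than refined: the input
arrives once per frame and nothing in the model varies faster than the
delay).  With γ = 0 the scheme converges at first order to the exponential
low-pass filter e^{−αt}, verified against the exact causal-convolution
recursion.

The sigmoid σ(ρe^{iθ}) = min(1, κρ)e^{iθ} saturates the modulus and
preserves the phase.  **Choice of κ** (the one gain the canonical
parameter sets do not fix): with quadrature-normalised rows the linearised
delayed loop has gain κγ⟨row mass⟩/α, and the canonical sets use γ
slightly *above* α (55 vs 53).  Any κ ≳ α/γ therefore makes the zero state
linearly unstable — activity saturates and self-sustains indefinitely,
every structure smears into a persistent background, and the crossing
chirps cease to be separable.  That hallucinatory regime is clearly not
the bounded, input-driven behaviour the model is meant to exhibit, so the
default is κ = 0.6: loop gain ≈ 0.62, interaction still a leading-order
term (comparable to decay), activity decays once input stops.  κ is a
config/CLI parameter.

After the last input frame the evolution runs on for a configurable
zero-input tail (default 0.5 s) so that decaying, transported activity —
the "persistence" effect — is visible in the output, which is accordingly
longer than the input.

## Experiments and metrics

The four canonical experiments run 2 s, 8 kHz synthetic chirps with
δ = 0.0625 s, β = 1 and: linear and interrupted chirp α = 55, γ = 55,
b = 0.05; crossing chirps α = 53, γ = 55, b = 0.01; sinusoidal FM α = 53,
γ = 55, b = 0.2.  The chirp parameters themselves (500 Hz start, ±1000
Hz/s slopes, 1500 ± 800 Hz FM at 1 Hz, gap of 2δ centred mid-signal) are
this package's choices: they keep all ridges well inside the Nyquist band
and spanning many windows.  The figure-level claims are quantified as:

* **Tail extension** (linear): ridge duration — time during which the
  per-frame peak stays within −20 dB of its maximum — after minus before.
  Expected ≥ 0.
* **Gap-energy ratio** (interrupted): energy in the box [gap interval] ×
  [chirp frequency at the gap edges ± 4 bins], normalised by each image's
  total energy (the two images live on different scales), after / before.
  Expected > 1.
* **Crosstalk index** (crossing): box energy (crossing time ± 2δ,
  crossing frequency ± 250 Hz) of the jointly processed pair over the sum
  of the two separately processed branches.  ≈ 1 means the branches,
  living in opposite chirpiness strata, evolve decoupled.
* **Diffusion spread** (sinusoidal FM): increase of the magnitude-weighted
  chirpiness standard deviation from lifted input to activation.
  Expected > 0.

## What the synthetic data does and does not show

The generator produces noiseless (optionally white-noise-contaminated)
single- and double-component chirps with hard-zeroed interruptions.  This
exercises exactly the mechanisms the model claims — transport along
chirps, stratification by slope, reality and invertibility — under clean,
measurable conditions.  It does not emulate speech: no harmonic stacks, no
formant transitions, no amplitude modulation, no broadband noise floors,
no reverberation.  Passing tests therefore certify the algorithmic and
numerical claims, not perceptual restoration quality on real audio.

## Known limitations

* The lift is single-valued: one chirpiness per time–frequency point.
  Where two ridges cross, the interference region is attributed to
  whichever slope locally wins, and its often-extreme ν* estimates are
  dropped or scattered; the crosstalk index absorbs this as a small
  deviation from 1.
* Near ridge crests ∂ω|S| → 0 and the ν* ratio degrades; such bins are
  either masked or contribute small misplaced mass.  A reassignment-style
  estimator would sharpen this at the cost of the simple level-line
  semantics.
* The interaction uses a single fixed delay, not a weighted history, and
  the evolution is one causal pass (consistent with the model's real-time
  interpretation), not an iteration to steady state.
* Problem sizes in the tests and the acceptance script (2 s at 8 kHz,
  257 × 41 lattices, 1e5 diffusion paths) are the package defaults; they
  resolve all the structures involved while keeping every check cheap to
  re-run.
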