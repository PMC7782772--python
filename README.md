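# chirplift

Cortical-inspired reconstruction of degraded sounds.

The human auditory system is remarkably good at repairing interrupted or
noisy sounds.  `chirplift` implements a neuro-geometric model of that
ability, patterned on the primary auditory cortex (A1): the incoming sound
is not processed as a waveform but as a time–frequency image enriched with
an extra sensory dimension — the **chirpiness** ν = dω/dτ, the rate of
change of the instantaneous frequency — and neural activity in this
augmented (τ, ω, ν) space flows preferentially *along* chirps, so that a
broken ridge gets transported across its own gap.

## The model

1. **Preprocessing.**  The sound s(t) is mapped to its short-time Fourier
   image S(τ, ω) (Hann window, invertible overlap-add geometry).  Each
   point of the image is lifted to the augmented space along the level
   lines of |S|: the chirpiness that keeps |S| stationary,

       ν*(τ, ω) = − ∂τ|S| / ∂ω|S|,

   selects one ν-slice per point, giving a sparse 3-D input
   I(τ, ω, ν) = S(τ, ω) on the lifted surface and 0 elsewhere.

2. **Processing.**  The complex A1 activation a(t, ω, ν) obeys a
   Wilson–Cowan equation with delay δ,

       ∂t a = −α a + β I
              + γ ∫ k_δ(ω, ν ‖ ω′, ν′) σ(a(t−δ, ω′, ν′)) dω′ dν′,

   with a ≡ 0 for t ≤ 0.  The saturation σ acts on the modulus only and
   preserves the phase.  The interaction kernel k_δ is the closed-form
   transition density of the chirp diffusion dω = ν dt, dν = √(2b) dW
   (generator ν∂ω + b∂ν²):

       k_δ(ω, ν ‖ ω′, ν′) = √3 / (2π b δ²) · exp(−g_δ / (b δ³)),
       g_δ = 3(ω−ω′)² − 3δ(ω−ω′)(ν+ν′) + δ²(ν² + νν′ + ν′²).

   Excitation at (ω′, ν′) therefore reappears a delay later around the
   transported point (ω′ + δν′, ν′), blurred by the hypoelliptic Gaussian —
   exactly the along-the-chirp flow described above.  Because k_δ decays
   as a Gaussian, each neuron interacts only with the compact region
   {k_δ ≥ ε}, known in closed form, which makes the operator a family of
   small sparse tables.

3. **Postprocessing.**  a is summed over ν and inverse-transformed.  The
   modulus-only sigmoid and the mirror symmetry of k_δ guarantee the
   result is a real waveform (checked to ~1e−16 at run time).

All test inputs are synthetic chirps the package generates itself (linear,
interrupted, two crossing slopes, sinusoidal FM); no external data is
needed.

## Worked example: bridging an interruption

```
$ chirplift synth --kind interrupted --out gapchirp.wav
wrote gapchirp.wav

$ chirplift experiment fig5 --out-dir exp
imag_ratio = 1.42262e-16
nu_max = 1614.77
dropped_fraction = 0.364336
output_max_abs = 0.0173386
gap_energy_ratio = 4.32304

$ chirplift reconstruct gapchirp.wav --out restored.wav
... INFO pipeline finished in 0.49 s (imag residual 1.33e-16, nu_max 1.61e+03 Hz/s)
wrote restored.wav
```

The synthetic input is a 2 s linear chirp (500 Hz + 1000 Hz/s) silenced
for 0.125 s — twice the delay δ = 0.0625 s — in its middle.  The numbers
mean:

* `gap_energy_ratio = 4.32` — the processed spectrogram holds 4.3× more
  (relative) energy inside the silenced time–frequency box than the
  degraded input did: the gap has been bridged by transport along the
  lifted slope.
* `nu_max = 1615 Hz/s` — the automatically selected chirpiness band
  comfortably contains the true slope of 1000 Hz/s.
* `imag residual ~ 1e−16` — the reconstructed waveform is real to machine
  precision, as the theory promises.
* `dropped_fraction = 0.36` — share of spectrogram magnitude (mostly
  low-level background with ill-defined chirpiness) that carries no lifted
  mass.

The other experiments: `fig4` (a linear chirp persists beyond its end),
`fig6` (two crossing chirps are lifted to opposite chirpiness strata and
evolve almost independently — crosstalk index ≈ 1.1), `fig7` (a
sinusoidally modulated chirp diffuses most where it is most linear).

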