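# pbdna

A verifiable workbench for the continuum **Peyrard–Bishop (PB) DNA model**:
it re-derives the model's exact traveling-wave solution families with the
unified ansatz method, validates every closed form against the PDE,
computes the modulation-instability (MI) dispersion and gain spectrum, and
propagates the solitary waves numerically in the full equation.

It is written for researchers in nonlinear waves / mathematical biophysics
who want *checkable* closed-form solutions: every coefficient is derived
symbolically inside the package and certified by back-substitution and by a
PDE-residual oracle, rather than copied from a table.

## The model

The hydrogen-bond stretching field R(x, t) of a DNA duplex obeys

```
R_tt − (a1 + 3 a2 R_x²) R_xx − 2 η ζ e^{−ηR} (e^{−ηR} − 1) = 0
```

with harmonic/anharmonic strand couplings a1, a2 and a Morse base-pair
potential of inverse width η and strength ζ.  The traveling substitution
R = r(ξ), ξ = x − ωt, one integration (multiply by r′), and the exponential
substitution s = e^{−ηr} turn this into a polynomial ODE,

```
(ω² − a1)/(2η²) · s² s′² − 3a2/(4η⁴) · s′⁴ + ζ s⁵ (s − 2) + C s⁴ = 0 ,
```

which the engine expands in powers (or ratios of powers) of an auxiliary
function λ(ξ) with (λ′)^q = Σ_k B_k λ^k.  Homogeneous balance of s′⁴
against s⁶ fixes the expansion degree (n = 2(p − 1), so n = 2 at p = 2);
collecting powers of λ yields an algebraic system whose solutions are the
closed-form branches.  Five families are built in — solitary (q = 1
Riccati), soliton (q = 2 exponential), elliptic (quartic auxiliary, Jacobi
sn), periodic-rational and soliton-rational — each assembled as
R = −(1/η) ln s(λ(ξ)) with the wave speed ω always computed from the
branch, never supplied by the user.

Linear stability of a steady state of incident power Z0 is described by the
dispersion relation κ(Ω) = ±√((−Ω² − 2(1+Z0) ζ η²)/a1) with MI gain
h(Ω) = 2 Im κ.

## Worked example

Derive the soliton-wave branch (q = 2 polynomial ansatz):

```
$ pbdna derive --family soliton
branch sign +1 variant None:
  A0 = 0
  A1 = sqrt(3)*B1*sqrt(a2/zeta)/eta**2
  A2 = 2*sqrt(3)*B2*sqrt(a2/zeta)/eta**2
  B0 = B1**2/(4*B2)
  ...
```

A0 vanishes and the auxiliary coefficient B0 is constrained to B1²/(4B2):
only the λ and λ² powers survive, and the auxiliary equation factors into
the exponential (sech-type) case.  The ∓ signs of the coefficient radical
appear as the two enumerated branches.

Residual certification of every branch (both signs, all five families):

```
$ pbdna verify
solitary           sign -1 variant -        max residual 2.503e-16
...
max residual 5.140e-08
PASS
```

Every assembled R(x, t) satisfies the PDE to better than 1e−6 (measured
with analytic derivatives on a 400 × 50 grid inside the validity domain).

MI gain spectrum — at (a1, η, ζ, Z0) = (1, 1, 1, 0) the gain at zero
frequency is h(0) = 2√2 ≈ 2.828427:

```
$ pbdna mi --a1 1 --eta 1 --zeta 1 --z0 0 --z0 1 --omega-max 3 --out mi_out
wrote mi_out/spectrum_Z0_0.csv (h(0) = 2.828427)
wrote mi_out/spectrum_Z0_1.csv (h(0) = 4.000000)
wrote mi_out/gain.png
```

Propagate the benchmark solitary wave in the full PDE (method of lines,
RK4 over centered differences, periodic domain):

```
$ pbdna simulate --n 1024 --t-final 5
measured speed 1.286244 (branch omega 1.286817, rel err 4.46e-04)
relative energy drift 4.28e-06
```

The measured core speed agrees with the branch's ω to 0.04%, and the
discrete energy is conserved to a few parts in 10⁶ at this resolution
(below 10⁻⁶ at n = 4096).

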