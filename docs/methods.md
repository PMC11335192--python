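# Methods

`gatkin` analyzes the electrophysiology and flux assays used to characterize
electrogenic secondary-active transporters of the SLC6 family (GAT1-type):
pre-steady-state (PSS) charge movement from voltage-step recordings,
steady-state transport kinetics from dose–response and two-substrate
competition measurements, and superfusion (batch release) efflux assays.
Because raw recordings of this kind are rarely deposited, the package pairs
every analysis stage with a forward simulator whose closed forms serve as
ground truth, so the whole chain is validated by parameter recovery.

## Charge-movement model

The generator uses the simplest scheme whose steady state is exactly a
Boltzmann and whose relaxation is mono-exponential: a two-state Eyring model
with a symmetric barrier. A charge packet of effective valence `z_eff`
distributes between an outer and an inner position in the membrane field.
With the reduced potential `u = (V − V_half)/σ`, `σ = RT/(z_eff·F)`:

    inrate  β(V) = k0·exp(−u/2)        (charge moving into the vestibule)
    outrate α(V) = k0·exp(+u/2)        (charge leaving it)
    f(V)  = β/(α+β) = 1/(1+e^u)        (inward occupancy, Boltzmann)
    τ(V)  = 1/(α+β)                    (relaxation time constant)

A step from the holding potential Vh to V displaces `ΔQ = Qmax·(f(V)−f(Vh))`
with transient current `(ΔQ/τ)·e^(−t/τ)`, so the trace integral equals ΔQ
exactly. The analysis pipeline inverts this: after blocker subtraction each
sweep's ON relaxation is fitted with a single exponential, the charge is
integrated, the Q–V relation is fitted with a Boltzmann (free offset), and
the unidirectional rate constants follow from

    inrate = (1/τ)·(Qin/Qmax),   outrate = (1/τ)·(1 − Qin/Qmax),

which satisfy `inrate + outrate = 1/τ` identically. α/β are display aliases
for outrate/inrate; the code uses the unambiguous names throughout.

Key conventions, chosen where the procedure is genuinely underdetermined:

- **Amplitude reference.** The exponential's amplitude is referenced to the
  step onset, not the fit-window start: `I(t) = A·e^(−(t−t_step)/τ) + b`
  fitted over the window. `Q = A·τ` is then the *total* displaced charge,
  independent of the capacitive-exclusion delay. Referencing A to the window
  start would under-report Q by `e^(−offset/τ)` — 10–35% here, differently
  at each potential, which would distort the Q–V shape. The raw trapezoid
  integral is exposed separately as a diagnostic (`trapezoid_charge`).
- **Fit window.** Default 5 ms after step onset to the step end (half-open:
  the step-end sample already belongs to the OFF phase). With a capacitive
  time constant near 1 ms, 5 ms leaves <1% capacitive residue.
- **ON transients only.** OFF relaxations at the return to holding are
  simulated for realism but not analyzed.
- **Boltzmann offset and orientation.** Integrated charge is defined only
  relative to the holding potential, so the fit carries a free offset. The
  slope sign is free during optimization and the result is normalized to
  σ > 0 with the curve orientation kept as a flag; `fraction_in(V)` (the
  `Qin/Qmax` of the rate decomposition) always denotes the occupancy that
  saturates at hyperpolarized potentials.
- **Weighting.** Per-potential charge uncertainties are propagated from the
  relaxation-fit covariance (delta method on `A·τ`) and used as 1/se²
  weights in the Boltzmann fit; τ varies several-fold across the protocol,
  so the Q points are strongly heteroscedastic.
- **Convergence policy.** Optimizer failure or an amplitude within 2 SE of
  zero yields `converged=False` (e.g. at the holding potential, where
  ΔQ = 0); such potentials are excluded from the Q–V/τ–V tables and
  reported, never silently defaulted. Exponential fits start from the
  prescribed coarse guess (τ₀ = window/5) plus a 1/e-crossing estimate and
  keep the lower-RSS solution, which rescues fast relaxations from shallow
  local minima.

## Steady-state transport and the dual effect

Two substrates G (µM scale, GABA-like) and B (mM scale, betaine-like)
compete for the transport site; each carries current in proportion to its
occupancy:

    I(G,B,V) = factor(V) · (I_G·g + I_B·b) / (1 + g + b),   g = G/K_G, b = B/K_B

`factor(V)` is a monotone sigmoid in [0,1] standing in for the voltage
dependence of transport. This pure competitive form is a Möbius function of
B at fixed G and is therefore *provably monotone* along any betaine row — it
can describe competitive inhibition or substrate addition, but never the
observed biphasic behaviour (current first falling, then rising, as B
increases). A slow secondary substrate that also throttles the primary
substrate's turnover needs one more ingredient. The generator therefore
offers an optional high-affinity slowdown term: the G-current contribution
is divided by

    1 + (B/K_inh) / (1 + g)²,

representing capture of free outward-facing transporters by the slow
substrate — an effect that saturating G outcompetes (the quadratic
protection makes it vanish at high g). With `K_inh = None` (the default)
the pinned competitive form is recovered exactly; the competition-grid
defaults enable it (`K_inh = 0.3 mM`). Under these defaults rows with
G < K_G are biphasic with an interior |I| minimum, and rows at ≥ 10·K_G are
monotone — the concentration dependence the analysis is designed to detect.

The dual-effect analysis splits each GABA row at the tested betaine level
minimizing |mean current| (ties toward the lower concentration, the
boundary being unstated in such assays), fits the descending limb with a
decreasing logistic (IC50-style) and the ascending limb with a Hill fit on
the increment above the minimum. `biphasic=True` requires an interior
minimum and at least 3 betaine levels on each side of the split.

Dose–response tables are fitted with the logistic (Hill) model through the
origin, `I(S) = Imax·S^p/(S^p + K½^p)`, weighted by 1/SEM² when SEMs are
available; p is free (initialized at 1) and reported so it can be fixed.
A floor parameter is deliberately excluded: currents at zero substrate are
baseline-subtracted. Transport efficiency is `Imax/K½` with a delta-method
SE from the fit covariance (validated against Monte-Carlo propagation).

## Efflux quantification

Cells preloaded with tracer release counts in timed fractions (2 min by
default, carried as data). Percent release is always computed against
`total = Σ released + remaining`, so the percent series plus the remaining
percent is exactly 100. The basal rate is the mean percent of the drug-free
fractions divided by the fraction length; drug-induced efflux is read at the
plateau of the drug phase — the first fraction whose percent differs from
the next by less than 10% (configurable) of the drug-phase range, falling
back to the final fraction with a flag. Both basal-corrected and uncorrected
induced rates are emitted, because either convention is defensible; the
concentration–response of the corrected rate is fitted with the same Hill
form to give K½ of induced efflux. The simulator depletes content
multiplicatively (each fraction releases a rate-determined share of what
remains), matching superfusion physics and keeping the conservation
identity exact.

## Study conditions (generator defaults)

| parameter | default | rationale |
|---|---|---|
| protocol | Vh −60 mV; 0.8 s steps −140…+40 mV by 20 mV; 1 kHz | the standard GAT1 voltage-step protocol |
| analysis voltage range | −120…+20 mV | the range over which such Q–V/τ–V data are reported |
| Qmax | 10 nC | oocyte-scale total displaceable charge |
| V_half | −32.87 mV | the substrate-free midpoint such recordings report |
| z_eff (σ) | 1 (σ = 25.09 mV at 291.15 K) | σ/z never stated for this system; unit valence at 18 °C |
| k0 | 10 s⁻¹ (τ: 12–50 ms) | GAT1-typical τ–V magnitudes; also keeps the fastest relaxation resolved at 1 kHz so the trapezoid/charge identity holds to 0.1% |
| Cm, τc, g_leak | 200 nF, 1 ms, 1 nA/mV | oocyte-typical passive properties (not estimates of any particular cell) |
| trace noise | 5% of the observable PSS peak (at the 5 ms window start, within the analysis range) ≈ 8.7 nA | the canonical recovery condition; "observable peak" is what a recording actually shows after the capacitive transient |
| substrate modulation | Qmax/(1+L), k0·(1+4L), L = g+b | reproduces shrinking, accelerating transients; c = 4 makes the transient at ≥20× saturation unobservable (<1% of the substrate-free peak) past the capacitive window |
| I_G, K_G | −150 nA, 16 µM | saturating primary-substrate current and its physiological K½ |
| I_B, K_B | −80 nA, 11.57 mM | secondary-substrate ceiling and K½ on the betaine scale |
| K_inh | 0.3 mM (grid only) | places the inhibitory limb at 0.1–3 mM, below K_B |
| dose/efflux noise | 5% multiplicative, n = 8 cells / 6 wells | typical assay scatter and replication |
| efflux | basal 0.12 %/min, k_max 0.8 %/min, K½ 6.73 mM, rise 2 fractions, monensin ×2 | the release-assay regime the analysis targets |

## What the simulator does and does not emulate

It emulates: capacitive transients, linear leak, mono-exponential PSS
relaxations with Boltzmann charge distribution, substrate-dependent
quenching/acceleration of the transients, competitive (and optionally
dual-effect) steady currents, seeded Gaussian noise, and depleting
fractional release with a finite rise to plateau. It does **not** emulate:
multi-state (multi-exponential) charge movements, solution-exchange
artifacts, the rig's 0.1 kHz analog filter (traces are band-limited by
construction; simulating the filter would add design choices irrelevant to
the fits), capacitance-compensation artifacts, series-resistance errors,
scintillation-counting corrections, or cell-to-cell parameter variability
(noise is measurement noise, not biological scatter). Passing recovery tests
therefore demonstrates correctness of the estimators under the stated model,
not robustness to every artifact of real recordings.

## Numerical choices and degenerate inputs

- All fits use `scipy.optimize.curve_fit` (Levenberg–Marquardt / TRF with
  bounds); τ is bounded to [2 samples, 2× window].
- Exponential-fit and Boltzmann-fit failures are flags, not exceptions; the
  pipeline runs end-to-end on blocker-vs-blocker input and reports empty
  fits.
- Degenerate kinetics inputs (all-zero or all-equal responses, e.g. a
  blocked negative control) yield `converged=False`.
- Floats are written with 17 significant digits and read back with
  round-trip parsing, so every CSV the package writes re-reads bit-exactly.
- Problem sizes used by the validation suites: 50 seeded replicates for
  voltage-clamp and dose–response recovery, 100 runs × 5 doses × 6 wells for
  efflux recovery, 10 random traces for the exhaustive grid-search
  cross-check; these sizes give stable medians while keeping the suites
  quick on one CPU.

## Known limitations

- The two-state model cannot represent charge movements with multiple
  exponential components; fitting such data with this pipeline averages the
  components into a single τ.
- The slowdown extension is a phenomenological, rapid-equilibrium stand-in
  for a kinetic (cycle-time) mechanism; its K_inh and the quadratic
  protection exponent are generative choices, not measured quantities.
- Charge integration by `A·τ` assumes the relaxation is complete within the
  step (worst case here: 0.8 s / 50 ms = 16 τ, negligible truncation).
- The basal-corrected induced efflux assumes basal release is additive with
  the drug-induced component.
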