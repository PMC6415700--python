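# Methods

## Model and assumptions

A single naive T cell is modelled as an absorbing continuous-time Markov
chain on `{B, C1, …, CM, ∅}`. The chain is time-homogeneous: rates
depend only on the current compartment, never on cell age or history
(no ageing, no differentiation states). Migration is star-shaped around
the blood — every inter-tissue transfer passes through `B` — except in
the extended variant, where compartment 1 is split into `(C1a, C1b)`
joined by a direct edge and `C1a` has no exit to the blood. Division is
a marked self-loop: one of the two post-division cells keeps the
mother's identity and position; the other is an independent daughter
starting at the same place and time under identical rules, giving a
branching (Bellman–Harris-free, purely Markovian) genealogy.

All rates are stored and computed in min⁻¹; `per_day` converts for
reporting (1 day = 1440 min). The packaged `table1` parameter set holds
published mouse CD4⁺ T-cell rates: migration 10⁻³–10⁰ min⁻¹, death
1.478×10⁻⁵ min⁻¹ (≈1/47 day⁻¹) and division 1.458×10⁻⁵ min⁻¹
(≈1/48 day⁻¹), uniform across compartments. `table1_extended` keeps the
mesenteric-LN/Peyer's-patch pair split. The fixture's effective
`ξ_C1,B = 2.60×10⁻³` is the published value; recomputing it from the
(rounded) split rates via the mean-first-passage merge gives
1/392.157 ≈ 2.55×10⁻³ — the discrepancy stems from rounding in the
published inputs, so both routes are exposed and tested separately
rather than reconciled.

## Exact descriptors

All statistics follow from first-step analysis. The closed forms share
the hub quantity `D = μ_B + Σξ_B,Ci − Σ ξ_B,Ci ξ_Ci,B/(μ_Ci+ξ_Ci,B)`,
the net drain rate seen from the blood once tissue excursions are
folded in; `D ≤ 0` means death is not certain and is raised as
`AbsorptionError`. Every closed form is checked against
`solve_first_step`, a generic dense solve of
`(−A − c·diag(λ)) x = r` on the living sub-generator `A` (c = 0 for
single-cell rewards, c = 1 for the genealogy, whose daughters feed the
expectation back at the division location). Dense direct solves are
used throughout — the chain has at most a few dozen states; no sparse
path is warranted.

The division-count PMF uses a matrix-geometric recursion on the
embedded jump chain: splitting first-step probabilities into migration
`P_mig`, division `P_div` (diagonal) and death `p_dead`,

    p_0 = (I − P_mig)⁻¹ p_dead,   p_n = [(I − P_mig)⁻¹ P_div] p_{n−1}.

The recursion matrix's spectral radius is < 1 exactly when the count is
almost-surely finite; it is checked with a 10⁻¹⁰ tolerance because for
an immortal model the radius is exactly 1 and lands on either side in
floating point. Truncation is at `n_max` or when the remaining mass
(1 − cumulative sum, exact under certain absorption) drops below
`tail_tol`; the reported tail is that remaining mass.

The lifetime transform solves `(sI − A) L = d` with the death-rate
vector `d`; division self-loops do not enter, since they change neither
the state nor the absorption time.

### Genealogy counting convention

`m̃` counts 2 cells per division event and excludes the founder, the
only convention under which the closed forms vanish when all division
rates are zero. The fast-migration genealogy formula
`(μ̄+λ̄)/(μ̄−λ̄)` includes the founder (it equals 1 when `λ̄ = 0`).
The two conventions differ by exactly one cell; comparisons between
them in the tests are made at magnitudes (~10²) where one cell is
negligible.

### Non-explosion conditions

The genealogy is almost-surely finite when, strictly,
`ξ_Ci,B + μ_Ci > λ_Ci` for every compartment and
`Σξ_B,Ci + μ_B > λ_B + Σ ξ_B,Ci ξ_Ci,B/(ξ_Ci,B+μ_Ci−λ_Ci)`.
The inequalities are evaluated exactly in floating point with no
tolerance band, and signed margins are reported so callers can detect
near-criticality (the published parameter set sits ~2×10⁻⁷ min⁻¹ from
the boundary). `critical_death_rate` inverts the binding condition
analytically for one compartment's death rate; the published model's
critical `μ_C1` is ≈1.40×10⁻⁵ min⁻¹, just below the baseline
1.478×10⁻⁵, which is why small perturbations of `μ_C1` flip the
genealogy from finite to infinite. Monotonicity holds in death rates
(raising any `μ` can only help) but *not* in emigration rates: when the
blood is locally supercritical (`λ_B > μ_B`), faster return to blood
destabilizes the system.

## Fast-migration approximation

Stationary fractions are computed from the ratio closed forms, never by
solving the balance equations numerically; the extended model uses the
analogous three-ratio closed form. `E(N(j)) = (λ̄/μ̄) f_j` is the
reported split of divisions by location; the alternative weighting
`f_j λ_j/μ̄` (identical when `λ` is uniform, and arguably the natural
rate-weighted form) is exposed as
`divisions_by_location_local_rates` and marked experimental — no claim
is made about which better matches the exact values in general. The
mean extinction time `−λ̄⁻¹ log(1 − λ̄/μ̄)` switches to a three-term
series in `λ̄/μ̄` below 10⁻⁸ to avoid cancellation. Supercritical
inputs are flagged (`subcritical=False`, infinite fields), never
raised.

## Sensitivity analysis

The fractions depend on migration only through `K_i`, so
`S̃ = ∂f/∂K` has the rank-one-plus-diagonal closed form and `S = ∂f/∂ξ`
follows by the chain rule; columns of `S` are ordered compartment-major
(`ξ_B,C1, ξ_C1,B, …`). The finite-difference oracle uses central
differences with per-parameter relative step 10⁻⁶, symmetric about the
evaluation point; agreement to 10⁻⁵ relative is asserted in the tests.

## Gillespie simulation

The naive sampler is the textbook event loop and works for both
topologies. With the published rates it is impractical for full
lifetimes: a cell undergoes ~10⁴ migration events per life. The
jump-skipping sampler removes that cost exactly, for the star topology:
between two *marked* events (division or death), each visit to the
blood either ends in a marked event (probability `p_abs`) or completes
one excursion to a single compartment and returns. Hence the number of
completed excursions is geometric with parameter `p_abs`, their
destinations are multinomial, and the elapsed time — a sum of
independent exponential sojourns — is a sum of per-state gamma
variables given the visit counts. The sampler draws exactly those
sufficient statistics, so it is distributionally identical to the naive
loop (asserted by comparing both modes' estimates, and their division
histograms via chi-square, against the exact closed forms) at O(1)
random draws per marked event. Extended-topology simulation falls back
to the naive loop.

Randomness: each estimator call takes one master integer seed; replicate
`k` uses child `k` of `numpy.random.SeedSequence(seed)`, so any
replicate is reproducible in isolation and runs are bit-identical under
a fixed seed.

Caps: genealogies stop at 10⁶ recorded events or 10⁵ total cells per
realization (the tree is simulated one cell at a time, so the cap is on
total cells, which bounds the simultaneous population from above).
Capped realizations are returned flagged `censored`, excluded from
Monte-Carlo means and counted in the summary; supercritical models
therefore terminate with high censoring frequency instead of hanging.

## Problem sizes and what the tests show

The agreement suite runs 10⁴ single-cell and 10³ genealogy replicates
on the published model (matching the published experiment sizes) and
asserts every exact descriptor within 3 standard errors (4 for the
genealogy mean — the published model is near-critical, so the progeny
distribution is heavy-tailed and its sample mean noisy; ~147 expected
cells with sample SD ~1.8×10³). Oracle equivalence uses 100 random
subcritical models at 10⁻⁹ relative tolerance. Random models draw
log-uniform rates over migration 10⁻³–10⁰ and demography 10⁻⁶–10⁻³
min⁻¹, the decade ranges of the published data; they exercise the
algebra and the samplers, not biological realism — passing tests show
the implementation is internally consistent and matches its own
stochastic semantics, not that the star topology or rate constancy
describe real recirculation.

## Known limitations

- Only the star topology plus the single direct `C1a → C1b` edge; no
  arbitrary migration graphs.
- No time-inhomogeneous rates, ageing, or phenotype change.
- The lifetime distribution is available only through its transform and
  mean; the genealogy only through its mean.
- No fitting/calibration machinery: the package computes forward
  quantities from given rates.
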