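# Methods

`n2oiso` analyses N₂O isotopocule measurements from anaerobic cultures of
nitrate-ammonifying (DNRA) bacteria and the associated nitrogen budgets.  This
note records the models, the defaults and why, the numerical choices, and what
the synthetic generator does and does not emulate.

## Isotopocule calculus

The linear N₂O molecule (β-N–α-N–O) carries two distinguishable ¹⁵N sites.
Four per-mil quantities describe them — δ¹⁵Nα, δ¹⁵Nβ, δ¹⁵Nbulk and the site
preference SP — linked by two identities:

    SP       = δ¹⁵Nα − δ¹⁵Nβ
    δ¹⁵Nbulk = (δ¹⁵Nα + δ¹⁵Nβ) / 2     (equivalently δ¹⁵Nβ = 2δ¹⁵Nbulk − δ¹⁵Nα)

Any two of the four determine the rest; `iso_core.complete_isotopocule` solves
the pair it is given and validates over-determined records.  δ values are
stored as plain per-mil numbers (46.5 means 46.5‰) because every relation used
anywhere in the pipeline is linear in per-mil; no ratio-space conversion is
performed.  The consistency tolerance is **0.01‰** — one decimal beyond the
0.1‰ precision at which isotope tables are conventionally reported — so a
record must disagree with its own completion by more than a reporting rounding
error before it is flagged.

Substrate referencing subtracts the substrate's δ¹⁵N from *every* ¹⁵N position
and δ¹⁸O_substrate from δ¹⁸O, so δ¹⁵Nbulk becomes the net fractionation of
production while SP — a difference of two ¹⁵N positions — is exactly frame
invariant.  Shipped references (measured for the growth medium by the
denitrifier and azide methods respectively): NO₃⁻ δ¹⁵N 2.4 ± 0.1‰,
δ¹⁸O 17.9 ± 0.3‰; NO₂⁻ δ¹⁵N −1.8 ± 0.3‰, δ¹⁸O 3.7 ± 0.2‰.

Calibration against working-standard gases and mass-spectrometer scrambling
corrections are upstream of this package and out of scope.

## Gas partitioning

Cultures grow in sealed serum bottles (default 20 mL medium / 30 mL headspace,
25 °C, 1 atm) and only the headspace is sampled by GC.  Dissolved N₂O is
recovered by Bunsen solubility equilibrium with α = 0.544 (N₂O at 25 °C):

    n_total = n_headspace · (1 + α·V_liq/V_gas)

α is a plain configuration scalar — no solubility–temperature correlation,
salinity correction or kinetic dissolution is modelled, and the partition is
applied uniformly to every reading.  Pressure enters only through the optional
ppmv→µmol ideal-gas helper and defaults to 1 atm (configurable).  The total is
computed as headspace + dissolved in a single addition so the conservation
identity holds to the last bit.

## Nitrogen budgets

Concentrations convert to absolute pools as mM × V_liq (mL) = µmol; each µmol
N₂O counts 2 µmol N.  No N₂, NO or hydroxylamine pools are tracked (not
measured in the budgets being emulated).  End-stage composition divides each
pool at the final sampling time (overridable) by the initial substrate-N;
the *unrecovered* remainder closes the sum to exactly 1 and may be negative
when measurements over-close — it is reported, never clipped.

`conversion_ratio` (product-N per consumed substrate-N) refuses intervals with
zero consumption rather than returning 0 or NaN.  Because NH₄⁺ and N₂O arise
from the *onward reduction* of NO₂⁻, `yield_estimates` additionally normalises
by reduced NO₂⁻-N (consumed substrate-N minus net NO₂⁻ accumulation) — the
estimator that recovers the branch-point yields themselves while NO₂⁻ remains
in the bottle.

**NO₂⁻–N₂O association.**  The coupling between N₂O production and transient
NO₂⁻ accumulation is quantified by OLS of cumulative N₂O-N on NO₂⁻
accumulation, defined as the max-to-date net increase above the initial level.
By default the fit uses the *accumulation phase* — sampling times up to and
including the accumulation peak.  This is a deliberate design choice: the
claimed coupling operates while NO₂⁻ is building up (blocking accumulation
halts N₂O production), whereas after the peak the regressor is frozen by
construction while the product pool keeps integrating, so post-peak samples
contribute only unexplainable variance.  Under the simulator's kinetics the
full-series fit caps near R² ≈ 0.6 for every realistic parameter set while the
accumulation-phase fit sits near 0.75–0.8.  `phase="full"` and
`x_mode="level"` (instantaneous net change) are available alternatives.

## Endmember mixing

Two co-occurring production pathways mix linearly in SP:

    SP_mix = f·SP_A + (1 − f)·SP_B   ⇒   f = (SP_mix − SP_B)/(SP_A − SP_B)

The canonical use partitions late-culture N₂O between the high-SP DNRA
pathway (the culture's own 3-day SP as endmember A) and cNor-type denitrifier
NO reduction (SP = −5.9 ± 2.1‰).  `solve_fraction` returns the unclipped f —
values outside [0, 1] flag an observation not bracketed by its endmembers.
Monte-Carlo propagation draws the three SP values independently from
Gaussians (± values are read as 1 SD; the underlying reports state no
distribution, and a symmetric unimodal choice is the conventional reading),
computes the closed form per draw, and summarises mean, SD and the 2.5–97.5
percentile interval.  Draws with |SP_A − SP_B| < 10⁻⁶‰ are rejected and
resampled (counted); out-of-[0, 1] draws are *retained* and their share
reported (`clipped_share`), since silent truncation biases f near the
boundaries.  With all SDs zero the result short-circuits to the closed form
exactly.  Inversion with more than two endmembers on the single SP axis is
under-determined and refused; only the forward k-endmember prediction is
exposed.

## Source zones and the reduction vector

Production pathways occupy characteristic regions of (SP, δ¹⁵Nbulk, δ¹⁸O)
space.  The shipped DN (DNRA) zone is SP 43.0–49.9‰, δ¹⁵Nbulk −39.9 to −5.8‰,
δ¹⁸O 14.1–30.5‰ (substrate-referenced δ axes).  Other zones (bacterial/
fungal/chemical denitrification, nitrification, nitrifier denitrification)
ship as a clearly-labelled, user-editable TOML config of literature-typical
ranges — they are illustrative defaults, not measured by this package's data.
Membership uses closed intervals (boundary points match); a zone constraining
an axis a sample lacks is a warned non-match, not an error.

Partial N₂O consumption by N₂O reductase enriches the residual gas along a
line with slopes ε(SP)/ε(δ¹⁵N) = 0.96 and ε(δ¹⁸O)/ε(δ¹⁵N) = 2.21.  δ¹⁵N is
the master parameter: a shift Δ moves SP by 0.96Δ and δ¹⁸O by 2.21Δ.  The
independently reported ε(SP)/ε(δ¹⁸O) = 0.45 is carried for reference but is
slightly inconsistent with 0.96/2.21 ≈ 0.434 (rounding in the source values);
the δ¹⁵N-parameterised pair is used so the three axes stay mutually
consistent.  `reachable_zones` solves, per zone, the interval of Δ for which
the back-projected source point lies inside the zone (intersection of
per-axis interval constraints); Δ-range (0, 0) reduces exactly to `classify`.

## Group statistics

Medians are the standard sample median; *reported* medians additionally round
half-away-from-zero to one decimal, matching isotope-table convention (this is
what turns the raw NO₃⁻ substrate median 46.35 into 46.4).  The value is
snapped at 9 digits before quantisation so binary-float representation error
cannot flip a genuine half tie.  Substrate comparisons exclude the two
nitrite-only strains by default (they have no NO₃⁻ arm, so including them
unbalances the pairing); an include flag is provided.

Mann–Whitney U uses the exact U distribution when min(n₁, n₂) ≤ 8 and there
are no ties, and the tie-corrected normal approximation with continuity
correction otherwise (matching R's `wilcox.test` defaults); both delegate to
`scipy.stats.mannwhitneyu`.  A full-enumeration permutation mode (midranks,
two-sided by distance from the null mean) is kept for exact handling of small
tied samples.  Kruskal–Wallis is `scipy.stats.kruskal` (tie-corrected H,
χ² p on k − 1 df) with two guards: fewer than three groups is an error
directing to Mann–Whitney, and all-identical values return H = 0, p = 1
instead of scipy's degenerate-input error.

## Synthetic cultures

The generator exists so the whole pipeline is testable without external data;
its defaults *are* the study conditions the analysis assumes.

**Kinetics** (`simulate_culture`, forward Euler, step ≤ 0.1 h, default
0.05 h): logistic biomass (r = 0.12 h⁻¹, K = 0.4 OD₆₀₀, OD₀ = 0.02);
substrate → NO₂⁻ first order scaled by biomass (k_consume = 0.12 (OD·h)⁻¹);
NO₂⁻ → products likewise (k_nitrite = 0.07 (OD·h)⁻¹), the reduced flux
partitioned into NH₄⁺ (y_nh4 = 0.65), N₂O-N (y_n2o = 0.01 for NO₃⁻ runs,
0.02 for NO₂⁻ runs) and an unmeasured remainder.  This is the simplest form
reproducing the qualitative culture behaviour: 8 mM NO₃⁻ drawn down over
~3–4 days, transient NO₂⁻ accumulation with a few percent remaining at
168 h, NH₄⁺ above 60% of substrate-N, N₂O ≈ 1% — no rate law is prescribed
by the data being emulated, so the form is the package's own.  The latent
state conserves N exactly (pool-to-pool transfers only); a state going below
−10⁻⁹ µmol aborts with advice to shrink the step.  Optional Gaussian
measurement noise is applied at sampling times only: 0.05 mM on
concentrations (ion-chromatography/colorimetry scale), 0.005 on OD, 2%
relative on N₂O (GC-ECD scale); noisy values are floored at zero.

**Isotopes** (`simulate_isotopes`): per replicate and sampling day, SP is the
value-level pathway mixture f·N(SP_DNRA) + (1−f)·N(SP_cNor) with
SP_DNRA = 46.2 ± 1.5‰ and SP_cNor = −5.9 ± 2.1‰, plus instrument noise;
δ¹⁵Nbulk and δ¹⁸O are the substrate value plus a drawn net fractionation
(ε¹⁵N = −24.6 ± 6.0‰, ε¹⁸O = 23.6 ± 6.3‰) plus instrument noise.  Linear
per-mil mixing is exact to first order and consistent with the linear mass
balance used for inversion.  Instrument SDs follow the stated analytical
precisions 0.2‰ (δ¹⁵Nα) and 0.1‰ (δ¹⁵Nbulk, δ¹⁸O); no SP precision is
stated, so the generator propagates √(0.2² + (2·0.1)²) ≈ 0.28‰ through
δ¹⁵Nβ = 2δ¹⁵Nbulk − δ¹⁵Nα and draws bulk and SP independently, then derives
δ¹⁵Nα/β from the noisy pair — every generated row therefore satisfies the
isotopocule identities exactly by construction.  A step-function schedule
f(day) is supported for time-varying pathway mixtures; no schedule is
prescribed by default.

**What the generator does not emulate:** Rayleigh closed-system drift of the
substrate δ values over time (substrate isotopes are treated as fixed);
NO/hydroxylamine intermediate pools; growth–substrate coupling beyond the
logistic×first-order form; autocorrelated instrument drift.  Passing
round-trip tests therefore demonstrates that the *pipeline's* estimators
recover the generator's truth under realistic noise — not that real cultures
obey these rate laws.

## Numerical and reporting choices

* Per-mil quantities never pass through isotope-ratio space; all algebra is
  linear in ‰.
* Monte-Carlo results are deterministic for a fixed seed
  (`numpy.random.default_rng`); every CLI entry point requires an explicit
  seed, and output tables carry a provenance header (version, seed, config
  hash).
* Zone membership and reachability use closed intervals; ties on a boundary
  match.
* The analysis drivers use 3 replicate bottles, 15 sampling times (12 h
  cadence over 168 h) and 10⁵ Monte-Carlo draws; the acceptance script uses
  the same sizes with 8 noisy-replicate yield estimates and 2×10⁴ draws per
  recovery point — sizes chosen so the full pipeline re-runs in seconds while
  Monte-Carlo error stays an order of magnitude below the tolerances quoted
  with the results.

## Known limitations

* The two-endmember inversion is exactly identified on one axis; it cannot
  detect a third co-occurring pathway, and the package deliberately refuses
  under-determined multi-endmember inversions rather than regularising them.
* Non-DN zone ranges are illustrative defaults, not curated compilations.
* The replicate-level SP extrema of the DN zone (43.0/49.9‰) come from
  replicate-level source data that is not redistributed here; the bundled
  survey carries strain means, whose extrema (44.4/47.4‰) are strictly inside
  the zone, and range checks are therefore bracketing properties rather than
  reproductions.
* Reported strain-mean-based DNRA fractions for the two mixed-process
  cultures (93.0%/88.8%) differ from the published replicate-level figures
  (93.9%/94.0%), which derive from an averaging scheme over raw replicates
  that the strain means cannot reproduce; both are documented, neither is
  adjusted toward the other.
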