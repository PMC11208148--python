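# Methods

## Measurement model

`diazosym` analyses dual-label SIP incubations read out by nanoSIMS.
Each region of interest (ROI) is one cell — a diatom host or one of its
intracellular N₂-fixing symbionts — with two measured isotope ratios,
¹³C/¹²C and ¹²C¹⁵N/¹²C¹⁴N. Ratios convert to heavy-atom fractions
`A = R/(1+R)`; all arithmetic is done on atom fractions.

**Fixation rates** use the linear-incorporation estimator
`rate = (A_meas − A_init)/(A_source − A_init) · B/t`: the normalised
label excess times the cell's element content `B` per incubation day.
It assumes the substrate pool enrichment is constant over the (single,
24 h) incubation and that element content does not change appreciably —
the standard endpoint approximations for short incubations. The same
functional form, applied to the whole particulate pool in µmol l⁻¹,
gives the bulk rate (`bulk_fixation_rate`, nmol l⁻¹ d⁻¹).

**Growth** assumes exponential growth on the labeled carbon source, so
the new-carbon fraction after time `t` at growth rate `g`
(divisions d⁻¹) is `x = 1 − 2^(−g·t)`; the estimator inverts this
exactly: `g = −ln(1−x)/(t·ln2)`. Enrichment at or above the source
(`x ≥ 1`) is a saturation condition: the rate is undefined and the cell
is reported as NaN by the table stage (an exception at the function
level). Apparent enrichment *below* the initial composition — possible
under measurement noise — would give negative rates with no physical
meaning; it is clamped to zero with a warning. Rounding-level
undershoots (|x| < 1e−12) are clamped silently.

**Biomass from geometry.** Hosts (pennate diatoms measured as length ×
width) are modeled as elliptic cylinders with height equal to width,
`V = (π/4)·L·W²` — the simplest solid consistent with two recorded
dimensions. Host carbon uses the Menden-Deuer–Lessard protist
allometry, `pg C = 0.288·V^0.811`. Symbionts (cocci) are spheres with a
constant carbon density. The default density, 114.71 fg C µm⁻³, is not
a free parameter: it is the unique value at which geometry-based
symbiont biomass coincides with the biomass implied by the carbon mass
balance at the reference configuration (40 × 5 µm host at 0.8
divisions d⁻¹ passing 1% of fixed carbon to four 1.5 µm symbionts at
0.6 divisions d⁻¹ over one day). It sits in the upper range of
literature values for small heterotrophic bacteria, consistent with the
carbon-dense appearance of the symbionts. Nitrogen is carbon divided by
a molar C:N of 6.625 (Redfield) for hosts and 5.0 (typical
heterotrophic bacterium) for symbionts. All four constants are
configurable (`[biomass]` in the TOML config).

## Mass balance

The host carries no nitrogenase, so all host ¹⁵N excess is attributed
to symbiont-fixed, transferred nitrogen (no correction for release and
re-uptake of dissolved ¹⁵NH₄⁺; any such recycling would make the
transfer estimate conservative in the other direction). Then

- `F_total = F_host + ΣF_sym`, `φ = 1 − ΣF_sym/F_total`,
  amplification `= F_total/ΣF_sym = 1/(1−φ)`;
- carbon mirror-image: `ψ = ΣC_sym/(C_host + ΣC_sym)` with all cells'
  ¹³C excess counted, since photosynthesis is the only carbon entry
  point;
- whole-symbiosis growth applies the growth estimator to the
  carbon-content-weighted mean atom fraction over all members.

Symbionts are aggregated within a symbiosis before computing φ and ψ;
per-cell rates are available from the `cellrates` stage. Population
summaries average the per-symbiosis fractions (the per-symbiosis and
pooled-total variants coincide on noise-free data and differ only at
third decimals under noise; both are recoverable from the output
tables). Degenerate inputs: φ is NaN when no nitrogen fixation is
detected at all, amplification is +inf when the symbionts retained
nothing, ψ is NaN when no carbon was fixed.

## Census scaling and bulk rates

Census counts are tens of cells per filter, so abundance intervals use
the exact Garwood construction (χ² quantiles), not a normal
approximation; the upper bound for a zero count is 3.689/volume.
Volumetric rates are `rate × abundance × 10⁻⁶` (fmol → nmol), using the
mean whole-symbiosis rate — host-recovered plus symbiont-retained
nitrogen — as the scaling quantity. Note the worked consistency check:
650 fmol d⁻¹ × 2,000 l⁻¹ = 1.3 nmol N l⁻¹ d⁻¹ pooled, whereas
station-wise averaging of the same data can yield ~1.5; the package
reports the pooled product and leaves station structure to the user's
census table. Replicate summaries are mean ± sample SD (n−1).

## Genome detection

A genome is called present when observed breadth ≥ θ × expected breadth
with `expected = 1 − e^(−0.883·coverage)` and θ = 0.95 by default. The
exponent constant is an empirical read-recruitment calibration (it is
close to, but flatter than, the ideal Lander–Waterman `1 − e^(−c)`;
uniform random placement reproduces it within 0.05 absolute for
coverage ≤ 2, which is the regime where the detection decision
matters). θ is a one-sided "close to" criterion; there is no upper
band, since breadth above expectation is not evidence of absence. qPCR
counts get `log₁₀(copies + 1)`, with zero-count samples flagged and
excluded from mapping; filtering before or after the transform is
equivalent.

## Synthetic generator

The generator emulates the full measurement design: sample host
geometry uniformly on 20–58 µm × 3–8 µm and symbiont diameters on
1–2 µm (defaults; a `fixed_geometry` mode pins 40 × 5 µm hosts, 1.5 µm
symbionts and growth at the distribution means), sample growth from
N(0.8, 0.1) for hosts and N(0.6, 0.3) for symbionts (divisions d⁻¹,
clipped below at 0.05), then write atom fractions by running the
labeling model *forward* and convert to ratios. Estimator and generator
are exact inverses by construction, which is what the round-trip tests
exploit.

Three modeling choices deserve note:

1. **Symbiont biomass is parameterized through ψ.** Total symbiont
   label uptake is set to `ψ/(1−ψ)` times the host's photosynthetic
   uptake, split equally across symbionts, and each cell's carbon
   content follows from its own growth rate. This makes the configured
   carbon-transfer fraction exact by construction; the implied carbon
   density is recorded in the truth table (114.71 fg C µm⁻³ at
   defaults, matching the estimator's default — deliberately, see
   above). When a symbiosis has zero transfer or zero growth, symbiont
   content falls back to density × volume.
2. **Whole-symbiosis N₂ fixation scales with host size.** The default
   650 fmol N d⁻¹ is anchored at the reference 40 × 5 µm host and
   scaled by relative host nitrogen content: a 20 µm host contains only
   ~200 fmol N and cannot absorb the reference transfer in a day
   without isotopically saturating, which would be unphysical.
   Fixed-geometry mode therefore fixes exactly 650 fmol N d⁻¹.
3. **Saturation handling.** Configurations that saturate the host
   nitrogen label even at reference geometry raise a configuration
   error. Per-cell stochastic excursions (fast-growing sampled
   symbionts whose ψ-derived nitrogen pool is small — about 0.1–2% of
   cells at defaults) are clamped at a label excess of 0.995 and
   flagged `saturated_n` in the truth table rather than emitted
   unphysically; carbon channels are unaffected.

Poisson noise mode draws the heavy-isotope ion count as
Poisson(A × total) at 10⁷ carbon and 10⁶ nitrogen ions per ROI
(realistic nanoSIMS accumulations) and recomputes the measured ratio.
Sampling order is fixed (per symbiosis: host length, width, growth;
per symbiont: diameter, growth; then noise draws cell by cell, carbon
before nitrogen) so a single integer seed reproduces runs exactly.

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: isotopic dilution during sample
preparation (real rates are underestimates; no correction is applied),
within-incubation dynamics of transfer (the linear/exponential forward
model is assumed by generator and estimator alike, so round-trip tests
validate internal consistency, not the labeling model itself),
ROI-segmentation error, QSA/dead-time effects, diel variation in
fixation, and between-symbiosis variance in φ and ψ (configured as
constants).

## Problem sizes and numerics

Default analyses run 16 symbioses (the analysed single-cell sample:
16 hosts, 64 symbionts); statistical checks use 200 symbioses (200
hosts / 800 symbionts) and 100-seed sweeps, which keep the full test
suite in seconds. Breadth simulations use a 10 kb genome with 100 b
reads, circular placement, 100 replicates per coverage. Tolerances:
exact-inversion checks at 1e−9 relative; stochastic recovery at ±0.05
absolute on mean growth (the standard error of the mean at n = 200
hosts is ~0.007, so this is a loose bound dominated by model risk, not
sampling noise).

## Known limitations

- Transfer attribution is all-or-nothing (host excess = transfer); any
  host uptake of ambient dissolved ¹⁵N would inflate φ.
- The symbiont carbon-source enrichment is taken equal to the DIC
  source (freshly fixed carbon passed without dilution); storage-pool
  turnover would bias symbiont growth estimates low.
- Host height = width is an upper-bound volume for strongly flattened
  cells; biomass (and hence absolute rates, but not φ, ψ or growth)
  scales accordingly.
- Detection's θ = 0.95 is a pragmatic default; there is no published
  numeric criterion for "close to expected breadth".
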