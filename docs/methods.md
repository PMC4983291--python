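# Methods

This note records the models behind each stage of the toolkit, the defaults
and why they were chosen, and what the synthetic studies do and do not show
about real spectra.

## Pulse-level calculators

Rectangular pulses are treated as ideal constant-amplitude rotations: a spin
on resonance nutates at ν₁, so a flip of θ degrees takes `θ/360 · 1/ν₁`.  A
spin off resonance by Δν rotates about the tilted effective field
`√(ν₁²+Δν²)`, giving the effective rotation `θ·√(1+(Δν/ν₁)²)`.  At offset
ratio √15 a nominal 180° pulse produces an effective 720° rotation — the
condition used to set the MOCCA-XY16 carbonyl RF field so that Cα returns to
its initial state during every mixing pulse; the √3 ratio gives the
lower-power 360° alternative.  Inverting the same relations yields the
selective CA/CO RF rules `|ΔΩ|/√15` (90°) and `|ΔΩ|/√3` (180°).

The CA–CO offset ΔΩ is not an independent input anywhere in the package; it
is recovered from the MOCCA condition as `√15 · ν₁(MOCCA)` at each field
(≈18.1 kHz at the 600 MHz setting, ≈24.1 kHz at 800 MHz, both ≈120 ppm of
¹³C).  This makes one number (the MOCCA RF) the single source of all six
rectangular pulse durations the calculator reports, which agree with the
published settings to better than 0.3 %.  Sinc-shaped selective-pulse
durations depend on a time–bandwidth factor that is not derivable from the
rectangular rules, so they are stored as calibration constants, not computed.

Semi-constant-time and constant-time evolution delays implement the standard
three-delay schemes; both satisfy `a+b−c = t` exactly for all t, and the
constant-time block has fixed total duration Δ.  No Bloch-equation shaped
pulse simulation and no phase-cycle bookkeeping is attempted: those are
acquisition-side concerns with no bearing on the simulated data content.

## CO–CO mixing model

In-phase transfer under ideal isotropic mixing is modelled as a continuous
quantum walk on the chain of carbonyl spins: Hamiltonian matrix elements
`H_{k,k±1} = πJ` (rad/s), propagator `U = exp(−iHt)`, transfer fractions
`|U_{ms}|²`, all multiplied by a single relaxation envelope `exp(−R(B₀)t)`.
For two spins this reduces exactly to the textbook TOCSY closed form
`(cos², sin²)(πJt)`.  The walk is windowed to ±2 neighbours of the source;
i±2/i±3 amplitude is computed but never emitted as peaks, matching the
deliberate tuning of the mixing time for i±1 transfer only.

Defaults, chosen once and exposed in the configuration:

* `J = 1.0 Hz`.  The effective CO–CO mixing coupling is not published; any
  value ≤ 2 Hz makes 250 ms mixing superior to 150 ms, reproducing the
  observed ordering.
* `R₆₀₀ = −ln(0.7)/0.25 ≈ 1.43 s⁻¹`, i.e. the 250 ms envelope retains ≈70 %
  of the polarization at 600 MHz.  Carbonyl relaxation during the mixing
  train is CSA-dominated, hence `R(B₀) = R₆₀₀(B₀/600)²`; this single scaling
  reproduces the qualitative observation that a 600 MHz instrument can
  outperform an 800 MHz one for long mixing periods.

Absolute transfer amplitudes are model-dependent; only orderings and trends
are asserted anywhere in the test suite.  MOCCA train imperfections (finite
repetition period, duty cycle, Hartmann–Hahn mismatch, the XY16 supercycle
itself) are not simulated.

## Synthetic shifts

Each nucleus of each residue is drawn from a Gaussian centred on a bundled
random-coil mean for its residue type, clipped to a plausible window.
Per-nucleus standard deviations at unit dispersion: N 2.0, CO 0.4, CA 0.4,
HN 0.15, HA 0.08 ppm — sequence-neighbour effects spread amide ¹⁵N far more
than ¹³C′ in coil ensembles.  The random-coil table is literature-style
configuration data, not a fit.  No sequence-neighbour corrections are
applied (the realistic per-type spread already produces the near-degenerate
(CO, N) anchor pairs that make linking hard, which is the behaviour that
matters here).  Proline amide nitrogens centre at 136.8 ppm, far above every
other type — the physical fact the proline-bridging gate exploits.  Random
test sequences carry ~10 % prolines at internal, non-adjacent positions,
the typical IDP abundance.

## Signal model and sampling

Peaks become sums of ideally phased complex exponentials with per-axis decay
(default `R = 2/t_max`, a linewidth of about two grid cells) plus complex
Gaussian noise.  Quadrature is ideal complex sampling per dimension; the
States-TPPI/echo-antiecho bookkeeping of a real acquisition adds no testable
behaviour for reconstruction correctness and is not modelled.  Out-of-window
peaks are an error: folding is not supported, and the default spectral
windows (¹³C′ 10 ppm about 176 ppm; ¹⁵N 40 ppm about 121 ppm, covering
prolines) are matched to the generator's shift ranges the way an
experimentalist matches sweep widths to a first HSQC.

NUS schedules are uniform-random unique grid points, always including the
zero-time coordinate.  The sparse schedule lives on the **resolved**
CO/N grid (default 64×64, 1100 points ≈ 27 %); the two anchor evolution
dimensions (N and CO of the HNCO triple) are represented as conventionally
sampled full grids, combined with the NUS schedule as a Cartesian product.
Rationale: the anchor coordinates are supplied by a separately recorded,
well-resolved HNCO base spectrum, so resolving them costs no NUS budget in
this model, and anchor-dimension resolution is precisely what keeps one
anchor's strip from bleeding into another's.  Anchor grids default to 64 (N)
× 256 (CO) points — maximum evolution times of roughly 26 ms (N) and 170 ms
(CO) at 600 MHz, long but physical for slowly relaxing IDP carbonyls, and
chosen because truncation-sidelobe leakage between anchors closer than a few
grid cells was the dominant error source in link recovery.  The amide-proton
dimension is not synthesized at all; anchors are discriminated by their
(N, CO) coordinates plus the HNCO list.  This is the one deliberate departure
from a literal acquisition, where all four indirect dimensions share a single
NUS schedule; a joint 4-D schedule at desk-scale point counts would be
dominated by sampling artefacts that real workflows remove with dedicated
cleaning algorithms, which are out of scope here.

## SMFT, noise floor, picking

Cross-sections evaluate the zero-augmented Fourier transform at the exact
(not grid-snapped) anchor frequencies and on a dense resolved-frequency grid
(default 2× Nyquist oversampling), in magnitude mode.  The sampling-noise
floor is the median magnitude at random positions of the section (optionally
excluding known peak neighbourhoods); the picker accepts local maxima above
`threshold × floor` (default 5), greedily in height order with a Chebyshev
exclusion radius (default 2 grid steps), and refines each coordinate with
3-point parabolic interpolation.  No apodization, maximum-entropy, CS, MDD
or SSA reconstruction is implemented: the threshold is the single artefact
control, and the tests show what that simple rule can and cannot recover.

## Linking, proline bridging, chains

Every strip's diagonal is the nearest in-tolerance pick to the anchor's own
(CO, N) pair; strips without one are flagged and excluded from the eligible
set.  Non-diagonal picks are matched to other anchors' pairs by normalized
Euclidean distance (default tolerances 0.05 ppm CO, 0.2 ppm N, set relative
to the synthetic linewidths).  The nearest candidate wins unless a second
candidate is nearly as close — distance ratio below 1.2, with a floor of half
the tolerance radius so that a dead-on best match cannot silently beat an
equally plausible runner-up — in which case the pick is rejected as
ambiguous: real practice resolves such clashes with the extra amide-proton
dimension, not by guessing.

Picks that match no anchor are offered for proline bridging: two orphan picks
from distinct strips agreeing within √2-widened tolerances (both carry
position error) whose mean nitrogen lies in the proline ¹⁵N window
(128–143 ppm) create a virtual pair node with edges from both strips.  The
nitrogen gate is what distinguishes a genuine proline gap from a merely
missing strip — the two situations are otherwise observationally identical —
and it is physically grounded: no other residue type reaches the proline
¹⁵N region.  Acceptance of edges and bridges is a single global greedy pass
by ascending match distance; for the complementary-4D route, where 2D picks
are Cartesian combinations of CO-only and N-only picks, accepted evidence
consumes its constituent 1D picks so that redundant combinations cannot
create spurious bridges.

Chains are maximal simple paths in the consistency-filtered adjacency graph
(an anchor-to-anchor edge survives if the reverse evidence agrees or is
absent, not if it contradicts; branch points and cycles are opened at their
worst edges).  Chain assembly is orientation-free: from (CO, N) content
alone, without residue typing, the forward/backward sense of an adjacency is
undecidable, so direction labels are attached only at scoring time from the
synthetic ground truth.  A chain's length is reported as the number of
CON-pair nodes it visits — one sequential transition per pair.

Scoring follows the published table format.  For pair (j−1, j), forward
evidence lives on strip j−1 and backward evidence on strip j+1; a direction
is matched when the carrier strip has an accepted edge to a node whose pair
equals the true shifts within tolerance.  When the carrier strip cannot
exist (chain terminus or proline), the direction is credited iff the pair's
own node was identified; a perfect data set therefore scores 100 % in both
rows, which is the behaviour the denominators imply.  The complementary-4D
route is scored against the 5D experiment's eligible-pair set, since the
pair of 4Ds carries the same information.

## Problem sizes and test conditions

The end-to-end study uses a 100-residue synthetic IDP with ten prolines,
64×64 resolved grids, an 1100-point NUS schedule and peak signal-to-noise 20,
with all defaults above; it recovers ≥95 % of the 99 eligible sequential
pairs in both directions, bridges all ten prolines, and — on the same spin
system — the amide-start experiment recovers no proline pair at all.  Smaller
fixtures (5- to 50-residue chains) exercise the individual rules.  The
oracle for reconstruction is a dense FFT on fully sampled instances; the
oracle for the mixing walk is an independent eigendecomposition.

## Known limitations

* Synthetic shifts have no sequence-neighbour correlations and exact
  Lorentzian-ish lineshapes; real IDP spectra add solvent exchange
  broadening, temperature gradients and ²H isotopomer satellites (visible in
  real ¹⁵N dimensions, not modelled).
* Anchor dimensions are idealized as conventionally sampled; joint 4-D NUS
  artefact structure is therefore not represented, and passing tests say
  nothing about reconstruction quality under a shared sparse schedule.
* Amplitude ratios between diagonal and cross peaks follow the windowed
  walk model, not measured transfer efficiencies.
* Near-degenerate anchors (same residue type, shifts within tolerance) are
  rejected as ambiguous rather than resolved; sequences with several such
  coincidences lose the affected links, as real analyses do without extra
  dimensions.  Residue-type mapping of finished chains onto the sequence is
  out of scope; scoring uses the synthetic ground truth.
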