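# Methods

## Physical model

A fluorophore is modelled as an ideal oscillating electric dipole embedded
in the aqueous medium above a planar layered substrate
(glass / graphene / SiO₂ spacer / water). Its normalized total decay rate
S — total dissipated power relative to the same dipole in unbounded
water — follows the classical wavevector-resolved treatment of dipole
emission near stratified media: S equals one plus the real part of a
reflected-field correction integral over the normalized in-plane
wavevector q, with the standard s/p integrands for horizontal and vertical
dipoles and, when finite layers exist on both sides of the emitter, the
full two-sided cavity form (multiple reflections summed via the
1/(1 − r_b r_t e^{2ikw(z_b+z_t)}) denominator). Reflection coefficients
come from the transfer-matrix recursion; the Fresnel convention is the one
in which a perfect mirror has r_s = −1, r_p = +1, and every normal
wavevector component takes the square-root branch with non-negative
imaginary part (decaying evanescent waves).

The absorbing graphene monolayer makes the integral pick up near-field
energy transfer, which is what converts lifetime into distance. Lifetimes
follow from the free-space photophysics of the dye:

    tau(z) = tau0 / (1 − phi + phi · S̄(z)),

with the spectrally averaged rate S̄ formed first (rates averaged over the
emission spectrum, then converted once to a lifetime).

Assumptions: planar geometry, laterally homogeneous layers, a fixed dipole
orientation class (horizontal for the membrane-embedded head-group label;
`isotropic` is the exact 2:1 horizontal:vertical mix), and linear passive
media. Only the emission/lifetime channel is modelled — no excitation
enhancement or detected-intensity model.

## Height reference

Heights are measured from the graphene top surface, the physical origin of
the energy-transfer ruler. Water-accessible dye positions start at the
SiO₂ spacer surface (z = 10 nm for the default 10 nm spacer); calibration
curves are computed on z ∈ [10, 40] nm by default. In this frame the
bottom leaflet of an SLB resting on the spacer sits near z ≈ 11 nm and the
lifetime recovers 90% of its far-field plateau near z ≈ 24 nm, i.e. within
the ~25 nm dynamic range characteristic of graphene-based energy transfer.

## Materials and parameters

| parameter | default | note |
|---|---|---|
| glass index | 1.52 | coverslip |
| SiO₂ index / thickness | 1.46 / 10 nm | CVD spacer |
| water index | 1.333 | top medium |
| SLB slab index | 1.46 | membrane treated as a homogeneous slab |
| graphene thickness | 0.34 nm | single-sheet effective optical thickness |
| graphene index | n = 3.0, k = (5.446/3)·λ[µm] | Bruna–Borini ellipsometry parametrization, packaged as a replaceable dispersion table |
| tau0 / phi | 2.6 ns / 0.36 | Atto655, horizontal dipole |
| emission spectrum | synthetic asymmetric Gaussian, peak 684 nm | stand-in for the Atto655 band; replaceable by a measured `wavelength_nm,weight` table |

Every value is overridable through `StackSpec`, `Emitter`, or the TOML
configuration. Results that hinge on the graphene optical constants (e.g.
the exact magnitude of the below-SLB curve shift) will move somewhat with
a different dispersion table.

## Numerics

**Wavevector quadrature.** The integral is split at the branch point
q = 1. The propagating part uses Gauss–Legendre nodes in θ with q = sin θ,
which removes the 1/√(1−q²) endpoint singularity. The evanescent part is
integrated in s = √(q²−1) over panels split at every branch point
s_c = √((n/n_top)² − 1) of the (nearly) lossless media, each panel mapped
through the cubic smoothstep so the square-root behaviour at the panel
ends becomes analytic; strongly absorbing media (graphene) have their
branch point far off the real axis and need no split. The tail is capped
at s = 50 — contributions beyond are damped at least like
exp(−2ks·(z + spacer)) and are far below the quadrature tolerance for this
geometry. Default fixed node counts (96 propagating, 24 per evanescent
panel) agree with the adaptively refined integrator to better than 1e−8
relative and with a 10⁶-node brute-force trapezoid to 1e−6 (tested); the
public `relative_decay_rate` doubles node counts until stable to 1e−9.

**Spectral averaging.** The emission spectrum is resampled to a uniform
2 nm grid over its support; the dispersions involved are smooth, so finer
grids change S̄ negligibly.

**Curve families.** The below-SLB calibration curve depends on the slab
thickness d. A family on d ∈ [0, 10] nm in 0.25 nm steps is precomputed
(the substrate reflection and height phases are shared across the family,
so this costs little more than one curve) and inversions are interpolated
linearly in d between exact single-curve inversions. Above-SLB curves
barely depend on d, so a coarse family (2.5 nm steps) suffices.

**Inversion.** τ(z) is interpolated with a cubic spline on the rising
branch (up to the first local maximum, or the grid end) and inverted by
bracketed root finding (`brentq`, xtol 1e−7 nm). Lifetimes outside the
branch raise an out-of-range error rather than being clamped — beyond the
first maximum the distance is outside the GIET dynamic range.

**Iterative thickness estimation.** Starting from d = 0, the fixed point
z_top = g_top(τ_long, d), z_bottom = g_bottom(τ_short, d),
d ← z_top − z_bottom is iterated until |Δd| < 0.01 nm (cap 20). Because
g_bottom moves by well under 0.1 nm per nm of d, the map is strongly
contractive and converges in ≤ 4 iterations on forward-model pairs;
d = z_top − z_bottom holds exactly on output by construction.

**Curve-shift metric.** The horizontal displacement between two
calibration curves is max over shared invertible lifetimes of
|z_a(τ) − z_b(τ)|, restricted to z ≤ 25 nm. Beyond the dynamic range the
curves are nearly flat, and dividing a sub-1% lifetime offset by a
vanishing slope would report nanometre "shifts" that no measurement could
resolve; the windowed metric reports the shift where inversion is actually
performed. Under it, an 8 nm slab shifts the below-SLB curve left by
≈ 0.6 nm, while the above-SLB curve coincides with the bare-substrate
curve to ≈ 0.01 ns (≈ 0.5% of the lifetime dynamic range) — coincidence is
therefore asserted in the lifetime domain.

## TCSPC model and fitting

Decays are modelled per bin as the exact integral of two exponentials
convolved with a Gaussian IRF (exponentially-modified-Gaussian CDF
differences, evaluated in log-stable form) plus a constant background;
σ = 0 switches to the analytic delta-IRF limit. Defaults: 50 ns window,
16 ps bins, IRF σ = 100 ps with a 2 ns arrival shift — typical hardware
values, all configurable. Fits maximize the Poisson likelihood (correct in
the low-count tail, where least squares is biased) with the analytic
gradient in log-parameter space; initialization uses the pre-rise bins for
the background and a weighted log-linear tail fit for the long lifetime.
Output lifetimes are relabeled so τ_short ≤ τ_long (bottom/top leaflet
convention); fits whose lifetimes collapse within 1% are flagged as
effectively mono-exponential. A constant background term is always
included: it is identifiable at 10⁶ photons and real data always have a
dark-count floor.

## Synthetic data

The generator emulates the study design: for a true geometry
(z_bottom, d) it computes the exact lifetime pair through the calibration
model, then draws photon micro-times from the three-component mixture
(background uniform in the window; each leaflet an IRF-convolved
exponential) by inverse-CDF sampling on a 0.25 ps grid, truncated to the
window and renormalized — exact, vectorized, no rejection loops. Defaults:
10⁶ photons per bunch, 20 bunches, leaflet fraction 0.5 (symmetric
labelling), background fraction 0.02 (realistic but small); per-bunch
generators are seeded `seed + bunch_index` so any subset reproduces in
isolation. The default panel spans 3 lipids × 4 cholesterol levels with
plausible thickness truths (3.7–6.4 nm).

What the generator does **not** emulate: lateral heterogeneity and
lipid-phase domains, photobleaching, detector afterpulsing and dead-time,
leaflet-dependent brightness (the leaflet amplitude ratio is a free
parameter, not asserted), and substrate roughness. Passing end-to-end
tests therefore demonstrate the correctness and statistical precision of
the analysis chain on ideal measurements, not the sample-induced
variability of real SLBs — real bunch-to-bunch spreads (~0.4 nm) are
dominated by sample heterogeneity that synthetic data lack (~0.1 nm at the
same photon count).

## Aggregation and trends

Each bunch is fitted and inverted independently; the thickness estimate is
the mean ± sample SD (ddof = 1) over converged bunches, with dropped
bunches (failed fit, degenerate fit, out-of-range inversion, unconverged
iteration) excluded and counted — clamping them would bias the mean.
Thickness-vs-cholesterol trends are summarized by an ordinary unweighted
least-squares parabola (a 1/sd² weighted option exists behind a flag);
this is a descriptive device only and implies no physical square law.

## Known limitations

* The graphene dispersion is a two-parameter model; absolute curve shapes
  (and the ~0.6 nm slab shift) inherit its uncertainty.
* Measured heights include the dye/linker offset: no subtraction is
  applied, so bilayer thicknesses are systematically larger (≈ 5 Å) than
  head-group-to-head-group distances from scattering methods.
* Inversion is restricted to the monotone rising branch; dyes beyond
  ~25 nm from the graphene are reported as out of range.
* The biexponential fit assumes exactly two lifetime components plus flat
  background; strongly heterogeneous membranes violate this.
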