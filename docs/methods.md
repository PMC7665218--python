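# Methods

This note documents the models implemented in `fibrilkit`, their
assumptions, the defaults that matter, what the synthetic generators do
and do not emulate, and the numerical choices made where the design was
genuinely open.

## Helical lattice arithmetic (`fibrilkit.helix`)

A fibril lattice is described by a screw operator: rise (Å) and twist
(degrees) per helical step, with symmetry C1, quasi-2₁, or C2. Negative
twist denotes a left-handed helix; handedness is carried as a property of
`HelicalParams`. Internal lengths are Å; MPL values are kDa/nm, with the
Å→nm conversion confined to the reporting boundary, because the two unit
systems are conventional in, respectively, lattice parameters and MPL.

*Crossover period.* The axial distance over which the accumulated twist
reaches 180° (mod 360). For quasi-2₁ input the relevant per-step rotation
is the deviation of the twist from 180°, so the period is
`rise·180/|180 − twist|`; for C1/C2 the twist is wrapped to (−180, 180°]
first. An untwisted lattice returns `math.inf` — a usable "no crossover"
value rather than an exception, so vectorized callers can filter.

*Quasi-2₁ ↔ per-dimer equivalence.* Two screw steps advance one subunit
by one molecule: `(rise, twist) → (2·rise, 2·twist − 360)`. The two
descriptions give identical crossover periods (property-tested), and
`quasi21_from_dimer` inverts the map exactly.

*MPL arithmetic.* `mpl_from_rise` (mass per rise) and
`expected_crossbeta_mpl` (mass per β-sheet spacing, default 0.48 nm from
the canonical 0.47–0.48 nm range) are one-line identities;
`subunit_count_from_mpl` rounds the measured/expected ratio to the nearest
integer, flags ratios more than 0.25 from an integer as ambiguous, and
breaks exact half-integer ties toward the smaller count (conservative:
prefer the less elaborate structure, always flagged).

*Spiral-path strain.* A core of twist period L (nm) forced to follow a
helical path of radius R has path length √(L² + 4π²R²) per turn
(validated against quadrature). The strain factor is reported in two
conventions: the exact ratio path/L, and the ratio with the path rounded
to integer nanometres first — the arithmetic used when such estimates are
quoted to two digits (95/88 = 1.08). Both are returned; consumers choose.

*Free energies.* `entropy_penalty` is RT·ln(volume-reduction factor);
`ddG_from_ratio` is RT·ln(solubility ratio) with first-order (delta
method) error propagation RT·σ/ratio, cross-checked against lognormal
Monte Carlo within 10%. Default temperature is 298.15 K; a sample
temperature near 24 °C corresponds to ~297 K, and the temperature is an
explicit argument everywhere, since RT estimates quoted without a stated
temperature differ by ~1% across this range. Note that RT·ln(1.9) ≈ 0.38
kcal/mol at 297 K, slightly above the commonly quoted 0.35 ± 0.19 for the
FUS-LC-C/FUS-LC-N solubility ratio — consistent within its uncertainty;
averaging per-experiment log-ratios rather than ratios would account for
the difference, but that raw data is not available, so both entry points
(ratio-based and pair-based) are provided and neither is adjusted.

## INEPT disorder quantification (`fibrilkit.inept`)

The signal model for a Cα peak after ¹H→¹³C INEPT transfer with delays
τ₁, τ₂ is sin(2πJτ₁)·sin(2πkJτ₂)·exp(−2τ₁/T₂H)·exp(−2τ₂/T₂C), with
J = 140 Hz by default and k the α-proton count (Gly→2, others→1; CH₃
groups are not modelled). The normalization is fixed by the ideal maximum:
both sines at unity with no relaxation give exactly 1, which is what makes
the reduction factors (0.37 Gly, 0.23 non-Gly at the published maxima)
well defined. Delays are milliseconds and J is Hz; the phase is
2π·J·(τ·10⁻³) with the conversion in exactly one place — this is a classic
silent-bug site and is pinned by the analytic tests.

Inverting ∂(amplitude)/∂τ = 0 gives T₂H = tan(2πJτ₁,max)/(πJ) and
T₂C = tan(2πkJτ₂,max)/(kπJ), valid on the first tangent branch
(2πkJτ < π/2); delays at or beyond the quarter-period singularity are
rejected as non-physical. A property test confirms the closed form and the
signal model are mutually consistent (numerical derivative ≈ 0 at the
inferred maximum over fuzzed J, k, T₂).

`fit_tau_max` locates each scan's maximum by quadratic interpolation
through the top three points (repeated delays are averaged first), so the
coarse grids of real delay-dependence experiments still give sub-grid
maxima; a maximum on the grid boundary is an error, not a value. The scan
structure (which delay was varied at which fixed partner) is inferred from
the table: the largest row group sharing the other delay. Whether the τ₂
scan was acquired at τ₁ = τ₁,max is generally not recorded in published
tables; the generator adopts that convention and the fitter does not
require it.

The disorder chain is pure algebra: corrected ratio = observed ×
(reduction_other/reduction_gly); Gly share = 100·r/(1+r). The observed
ratio itself (how overlapping Gly and non-Gly Cα regions were integrated)
is an input, not something this package re-derives from spectra — spectral
processing is out of scope.

`INEPTExperiment.fit()` returns an `INEPTResults` object carrying the
per-class delay maxima, T₂ values and reduction factors, with `summary()`,
`plot()` and `disorder_estimate()`.

## Dark-field MPL (`fibrilkit.darkfield`)

Intensities integrated over 100 nm × 60 nm boxes arrive as a table
(`segment_id, kind, I_center, I_B1, I_B2`). The calibration constant
I_TMV is the mean background-corrected intensity over TMV rods
(131 kDa/nm); each fibril count is (I_F/I_TMV)·131 with
I_F = I_center − (I_B1+I_B2)/2. The two flanking background boxes are
averaged as stated; a row missing one box reuses the other with a warning
(the published procedure always has both, so this is a permissive
extension, not an interpretation). Negative counts are retained — they are
meaningful for the error distribution — and excluded from the physical
histogram fit only on request (`exclude_negative`, default off).

The error statistic √(3/2)·(I_B − I_B,ave)/I_TMV·131 evaluates the MPL
formula on pure background; the √(3/2) reflects the variance of one
centre box minus the average of two background boxes. Its distribution is
centred at zero (tested within 3 SE).

Histogram fitting bins at a fixed user-supplied width (default 2 kDa/nm)
and least-squares fits A·exp(−(x−μ)²/2σ²) on bin centres
(`scipy.optimize.curve_fit`, initialized from sample moments). Whether a
published mean ± uncertainty refers to the fit or to sample moments is
often unstated, so `MPLResults` reports both. An all-equal sample has no
histogram width and is rejected rather than fitted.

## Structure and trajectory metrics (`fibrilkit.structure`)

*Containers.* `FibrilAssembly` is a labelled atom table (chain, subunit,
repeat index, biological residue number, atom name, position) plus a unit
growth axis; construction validates complete backbones (N, CA, C, O) per
residue. `TrajectoryEnsemble` holds frames over a fixed roster with a
frame interval in ns; waters are residues named HOH/WAT/TIP3 and only
their oxygens are used. The growth axis is +z for built assemblies; for
loaded ones it is estimated from the Kabsch rotation relating two chains
(the screw-rotation axis, which is insensitive to where the axis lies and
to the side-to-side alternation of chain centroids under 2₁ symmetry),
falling back to the principal axis of chain centroids for untwisted
stacks.

*Hydrogen bonds.* A bond requires donor–acceptor distance strictly below
3.0 Å and deviation from linearity below 20°, where the deviation is
180° minus the donor–H···acceptor angle at the hydrogen — the standard
reading of "deviation from linearity". Explicit hydrogens are used when
present (any attached H within 1.3 Å of the donor; a bond exists if any
candidate H satisfies the criteria, which handles NH₂ donors); backbone
amide H is otherwise inferred from N/CA/C(prev) geometry (exterior
bisector in the peptide plane, N–H = 1.01 Å). Occupancy is the fraction
of frames containing the bond, verified against an independently written
per-frame scan.

*β-strand assignment.* A residue is strand-like when its backbone N–H
donates to, and its C=O accepts from, the *same residue number* of an
axially adjacent chain of the same sheet — the in-register parallel
criterion — and successive side chains alternate faces of the local sheet
plane. The side is the sign of (Cβ − Cα)·(strand_dir × axis); Gly, with
no Cβ, is exempt and simply advances the alternation parity. Runs are
split where alternation fails and reported only at length ≥ 3 (shorter
runs are not meaningful β-strands). Boundary chains, lacking an axial
neighbour, are excluded rather than misassigned. Under quasi-2₁ symmetry
the "axially adjacent chain of the same sheet" is the same-subunit
neighbour at 2·rise.

*Strand angles.* Strand direction is the first principal component of the
strand's Cα positions (≥ 4 required); angles to the growth axis or
between subunits are reported in [0°, 90°]. A per-strand least-squares
line is the adopted definition; measuring against a sheet-plane normal
would be an alternative, but the line is unambiguous for the 10–11-residue
strands this targets.

*Pseudo-torsion ξ.* The dihedral over (Nε2, Oε1, Cα of molecule k,
Cα of molecule k+1 in the same subunit), wrapped to (−180°, 180°]. The
atom order and IUPAC sign convention are fixed by the physical contract:
side-chain amide O→N parallel to the growth direction gives ξ ≈ 0,
antiparallel gives ξ ≈ ±180° (both verified on constructed geometry).

*Ring flips.* Tyr flips appear as sign changes of χ₂ between the +100°-
and −100°-centred conformers. Counting uses hysteresis: a well is entered
only within ±45° of its centre, so jitter inside one well or excursions
near the ±0/180° barriers do not register as flips. The ±45° band is half
the inter-well separation minus a margin; programmed telegraph series with
5° jitter are recovered exactly.

*Water metrics.* `count_waters_near` counts water oxygens strictly within
a cutoff (default 7.0 Å) of any centre atom/point; `mean_waters_near`
averages over frames and over symmetric centre sets (the equivalent
interior molecules of the two subunits). "Internal" versus "bulk" is the
caller's centre choice, not a classification this package invents.
`transport_time_10A` reports per-molecule first-passage times to a 10 Å
displacement from the initial frame; molecules that never reach it are
censored — counted and reported, never averaged in, since averaging
censored times as if observed would bias the mean downward.

*RMSD and helical-parameter recovery.* RMSD uses optional least-squares
superposition (Kabsch via `scipy.spatial.transform.Rotation`). Measured
rise is the mean axial spacing of consecutive per-chain Cα centroids;
measured twist is the rotation angle (about the growth axis) of the
Kabsch rotation between consecutive chains, circularly averaged — again
location-independent. Builder→measure round trips are exact to ~1e−8 over
rises 2–6 Å and twists 170–190°.

## Synthetic data (`fibrilkit.synth`)

The generators define the test conditions for every estimator; all are
bit-reproducible functions of their seed.

*Idealized monomer and fibril builder.* The template chain is a lattice
idealization, not a stereochemically faithful peptide: Cα every 3.5 Å
along the strand, N–H pointing −z and C=O pointing +z so that stacking at
4.8 Å yields donor–acceptor distances of 2.9 Å with zero deviation from
linearity (and fails cleanly at 6 Å spacing), Cβ alternating sheet faces,
and minimal side chains (OG for Ser; CG/CD/Oε1/Nε2 for Gln/Asn with the
amide O→N direction along +z; CG/CD1/OH for Tyr) where torsion or water
metrics need them. An extended and a U-shaped (hairpin) template are
available. `build_fibril` stacks screw-transformed copies; quasi-2₁
alternates subunit labels per step, and the template sits 3 Å off the
screw axis by default so the two subunits of a 2₁ assembly occupy opposite
sides rather than overlapping. Chains approaching within 1.5 Å raise a
warning, not an error. Consequently, passing tests demonstrate the
*metrics and their inversions*, not force-field realism: real fibrils
have imperfect H-bond geometry, correlated motions, and side-chain
packing that these fixtures deliberately do not emulate.

*Trajectories.* Frames are the base assembly plus per-atom Gaussian
jitter (default 0.05 Å). Programmed hydrogen-bond occupancies are
realized by displacing the acceptor beyond the cutoff in an exact-count
random subset of frames — not per-frame Bernoulli — so small tests are
deterministic: measured occupancy equals round(occ·n)/n exactly.
Programmed χ₂ series are telegraph processes with the exact requested
number of well transitions plus 5° angular jitter, written into atom
positions by internal-coordinate (NeRF) placement of CD1. Waters are
placed uniformly within a radius of a centre. Atoms under direct control
are excluded from the jitter so the programmed ground truth is exact;
everything else jitters freely. Brownian water ensembles (per-coordinate
step σ = √(2DΔt)) provide the internal-vs-bulk transport contrast, with
diffusion constants differing 100-fold giving first-passage ratios
comfortably above 10.

*INEPT curves.* Two 1-D scans (τ₁ at the analytic τ₂ maximum and vice
versa) evaluated from the signal model, plus optional Gaussian amplitude
noise; the analytic maxima are recorded as ground truth.

*Dark-field tables.* Box intensities are a constant background plus
signal plus Gaussian noise, with the noise scale parameterized directly
as the standard deviation of a single MPL count (default 3 kDa/nm — a
realistic dark-field spread consistent with a ~±1 kDa/nm fitted
uncertainty at n = 96; each count combines three boxes, hence the √(3/2)
relation between box noise and count noise). Default study size is 96
fibril segments against 52 TMV rods. Scaling every intensity by a common
factor leaves all MPL outputs unchanged (tested).

## Reference sequence

`fibrilkit.seqstats` embeds the 214-residue FUS low-complexity domain
with biological numbering, from which `FUS_LC_C` (111–214), `FUS_LC_N`
(2–108), the core range 112–150 and the core β-strand segments
(113–122, 135–136, 139–149) are derived. The embedded sequence is a
reconstruction of the canonical human FUS sequence verified against an
extensive set of published range-wise constraints (compositions, per-type
counts, individually reported residue identities in the core, and the
10.02 kDa monomer mass); the ordering of a few residues within the
Gly-rich disordered tail is not independently verifiable here, and no
computation in this package depends on residue order within that span.
Compositions are reported to one decimal; non-standard residue codes are
rejected rather than silently pooled into "other".

## Problem sizes and scope

All analyses here run in seconds on one CPU: fixtures use 3–10 chains of
3–10 residues, trajectories of 10–500 frames, and measurement tables of
tens to ~150 rows — sizes chosen because every estimator reaches its
asymptotic behaviour there while round trips stay exact. The package does
not reconstruct density maps, refine coordinates against maps, integrate
MD trajectories, process NMR spectra, or predict amyloid propensity.

## Package shape

The two analyses that genuinely fit data — the INEPT delay-dependence fit
and the dark-field MPL analysis — follow the statsmodels convention of a
model object whose `fit()` returns a results object with estimates,
uncertainties and `summary()`. The remaining functionality is
deterministic arithmetic or geometry on explicit inputs, where a fitted
results object would be ceremony; those modules expose plain functions
over typed containers.
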