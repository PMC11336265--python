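# Methods

## Scope and model structure

The package models three whole-cell biosensors — arsenic, mercury and lead
— at three levels: the DNA construct (part assembly and export), one cell
(deterministic kinetics of repression and derepression), and a 2D
population (agent-based colony over a diffusing or homogeneous metal
field). The levels are consistent by construction: the activation
threshold used by the population comparator is the same concentration at
which the calibrated single-cell dose response flips.

## Circuit assembly

A sensor circuit is eight parts in a fixed tandem grammar: constitutive
promoter, RBS, repressor CDS, terminator, metal-sensitive (repressible)
promoter, RBS, chromoprotein CDS, bidirectional double terminator. The
grammar is enforced positionally — any role disorder is rejected — and the
same part may appear twice (the RBS BBa_B0030 does). The circuit
partitions losslessly into a regulator operon (parts 1–4, named after the
repressor: arsR / merR / pbrR) and a reporter operon (parts 5–8, named
after the chromoprotein: mRFP1 / amilCP / amilGFP).

Export: FASTA is the in-order concatenation of part sequences with no
spacer — assembly-standard scar chemistry is out of scope. GenBank files
carry one feature per part (promoter/RBS/CDS/terminator keys), contiguous,
non-overlapping, plus-strand, 1-based inclusive coordinates, with the part
ID as a qualifier; the double terminator is annotated with a
bidirectionality note rather than a second strand.

Real part sequences are not bundled. Placeholder sequences with plausible
lengths (promoters 35 bp, RBS 15 bp, CDS 700 bp, terminators 80/129 bp)
are drawn deterministically: the per-part stream seed is
`SeedSequence([global_seed, crc32(part_id)])` and bases come from PCG64
draws mapped onto ACGT, so one integer reproduces a whole fixture genome
and distinct parts get independent streams. A user FASTA keyed by part ID
replaces fixtures record by record.

## Single-cell kinetics

State: free repressor R, metal–repressor dimer D and chromoprotein C
(molecules per cell), with ambient metal M (µg/L) imposed as a boundary
condition — the bath is not depleted, cells being small relative to it.
Binding is mass-action directly in concentration units (no molar
conversion; all concentrations in this domain are quoted in µg/L), and
repression is a Hill function of free repressor:

    dR/dt = n·α_R − k_b·R·M + k_u·D − δ_R·R
    dD/dt = k_b·R·M − k_u·D − δ_D·D
    dC/dt = n·α_C·P_on(R) − δ_C·C,    P_on(R) = 1/(1 + (R/K)^h)

Defaults (all in `defaults.toml`): n = 15 copies, α_R = 2 and α_C = 1
molecules·min⁻¹·copy⁻¹, δ_R = δ_D = δ_C = 0.05 min⁻¹, k_u = 0.1 min⁻¹,
K = 50 molecules, h = 2, on-fraction 0.5. These are conventions of
plausible magnitude, not measurements; what is *not* a convention is the
threshold behaviour, which calibration pins (below).

Because M is imposed, R and D close among themselves and the steady state
is available in closed form,

    R_ss(M) = n·α_R / (δ_R + k_b·M·δ_D/(k_u + δ_D)),

which the steady-state dose response, the calibration and several test
oracles use; the ODE integration (`scipy.solve_ivp`, LSODA, atol 1e-9,
rtol 1e-6, from the empty-cell state R=D=C=0) is checked against it.

**Calibration.** `calibrate_threshold` adjusts k_b by Brent root finding
so that P_on(R_ss(threshold)) equals the on-fraction — i.e. the dose
response flips exactly at the sensor's activation threshold (10 µg/L
arsenic, 6 µg/L mercury, 10 µg/L lead). The ON comparison carries a 1e-9
tie tolerance so the calibrated sensor reads ON at exactly its threshold.
A copy "expresses" when P_on exceeds the on-fraction; time series report
the real-valued n·P_on (and a rounded integer count). Note the
trajectory's two derepressed extremes: it *starts* fully derepressed
(R = 0 at t = 0, so the first output is n copies) and approaches n again
for M far above threshold, while the plateau at exactly the threshold is
n × on-fraction.

The single-cell model is deliberately deterministic; noise lives in the
population layer's induced-error process.

## Metal field

A square dish of side 800 µm (grid spacing 10 µm), in two modes.
Homogeneous mode is a constant bath — stepping is a no-op. Central-source
mode models "continuously poured at the centre" as a Dirichlet clamp: grid
nodes within 100 µm of the centre are held at the pour concentration while
the rest evolves by explicit FTCS diffusion (5-point Laplacian,
D = 3×10⁴ µm²·min⁻¹, a small-molecule order of magnitude) with zero-flux
(reflecting) or absorbing walls. A clamp was preferred over an additive
flux source because no pour rate is available to parameterise the latter.
None of these geometry/transport values is a measured quantity; they are
calibrated only to sustain the qualitative inner-high/outer-low radial
profile.

The explicit scheme's stability bound dt ≤ dx²/(4D) is enforced — a
violating step raises rather than silently shortening — and the driver
advances by stable substeps (0.9 safety factor). With the clamp off and
zero-flux walls the scheme conserves total mass to machine precision, the
field never exceeds the source concentration (discrete maximum
principle), and the azimuthally averaged concentration is non-increasing
in radius; all three are tested. Cells sample the field by bilinear
interpolation; queries outside the dish are errors.

## Colony simulation

Cells are 1 µm disks on a continuous plane; mild overlap is permitted and
no rigid-body mechanics are modelled (rendering-level detail the counts do
not depend on). Per step of dt = 1 min, in order: (1) division with
probability growth·dt, suppressed when the population is at its cap
(carrying capacity, not an error), daughter adjacent at a 2 µm random
offset; (2) local concentration sampling; (3) nominal state = local ≥
threshold; (4) induced error: with probability 0.1 % the reported state is
inverted for this step — transient, both false positives and false
negatives, matching the observation that some in-range cells fail and some
out-of-range cells fire; (5) maturation debounce: the visible `expressing`
flag follows the reported state only after it has persisted 20 min
(default), modelling chromoprotein accumulation and decay symmetrically.
One PCG64 generator seeded from the scenario seed drives all draws in
fixed cell-id order, so runs are bit-reproducible.

Regimes (the twelve built-in scenarios are three sensors × four
conditions): **growing** — 1000 cells seeded uniformly in a central
150 µm disk, growth 0.023 min⁻¹ (≈30 min doubling), cap 20 000, central
source at the threshold concentration, 190 min; **stationary** — 1999
cells uniform over the dish, growth 1e-6 min⁻¹ (virtually none), cap
2000, homogeneous bath at the threshold, half-threshold or zero
concentration, 240 min. Growth rate, seeding radius, maturation delay and
run lengths are this package's choices; the population counts,
concentrations, thresholds and error rate are the study conditions. The
seeding disk intentionally exceeds the 100 µm source disk: daughter
placement is a local offset and does not reproduce the mechanical outward
push of a real expanding colony, so seeding across the activation front is
what produces the expressing-centre/dark-rim pattern.

## What the synthetic data does and does not emulate

The fixtures emulate part records, the stated concentration fields and
the two placement regimes. They do not emulate real nucleotide sequences
(placeholders), colony mechanics (no pushing, so spatial expansion is
understated), metal uptake or depletion by cells, 3D diffusion, or
mRNA-level stochasticity. Passing tests therefore demonstrate the logic
and calibration of the sensor model under the stated conditions, not
quantitative agreement with any wet-lab colony geometry.

## Numerical and degenerate-input choices

* ON/OFF ties: P_on ≥ on_fraction − 1e-9, so calibration-exact thresholds
  read ON.
* Homogeneous bath at exactly the threshold compares equal (same float),
  so the whole population is nominally ON.
* Division when exactly at cap: silently suppressed; excess simultaneous
  division attempts are granted in cell-id order.
* Zero diffusion or homogeneous mode: field stepping is an exact no-op.
* `run_scenario` sizes: stationary runs (2000 cells, 240 steps) take well
  under a second; the growing run (20 000 cells, 190 steps plus ~250 k
  diffusion substeps) takes about half a minute.

## Known limitations

* The threshold comparator in the population layer is binary; cells near
  the source rim flip with the interpolated field rather than integrating
  the single-cell ODE (the calibrated ODE is the comparator's
  justification, not its implementation).
* Kinetic rate magnitudes are conventions; only the threshold location is
  calibrated. Absolute molecule numbers and response times should not be
  read quantitatively.
* The growing colony's footprint growth is diffusive (offset placement),
  so late-time spatial patterns are qualitative.
* SBOL export and live part-registry queries are out of scope; exports are
  FASTA and GenBank only.
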