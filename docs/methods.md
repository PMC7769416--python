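# Methods

This note records the models implemented in `scatterrisk`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
setup does and does not emulate.

## Phantom and materials

Phantoms are regular voxel grids (axis order x/y/z, voxel-center world
convention `world = origin + (index + 0.5)·spacing`) whose integer labels
map to materials with mass density and elemental composition in the style
of the ICRP reference-tissue tables. The shipped `female_torso_spec()` is
a deliberately simplified stand-in for a segmented whole-body model: an
elliptical soft-tissue trunk (224 × 144 × 440 mm at 4 mm voxels,
~222k voxels) with 14 shape-primitive organs at anatomically ordered
axial positions — thyroid superior, breasts/lungs/heart mid-thorax,
stomach/liver upper abdomen, large intestine, bladder/uterus/ovaries
pelvic. Organs are painted in list order (later organs overwrite
earlier), so labels are disjoint by construction. This gives the
downstream stages the features that matter — an in-field high-dose
region, organs at graded distances from the field edge, low-density lung,
multi-decade out-of-field dose range — while making no claim to
anatomical realism.

CT calibration: the inverse assignment of density from CT number uses a
piecewise-linear table; the shipped default has three anchor points (air
−1000 HU / 0.0012 g cm⁻³, water 0 HU / 1.0, compact bone +1300 HU /
1.85). No specific scanner calibration is reproduced; the table is an
editable convention. Grid downsampling supports integer factors only:
block averaging for scalar fields (conserves the integrated quantity to
1e-6 relative) and block-center picking for label grids.

## Beam geometry and plans

The gantry rotates about the patient z (superior–inferior) axis; a beam
is a point source at SAD = 1000 mm with a rectangular field defined in
the isocenter plane. The whole-breast plan uses opposed grazing
tangentials (gantry 45°/225°, 70 × 100 mm field) prescribed 50 Gy in
25 fractions to the breast; the breast+nodal plan adds opposed
anterior/posterior nodal fields over the subclavicular region, carrying
their own 50 Gy course (total plan prescription 100 Gy split equally
over four beams). Field-in-field segments, MLC shapes, and accelerator
head scatter/leakage are deliberately not modelled: the simulated
out-of-field dose is internal body scatter only.

Per-beam dose is rescaled so each beam delivers its prescription share at
its specification point. On Monte Carlo grids the specification-point
dose is averaged over a 10 mm-radius ball (the single containing voxel is
used for deterministic grids); a point estimate on a noisy grid would
make the overall normalization fluctuate with one voxel's tally.

## Monte Carlo transport

Photons are tracked by Woodcock (delta-collision) sampling against an
energy-dependent majorant cross section, which handles heterogeneous
voxels without boundary ray tracing. Interactions: Compton scattering
sampled from the Klein–Nishina distribution by rejection (constant
envelope 2, the forward-peak value of the angular kernel), and
photoelectric absorption with a power-law mass coefficient
τ/ρ = C·Z_eff^3.8·E^−3.2 calibrated to water at 30 keV. Coherent
scattering and pair production are neglected — at 0.25–6 MeV in tissue
the induced error in total attenuation is at the percent level (the
package's water value at 1 MeV is within 2% of the published 0.0707
cm⁻¹). The tabulated energy range is 0.01–10 MeV with log-log
interpolation on 160 nodes.

Energy deposition uses the kerma approximation: the energy transferred to
secondary electrons (full E for photoelectric, E − E′ for Compton) is
deposited in the interaction voxel, and photons below the 10 keV cutoff
are deposited locally and terminated. At 2–4 mm voxels the CSDA range of
the liberated electrons (≲2 mm below ~600 keV) makes this a reasonable
approximation away from interfaces; near build-up regions and
low-density boundaries it overestimates local deposition, a known
limitation.

Statistical uncertainty is the batch estimate: histories are split into
≥10 independent batches (seeds spawned from one `SeedSequence`, so runs
are bit-reproducible given the seed), and the per-voxel relative 1σ of
the batch mean is reported, quoted at the 68% level. Voxel-tally
correlations within a history are thereby captured, unlike a naive
per-history estimator. The mean-dose CI of an organ combines per-voxel
absolute σ in quadrature divided by the voxel count, treating voxels as
independent — an approximation that ignores inter-voxel correlation from
shared histories; the max-dose CI is the maximum voxel's own σ.

Default problem sizes are desk-scale by design: 2×10⁵ histories per beam
on the ~222k-voxel torso (seconds per beam on one CPU) resolve organ
means over four decades of dose but leave single-voxel maxima and
in-field voxel noise large (tens of percent). Cluster-scale history
counts are configurable but not the default; consequently absolute
in-field dose distributions, their gamma agreement with a planning
system, and DVH tails should be read as method demonstrations, not as
converged values.

## Analytic beam model

The deterministic engine evaluates inverse-square × exponential depth
attenuation with an exponential build-up (default build-up length 12 mm,
effective attenuation 0.05 cm⁻¹, isocenter depth 50 mm) × a product of
error-function lateral profiles (penumbra σ 4 mm), plus an additive
out-of-field scatter tail a·e^(−d/L) in distance d to the field edge
(default a = 0.005 relative, L = 80 mm). `fit_scatter_tail` recovers
(a, L) by least squares on log dose over voxels beyond a minimum edge
distance; on a noiseless analytic grid the recovery is exact, and on
Monte Carlo grids the fitted L is stable to ~10% CV across seeds at
2.5×10⁵ histories.

## DVH, OED, EAR

DVHs are exact voxel counts into left-closed right-open bins; the bin
volumes sum to the organ volume identically. Default binning is
two-segment — 0.01 Gy below 2 Gy, 0.1 Gy above — to keep the exponential
weighting of the linear-exponential response resolved in the out-of-field
regime without carrying 10⁵ bins for in-field organs. OED uses bin-center
doses, so the linear OED equals the voxelwise mean only to half a bin
width; tests and the linearity property account for exactly this bound.

Model selection per organ compares the mean dose to 2 Gy with a strict
inequality at the boundary (mean > 2 Gy → linear-exponential, α = 0.044
Gy⁻¹; else linear). A single model is used per organ even when its DVH
spans both regimes — no hybrid piecewise response is defined.

Risk coefficients ship as an editable YAML table (per organ and exposure
age 30/50, attained age 70, with 90% CIs), with per-Gy values consistent
with the atomic-bomb-survivor solid-cancer incidence analyses. EAR CIs
are the coefficient CI scaled by OED with the lower bound clamped at
zero; the dose's statistical uncertainty is reported separately in the
organ-dose table and deliberately not convolved into the risk CI, since
no standard convolution is defined for these quantities and coefficient
uncertainty dominates.

## Dose comparison

The mean-dose difference is Δ = (TPS − MC)/MC × 100, i.e. normalized to
the Monte Carlo mean; a flag provides the opposite normalization. The
gamma index is local-normalization: at each reference voxel center the
minimum over spatial offsets of
√[((D_e − D_r)/(3%·D_r))² + (|r|/3 mm)²], searching a cubic offset
lattice out to 3×DTA with trilinear interpolation of the evaluated grid.
The lattice pitch defaults to DTA/3 (1 mm at 3 mm DTA) — a deliberate
resolution/cost balance for 3-D grids on one CPU; it is configurable down
to DTA/10 and the tests cross-check the fine-pitch setting against an
exhaustive-search implementation. Offsets are visited in order of
increasing distance with early termination once the distance term alone
exceeds every voxel's current best, so near-identical distributions cost
a handful of offsets. Voxels below 10% of the reference maximum are
excluded from statistics; γ ≤ 1 (with 1e-6 float slack) passes.

## Pipeline and reproducibility

One global seed fans out through `numpy.random.SeedSequence.spawn` to
per-beam transport seeds, so every stage is independently reproducible
and two runs with the same configuration produce byte-identical CSV
reports. Outputs: an organ-dose table (mean/max ± 68% CI), a risk table
(organ × exposure age with model, OED, EAR, 90% CI; organs without a
survivor-data coefficient listed blank), per-organ DVH CSVs, and a
manifest with seed, package version and a configuration hash.

## What the synthetic setup shows — and does not

Passing tests demonstrate: correctness of the OED/EAR arithmetic against
published mean-dose/EAR pairs in the linear regime; the Δ convention
against published table values; transport correctness against closed-form
attenuation and Klein–Nishina quadrature; gamma behaviour on constructed
cases and against an independent implementation; and the qualitative
out-of-field physics (monotone dose fall-off with distance, nodal fields
raising head/neck dose, prescription linearity, seeded determinism).
They do not validate absolute organ doses for real anatomy: the phantom
is geometric, spectra are parameterized rather than measured, electron
transport is absent, and history counts are orders of magnitude below
what converged in-field distributions require. Risk outputs inherit every
caveat of the survivor-data coefficients (population transfer, sex
averaging, attained-age specificity).
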