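# Methods

`muquant` evaluates how the CT acquisition protocol (tube potential kVp and
quality-reference mAs, QRM) of a SPECT/CT system propagates into quantitative
¹⁷⁷Lu imaging: through the attenuation map (μ-map) at the 208.4 keV emission,
through Chang-type attenuation correction factors (ACF), through μ-map noise,
and finally through OSEM-based activity recovery. Everything runs on digital
phantoms, so the whole chain is testable without scanner data. This note
records the models, the defaults and their rationale, and the limits of what
the synthetic pipeline can show.

## Reference physics

Theoretical linear attenuation coefficients come from the elemental mixture
rule, μ(E) = ρ Σᵢ wᵢ (μ/ρ)ᵢ(E), with elemental mass attenuation tables
packaged as plain text on a 40–400 keV grid. Off-grid energies are
interpolated log-log linearly — the standard scheme for photon cross sections;
grid energies reproduce the stored values bit-exactly, and no extrapolation is
allowed. The H, C, N, O entries are transcribed anchors validated through
compound sums (water and polyethylene); the remaining low-Z elements (F, Na,
Mg, P, S, Cl, Ar, K, Ca) are derived from a Klein–Nishina scattering baseline
plus photoelectric (∝ Z⁴·⁵/E³) and coherent (∝ Z²·⁵/E²) residual terms
calibrated on oxygen (`scripts/build_fixtures.py`). The derivation reproduces
the carbon anchor to 0.1–0.6% and ICRU cortical bone at 100 keV to ~1%; above
150 keV, where the 208.4 keV work happens, these residuals are a <2%
correction for every element used. The power-law photoelectric term
overestimates the (tiny) photoelectric contribution of Ca/K above ~150 keV by
up to a few times; this affects only bone-like emulation materials at the
per-cent level and none of the anchor quantities.

Tissue compositions are ICRU-44-style defaults (lung, adipose, breast,
muscle, liver, cortical bone), with the lung-inhale insert at the reported
density 0.204 g/cm³. The plastic-water body material is a generic epoxy-based
solid-water formulation (8.09% H, 67.22% C, 2.40% N, 19.84% O, 0.13% Cl,
2.32% Ca, ρ = 1.035 g/cm³), giving μ(208.4 keV) = 0.1358 cm⁻¹, within 0.3% of
the manufacturer value 0.1355 cm⁻¹; a manufacturer datasheet transcription can
be dropped into the registry with the same YAML schema. Air is modelled as
N/O/Ar at 1.205 mg/cm³ so its μ is computed (≈1.5·10⁻⁴ cm⁻¹), not asserted as
zero. The registry holds 19 materials: the nine insert tissues, phantom body
and reference media, and the four quantification-phantom plastics.

## Digital phantoms

The electron-density phantom is an elliptical plastic-water cylinder (26 cm
anterior–posterior × 32 cm lateral) with 17 cylindrical inserts (3 cm
diameter) of nine materials: eight materials appear on both an inner ring
(r = 6 cm) and an outer elliptical ring; the 1250 mg/cm³ hydroxyapatite bone
insert appears once, centrally, so the inner section holds nine inserts and
the outer eight. The printed sources give the body half-dimensions but not
insert coordinates, and their inner/outer counts (nine inner excluding the
1250 HA insert, eight outer) cannot all hold with 17 inserts; the layout here
satisfies the 17-insert total, the single-occurrence 1250 HA insert, and the
9 + 8 ring split, and is configurable. Bone inserts are water–hydroxyapatite
mixtures at 200/800/1250 mg/cm³ HA with densities 1.16/1.52/1.82 g/cm³. An
insert-free axial section provides the homogeneous plastic-water region for
noise analysis. Voxelization is by voxel-center membership, which makes
phantom generation bit-deterministic; the native grid is 512 × 512 × 86 at
0.977 × 0.977 × 3 mm³ with the μ-map/SPECT grid at 4.8 mm (128 × 128 × 55).
Label downsampling is majority vote over contained source-voxel centers with
ties broken to the smallest label id (platform independent).

The quantification phantom is a water-filled NEMA-style elliptical body
(30 × 22 cm) holding four attenuation cylinders — polystyrene foam
(Ø 5 cm, 0.023 g/cm³), PTFE (Ø 3 cm, 2.18 g/cm³), polyamide (Ø 3 cm,
1.02 g/cm³), polypropylene (Ø 3 cm, 0.91 g/cm³) — each with an axial bore
carrying a syringe source: 1 mL (Ø 0.7 cm) or 10 mL (Ø 1.6 cm). Source
voxel activities are normalised so the voxelized total equals the nominal
activity exactly. Default nominal activities correspond to a shared
10 MBq/mL stock (10 MBq per 1 mL syringe, 100 MBq per 10 mL syringe), a
typical phantom-filling concentration; only relative errors are analysed, so
the absolute level is inconsequential.

## CT emulation and the HU→μ conversion

The CT emulator replaces the scanner and its iterative reconstruction. Ideal
HU per material are computed at a per-kVp effective monoenergetic energy —
58/66/72 keV for 80/110/130 kVp — representing spectrum, filtration and
beam-hardening calibration. These are deliberately higher than bare spectrum
mean energies: they describe the energy at which a calibrated scanner's HU
scale is effectively anchored, and they keep the bilinear conversion's
round-trip behaviour consistent with the reported soft-tissue accuracy.

HU→μ conversion is the standard bilinear model with breakpoint at HU = 0:
μ = μ_w(HU + 1000)/1000 below (clipped at zero), μ = μ_w + HU·k(kVp) above,
with the bone slope k calibrated per kVp from water and a cortical-bone-like
material. With ICRU-44 compositions the round trip (noise-free emulated CT →
bilinear conversion) recovers soft-tissue μ(208.4 keV) within 3% at the
130 kVp reference setting. At 80 kVp, ICRU adipose lands near −4%: a genuine
property of single-breakpoint bilinear conversion applied to real fat
composition at low effective energy (physical phantom inserts are epoxy
formulations with Z_eff closer to water and do not show it). Resampling of
μ-maps to the SPECT grid is values-based trilinear interpolation, matching
the smoother appearance of scanner μ-maps relative to the underlying CT.

Noise has two components per scan setting. (1) Voxel noise: additive
Gaussian HU noise with per-setting sigma (35…15 HU across the seven studied
kVp/QRM combinations), strictly decreasing in both kVp and QRM. (2) A
per-acquisition global HU offset emulating scan-to-scan calibration drift.
At a 8000-voxel VOI scale, voxel noise averages to ~0.2 HU and cannot explain
per-mille-level variability of repeated VOI means; the drift term is what
carries it. The drift sigma is not set by hand: it is solved in closed form
(including the c₄ small-sample SD bias factor and the local mean slope of the
piecewise conversion at the plastic-water operating point) from packaged
target coefficients of variation. Targets span 3.15–3.55 × 10⁻³ across the
seven settings, decreasing with dose, chosen inside the reported
2.9–3.9 × 10⁻³ range with margin because a 10-repetition COV estimate itself
carries ≈24% relative sampling scatter; the emulator claims the band and the
ordering, not the per-setting endpoints. CTDI_vol values are a fixture
(0.9/1.5/2.0/3.6 mGy anchors) with linear-in-mAs scaling at fixed kVp for
unlisted QRM.

## Chang attenuation correction factors

The first-order (modified) Chang factor at a voxel is the inverse mean
survival over M equally spaced in-plane rays:
ACF = [ (1/M) Σₘ exp(−∫ μ dl) ]⁻¹, with path integrals by fixed-step
trapezoid sampling (step = half the smallest voxel spacing) and trilinear μ
lookup; μ vanishes outside the volume, with interpolation across the boundary
voxel shell so a uniform slab attenuates over its full physical extent. M
defaults to 64 (the tradition is in-plane rays; axial presentation matches).
Halving the step provably reduces the closed-form slab error, and M = 360
agrees with analytic chord-length quadrature at off-center disk voxels to
<0.5%. The expected activity change from an ACF mismatch is
ΔA = (ACF_theoretical/ACF_measured − 1)·100%. The pipeline reproduces the
error-damping property that motivates the analysis: an 18% μ error confined
to a small low-μ insert moves ΔA by only a few per cent, because the insert
occupies a short fraction of every ray.

## SPECT emulation

A slice-by-slice parallel-beam projector applies Beer–Lambert weighting
exp(−∫ μ dl) from each voxel to the detector (rotation-based implementation),
an optional depth-independent Gaussian detector PSF (default σ = 5 mm,
medium-energy collimator scale), and optional Poisson counting noise.
Acquisition defaults mirror the study protocol: 60 views, 30 s per view, and
an image calibration factor (ICF) of 20.3 cps/MBq converting reconstructed
count rate to activity. OSEM uses the matched attenuated projector
(default 6 iterations × 6 subsets); reconstructions are in count rate, with
a calibrated variant folding the ICF into the model. VOI recovery uses
cylindrical VOIs extended beyond the source (default margin 2 × FWHM of the
PSF) to capture spill-out.

Numerical notes: the rotation resampling (bilinear) conserves mass only for
smooth fields — single-voxel sources inflate by up to ~30%, so symmetry and
linearity contracts are exercised on extended sources; OSEM zero handling
keeps voxels with zero sensitivity at zero; all updates preserve
nonnegativity and determinism.

## Experiments and provenance

Four orchestrated experiments reproduce the study structure: `mu_comparison`
(insert VOI means, 3 × 3 × 8 voxels at the 4.8 mm grid, inner/outer rings,
Eq.-style ring mean, relative errors, normality-gated ring comparison),
`acf_delta` (theoretical vs CT-derived ACF at the insert VOIs, ΔA,
across-setting comparison), `noise_cov` (eight 10 × 10 × 10-voxel VOIs in the
homogeneous section, per-repetition means, grand mean, n−1 SD, COV), and
`quantification` (phantom → projection → OSEM → VOI recovery per source size
and setting). Statistical comparisons gate on Shapiro–Wilk normality at
α = 0.05 and then use unpaired t-test/ANOVA or Mann–Whitney/Kruskal–Wallis;
the statistics themselves are SciPy's, the gating and reporting are this
package's. Every output row carries (kVp, QRM, seed, config hash); a JSON
manifest accompanies written tables, and a fixed configuration plus seed
reproduces tables byte-identically.

Default problem sizes in tests and reproduction scripts are scaled down from
the native grids (e.g. decimated CT grids, 44³ noise volumes, 64 × 64 × 40
reconstruction grids) — the physics is grid-agnostic and the package's checks
are chosen to run comfortably on a single CPU; the native 512 × 512 × 86
phantom build itself takes ~2 s.

## What the synthetic pipeline does and does not show

The generator emulates material compositions, geometry, HU statistics and
attenuation physics, but not: polyenergetic CT spectra and beam hardening,
iterative CT reconstruction texture, scatter and septal penetration,
depth-dependent collimator response, dead time, or vendor conversion curves.
Consequently the package asserts structure, closed forms, orderings and
sensitivities — not the per-setting measured values of the original scanner
(its μ errors per insert, per-setting COV endpoints, or the per-material
activity-error matrices), which depend on that hardware. One documented
limitation: the advantage of finer reconstruction voxels for small sources,
expected from partial-volume arguments, is not reproducible in a noiseless
matched-model emulation — there, recovery error is convergence-dominated and
finer grids converge more slowly per OSEM pass — so it is discussed but not
asserted.
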