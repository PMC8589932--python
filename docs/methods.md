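# Methods

## Scope and model

`y90dose` implements the dosimetry chain for trans-arterial liver
radioembolization with ⁹⁰Y microspheres. The physical model rests on two
assumptions that are standard for microspheres:

1. **Permanent trapping.** Microspheres do not clear biologically, so the
   time–activity curve of every region is a pure physical decay and a single
   imaging time point determines the whole dose delivery. The cumulated
   activity per unit present activity is T½/ln 2.
2. **Local energy deposition at the macroscopic scale.** The mean absorbed
   dose of a volume of interest (VOI) is proportional to its counts in the
   nuclear-medicine image.

From these, the mean absorbed dose of a VOI is

    D_VOI = 49.75 · CF · N_VOI / M_VOI      [Gy]

with the conversion factor CF = A_total / N_total (GBq per count, the
patient-relative calibration), N_VOI the VOI counts and M_VOI the VOI mass
in kg (CT volume × density).

## Units

Package-wide: activity GBq, mass kg, volume mL, absorbed dose Gy, lengths
mm. Conversions happen only at I/O boundaries.

## Constants and their internal consistency

Two half-life values circulate: the nuclide reference 64.042 h and the
64.053 h embedded in the canonical dose constant. The package uses
**64.053 h** wherever a value must reproduce 49.75 Gy·kg/GBq (mean dose,
voxel Q factor) and exposes 64.042 h separately. The canonical dose
constant is stored as the printed **49.75** exactly; re-deriving it from
the per-decay dose factor (1.495·10⁻¹³ Gy·kg/(Bq·s), numerically the mean
β energy in joules) gives 49.73, and the 0.04 % gap is checked as an
invariant rather than resolved — vendor package inserts use 49.67 and 50
for the same quantity, so sub-0.1 % agreement is the meaningful statement.

The voxel self-irradiation S value is defined from the *effective* energy
per decay implied by the canonical constant (49.75·ln 2/T½ = 1.4955·10⁻¹³ J,
within 0.1 % of both the printed dose factor and the evaluated 933.7 keV).
This makes the voxel and compartmental routes close algebraically: the mean
of the dose map over any VOI equals the compartmental formula exactly when
the VOI mass is voxel count × voxel volume × density. A secondary
`s_value_from_mean_energy` computes S directly from 933.7 keV and is
cross-checked against the canonical route at 0.1 %. At the reference
4.42 mm voxel and 1.05 g/cm³ both round to 1.65 Gy/(GBq·s).

The voxel Q factor uses 1/ln 2 exactly instead of the rounded 1.443
(difference < 0.03 %).

## Lung shunt

Planar LSF uses the conjugate-view geometric mean of background-corrected
anterior/posterior counts (Buijs large-organ factor 0.5); a single
anterior-view legacy mode exists because the historical 30 Gy limit was
derived with it. Classes: LSF = 0 (none), 0 < LSF ≤ 0.10 (non-relevant,
boundary inclusive because the substantial cut-off is printed strictly
greater-than), LSF > 0.10 (substantial). For liver quantification without
lung tomography the approximation LSF* = LSF_planar/2.7 is used; the 2.7 is
the field's empirical average correction for the planar overestimation and
is adopted as printed. Tomographic LSF takes whole-lung counts from the
left-lung count density extrapolated by volume (liver scatter contaminates
the right lung); a direct whole-lung VOI emits a scatter warning and a
truncated-lung field of view is refused. Resin-sphere prescription bands
(full activity ≤ 0.10; −20 % in (0.10, 0.15); −40 % in [0.15, 0.20);
contraindicated ≥ 0.20) assign open boundaries to the more conservative
option. Only the planar-methodology 30 Gy/50 Gy lung limits are encoded;
no tomographic lung-dose limit exists in the field yet, so LSF_TOMO is
reported alongside without a limit check.

## Segmentation and the two-VOI convention

Masks are binary label images on one shared grid; volumes are voxel count
× voxel volume; the world affine is carried through NIfTI I/O but unused
in algebra (images are assumed co-registered; only an integer-voxel rigid
shift utility is provided). When CT and NM borders disagree (breathing
motion, low-perfusion regions), each object gets two VOIs: **counts from
the NM mask, volume from the CT mask**. The compartment bookkeeping:
perfused-liver (PL) counts from the NM PL VOI; PL volume = NM PL ∩ CT
liver minus necrosis; perfused non-tumoural (PNTL) counts = PL − lesions −
necrosis; PNTL volume = PL volume − CT lesion volumes; whole non-tumoural
(NTL) volume = CT liver − lesions − non-target lesions − necrosis, with
NTL counts equal to PNTL counts; Vf = V(PNTL)/V(NTL). Necrosis from
previous treatments is removed from both PL volume and PNTL; lesion VOIs
by contrast *include* their own low-perfusion cores, which is why the
phantom's necrotic cores do not enter the NTL subtraction.

The adaptive NM isocontour bisects on the threshold (fraction of the local
maximum in a 15 mm-dilated CT neighbourhood) until the largest 26-connected
component matches the CT volume; ties resolve toward the lower threshold
(larger VOI, conservative for normal tissue — connectivity and tie-break
are this package's choices, the procedure fixes neither). Failure to come
within ±50 % of the CT volume raises an error. Lesions whose CT
sphere-equivalent diameter is below 2 cm are flagged: partial-volume losses
make their dosimetry unreliable and they should be excluded from analysis.
Infiltrative lesions are handled by the safe convention — pass an empty
lesion list so the whole liver counts as non-tumoural.

## Planning

Doses are strictly linear in the administered activity, so a per-GBq
normalised CF scales to every candidate activity. Rules are evaluated as
flags, never refusals: lung 30 Gy single / 50 Gy cumulative, resin bands,
small-lesion warnings, and the volume-effect note that for Vf < 0.40 the
whole-liver mean-dose criterion is not applicable (a well-functioning
fraction below 40 % of the organ may tolerate arbitrarily high dose). The
absorbed-fraction correction is **off by default** — the canonical formula
assumes φ = 1 and treats the size dependence as a known systematic — and
when enabled applies per-lesion via the CT sphere-equivalent volume.

## Absorbed fraction kernel

φ(V) for a uniformly loaded soft-tissue sphere is computed as the
expectation of the classical geometric self-overlap factor
U(x) = 1 − 3x/4 + x³/16 (x = r/R ≤ 2) under the radial energy-deposition
CDF F(r) of a ⁹⁰Y point source. F is built in-package: Fermi β spectrum
with the unique first-forbidden shape factor (end point 2280 keV, daughter
Z = 40; spectrum mean 968 keV, within 4 % of the evaluated 933.7 keV),
Katz–Penfold range–energy relation, straight-ahead continuous slowing
down, and a single mean detour factor (0.774) calibrated so that 90 % of
the emitted energy falls within the evaluated 4.9 mm in unit-density
matter. The maximum (straight-path) range reproduces ≈ 11 mm in water.
A seeded Monte Carlo oracle sharing only F(r) — not the overlap-factor
quadrature — verifies φ to 0.01. Straight-ahead transport with a constant
detour factor is a deliberate simplification; it is accurate where it
matters (spheres ≥ 2 cm, where φ ≈ 0.83 and rises) and φ is monotone and
→ 1 for large volumes by construction. Note that the approach to 1 is
slow, deficit ≈ (3/4)·⟨r⟩/R ≈ 2.8·10⁻³ even at 10⁶ mL.

## Voxel dosimetry

D_voxel = Q · N_voxel with Q = (1/ln 2)·T½·CF·S. Applicability requires
FWHM_PSF ≥ 5.3 mm (the β dose-kernel width); below it (digital PET ≈ 4 mm)
the check returns an approximation note, not a refusal. No convolution or
Monte Carlo transport is provided, and lung voxel dosimetry is out of
scope (the β range in lung exceeds the local-deposition premise). DVHs
default to 1 Gy bins (narrower bins get sparse); summary statistics
(D_mean, D_max, D_min, D_x) come from raw voxel doses, not bins, so they
carry no binning error. The 16-bit integer export reproduces the
camera-software failure modes as diagnostics: floor(dose × scale) with
scale 1/10/100, counting voxels truncated to zero and refusing exports
beyond the representable maximum (655.35 Gy at ×100).

## The synthetic phantom

The phantom is the package's test bed, not a transport simulation. It
paints uniform activity concentrations — non-tumoural liver at 1, lesions
at their tumour/normal ratio, necrotic cores at 0, lungs receiving the
shunt fraction — on an ellipsoidal liver (default ≈ 1005 mL) and two
ellipsoidal lungs, scales to the requested total counts, then degrades:
Gaussian PSF blur (count-conserving), Poisson sampling (one seeded
generator per phantom), and an integer-voxel axial shift of the NM image
only (the minimal breathing-motion model that exercises the two-VOI
machinery). Planar views are attenuation-free axis projections: the
phantom models the post-correction world, consistent with using planar LSF
without attenuation correction and "fully corrected" tomography.

Default conditions: 64³ grid at 4.42 mm, one 3 cm lesion at ratio 5:1,
lung shunt 0.08, 2 GBq, 10⁷ total counts, 7 mm FWHM, Poisson on, no shift.
These sizes keep every phantom-based check seconds-scale while leaving
count densities realistic for a loco-regional injection.

What passing phantom tests shows: the bookkeeping and calibration chain is
exact (undegraded phantom recovers CF, LSF and all compartment doses to
1e-9), Poisson noise at clinical count levels introduces negligible LSF
bias (< 0.002 over 20 seeds), the two-VOI method strictly beats the
CT-only shortcut under a 2-voxel breathing shift, and a 1.8 cm sphere at
7 mm FWHM loses > 20 % of its counts to partial-volume spill. What it does
*not* show: robustness to attenuation, scatter, reconstruction artefacts,
deformable motion, or the MAA-vs-microsphere biodistribution mismatch —
none of which are simulated.

## Numerical choices and degenerate inputs

Negative background-corrected planar counts clamp to zero with a warning;
zero counts in both lung and liver make the LSF undefined (error); the
geometric mean of a zero view is zero with a warning. LSF values are
validated to [0, 1). Mask operations refuse mismatched grids or alignment
frames. Empty CT masks are zero-volume errors. The bisection threshold
search runs 60 iterations (threshold resolution ≈ 2⁻⁶⁰ of the local
maximum) and keeps the candidate closest to the CT volume.

## Known limitations

* The β kernel is a calibrated one-parameter transport approximation, not
  a Monte Carlo kernel; φ below ~1 mL is indicative only.
* Absolute-calibration quantification is a pass-through; no system
  calibration machinery.
* No DICOM; NIfTI only. No registration beyond integer-voxel shifts.
* The breathing model is rigid and axial; real motion deforms.
* Reports carry rule flags; clinical judgement is explicitly out of scope.
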