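# y90dose

Dosimetry for liver radioembolization (TARE) with ⁹⁰Y microspheres, for
medical physicists and imaging scientists: planar and tomographic
lung-shunt estimation, patient-relative image quantification, compartmental
mean absorbed dose by the subtraction method, local-deposition voxel
dosimetry with dose–volume histograms, treatment-planning rule checks, the
three standard report documents, and a synthetic digital phantom that
exercises the whole chain with known ground truth.

## The model in brief

⁹⁰Y microspheres are permanently trapped, so a single image determines the
dose delivery and every region's time–activity curve is pure physical decay
(T½ = 64.053 h where it feeds dose constants). With the patient-relative
conversion factor

    CF = A_total / N_total        [GBq per count]

the mean absorbed dose of any volume of interest is

    D_VOI = 49.75 · CF · N_VOI / M_VOI        [Gy]

with counts N_VOI taken from the nuclear-medicine image and mass M_VOI from
the CT volume × density (1.05 g/cm³ liver, 0.3 g/cm³ lung) — the **two-VOI
convention** that makes the result robust to CT/NM mismatch from breathing
motion or low-perfusion lesion cores. Non-tumoural liver counts and mass
are obtained by subtracting lesion VOIs from the whole liver; for one
lesion this is numerically identical to the classical partition model.

Lung shunt: planar conjugate-view LSF with background correction classifies
patients (none / ≤ 0.10 non-relevant / > 0.10 substantial); liver
quantification uses LSF\* = LSF_planar/2.7 or, when lungs are imaged
tomographically, LSF_TOMO from the left-lung count-density extrapolation.
Lung dose is 49.75·A_total·LSF/M_lung against the historical 30 Gy single
/ 50 Gy cumulative limits.

Voxel dosimetry (local deposition method): D_voxel = Q·N_voxel with
Q = (1/ln 2)·T½·CF·S and S the voxel self-irradiation S value
(1.65 Gy/(GBq·s) at 4.42 mm, 1.05 g/cm³), valid when the imaging PSF is at
least as wide as the 5.3 mm β dose kernel.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

A pre-therapy case: planar ROIs give the lung shunt, LSF\* builds the
starred conversion factor, and the subtraction method doses the
compartments for an intended 2.0 GBq.

```python
from y90dose import conversion_factor_star
from y90dose.shunt import PlanarRoiCounts, assess_from_planar
from y90dose.voi import CompartmentMeasure, Role, SegmentationSet
from y90dose.compartment import subtraction_method, dose_results_frame

mk = lambda raw, view: PlanarRoiCounts(raw, 400, 1000, 100, view)
shunt = assess_from_planar([mk(12000, "ANT"), mk(12000, "POST")],
                           [mk(92000, "ANT"), mk(92000, "POST")], a_total=2.0)
# net counts 10000 (lung) / 90000 (liver) -> LSF_planar 0.10, class NON_RELEVANT,
# lung dose 9.95 Gy, LSF* = 0.10/2.7 = 0.037

cf = conversion_factor_star(2.0, 1.0e6, shunt.lsf_star)   # 1.926e-06 GBq/count

ml = lambda m: m / 1.05 * 1e3    # mass (kg) -> volume (mL) at liver density
seg = SegmentationSet([
    CompartmentMeasure("whole_liver", Role.WHOLE_LIVER, 1.0e6, ml(1.5), 1.5),
    CompartmentMeasure("perfused_liver", Role.PL, 1.0e6, ml(1.5), 1.5),
    CompartmentMeasure("lesion_1", Role.LESION_CT, 3.0e5, ml(0.15), 0.15),
    CompartmentMeasure("pntl", Role.PNTL, 7.0e5, ml(1.35), 1.35),
    CompartmentMeasure("ntl", Role.NTL, 7.0e5, ml(1.35), 1.35),
], vf=0.9)
print(dose_results_frame(subtraction_method(seg, cf)).to_string(index=False))
```

```
          name        role  activity_GBq  mass_kg  mean_dose_Gy  absorbed_fraction_applied flags
   whole_liver WHOLE_LIVER      1.925926     1.50     63.876543                      False
perfused_liver          PL      1.925926     1.50     63.876543                      False
      lesion_1   LESION_CT      0.577778     0.15    191.629630                      False
          pntl        PNTL      1.348148     1.35     49.681756                      False
           ntl         NTL      1.348148     1.35     49.681756                      False
```

Reading it: of the 2.0 GBq intended, 0.58 GBq lands in the 150 g lesion
(192 Gy) and 1.35 GBq in the 1.35 kg of non-tumoural liver (49.7 Gy — the
planning parameter averaged over the whole functional organ). Activities
sum to the liver share of the total; the lung share follows from LSF\*.

The same workflow is scriptable from the shell:

```sh
y90dose phantom --out /tmp/ph --seed 1
y90dose quantify --activity 2.0 --total-counts 1e7
y90dose lsf-planar --rois rois.csv --activity 2.0
y90dose voxel-dose --image counts.nii.gz --cf 2e-7 --out dose.nii.gz \
        --dvh-mask lesion.nii.gz --dvh-out dvh.csv --psf-fwhm 7
```

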