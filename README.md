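# muquant

Digital-phantom analysis of CT-based attenuation correction (CT-AC) in
quantitative ¹⁷⁷Lu SPECT/CT.

Low-dose CT settings — tube potential (kVp) and quality-reference mAs (QRM) —
change the CT image and therefore the attenuation map (μ-map) used to correct
SPECT data at the 208.4 keV ¹⁷⁷Lu emission. `muquant` provides, as a single
tested pipeline on synthetic phantoms, the tools to quantify how much that
matters: it is aimed at medical-physics researchers who want to evaluate
CT-AC protocols without scanner time.

The chain it implements:

* **Reference physics** — elemental mass-attenuation tables and the mixture
  rule μ(E) = ρ Σᵢ wᵢ (μ/ρ)ᵢ(E) for tissue-equivalent materials (log–log
  interpolation, 40–400 keV);
* **Digital phantoms** — a voxelized electron-density phantom (17 inserts of
  9 tissue materials in a plastic-water body) and a NEMA-style quantification
  phantom (four syringe sources in polystyrene/PTFE/polyamide/polypropylene
  cylinders);
* **CT emulation** — per-setting HU synthesis at an effective energy, a
  calibrated two-component noise model (voxel noise + scan-to-scan
  calibration drift), and a CTDI_vol fixture;
* **μ-map pipeline** — bilinear HU→μ conversion,
  μ = μ_w(HU+1000)/1000 below HU = 0 and μ = μ_w + HU·k(kVp) above, with
  in-repo bone-slope calibration, plus trilinear resampling to the SPECT grid;
* **Chang ACF** — first-order attenuation correction factors
  ACF = [⟨exp(−∫μ dl)⟩_M]⁻¹ by ray integration, and the expected activity
  change ΔA = (ACF_theoretical/ACF_measured − 1)·100%;
* **Noise metrics** — the repeated-acquisition coefficient-of-variation
  chain (per-repetition VOI means → grand mean → n−1 SD → COV) and
  normality-gated statistical comparisons;
* **SPECT emulation** — an attenuated parallel-beam projector, OSEM with the
  matched projector, and ICF-based VOI activity recovery.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
from muquant import load_material_registry, linear_attenuation
from muquant.experiments import ExperimentConfig, run_experiment

reg = load_material_registry()
for name in ("plastic_water", "lung_inhale", "cortical_bone"):
    print(f"mu({name}) = {linear_attenuation(reg[name]):.4f} cm^-1")

cfg = ExperimentConfig(experiment="noise_cov", kvp_qrm=((80, 20), (130, 35)),
                       spect_n=44, spect_nz=44, realizations=5, seed=1)
cov = run_experiment(cfg)["cov"].groupby(["kvp", "qrm"])["cov"].mean()
print(cov)
```

prints

```
mu(plastic_water) = 0.1358 cm^-1
mu(lung_inhale) = 0.0273 cm^-1
mu(cortical_bone) = 0.2474 cm^-1
kvp  qrm
80   20     0.003281
130  35     0.003238
Name: cov, dtype: float64
```

The first block is the theoretical 208.4 keV attenuation of the phantom body
material (within 0.3% of the manufacturer value 0.1355 cm⁻¹), of the
lung-inhale insert (0.027 cm⁻¹ — the small value that makes lung μ errors
look large while barely moving activity quantification), and of cortical
bone. The second block runs the full noise chain — emulated repeated CT
acquisitions, bilinear conversion, eight 1000-voxel VOIs in the homogeneous
section — and reports the mean COV of the μ-map per scan setting, landing in
the few-per-mille range typical of low-dose CT-AC, with the higher-dose
setting the less noisy.

A command-line interface mirrors the library
(`muquant phantom|mu|acf|ctdi|mutable|experiment ...`), e.g.:

```sh
muquant phantom density --ct-scale 4 -o labels.nii.gz
muquant experiment --experiment noise_cov --seed 1 -o results/
```

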