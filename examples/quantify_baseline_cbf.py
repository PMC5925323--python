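"""Baseline perfusion quantification with the single-compartment model.

Simulates a background-suppressed baseline ASL run (60 volumes) over a
perfusion gradient of 30-90 ml/100g/min with 1% thermal noise, then
inverts it with the standard single-compartment formula using the
slice-dependent post-label delay (1.9 s at the lowest slice, +50 ms per
ascending slice).
"""

import numpy as np

from boldcbf import QuantParams, quantify_run
from boldcbf.quant import slice_pld
from boldcbf.synth import assemble_baseline_run, uniform_truth

shape = (8, 8, 4)
truth = uniform_truth(shape, noise_sd=0.01)
truth.baseline_cbf = np.linspace(30.0, 90.0, int(np.prod(shape))).reshape(shape)

run = assemble_baseline_run(truth, n_volumes=60, seed=3)
cbf = quantify_run(run)

params = QuantParams().with_slices(shape[2])
plds = slice_pld(np.arange(shape[2]), params)
err = np.abs(cbf.cbf - truth.baseline_cbf).mean()

print(f"slice PLDs             : {np.round(plds, 3)} s")
print(f"true map mean          : {truth.baseline_cbf.mean():.1f} ml/100g/min")
print(f"recovered map mean     : {cbf.cbf.mean():.1f} ml/100g/min")
print(f"voxelwise mean |error| : {err:.1f} ml/100g/min")
print("The temporal control/label means invert the forward model exactly in the")
print("noise-free limit.  At 1% image noise single-PLD voxel estimates are noisy")
print("(the label/control difference is <1% of M0), but the map mean recovers")
print("the true perfusion within a few percent.")
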