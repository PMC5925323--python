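"""Simulate a dual-echo pCASL run and separate BOLD and CBF fluctuations.

Builds a small noise-free run with a known coupling (r = 0.8) between the
perfusion and BOLD fluctuation processes, runs the temporal separation
(high-pass + demodulation for CBF, low-pass + pair mean for BOLD), and
checks how faithfully each separated channel tracks its injected process.
"""

import numpy as np

from boldcbf import AcquisitionParams, assemble_dual_echo_run, separate_run, uniform_truth
from boldcbf.coupling import pearson_r

acq = AcquisitionParams(matrix=(8, 8, 4), n_volumes=90)
truth = uniform_truth(acq.matrix, baseline_cbf=60.0, coupling=0.8, lag=-1.05, noise_sd=0.0)
run, fields = assemble_dual_echo_run(truth, acq, seed=42, return_fields=True)

sep = separate_run(run, fwhm=0.0)
pair = lambda x: 0.5 * (x[..., 0::2] + x[..., 1::2])
r_cbf = pearson_r(sep.cbf[..., sep.interior], pair(fields["perfusion"])[..., sep.interior])
r_bold = pearson_r(sep.bold[..., sep.interior], pair(fields["bold"])[..., sep.interior])

print(f"separation cutoff      : {acq.separation_cutoff_hz:.3f} Hz (= 1/4TR)")
print(f"separated frames       : {sep.n_frames} at dt = {sep.dt:.1f} s")
print(f"CBF channel fidelity   : r = {r_cbf.mean():.4f} (vs injected perfusion process)")
print(f"BOLD channel fidelity  : r = {r_bold.mean():.4f} (vs injected BOLD process)")
print("Both separated series track their ground-truth processes almost perfectly")
print("on a noise-free run; the residual reflects filter edges and echo cross-leak.")
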