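"""Group comparison of BOLD-CBF coupling between two synthetic cohorts.

Simulates a young-like cohort (mean coupling 0.24, BOLD delayed 0.5 s)
and an elderly-like cohort (0.18, delayed 1.8 s), computes per-subject
r0 / rmax over a gray-matter ROI, and compares the groups: Fisher-z
two-sample t on r0 and the rmax - r0 contrast with Cohen's d.
"""

import numpy as np

from boldcbf import AcquisitionParams, fisher_z, rmax_minus_r0_contrast, two_sample_t
from boldcbf.pipeline import PipelineConfig, analyze_subject
from boldcbf.synth import assemble_dual_echo_run, cohort_preset, draw_subject_truth, uniform_truth

acq = AcquisitionParams(matrix=(6, 6, 4), n_volumes=90)
config = PipelineConfig(acq=acq)
rng = np.random.default_rng(21)


def cohort(preset_name, n):
    p = cohort_preset(preset_name)
    template = uniform_truth(acq.matrix, coupling=p["coupling"], lag=p["lag"])
    vals = []
    for _ in range(n):
        truth = draw_subject_truth(template, p["coupling_sd"], p["lag_sd"], rng)
        run = assemble_dual_echo_run(truth, acq, seed=rng)
        _, cmap, _ = analyze_subject(run, config)
        vals.append((float(np.nanmean(cmap.r0)), float(np.nanmean(cmap.rmax))))
    return np.array(vals)


young = cohort("young-like", 8)
elderly = cohort("elderly-like", 8)

t_r0 = two_sample_t(fisher_z(young[:, :1]), fisher_z(elderly[:, :1]))
contrast = rmax_minus_r0_contrast(elderly, young)

print(f"mean r0   : young {young[:, 0].mean():.3f}  elderly {elderly[:, 0].mean():.3f}")
print(f"mean rmax : young {young[:, 1].mean():.3f}  elderly {elderly[:, 1].mean():.3f}")
print(f"two-sample t on Fisher-z r0: t = {float(t_r0.t[0]):+.2f}, p = {float(t_r0.p[0]):.4f}")
print(f"rmax - r0 contrast (elderly - young): diff = "
      f"{contrast.mean_a - contrast.mean_b:+.4f}, p = {contrast.p:.4f}, Cohen's d = {contrast.d:.2f}")
print("The larger BOLD delay in the elderly-like cohort lowers r0 but is")
print("partly compensated by the lag scan, so rmax - r0 is larger for them.")
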