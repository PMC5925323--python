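"""Self-validation studies: ground-truth recovery experiments run on the
synthetic generator.

Each study builds its own inputs from the generator, runs the analysis
exactly as the pipeline does, and returns summary numbers.  Problem
sizes are scaled to desk hardware (small voxel grids, the protocol's 90
volumes / 45 separated frames); replicate counts are stated per study.
All studies are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np

from .core import AcquisitionParams, DEFAULT_BAND, LagGrid
from .coupling import (
    fdr_bh,
    fisher_z,
    lagged_rmax,
    one_sample_t,
    two_sample_t,
    upsample_sinc,
)
from .pipeline import PipelineConfig, analyze_subject
from .quant import quantify_cbf, quantify_run
from .separation import separate_bold, separate_cbf
from .synth import (
    assemble_baseline_run,
    assemble_dual_echo_run,
    cohort_preset,
    draw_subject_truth,
    generate_band_limited_process,
    generate_coupled_pair,
    uniform_truth,
)

__all__ = [
    "separation_cutoff_study",
    "lag_recovery_study",
    "coupling_recovery_study",
    "group_power_study",
    "contamination_study",
    "quant_inversion_study",
    "fdr_null_study",
    "lag_direction_study",
]

_TEST_MATRIX = (6, 6, 4)


def separation_cutoff_study(tr: float = 3.5) -> dict:
    """The separation cutoff 1/(4*TR) implied by the protocol's TR."""
    acq = AcquisitionParams(tr=tr)
    return {"cutoff_hz": acq.separation_cutoff_hz, "n": 1}


def lag_recovery_study(
    seed: int = 0,
    n_replicates: int = 50,
    lags: tuple = (-3.5, -1.05, 0.0, 1.05, 3.5),
    n_frames: int = 45,
    dt: float = 7.0,
    band: tuple = DEFAULT_BAND,
) -> dict:
    """Recovery of known lags by the lagged-correlation scan.

    Noise-free coupled pairs (target r = 1) at the separated sampling
    interval; success = |tau* - true lag| <= one grid step (0.35 s).
    """
    rng = np.random.default_rng(seed)
    grid = LagGrid()
    hits, total = 0, 0
    rmax_min = 1.0
    for _ in range(n_replicates):
        for lag in lags:
            cbf = generate_band_limited_process(n_frames, dt, band, 1.0, rng)
            bold = generate_coupled_pair(cbf, 1.0, lag, dt, rng)
            b_up = upsample_sinc(bold, dt, grid.upsample_dt)
            c_up = upsample_sinc(cbf, dt, grid.upsample_dt)
            rmax, tau = lagged_rmax(b_up, c_up, grid)
            total += 1
            hits += abs(float(tau) - lag) <= grid.step + 1e-9
            rmax_min = min(rmax_min, float(rmax))
    return {
        "recovered_pct": 100.0 * hits / total,
        "rmax_min": rmax_min,
        "n": total,
    }


def _study_config(matrix, fwhm: float = 6.0) -> PipelineConfig:
    acq = AcquisitionParams(matrix=tuple(matrix), n_volumes=90)
    return PipelineConfig(acq=acq, fwhm=fwhm)


def _subject_r0(
    preset: dict,
    matrix,
    rng: np.random.Generator,
    config: PipelineConfig,
) -> tuple[float, float]:
    """One synthetic subject: returns (injected coupling, estimated mean r0).

    Runs are thermal-noise-only (no physiological components), so the
    study isolates the separation + correlation chain; physiological
    regression is validated separately.
    """
    template = uniform_truth(matrix, coupling=preset["coupling"], lag=preset["lag"])
    truth = draw_subject_truth(template, preset["coupling_sd"], preset["lag_sd"], rng)
    run = assemble_dual_echo_run(truth, config.acq, seed=rng)
    _, cmap, _ = analyze_subject(run, config, compute_lags=False)
    return float(truth.coupling.mean()), float(np.nanmean(cmap.r0))


def coupling_recovery_study(
    seed: int = 0,
    n_replicates: int = 200,
    matrix: tuple = _TEST_MATRIX,
) -> dict:
    """Mean estimated zero-lag coupling for young-like (0.24) and
    elderly-like (0.18) subject draws, 45 separated frames each.

    Subjects are generated at zero BOLD-CBF lag so that r0 estimates the
    injected coupling directly; lag effects on r0 are the subject of the
    separate lag studies.
    """
    rng = np.random.default_rng(seed)
    config = _study_config(matrix)
    out = {}
    for name in ("young-like", "elderly-like"):
        preset = cohort_preset(name)
        preset["lag"] = 0.0
        est = [
            _subject_r0(preset, matrix, rng, config)[1]
            for _ in range(n_replicates)
        ]
        key = name.split("-")[0]
        out[f"mean_r0_{key}"] = float(np.mean(est))
        out[f"injected_r0_{key}"] = preset["coupling"]
    out["n"] = n_replicates
    return out


def group_power_study(
    seed: int = 0,
    n_replicates: int = 40,
    n_young: int = 15,
    n_elderly: int = 16,
    alpha: float = 0.05,
    matrix: tuple = _TEST_MATRIX,
) -> dict:
    """Empirical power of the two-sample t on Fisher-z subject means to
    detect the 0.24 vs 0.18 group coupling difference at the study's
    sample sizes (15 + 16)."""
    rng = np.random.default_rng(seed)
    config = _study_config(matrix)
    young, elderly = cohort_preset("young-like"), cohort_preset("elderly-like")
    rejections = 0
    for _ in range(n_replicates):
        zy = fisher_z(
            np.array([_subject_r0(young, matrix, rng, config)[1] for _ in range(n_young)])
        )
        ze = fisher_z(
            np.array([_subject_r0(elderly, matrix, rng, config)[1] for _ in range(n_elderly)])
        )
        res = two_sample_t(zy[:, None], ze[:, None])
        rejections += float(res.p[0]) < alpha
    return {"power": rejections / n_replicates, "n": n_replicates}


def contamination_study(seed: int = 0, matrix: tuple = (8, 8, 4)) -> dict:
    """Crosstalk between the separated channels.

    BOLD -> CBF: a full synthetic run with pure in-band BOLD fluctuation
    and zero perfusion (baseline CBF 0): the separated-CBF variance is
    compared with the BOLD fluctuation variance of the input series.
    Perfusion modulation -> BOLD: an interleaved series containing only
    the label/control modulation component (an alternating component with
    in-band amplitude fluctuation): the separated-BOLD fluctuation
    variance is compared with the modulation variance.
    """
    rng = np.random.default_rng(seed)
    acq = AcquisitionParams(matrix=tuple(matrix), n_volumes=90)
    interior = slice(1, acq.n_pairs - 1)

    # direction 1: pure BOLD, zero perfusion
    truth = uniform_truth(
        matrix, baseline_cbf=0.0, coupling=0.0, lag=0.0,
        cbf_fluct_amplitude=0.0, noise_sd=0.0,
    )
    run = assemble_dual_echo_run(truth, acq, seed=rng)
    sep_cbf = separate_cbf(run.echo2, acq.tr)[..., interior]
    bold_var = run.echo2.var(axis=-1).mean()
    bold_to_cbf = float(sep_cbf.var(axis=-1).mean() / bold_var)

    # direction 2: pure label/control modulation
    n = acq.n_volumes
    d = generate_band_limited_process(n, acq.tr, truth.band, 1.0, rng)
    modulation = (1.0 + 0.1 * d) * np.cos(np.pi * np.arange(n))
    series = 1000.0 * (1.0 + 0.005 * modulation)[None, None, None, :]
    sep_bold = separate_bold(series, acq.tr)[..., interior]
    mod_var = (1000.0 * 0.005 * modulation).var()
    cbf_to_bold = float(sep_bold.var(axis=-1).mean() / mod_var)

    return {"bold_to_cbf": bold_to_cbf, "cbf_to_bold": cbf_to_bold, "n": int(np.prod(matrix))}


def quant_inversion_study(seed: int = 0, matrix: tuple = (8, 8, 6)) -> dict:
    """Noise-free forward/inverse identity of the perfusion model, plus
    monotonicity of CBF in the label/control difference and in PLD."""
    shape = tuple(matrix)
    cbf_true = np.linspace(20.0, 100.0, int(np.prod(shape))).reshape(shape)
    truth = uniform_truth(matrix, noise_sd=0.0)
    truth.baseline_cbf = cbf_true
    run = assemble_baseline_run(truth, n_volumes=10, seed=seed)
    recovered = quantify_run(run)
    rel = np.abs(recovered.cbf - cbf_true) / cbf_true
    max_rel_error = float(rel.max())

    diffs = np.linspace(0.001, 0.02, 25)
    ones = np.ones((25, 1, 1))
    cbf_of_diff = quantify_cbf(
        diffs.reshape(-1, 1, 1), 0.0 * ones, ones, pld=1.9
    ).cbf.ravel()
    plds = np.linspace(1.9, 2.8, 25)
    cbf_of_pld = quantify_cbf(
        0.005 * ones, 0.0 * ones, ones, pld=plds.reshape(-1, 1, 1)
    ).cbf.ravel()
    return {
        "max_rel_error": max_rel_error,
        "monotone_in_diff": bool(np.all(np.diff(cbf_of_diff) > 0)),
        "monotone_in_pld": bool(np.all(np.diff(cbf_of_pld) > 0)),
        "n": int(np.prod(shape)),
    }


def fdr_null_study(
    seed: int = 0,
    n_replicates: int = 500,
    m: int = 10_000,
    n_subjects: int = 8,
    alpha: float = 0.05,
) -> dict:
    """Empirical false discovery rate of BH-FDR under the complete null.

    Null one-sample t p-values (Gaussian data, no effect) for m voxels;
    the per-replicate FDR is FP / max(R, 1), averaged over replicates.
    """
    rng = np.random.default_rng(seed)
    fdrs = np.empty(n_replicates)
    for i in range(n_replicates):
        data = rng.standard_normal((n_subjects, m))
        res = one_sample_t(data)
        reject, _ = fdr_bh(res.p, alpha=alpha)
        r = reject.sum()
        fdrs[i] = reject.sum() / max(r, 1)  # all discoveries are false here
    return {"empirical_fdr": float(fdrs.mean()), "n": n_replicates, "m": m}


def lag_direction_study(
    seed: int = 0,
    n_replicates: int = 100,
    n_per_group: int = 8,
    matrix: tuple = _TEST_MATRIX,
) -> dict:
    """Direction of the rmax - r0 group effect under a pure lag difference.

    Two cohorts with identical coupling (0.24) but BOLD delayed by 1.8 s
    (elderly-like) vs 0.5 s (young-like); counts the replicates in which
    the larger-lag group shows the larger mean rmax - r0, and verifies
    rmax >= r0 voxelwise along the way.
    """
    rng = np.random.default_rng(seed)
    config = _study_config(matrix)
    presets = {
        "small_lag": dict(coupling=0.24, lag=-0.5, coupling_sd=0.03, lag_sd=0.3),
        "large_lag": dict(coupling=0.24, lag=-1.8, coupling_sd=0.03, lag_sd=0.3),
    }
    wins = 0
    rmax_ge_r0 = True
    for _ in range(n_replicates):
        means = {}
        for name, preset in presets.items():
            template = uniform_truth(
                matrix, coupling=preset["coupling"], lag=preset["lag"]
            )
            vals = []
            for _ in range(n_per_group):
                truth = draw_subject_truth(
                    template, preset["coupling_sd"], preset["lag_sd"], rng
                )
                run = assemble_dual_echo_run(truth, config.acq, seed=rng)
                _, cmap, _ = analyze_subject(run, config)
                rmax_ge_r0 &= bool(np.all(cmap.rmax >= cmap.r0 - 1e-9))
                vals.append(float(np.nanmean(cmap.rmax - cmap.r0)))
            means[name] = float(np.mean(vals))
        wins += means["large_lag"] > means["small_lag"]
    return {
        "direction_pct": 100.0 * float(wins) / n_replicates,
        "rmax_ge_r0": rmax_ge_r0,
        "n": n_replicates,
    }
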