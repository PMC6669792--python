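"""Reusable validation experiments run on synthetic studies.

These are the quantitative checks that stand in for a reanalysis of the
(unavailable) original recordings: estimator recovery of known fractal
dimension, null calibration of the pipeline's type-I error, and recovery
of the injected taping-effect directions at full study size.  The same
functions back both the test suite and the reproduction script; problem
sizes are arguments so callers choose their precision/runtime trade-off.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .complexity import HiguchiSpec, higuchi_fd
from .pipeline import BalanceComplexityModel
from .synthetic import SyntheticStudySpec, generate_fbm

__all__ = [
    "fd_recovery",
    "type_i_error",
    "effect_detection_svden",
    "effect_detection_hdf",
]


def fd_recovery(
    seed: int,
    hurst_values=(0.2, 0.35, 0.5, 0.65, 0.8),
    n_paths: int = 200,
    n: int = 1001,
    k_max: int = 8,
) -> dict[float, float]:
    """Mean Higuchi FD over ``n_paths`` seeded fBm paths per Hurst value.

    The theoretical fractal dimension of an fBm path is ``2 - H``, so the
    returned means should track that line and decrease in H.
    """
    spec = HiguchiSpec(k_max)
    out = {}
    for i, h in enumerate(hurst_values):
        rng = np.random.default_rng([seed, i])
        out[h] = float(np.mean([higuchi_fd(generate_fbm(h, n, rng), spec) for _ in range(n_paths)]))
    return out


def _pvalues_one_study(spec: SyntheticStudySpec, channel: str) -> dict[str, float]:
    """ANOVA p per measure for one channel of one synthetic study."""
    results = BalanceComplexityModel.from_synthetic(spec, posthoc=False).fit()
    return {c.measure: c.p_anova for c in results.comparisons if c.channel == channel}


def type_i_error(
    seed: int,
    n_replicates: int = 1000,
    n_subjects: int = 20,
    n_trials: int = 5,
    channel: str = "ankle_ML",
    alpha: float = 0.05,
) -> dict:
    """Null calibration: studies with zero injected effects.

    Returns the empirical rejection rate at ``alpha`` and the raw ANOVA
    p-values (per measure), which should be approximately Uniform(0, 1).
    """
    base = SyntheticStudySpec(
        n_subjects=n_subjects, n_trials=n_trials, channels=(channel,), seed=0
    ).with_zero_effects()
    pvals = {"hdf": [], "svden": []}
    for r in range(n_replicates):
        spec = replace(base, seed=int(np.random.default_rng([seed, r]).integers(2**31)))
        ps = _pvalues_one_study(spec, channel)
        for m in pvals:
            pvals[m].append(ps[m])
    out = {"alpha": alpha, "n_replicates": n_replicates}
    for m, p in pvals.items():
        p = np.asarray(p)
        out[m] = {"rejection_rate": float((p < alpha).mean()), "pvalues": p}
    return out


def _detection_run(
    seed: int,
    n_replicates: int,
    n_subjects: int,
    channels: tuple,
    measure: str,
    direction: str,
    null_extra_channels: bool = False,
) -> dict:
    """Shared driver: fraction of replicates where every target channel
    shows p_anova < 0.05 and the taped-condition means sit on the
    expected side of no-tape."""
    detected = 0
    directions_ok = 0
    mean_nt, mean_taped = [], []
    for r in range(n_replicates):
        spec = SyntheticStudySpec(
            n_subjects=n_subjects,
            channels=channels,
            seed=int(np.random.default_rng([seed, r]).integers(2**31)),
        )
        results = BalanceComplexityModel.from_synthetic(spec, posthoc=False).fit()
        ok_p, ok_dir = True, True
        for c in results.comparisons:
            if c.measure != measure:
                continue
            taped = 0.5 * (c.means["ST"] + c.means["KT"])
            mean_nt.append(c.means["NT"])
            mean_taped.append(taped)
            if direction == "decrease":
                ok_dir &= taped < c.means["NT"]
            else:
                ok_dir &= taped > c.means["NT"]
            ok_p &= c.p_anova < 0.05
        detected += ok_p and ok_dir
        directions_ok += ok_dir
    return {
        "detection_rate": detected / n_replicates,
        "direction_rate": directions_ok / n_replicates,
        "mean_NT": float(np.mean(mean_nt)),
        "mean_taped": float(np.mean(mean_taped)),
        "n_replicates": n_replicates,
        "n_subjects": n_subjects,
    }


def effect_detection_svden(seed: int, n_replicates: int = 500, n_subjects: int = 41) -> dict:
    """Taping collapses latent sources at the ankle in the sagittal (AP)
    and transverse (SI) planes: SVD entropy should drop under ST/KT and
    the ANOVA should flag both channels."""
    return _detection_run(
        seed, n_replicates, n_subjects, ("ankle_AP", "ankle_SI"), "svden", "decrease"
    )


def effect_detection_hdf(seed: int, n_replicates: int = 500, n_subjects: int = 41) -> dict:
    """Taping roughens mediolateral ankle sway (lower Hurst exponent):
    Higuchi FD should rise under ST/KT on the ankle-ML channel."""
    return _detection_run(seed, n_replicates, n_subjects, ("ankle_ML",), "hdf", "increase")
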