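"""End-to-end orchestration: model and results objects plus config runs.

:class:`BalanceComplexityModel` is built from a long-format trial
dataset (read from CSV, a DataFrame, or generated synthetically) and
``fit()`` runs the full chain — family-appropriate signal conditioning,
1001-frame time normalization, per-trial Higuchi fractal dimension and
SVD entropy, five-trial averaging, per-condition summaries,
repeated-measures ANOVA and Tukey post-hoc tests — returning a
:class:`BalanceComplexityResults` that carries the estimates and writes
the six standard comparison tables (SvdEn and HDf for CoP, joint angles,
and muscles).
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as yio
from . import preprocess as prep
from .complexity import EmbeddingSpec, HiguchiSpec, measure_trial
from .io import TrialSignal, channel_family
from .stats import aggregate_trials, compare_conditions, condition_order, summarize
from .synthetic import SyntheticStudySpec, generate_study

__all__ = ["RunConfig", "BalanceComplexityModel", "BalanceComplexityResults", "run"]

log = logging.getLogger("ybalance")


@dataclass
class RunConfig:
    """Serializable recipe for one pipeline run."""

    input: str | None = None  # dataset CSV; None => synthetic
    output: str = "results"
    channels: tuple | None = None
    k_max: int = 8
    m: int = 2
    tau: int = 1
    center: bool = False
    angle_cutoff_hz: float = prep.ANGLE_CUTOFF_HZ
    cop_cutoff_hz: float = prep.COP_CUTOFF_HZ
    zero_phase: bool = True
    emg_use_envelope: bool = True
    normalize: bool = True
    n_frames: int = prep.N_FRAMES
    stats_mode: str = "within_subject"
    seed: int = 0

    def validate(self, available_channels=None) -> None:
        HiguchiSpec(self.k_max)
        EmbeddingSpec(self.m, self.tau)
        if self.stats_mode not in ("within_subject", "one_way"):
            raise ValueError(f"unknown stats mode {self.stats_mode!r}")
        if self.channels and available_channels is not None:
            unknown = set(self.channels) - set(available_channels)
            if unknown:
                raise ValueError(f"unknown channel(s): {sorted(unknown)}")


class BalanceComplexityModel:
    """Movement-complexity comparison model for a repeated-measures
    balance study.

    Parameters
    ----------
    signals
        List of :class:`~ybalance.io.TrialSignal` covering every
        (subject, condition, trial, channel) cell of interest.
    channels
        Optional channel subset to analyze.
    higuchi, embedding
        Estimator parameters (defaults ``k_max=8``; ``m=2, tau=1``).
    center
        Center the delay embedding before the SVD (default off: the DC
        level is part of the signal description).
    preprocess, normalize
        Toggle signal conditioning and 1001-frame time normalization.
    anova_mode
        ``within_subject`` (default) or ``one_way``.
    """

    def __init__(
        self,
        signals: list[TrialSignal],
        channels=None,
        higuchi: HiguchiSpec = HiguchiSpec(),
        embedding: EmbeddingSpec = EmbeddingSpec(),
        center: bool = False,
        preprocess: bool = True,
        normalize: bool = True,
        n_frames: int = prep.N_FRAMES,
        angle_cutoff_hz: float = prep.ANGLE_CUTOFF_HZ,
        cop_cutoff_hz: float = prep.COP_CUTOFF_HZ,
        zero_phase: bool = True,
        emg_use_envelope: bool = True,
        anova_mode: str = "within_subject",
        gg_correction: bool = False,
        posthoc: bool = True,
    ) -> None:
        if not signals:
            raise ValueError("empty dataset")
        available = sorted({s.channel for s in signals})
        if channels is not None:
            unknown = set(channels) - set(available)
            if unknown:
                raise ValueError(f"unknown channel(s): {sorted(unknown)}")
            signals = [s for s in signals if s.channel in set(channels)]
        self.signals = signals
        self.higuchi = higuchi
        self.embedding = embedding
        self.center = center
        self.preprocess = preprocess
        self.normalize = normalize
        self.n_frames = n_frames
        self.angle_cutoff_hz = angle_cutoff_hz
        self.cop_cutoff_hz = cop_cutoff_hz
        self.zero_phase = zero_phase
        self.emg_use_envelope = emg_use_envelope
        self.anova_mode = anova_mode
        self.gg_correction = gg_correction
        self.posthoc = posthoc

    # ------------------------------------------------------------------ build
    @classmethod
    def from_csv(cls, path, **kwargs) -> "BalanceComplexityModel":
        return cls(yio.read_dataset(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "BalanceComplexityModel":
        """Build from a long-format DataFrame (same columns as the CSV
        schema: subject, condition, trial, channel, time_s, value)."""
        signals = []
        for key, grp in df.groupby(["subject", "condition", "trial", "channel"], sort=False):
            t = grp["time_s"].to_numpy(dtype=float)
            step = float(np.median(np.diff(t))) if t.size > 1 else 1.0
            signals.append(
                TrialSignal(
                    subject=str(key[0]),
                    condition=str(key[1]),
                    trial=int(key[2]),
                    channel=str(key[3]),
                    rate=1.0 / step,
                    values=grp["value"].to_numpy(dtype=float),
                )
            )
        return cls(signals, **kwargs)

    @classmethod
    def from_synthetic(cls, spec: SyntheticStudySpec, **kwargs) -> "BalanceComplexityModel":
        return cls(generate_study(spec), **kwargs)

    # -------------------------------------------------------------------- fit
    def _condition_trial(self, s: TrialSignal) -> np.ndarray:
        x = s
        if self.preprocess:
            x = prep.preprocess_trial(
                x,
                angle_cutoff_hz=self.angle_cutoff_hz,
                cop_cutoff_hz=self.cop_cutoff_hz,
                zero_phase=self.zero_phase,
                emg_use_envelope=self.emg_use_envelope,
            )
        if self.normalize:
            return prep.time_normalize(x, n_frames=self.n_frames).values
        return x.values

    def fit(self) -> "BalanceComplexityResults":
        t0 = time.perf_counter()
        rows = []
        for s in self.signals:
            values = self._condition_trial(s)
            hdf, svden = measure_trial(values, self.higuchi, self.embedding, center=self.center)
            rows.append(
                {
                    "subject": s.subject,
                    "condition": s.condition,
                    "trial": s.trial,
                    "channel": s.channel,
                    "hdf": hdf,
                    "svden": svden,
                }
            )
        per_trial = pd.DataFrame(rows)
        log.info("complexity stage: %d trials in %.2fs", len(rows), time.perf_counter() - t0)
        long = per_trial.melt(
            id_vars=["subject", "condition", "trial", "channel"],
            value_vars=["hdf", "svden"],
            var_name="measure",
            value_name="value",
        )
        table = aggregate_trials(long)
        comparisons = compare_conditions(table, self.anova_mode, self.gg_correction, self.posthoc)
        return BalanceComplexityResults(self, per_trial, table, comparisons)


class BalanceComplexityResults:
    """Fitted results: per-trial measures, trial-averaged table, and one
    :class:`~ybalance.stats.ConditionComparison` per (channel, measure)."""

    def __init__(self, model, per_trial, table, comparisons) -> None:
        self.model = model
        self.per_trial = per_trial
        self.table = table
        self.comparisons = comparisons

    @property
    def summary_frame(self) -> pd.DataFrame:
        return summarize(self.table)

    def to_frame(self) -> pd.DataFrame:
        """One row per (channel, measure) with means, SEs, ANOVA and Tukey p."""
        rows = []
        for c in self.comparisons:
            rec = {"channel": c.channel, "measure": c.measure}
            for cond in c.conditions:
                rec[f"mean_{cond}"] = c.means[cond]
                rec[f"se_{cond}"] = c.ses[cond]
            rec.update(F=c.F, df1=c.df1, df2=c.df2, p_anova=c.p_anova)
            for (a, b), p in c.tukey.items():
                rec[f"p_{a}_{b}"] = p
            rows.append(rec)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable comparison table."""
        lines = []
        header = "Movement-complexity condition comparison"
        lines.append(header)
        lines.append("=" * len(header))
        n = self.comparisons[0].n if self.comparisons else 0
        lines.append(f"subjects (complete cases): {n}    ANOVA mode: {self.model.anova_mode}")
        for measure in ("svden", "hdf"):
            rows = [c for c in self.comparisons if c.measure == measure]
            if not rows:
                continue
            name = "SVD entropy (bits)" if measure == "svden" else "Higuchi fractal dimension"
            lines.append("")
            lines.append(name)
            lines.append("-" * len(name))
            conds = condition_order(rows[0].conditions)
            head = f"{'channel':<18}" + "".join(f"{c:>18}" for c in conds)
            head += f"{'F':>9}{'p':>9}"
            lines.append(head)
            for c in rows:
                cells = "".join(
                    f"{c.means[k]:>10.4g} ±{c.ses[k]:>6.2g}" for k in conds
                )
                lines.append(f"{c.channel:<18}{cells}{c.F:>9.3g}{c.p_anova:>9.3g}")
        return "\n".join(lines)

    def to_tables(self, outdir) -> list[Path]:
        """Write the comparison CSVs (one per measure x channel family)."""
        return yio.write_tables(self.comparisons, outdir)

    def plot_means(self, ax=None):
        """Bar plot of per-condition means with SE error bars, one group
        per channel/measure (simple diagnostic figure)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        frame = self.summary_frame
        labels = [f"{r.channel}\n{r.measure}" for r in frame.itertuples()]
        x = np.arange(len(frame))
        ax.bar(x, frame["mean"], yerr=frame["se"], capsize=2)
        ax.set_xticks(x, labels, rotation=90, fontsize=6)
        ax.set_ylabel("measure value")
        return ax


def run(config: RunConfig) -> BalanceComplexityResults:
    """Execute a full pipeline run from a config: load or synthesize the
    dataset, fit the model, and write tables + config snapshot + per-trial
    measures into ``config.output``."""
    outdir = Path(config.output)
    if config.input is not None:
        stage = "ingest"
        try:
            signals = yio.read_dataset(config.input)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage label
            raise RuntimeError(f"[{stage}] {exc}") from exc
    else:
        stage = "synthetic"
        spec = SyntheticStudySpec(seed=config.seed)
        signals = generate_study(spec)
    config.validate(available_channels={s.channel for s in signals})
    model = BalanceComplexityModel(
        signals,
        channels=config.channels,
        higuchi=HiguchiSpec(config.k_max),
        embedding=EmbeddingSpec(config.m, config.tau),
        center=config.center,
        normalize=config.normalize,
        n_frames=config.n_frames,
        angle_cutoff_hz=config.angle_cutoff_hz,
        cop_cutoff_hz=config.cop_cutoff_hz,
        zero_phase=config.zero_phase,
        emg_use_envelope=config.emg_use_envelope,
        anova_mode=config.stats_mode,
    )
    results = model.fit()
    outdir.mkdir(parents=True, exist_ok=True)
    results.to_tables(outdir)
    results.per_trial.to_csv(outdir / "per_trial_measures.csv", index=False, float_format="%.12g")
    yio.write_config(asdict(config), outdir / "config_snapshot.yaml")
    return results
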