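"""Dataset containers and tidy-CSV input/output.

A trial dataset is long-format: one row per sample with columns
``subject, condition, trial, channel, time_s, value``.  Each
(subject, condition, trial, channel) combination holds one uniformly
sampled series; the sampling rate is recovered from the time column and
validated (gaps and non-monotone time are ingest errors).

Channel names carry their family as a prefix-free convention:
``ankle_*`` / ``knee_*`` are intersegmental joint angles (degrees,
100 Hz), ``cop_*`` are center-of-pressure coordinates (meters, 1000 Hz),
and muscle names are surface-EMG channels (arbitrary units, 1000 Hz).
Axis suffixes follow the balance-lab convention AP (posterior-anterior,
x), ML (lateromedial, y), SI (external-internal rotation, z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrialSignal",
    "SchemaError",
    "ANGLE_CHANNELS",
    "COP_CHANNELS",
    "EMG_CHANNELS",
    "ALL_CHANNELS",
    "channel_family",
    "read_dataset",
    "write_dataset",
    "dataset_to_frame",
    "write_tables",
    "read_config",
    "write_config",
]

ANGLE_CHANNELS = ("ankle_AP", "ankle_ML", "ankle_SI", "knee_AP", "knee_ML", "knee_SI")
COP_CHANNELS = ("cop_AP", "cop_ML")
EMG_CHANNELS = ("gastrocnemius", "fibularis_longus", "rectus_femoris")
ALL_CHANNELS = ANGLE_CHANNELS + COP_CHANNELS + EMG_CHANNELS

CSV_COLUMNS = ["subject", "condition", "trial", "channel", "time_s", "value"]


class SchemaError(ValueError):
    """Raised when a dataset file violates the long-format schema."""


def channel_family(channel: str) -> str:
    """Map a channel name to its family: ``angle``, ``cop`` or ``emg``."""
    if channel.startswith(("ankle_", "knee_")):
        return "angle"
    if channel.startswith("cop_"):
        return "cop"
    return "emg"


@dataclass
class TrialSignal:
    """One channel of one trial: sample values plus identity and rate.

    ``values`` must be non-empty with no missing samples; time is
    implicit, uniform at ``rate`` samples/s starting at 0.
    """

    subject: str
    condition: str
    trial: int
    channel: str
    rate: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("values must be non-empty")
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite samples")

    @property
    def key(self) -> tuple:
        return (self.subject, self.condition, self.trial, self.channel)

    @property
    def family(self) -> str:
        return channel_family(self.channel)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate


def dataset_to_frame(signals: list[TrialSignal]) -> pd.DataFrame:
    """Long-format DataFrame view of a dataset (columns = CSV schema)."""
    parts = []
    for s in signals:
        parts.append(
            pd.DataFrame(
                {
                    "subject": s.subject,
                    "condition": s.condition,
                    "trial": s.trial,
                    "channel": s.channel,
                    "time_s": s.times,
                    "value": s.values,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_dataset(signals: list[TrialSignal], path) -> None:
    """Write a dataset to long-format CSV at full double precision."""
    df = dataset_to_frame(signals)
    df.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> list[TrialSignal]:
    """Read and validate a long-format dataset CSV.

    Raises :class:`SchemaError` on duplicated trial keys, non-monotone
    time, or sampling gaps larger than 1.5x the nominal sample interval.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    if df["value"].isna().any() or df["time_s"].isna().any():
        raise SchemaError("missing samples (NaN) in dataset")
    signals = []
    seen = set()
    for key, grp in df.groupby(["subject", "condition", "trial", "channel"], sort=False):
        if key in seen:  # pragma: no cover - groupby already merges
            raise SchemaError(f"duplicate trial key {key}")
        seen.add(key)
        t = grp["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            if np.unique(t).size < t.size:
                raise SchemaError(f"duplicate samples for {key}")
            raise SchemaError(f"non-monotone time for {key}")
        step = np.median(dt)
        if np.any(dt > 1.5 * step):
            raise SchemaError(f"sampling gap detected for {key}")
        rate = 1.0 / step
        signals.append(
            TrialSignal(
                subject=str(key[0]),
                condition=str(key[1]),
                trial=int(key[2]),
                channel=str(key[3]),
                rate=rate,
                values=grp["value"].to_numpy(dtype=float),
            )
        )
    keys = [s.key for s in signals]
    if len(set(keys)) != len(keys):
        raise SchemaError("duplicate (subject, condition, trial, channel) keys")
    return signals


# ---------------------------------------------------------------------------
# result tables


def _fmt_mean_se(mean: float, se: float) -> str:
    """mean +/- SE with at least two significant figures on the SE."""
    if se == 0 or not np.isfinite(se):
        return f"{mean:.4g} ± {se:.2g}"
    decimals = max(0, 1 - int(np.floor(np.log10(abs(se)))))
    return f"{mean:.{decimals}f} ± {se:.{decimals}f}"


def write_tables(results, path) -> list[Path]:
    """Write one comparison CSV per (measure, channel family).

    ``results`` is a list of ConditionComparison objects (see the stats
    module).  Each table has one row per channel; columns are the
    per-condition mean and SE in fixed condition order, then ANOVA F,
    degrees of freedom, p, and the Tukey-adjusted pairwise p-values.
    """
    if not results:
        raise ValueError("no results to write")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    groups: dict[tuple[str, str], list] = {}
    for r in results:
        groups.setdefault((r.measure, channel_family(r.channel)), []).append(r)
    for (measure, family), rows in sorted(groups.items()):
        recs = []
        for r in rows:
            rec = {"channel": r.channel}
            for cond in r.conditions:
                rec[f"mean_{cond}"] = r.means[cond]
                rec[f"se_{cond}"] = r.ses[cond]
                rec[f"{cond}"] = _fmt_mean_se(r.means[cond], r.ses[cond])
            rec.update(
                F=r.F, df1=r.df1, df2=r.df2, p_anova=r.p_anova,
                **{f"p_{a}_{b}": p for (a, b), p in r.tukey.items()},
            )
            recs.append(rec)
        out = path / f"{measure}_{family}.csv"
        pd.DataFrame(recs).to_csv(out, index=False, float_format="%.6g")
        written.append(out)
    return written


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
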