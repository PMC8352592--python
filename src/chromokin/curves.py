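"""Fluorescence time-series containers.

A :class:`TimeSeriesCurve` holds the raw channels a confocal FRAP/FLIP
acquisition produces: mean intensity of the bleached region of interest
(ROI), mean intensity of the whole nucleus, and a background estimate,
all sampled on a common time base.  ``n_pre`` marks how many frames were
acquired before the (instantaneous) photobleach; the first post-bleach
frame defines t = 0 of the recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class TimeSeriesCurve:
    """Raw FRAP/FLIP trace with acquisition metadata.

    Parameters
    ----------
    time
        Sample times in seconds, strictly increasing.
    roi
        Mean intensity of the bleached ROI per frame.
    whole
        Mean intensity of the whole nucleus per frame.
    background
        Background intensity per frame (may be all zeros).
    n_pre
        Number of pre-bleach frames (``1 <= n_pre < len(time)``).
    """

    time: np.ndarray
    roi: np.ndarray
    whole: np.ndarray
    background: np.ndarray
    n_pre: int
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "time", _as_float_array(self.time, "time"))
        object.__setattr__(self, "roi", _as_float_array(self.roi, "roi"))
        object.__setattr__(self, "whole", _as_float_array(self.whole, "whole"))
        object.__setattr__(
            self, "background", _as_float_array(self.background, "background")
        )
        n = len(self.time)
        for name in ("roi", "whole", "background"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length differs from time length")
        if n < 2:
            raise ValidationError("time must contain at least two samples")
        if not np.all(np.diff(self.time) > 0):
            raise ValidationError("time must be strictly increasing")
        if not (1 <= self.n_pre < n):
            raise ValidationError("n_pre must satisfy 1 <= n_pre < len(time)")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def post_time(self) -> np.ndarray:
        """Time since bleach for the post-bleach frames (first frame = 0)."""
        t = self.time[self.n_pre :]
        return t - t[0]

    def to_frame(self) -> pd.DataFrame:
        is_pre = np.zeros(len(self), dtype=int)
        is_pre[: self.n_pre] = 1
        return pd.DataFrame(
            {
                "time_s": self.time,
                "roi": self.roi,
                "whole": self.whole,
                "background": self.background,
                "is_pre": is_pre,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_pre: int | None = None) -> "TimeSeriesCurve":
        required = {"time_s", "roi"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"curve table missing columns: {sorted(missing)}")
        n = len(df)
        whole = df["whole"].to_numpy(float) if "whole" in df else np.ones(n)
        background = (
            df["background"].to_numpy(float) if "background" in df else np.zeros(n)
        )
        if n_pre is None:
            if "is_pre" not in df:
                raise ValidationError(
                    "n_pre not given and no is_pre column present"
                )
            n_pre = int(df["is_pre"].to_numpy(bool).sum())
        return cls(
            time=df["time_s"].to_numpy(float),
            roi=df["roi"].to_numpy(float),
            whole=whole,
            background=background,
            n_pre=n_pre,
        )

    @classmethod
    def from_csv(cls, path, n_pre: int | None = None) -> "TimeSeriesCurve":
        return cls.from_frame(pd.read_csv(path), n_pre=n_pre)


@dataclass(frozen=True)
class NormalizedCurve:
    """Full-scale normalized recovery curve.

    ``time`` is seconds relative to the bleach (pre-bleach samples are
    negative); ``value`` is dimensionless fluorescence where the
    pre-bleach mean maps to 1 and the first post-bleach sample to 0.
    """

    time: np.ndarray
    value: np.ndarray
    n_pre: int
    prebleach_reference: float = 1.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "time", _as_float_array(self.time, "time"))
        object.__setattr__(self, "value", _as_float_array(self.value, "value"))
        if len(self.time) != len(self.value):
            raise ValidationError("value length differs from time length")
        if not (1 <= self.n_pre < len(self.time)):
            raise ValidationError("n_pre must satisfy 1 <= n_pre < len(time)")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def post_time(self) -> np.ndarray:
        return self.time[self.n_pre :]

    @property
    def post_value(self) -> np.ndarray:
        return self.value[self.n_pre :]
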