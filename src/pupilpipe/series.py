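"""Core sample-series container shared by the generator and the preprocessing stages.

A :class:`SampleSeries` holds one continuous stretch of eye-tracker samples on a
uniform clock — pupil signal (device area units, or diameter after conversion),
a per-sample validity flag, and optional gaze position. Pupil values of zero with
``validity == False`` mark blinks / tracking loss, matching the conventions of
video-based eye trackers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import SchemaError

__all__ = ["SampleSeries"]

_REL_STEP_TOL = 1e-9


@dataclass
class SampleSeries:
    """Uniformly sampled pupil/gaze record.

    Parameters
    ----------
    time_ms : array of float
        Strictly increasing sample times in milliseconds, uniform step
        (nominal 2 ms at 500 Hz).
    pupil : array of float
        Pupil signal, ``>= 0``; 0 during blinks / tracking loss.
    validity : array of bool
        False where the tracker lost the pupil.
    gaze_x, gaze_y : array of float, optional
        Gaze position in screen pixels.
    units : str
        ``"area"`` (device arbitrary units, diameter²-proportional) or
        ``"diameter"`` after conversion.
    """

    time_ms: np.ndarray
    pupil: np.ndarray
    validity: np.ndarray | None = None
    gaze_x: np.ndarray | None = None
    gaze_y: np.ndarray | None = None
    units: str = "area"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.time_ms.ndim != 1 or self.time_ms.size < 2:
            raise SchemaError("a sample series needs at least two samples")
        if self.pupil.shape != self.time_ms.shape:
            raise SchemaError("time_ms and pupil must have equal length")
        steps = np.diff(self.time_ms)
        if np.any(steps <= 0):
            raise SchemaError("time_ms must be strictly increasing")
        step = steps[0]
        if np.any(np.abs(steps - step) > _REL_STEP_TOL * max(abs(step), 1.0)):
            raise SchemaError("time_ms must be uniformly sampled")
        if self.validity is None:
            self.validity = np.ones(self.time_ms.shape, dtype=bool)
        else:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.shape != self.time_ms.shape:
                raise SchemaError("validity must match series length")
        for name in ("gaze_x", "gaze_y"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.time_ms.shape:
                    raise SchemaError(f"{name} must match series length")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return self.time_ms.size

    @property
    def step_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def sampling_rate(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.step_ms

    def copy(self) -> "SampleSeries":
        return replace(
            self,
            time_ms=self.time_ms.copy(),
            pupil=self.pupil.copy(),
            validity=self.validity.copy(),
            gaze_x=None if self.gaze_x is None else self.gaze_x.copy(),
            gaze_y=None if self.gaze_y is None else self.gaze_y.copy(),
            meta=dict(self.meta),
        )

    def index_at(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms`` (must be in range)."""
        i = int(round((t_ms - self.time_ms[0]) / self.step_ms))
        if i < 0 or i >= len(self):
            raise IndexError(f"time {t_ms} ms outside series range")
        return i
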