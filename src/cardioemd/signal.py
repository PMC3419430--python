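"""Uniformly sampled single-channel signal container.

``Signal`` is the currency every stage of the toolkit consumes and
produces: a 1-D array of samples, a sampling rate in Hz and a free-text
label (e.g. ``"bp"`` for arterial blood pressure in mmHg or ``"ecg"``
for an electrocardiogram in mV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled channel.

    Parameters
    ----------
    samples : array_like
        Real-valued samples in the channel's physical units.
    rate : float
        Sampling frequency in Hz (> 0).
    label : str, optional
        Channel name.
    """

    samples: np.ndarray
    rate: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("signal samples must be one-dimensional")
        if samples.size < 2:
            raise ValueError("signal needs at least two samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal samples must all be finite")
        if not (self.rate > 0 and np.isfinite(self.rate)):
            raise ValueError("sampling rate must be a positive finite number")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate", float(self.rate))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.rate

    def replace(self, samples: np.ndarray, label: str | None = None) -> "Signal":
        """New Signal sharing this one's rate."""
        return Signal(samples, self.rate, self.label if label is None else label)
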