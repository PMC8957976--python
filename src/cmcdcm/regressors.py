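"""Low-frequency boxcar drivers for resting-state DCM and the GLM check.

Resting-state runs have no task events, so the deterministic DCM input is a
bank of phase-lagged boxcars tracking the slow rhythms of spontaneous
activity: for each frequency f in {0.01, 0.02, 0.04, 0.08} Hz (cycles of
100, 50, 25 and 12.5 s) two binary columns are built by thresholding
sin(2πft + φ) at zero, with φ = 0° and 90°, giving eight regressors in
total.  The same columns drive every node of the network and double as the
GLM design for the regressor-quality check.

Columns are generated on a micro-time grid (default TR/16) and evaluated at
bin centers, so boxcar switch times (which lie on the grid for the default
frequencies) never coincide with an evaluation point and every column has
duty cycle exactly 1/2 over an integer number of periods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_FREQUENCIES", "RegressorSet", "oscillator_boxcars"]

DEFAULT_FREQUENCIES = (0.01, 0.02, 0.04, 0.08)


@dataclass(frozen=True)
class RegressorSet:
    """A bank of binary boxcar drivers on a micro-time grid.

    ``values[t, k]`` is the k-th boxcar over bin ``[t·dt, (t+1)·dt)``;
    ``frequencies``/``phases`` give each column's frequency (Hz) and phase
    lead (degrees).  Columns come in (0°, 90°) pairs per frequency.
    """

    values: np.ndarray
    dt: float
    frequencies: tuple[float, ...]
    phases: tuple[float, ...]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.values.shape[0] * self.dt

    @property
    def names(self) -> list[str]:
        return [
            f"f{f:g}_p{int(p)}" for f, p in zip(self.frequencies, self.phases)
        ]

    def at_scans(self, tr: float, n_scans: int) -> np.ndarray:
        """Down-sample to scan resolution: the micro-time bin containing
        each scan time k·tr (k = 0 … n_scans−1)."""
        idx = np.floor(np.arange(n_scans) * tr / self.dt + 1e-9).astype(int)
        if idx[-1] >= self.values.shape[0]:
            raise ValueError("regressor duration shorter than requested scan window")
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def oscillator_boxcars(
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES,
    duration: float = 600.0,
    dt: float = 2.5 / 16,
) -> RegressorSet:
    """Build the phase-lagged boxcar bank.

    Parameters
    ----------
    frequencies:
        Oscillation frequencies in Hz; each contributes a 0° and a 90°
        column (K = 2 × len(frequencies)).
    duration:
        Total length in seconds; must cover at least one period of the
        slowest oscillation and be an integer number of bins.
    dt:
        Micro-time bin width in seconds; must resolve the fastest boxcar
        (dt < half-period of the highest frequency).
    """
    frequencies = tuple(float(f) for f in frequencies)
    if not frequencies or any(f <= 0 for f in frequencies):
        raise ValueError("all frequencies must be positive")
    if duration < 1.0 / min(frequencies):
        raise ValueError("duration must cover at least one period of the slowest frequency")
    shortest_half_period = 0.5 / max(frequencies)
    if dt >= shortest_half_period:
        raise ValueError(
            f"dt={dt} cannot resolve a boxcar with half-period {shortest_half_period}"
        )
    n = duration / dt
    if abs(n - round(n)) > 1e-9:
        raise ValueError("dt must divide duration into an integer number of bins")
    n = int(round(n))

    t = (np.arange(n) + 0.5) * dt  # bin centers; switch times sit on bin edges
    cols, freqs, phases = [], [], []
    for f in frequencies:
        for phase_deg in (0.0, 90.0):
            phase = np.deg2rad(phase_deg)
            cols.append((np.sin(2.0 * np.pi * f * t + phase) > 0).astype(float))
            freqs.append(f)
            phases.append(phase_deg)
    values = np.column_stack(cols)
    return RegressorSet(values=values, dt=dt, frequencies=tuple(freqs), phases=tuple(phases))
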