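"""Forward model: bilinear neural dynamics, balloon hemodynamics, scan sampling.

Neural model
------------
The five-region state vector y evolves as

    dy/dt = A·y + C·x(t) + Σ_i y_i · D(i)·y

where A holds fixed (first-order) connection strengths in Hz with strictly
negative self-decay on the diagonal, C couples the K boxcar drivers x(t)
into every node, and D(i) holds the second-order gains by which region i
multiplicatively modulates connections between other regions.

Hemodynamic model
-----------------
Each region's neural activity drives a balloon–Windkessel cascade
(vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin q):

    ds/dt = y − κ·s − γ·(f − 1)
    df/dt = s
    τ·dv/dt = f − v^{1/α}
    τ·dq/dt = f·(1 − (1−ρ)^{1/f})/ρ − v^{1/α}·q/v

with resting point s=0, f=v=q=1, and BOLD output (percent signal change)

    100·V0·(k1·(1−q) + k2·(1−q/v) + k3·(1−v)),  k1=7ρ, k2=2, k3=2ρ−0.2.

Both systems are integrated with classical fixed-step RK4 on the micro-time
grid (default TR/16).  The grid is aligned with the boxcar switch times, so
the piecewise-constant input is handled without order loss; the hemodynamic
stage interpolates neural activity linearly to step midpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_spec import CmcModelSpec
from .regressors import RegressorSet

__all__ = [
    "HemodynamicParams",
    "DcmParameters",
    "NeuralTrajectory",
    "BoldSignal",
    "SubjectRecording",
    "DivergenceError",
    "neural_derivative",
    "simulate_neural",
    "simulate_bold",
    "sample_to_scans",
    "DEFAULT_DIVERGENCE_BOUND",
]

DEFAULT_DIVERGENCE_BOUND = 1e3

#: Validity box for the balloon states: inflow, volume and deoxyhemoglobin
#: are dimensionless ratios to their resting values, physiologically O(1);
#: a trajectory outside (0, 100] means the hemodynamic model has left its
#: domain (inflow driven to zero is a genuine singularity of the
#: equations, not a numerical artifact) and is treated as divergence.
HEMO_STATE_BOUND = 100.0


class DivergenceError(RuntimeError):
    """A simulated trajectory left the valid region (|y| blow-up, or a
    hemodynamic state driven to zero or below)."""


@dataclass(frozen=True)
class HemodynamicParams:
    """Balloon–Windkessel constants (per region, shared by default).

    kappa: vasodilatory signal decay rate (1/s); gamma: flow
    autoregulation rate (1/s); tau: venous transit time (s); alpha:
    Grubb vessel stiffness exponent; rho: resting oxygen extraction
    fraction; v0: resting venous blood volume fraction.
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    rho: float = 0.4
    v0: float = 0.04

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "v0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hemodynamic constant {name} must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1)")

    @property
    def k1(self) -> float:
        return 7.0 * self.rho

    @property
    def k2(self) -> float:
        return 2.0

    @property
    def k3(self) -> float:
        return 2.0 * self.rho - 0.2


@dataclass
class DcmParameters:
    """One subject's full generative parameter set.

    ``a`` is 5×5 (Hz; row = target, column = source, strictly negative
    diagonal), ``c`` is 5×K (Hz per unit input), ``d`` maps each
    (modulator, source, target) label triple of the model spec to its
    unitless second-order gain.  ``noise_sd`` is the additive observation
    noise standard deviation in BOLD percent-signal-change units (None =
    to be resolved from a target SNR at generation time).
    """

    a: np.ndarray
    c: np.ndarray
    d: dict[tuple[str, str, str], float] = field(default_factory=dict)
    hemo: HemodynamicParams = field(default_factory=HemodynamicParams)
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.a.shape != (5, 5):
            raise ValueError("a must be 5x5")
        if self.c.ndim != 2 or self.c.shape[0] != 5:
            raise ValueError("c must be 5xK")
        if np.any(np.diag(self.a) >= 0):
            raise ValueError("diagonal of a (self-decay) must be strictly negative")

    def validate_against(self, spec: CmcModelSpec) -> None:
        """Check that nonzero entries respect the spec's masks."""
        off = ~np.eye(5, dtype=bool)
        bad = (self.a != 0) & (spec.a_mask == 0) & off
        if np.any(bad):
            raise ValueError(f"a has entries outside the {spec.variant} mask at {np.argwhere(bad)}")
        if set(self.d) - set(spec.d_masks):
            raise ValueError("d has entries outside the spec's d_masks")

    def d_triples(self, spec: CmcModelSpec) -> tuple[np.ndarray, np.ndarray]:
        """d as (n_d, 3) index array (modulator, source, target) + values."""
        ix = spec.regions.index
        idx, val = [], []
        for (m, s, t), g in self.d.items():
            idx.append((ix(m), ix(s), ix(t)))
            val.append(float(g))
        return np.asarray(idx, dtype=int).reshape(-1, 3), np.asarray(val, dtype=float)


@dataclass(frozen=True)
class NeuralTrajectory:
    """Micro-time neural states; row t is y at time t·dt."""

    y: np.ndarray
    dt: float


@dataclass(frozen=True)
class BoldSignal:
    """Continuous (micro-time) BOLD in percent signal change; row t is the
    output at time t·dt."""

    values: np.ndarray
    dt: float


@dataclass
class SubjectRecording:
    """Scan-resolution BOLD for one subject (scans × regions)."""

    values: np.ndarray
    tr: float
    region_labels: tuple[str, ...]
    group: str | None = None
    seed: int | None = None
    truth: DcmParameters | None = None
    noise_sd: float | None = None

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.region_labels))

    def write(self, tsv_path: str | Path) -> None:
        """Write the scans × regions TSV plus a JSON sidecar
        (same stem, ``.json``) holding TR, group, seed and truth values."""
        tsv_path = Path(tsv_path)
        self.to_frame().to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")
        side: dict = {
            "tr": self.tr,
            "group": self.group,
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "region_labels": list(self.region_labels),
        }
        if self.truth is not None:
            side["truth"] = {
                "a": self.truth.a.tolist(),
                "c": self.truth.c.tolist(),
                "d": {"|".join(k): v for k, v in self.truth.d.items()},
                "noise_sd": self.truth.noise_sd,
            }
        tsv_path.with_suffix(".json").write_text(json.dumps(side, indent=1))

    @classmethod
    def read(cls, tsv_path: str | Path) -> "SubjectRecording":
        tsv_path = Path(tsv_path)
        frame = pd.read_csv(tsv_path, sep="\t")
        side_path = tsv_path.with_suffix(".json")
        side = json.loads(side_path.read_text()) if side_path.exists() else {}
        truth = None
        if "truth" in side:
            tr_ = side["truth"]
            truth = DcmParameters(
                a=np.asarray(tr_["a"]),
                c=np.asarray(tr_["c"]),
                d={tuple(k.split("|")): v for k, v in tr_["d"].items()},
                noise_sd=tr_.get("noise_sd"),
            )
        return cls(
            values=frame.to_numpy(dtype=float),
            tr=float(side.get("tr", 2.5)),
            region_labels=tuple(side.get("region_labels", frame.columns.tolist())),
            group=side.get("group"),
            seed=side.get("seed"),
            truth=truth,
            noise_sd=side.get("noise_sd"),
        )


# ---------------------------------------------------------------------------
# dynamics


def neural_derivative(
    y: np.ndarray,
    x: np.ndarray,
    params: DcmParameters,
    spec: CmcModelSpec,
) -> np.ndarray:
    """Right-hand side A·y + C·x + Σ_i y_i·D(i)·y of the neural model."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite neural state or input")
    if y.shape != (5,):
        raise ValueError("y must be a 5-vector")
    if x.shape != (params.c.shape[1],):
        raise ValueError("x length must match the number of input columns")
    dy = params.a @ y + params.c @ x
    idx, val = params.d_triples(spec)
    for (m, s, t), g in zip(idx, val):
        dy[t] += y[m] * g * y[s]
    return dy


def _drive(params: DcmParameters, regs: RegressorSet) -> np.ndarray:
    """Precompute C·x(t) for every micro-time bin: (T, 5)."""
    return regs.values @ params.c.T


def simulate_neural(
    params: DcmParameters,
    regressors: RegressorSet,
    spec: CmcModelSpec,
    duration: float | None = None,
    bound: float = DEFAULT_DIVERGENCE_BOUND,
) -> NeuralTrajectory:
    """Fixed-step RK4 integration of the neural model from y(0) = 0.

    The driver is piecewise constant over each micro-time bin, so each RK4
    step sees a constant input and retains full order.  Trajectories whose
    magnitude exceeds ``bound`` raise :class:`DivergenceError`.
    """
    dt = regressors.dt
    if duration is None:
        duration = regressors.duration
    if duration > regressors.duration + 1e-9:
        raise ValueError("duration exceeds the regressor window")
    n_steps = int(round(duration / dt))
    u = _drive(params, regressors)
    a = params.a
    idx, val = params.d_triples(spec)
    has_d = len(val) > 0

    def f(y: np.ndarray, ut: np.ndarray) -> np.ndarray:
        dy = a @ y + ut
        if has_d:
            for (m, s, t), g in zip(idx, val):
                dy[t] += y[m] * g * y[s]
        return dy

    y = np.zeros(5)
    out = np.empty((n_steps, 5))
    for t in range(n_steps):
        out[t] = y
        ut = u[t]
        k1 = f(y, ut)
        k2 = f(y + 0.5 * dt * k1, ut)
        k3 = f(y + 0.5 * dt * k2, ut)
        k4 = f(y + dt * k3, ut)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > bound:
            raise DivergenceError(
                f"neural trajectory diverged at t={((t + 1) * dt):.2f}s "
                f"(|y| > {bound:g}); a diagonal {np.diag(a)}, max |d| "
                f"{np.max(np.abs(val)) if has_d else 0}"
            )
    return NeuralTrajectory(y=out, dt=dt)


def _hemo_derivative(state: np.ndarray, y: np.ndarray, h: HemodynamicParams) -> np.ndarray:
    s, f, v, q = state
    fv = v ** (1.0 / h.alpha)
    e = 1.0 - (1.0 - h.rho) ** (1.0 / f)
    return np.array(
        [
            y - h.kappa * s - h.gamma * (f - 1.0),
            s,
            (f - fv) / h.tau,
            (f * e / h.rho - fv * q / v) / h.tau,
        ]
    )


def simulate_bold(neural: NeuralTrajectory, params: DcmParameters) -> BoldSignal:
    """Balloon–Windkessel pass: neural trajectory → continuous BOLD (%).

    Per-region independent RK4 at the trajectory's dt; neural activity is
    interpolated linearly to step midpoints.  A venous volume or
    deoxyhemoglobin state at or below zero raises
    :class:`DivergenceError`.
    """
    y = neural.y
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite neural trajectory")
    dt = neural.dt
    n, r = y.shape
    h = params.hemo
    out = np.empty((n, r))
    # overflow inside a diverging trajectory is expected and handled by the
    # validity check below; silence the intermediate warnings
    with np.errstate(over="ignore", invalid="ignore"):
        return _balloon_loop(y, dt, n, r, h, out)


def _balloon_loop(y, dt, n, r, h, out) -> BoldSignal:
    for j in range(r):
        state = np.array([0.0, 1.0, 1.0, 1.0])  # s, f, v, q at rest
        for t in range(n):
            s_, f_, v_, q_ = state
            out[t, j] = 100.0 * h.v0 * (
                h.k1 * (1.0 - q_) + h.k2 * (1.0 - q_ / v_) + h.k3 * (1.0 - v_)
            )
            ya = y[t, j]
            yb = y[t + 1, j] if t + 1 < n else ya
            ym = 0.5 * (ya + yb)
            k1 = _hemo_derivative(state, ya, h)
            k2 = _hemo_derivative(state + 0.5 * dt * k1, ym, h)
            k3 = _hemo_derivative(state + 0.5 * dt * k2, ym, h)
            k4 = _hemo_derivative(state + dt * k3, yb, h)
            state = state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if (
                not np.all(np.isfinite(state))
                or np.any(state[1:] <= 0)
                or np.any(state[1:] > HEMO_STATE_BOUND)
            ):
                raise DivergenceError(
                    f"hemodynamic state diverged in region {j} at t={((t + 1) * dt):.2f}s"
                )
    return BoldSignal(values=out, dt=dt)


def sample_to_scans(
    bold: BoldSignal,
    tr: float,
    n_scans: int,
    region_labels: tuple[str, ...] | None = None,
) -> SubjectRecording:
    """Sample the continuous BOLD at scan times k·tr (nearest micro bin)."""
    duration = bold.values.shape[0] * bold.dt
    if (n_scans - 1) * tr > duration - bold.dt / 2 + 1e-9:
        raise ValueError(
            f"{n_scans} scans at TR={tr}s need {(n_scans - 1) * tr:.1f}s; "
            f"only {duration:.1f}s simulated"
        )
    idx = np.rint(np.arange(n_scans) * tr / bold.dt).astype(int)
    idx = np.minimum(idx, bold.values.shape[0] - 1)
    if region_labels is None:
        from .model_spec import REGION_LABELS

        region_labels = REGION_LABELS
    return SubjectRecording(values=bold.values[idx].copy(), tr=tr, region_labels=tuple(region_labels))
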