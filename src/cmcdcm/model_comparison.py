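"""Fixed-effects Bayesian model selection via the log group Bayes factor.

For two models fitted to the same n subjects, the group evidence ratio is

    log B = Σ_i log L(m_mod | y_i) − Σ_i log L(m_dir | y_i)

with each per-subject log evidence approximated by the variational free
energy.  Interpretation follows the conventional evidence thresholds:
log B > 10 is strong and log B > 3 moderate evidence for the alternative
(modulatory) model; otherwise the null (direct) model is retained.  The
inequalities are strict: a value of exactly 3 does not count as moderate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["Verdict", "BmsResult", "log_group_bayes_factor", "interpret_bayes_factor"]

STRONG_THRESHOLD = 10.0
MODERATE_THRESHOLD = 3.0


class Verdict(str, Enum):
    favor_modulatory_strong = "favor_modulatory_strong"
    favor_modulatory_moderate = "favor_modulatory_moderate"
    inconclusive_favor_direct = "inconclusive_favor_direct"


@dataclass(frozen=True)
class BmsResult:
    evidences_mod: tuple[float, ...]
    evidences_dir: tuple[float, ...]
    log_group_bayes_factor: float
    verdict: Verdict

    @property
    def per_subject(self) -> np.ndarray:
        """Per-subject log evidence differences (modulatory − direct)."""
        return np.asarray(self.evidences_mod) - np.asarray(self.evidences_dir)

    @property
    def n(self) -> int:
        return len(self.evidences_mod)


def log_group_bayes_factor(evidences_mod, evidences_dir) -> BmsResult:
    """Sum-difference of per-subject log evidences (modulatory − direct)."""
    mod = np.asarray(list(evidences_mod), dtype=float)
    dir_ = np.asarray(list(evidences_dir), dtype=float)
    if mod.size != dir_.size:
        missing = abs(mod.size - dir_.size)
        shorter = "modulatory" if mod.size < dir_.size else "direct"
        raise ValueError(
            f"evidence lists differ in length ({mod.size} vs {dir_.size}): "
            f"{missing} subject(s) missing from the {shorter} list"
        )
    if mod.size < 1:
        raise ValueError("need at least one subject")
    if not (np.all(np.isfinite(mod)) and np.all(np.isfinite(dir_))):
        raise ValueError("log evidences must be finite")
    value = float(mod.sum() - dir_.sum())
    return BmsResult(
        evidences_mod=tuple(mod),
        evidences_dir=tuple(dir_),
        log_group_bayes_factor=value,
        verdict=interpret_bayes_factor(value),
    )


def interpret_bayes_factor(value: float) -> Verdict:
    """Evidence-threshold verdict for a log Bayes factor (strict >3, >10)."""
    if not np.isfinite(value):
        raise ValueError("log Bayes factor must be finite")
    if value > STRONG_THRESHOLD:
        return Verdict.favor_modulatory_strong
    if value > MODERATE_THRESHOLD:
        return Verdict.favor_modulatory_moderate
    return Verdict.inconclusive_favor_direct
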