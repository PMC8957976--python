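"""Group-level parameter statistics: Bayesian Parameter Averaging and
directional group-difference tests.

Bayesian Parameter Averaging (BPA) combines per-subject Gaussian posteriors
into one group posterior under fixed effects, removing the prior that every
subject's posterior already contains once per extra subject:

    Λ_group = Σ_i Λ_i − (n−1)·Λ_0
    μ_group = Λ_group⁻¹ (Σ_i Λ_i μ_i − (n−1)·Λ_0 μ_0)

where Λ = Σ⁻¹ are precisions and (μ_0, Λ_0) is the shared prior.

The group comparison treats each parameter's group posteriors as
independent Gaussians and tests the directional hypotheses
H_A: M_PD − M_HC < 0 (and its mirror) with

    z = (μ_PD − μ_HC) / sqrt(σ_PD² + σ_HC²),  p_less = Φ(z),  p_greater = 1 − Φ(z)

which equals the posterior probability of the corresponding sign of the
difference.  Reported tables round to two decimals with a "<0.001" floor
and an em-dash for the direction that was not tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inversion import ParameterMap, ParameterPosterior, PriorSpec

__all__ = [
    "BpaResult",
    "DirectionalTestResult",
    "bayesian_parameter_average",
    "directional_test",
    "cross_model_contrast",
    "format_comparison_table",
]


@dataclass(frozen=True)
class BpaResult:
    """Group posterior summaries per parameter (diagonal dispersion)."""

    labels: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    cov: np.ndarray
    group: str | None
    n_subjects: int

    def __getitem__(self, label: str) -> tuple[float, float]:
        i = self.labels.index(label)
        return float(self.mean[i]), float(self.sd[i])

    def select(self, prefix: str) -> "BpaResult":
        """Restrict to parameters whose label starts with ``prefix``."""
        keep = [i for i, lab in enumerate(self.labels) if lab.startswith(prefix)]
        idx = np.asarray(keep, dtype=int)
        return BpaResult(
            labels=tuple(self.labels[i] for i in keep),
            mean=self.mean[idx],
            sd=self.sd[idx],
            cov=self.cov[np.ix_(idx, idx)],
            group=self.group,
            n_subjects=self.n_subjects,
        )


def bayesian_parameter_average(
    posteriors: list[ParameterPosterior],
    priors: PriorSpec,
    pmap: ParameterMap | None = None,
    group: str | None = None,
) -> BpaResult:
    """Fixed-effects combination of per-subject Gaussian posteriors.

    Operates on the generative parameter scale; the prior enters through
    its delta-method moments on that scale.  With a single posterior the
    input is returned unchanged (n−1 = 0).
    """
    if not posteriors:
        raise ValueError("need at least one posterior")
    labels = posteriors[0].labels
    for p in posteriors[1:]:
        if p.labels != labels:
            raise ValueError("posterior index maps differ; cannot average")
    if tuple(priors.labels) != tuple(labels) and pmap is None:
        raise ValueError("prior index map does not match the posteriors")
    n = len(posteriors)
    if pmap is None:
        # reconstruct kinds from labels for the scale transform
        mean0, var0 = _generative_prior_from_labels(priors)
    else:
        mean0, var0 = priors.generative_moments(pmap)
    lam0 = np.diag(1.0 / var0)

    lam_sum = np.zeros((len(labels), len(labels)))
    lam_mu_sum = np.zeros(len(labels))
    for p in posteriors:
        lam_i = np.linalg.inv(p.cov)
        lam_i = 0.5 * (lam_i + lam_i.T)
        lam_sum += lam_i
        lam_mu_sum += lam_i @ p.mean
    lam_g = lam_sum - (n - 1) * lam0
    w = np.linalg.eigvalsh(0.5 * (lam_g + lam_g.T))
    if w.min() <= 0:
        raise RuntimeError(
            f"combined group precision is not positive definite "
            f"(min eigenvalue {w.min():.3e}, n={n}); per-subject posteriors "
            f"may be wider than the prior"
        )
    cov_g = np.linalg.inv(lam_g)
    cov_g = 0.5 * (cov_g + cov_g.T)
    mu_g = cov_g @ (lam_mu_sum - (n - 1) * (lam0 @ mean0))
    return BpaResult(
        labels=tuple(labels),
        mean=mu_g,
        sd=np.sqrt(np.clip(np.diag(cov_g), 0.0, None)),
        cov=cov_g,
        group=group,
        n_subjects=n,
    )


def _generative_prior_from_labels(priors: PriorSpec) -> tuple[np.ndarray, np.ndarray]:
    mean = priors.mean.copy()
    var = priors.var.copy()
    for i, lab in enumerate(priors.labels):
        if lab.startswith("self:"):
            g = -0.5 * np.exp(priors.mean[i])
            mean[i] = g
            var[i] = g ** 2 * priors.var[i]
    return mean, var


@dataclass(frozen=True)
class DirectionalTestResult:
    """Per-parameter directional comparison of two group posteriors."""

    labels: tuple[str, ...]
    z: np.ndarray
    p_less: np.ndarray       # posterior P(M_PD − M_HC < 0)
    p_greater: np.ndarray    # posterior P(M_PD − M_HC > 0)
    group_a: str | None = None
    group_b: str | None = None

    def row(self, label: str) -> tuple[float, float, float]:
        i = self.labels.index(label)
        return float(self.z[i]), float(self.p_less[i]), float(self.p_greater[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"z": self.z, "p_less": self.p_less, "p_greater": self.p_greater},
            index=list(self.labels),
        )


def directional_test(bpa_pd: BpaResult, bpa_hc: BpaResult) -> DirectionalTestResult:
    """One-sided tests of the standardized group difference per parameter."""
    if bpa_pd.labels != bpa_hc.labels:
        raise ValueError("group results cover different parameter sets")
    var = bpa_pd.sd ** 2 + bpa_hc.sd ** 2
    if np.any(var <= 0):
        raise ValueError("zero combined dispersion; directional test undefined")
    z = (bpa_pd.mean - bpa_hc.mean) / np.sqrt(var)
    p_less = stats.norm.cdf(z)
    return DirectionalTestResult(
        labels=bpa_pd.labels,
        z=z,
        p_less=p_less,
        p_greater=1.0 - p_less,
        group_a=bpa_pd.group,
        group_b=bpa_hc.group,
    )


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.2f}"


def format_comparison_table(
    bpa_pd: BpaResult,
    bpa_hc: BpaResult,
    test: DirectionalTestResult,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Publication-dialect group table: per parameter, group (μ, σ) pairs
    and the p column(s).  p_less is always reported; p_greater only where
    the 'less' direction failed to reject (otherwise an em-dash), mirroring
    the two-stage directional testing procedure."""
    rows = []
    for i, lab in enumerate(test.labels):
        p_less = test.p_less[i]
        p_greater = test.p_greater[i]
        rows.append(
            {
                "parameter": lab,
                "mu_PD": round(float(bpa_pd.mean[i]), 2),
                "sigma_PD": float(bpa_pd.sd[i]),
                "mu_HC": round(float(bpa_hc.mean[i]), 2),
                "sigma_HC": float(bpa_hc.sd[i]),
                "p_less": _fmt_p(p_less),
                "p_greater": _fmt_p(p_greater) if p_less > alpha else "—",
            }
        )
    return pd.DataFrame(rows)


def cross_model_contrast(
    bpa_modulatory: tuple[BpaResult, BpaResult],
    bpa_direct: tuple[BpaResult, BpaResult],
) -> pd.DataFrame:
    """Group-difference signs of the shared fixed connections under each
    variant (the post-hoc contrast of the two model fits).

    Takes (PD, HC) pairs for each variant and reports, per fixed connection
    estimated in both, μ_PD − μ_HC under each variant plus a flag where the
    two variants disagree in sign.
    """
    mod_pd, mod_hc = bpa_modulatory
    dir_pd, dir_hc = bpa_direct
    shared = [
        lab
        for lab in mod_pd.labels
        if lab.startswith("a:") and lab in dir_pd.labels
    ]
    rows = []
    for lab in shared:
        diff_mod = mod_pd[lab][0] - mod_hc[lab][0]
        diff_dir = dir_pd[lab][0] - dir_hc[lab][0]
        rows.append(
            {
                "connection": lab,
                "diff_modulatory": diff_mod,
                "diff_direct": diff_dir,
                "sign_disagrees": bool(np.sign(diff_mod) != np.sign(diff_dir)),
            }
        )
    return pd.DataFrame(rows)
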