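"""Cross-validatory model checking and comparison.

Per observation the conditional predictive ordinate (CPO) is the
leave-one-out posterior predictive density Pr(y_ij | y_[ij]); it is
estimated from a single MCMC run by the harmonic-mean identity

    CPO_ij = [ T^-1 sum_t 1 / Pr(y_ij | theta^(t)) ]^-1

which avoids n-fold refitting.  For Bernoulli outcomes CPO lies in (0, 1];
very small values flag observations the model cannot explain.  The Bayesian
predictive p-value (B-p) is the posterior probability that a replicate
outcome matches the observed one, computed here in Rao-Blackwellized form
(the analytic replicate-match probability averaged over draws) rather than
by simulating replicates.  Model comparison uses the pseudo marginal
likelihood PsML = sum log CPO (a pseudo Bayes factor; larger is better).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "ValidationReport",
    "compute_cpo",
    "compute_bp_values",
    "psml",
    "scaled_cpo_screen",
    "validation_report",
]


def _loglik_matrix(samples) -> np.ndarray:
    if isinstance(samples, np.ndarray):
        ll = samples
    else:
        ll = samples.loglik_obs
        if ll is None:
            raise ValueError("samples carry no per-observation log-likelihoods "
                             "(fit with store_loglik=True)")
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2:
        raise ValueError("expected a (draws, observations) log-likelihood matrix")
    return ll


def compute_cpo(samples, return_flags: bool = False):
    """Harmonic-mean CPO per observation.

    ``samples`` is a PosteriorSamples or a (T, n) matrix of per-draw
    log-likelihoods log Pr(y_ij | theta^(t)).  Entries whose harmonic-mean
    denominator is dominated (> 50%) by a single draw, or that contain a
    zero-likelihood draw, are flagged as unstable.
    """
    ll = _loglik_matrix(samples)
    T = ll.shape[0]
    neg = -ll  # log 1/Pr
    denom = logsumexp(neg, axis=0)       # log sum_t 1/Pr
    cpo = np.exp(math.log(T) - denom)
    max_share = np.exp(neg.max(axis=0) - denom)
    flags = (max_share > 0.5) | ~np.isfinite(ll).all(axis=0)
    if return_flags:
        return cpo, flags
    return cpo


def compute_bp_values(samples) -> np.ndarray:
    """Rao-Blackwellized B-p value: posterior mean replicate-match probability,
    B-p_ij = T^-1 sum_t Pr(y_ij | theta^(t))."""
    ll = _loglik_matrix(samples)
    return np.exp(logsumexp(ll, axis=0) - math.log(ll.shape[0]))


def psml(cpo: np.ndarray) -> float:
    """Pseudo marginal likelihood, sum of log CPOs (larger is better)."""
    cpo = np.asarray(cpo, dtype=float)
    if cpo.size == 0:
        raise ValueError("empty CPO vector")
    if np.any(cpo <= 0.0):
        raise ValueError("zero CPO encountered; PsML undefined")
    return float(np.log(cpo).sum())


def scaled_cpo_screen(cpo: np.ndarray, limit: float = 0.001):
    """Scale CPOs to a maximum of one and flag entries below ``limit``.

    Returns (scaled, flags).  On a well-fitted model no observation should
    fall below the 0.001 screening limit.
    """
    cpo = np.asarray(cpo, dtype=float)
    if cpo.size == 0:
        raise ValueError("empty CPO vector")
    scaled = cpo / cpo.max()
    return scaled, scaled < limit


@dataclass
class ValidationReport:
    """Per-observation checks plus the model-level PsML."""

    model: int
    table: pd.DataFrame      # cpo, bp, scaled_cpo, unstable, outlier_flag
    psml: float
    n_flagged: int
    scaled_limit: float

    def summary(self) -> dict:
        t = self.table
        return {
            "model": self.model, "psml": self.psml,
            "cpo_min": float(t["cpo"].min()), "cpo_max": float(t["cpo"].max()),
            "bp_min": float(t["bp"].min()), "bp_max": float(t["bp"].max()),
            "min_scaled_cpo": float(t["scaled_cpo"].min()),
            "n_flagged": self.n_flagged,
            "n_unstable": int(t["unstable"].sum()),
        }


def validation_report(samples, limit: float = 0.001) -> ValidationReport:
    """Full validation pass over one fitted model's samples."""
    cpo, unstable = compute_cpo(samples, return_flags=True)
    bp = compute_bp_values(samples)
    scaled, flags = scaled_cpo_screen(cpo, limit=limit)
    table = pd.DataFrame({"cpo": cpo, "bp": bp, "scaled_cpo": scaled,
                          "unstable": unstable, "outlier_flag": flags})
    model = samples.model if hasattr(samples, "model") else 0
    return ValidationReport(model=model, table=table, psml=psml(cpo),
                            n_flagged=int(flags.sum()), scaled_limit=limit)
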