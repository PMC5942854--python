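"""Binomial burst model of msp gene-cluster transcription.

A primary spermatocyte nucleus holds ``K`` transcribable cluster states
(K=4 in the study: the maximum transcription-site count observed). In a
smFISH snapshot each state shows an active transcription site (TS)
independently with probability ``p``, so the per-nucleus TS count is
Binomial(K, p) and the per-cluster ON probability is estimated by moment
matching, ``p = mean(ts_count) / K``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "BinomialBurstModel",
    "FitReport",
    "estimate_cluster_probability",
    "positive_fraction",
    "model_pmf",
    "goodness_of_fit",
    "probability_reduction",
]


@dataclass
class FitReport:
    """Goodness of fit of the binomial model to an empirical TS histogram.

    ``r_squared`` is the squared Pearson correlation between the empirical
    relative frequencies and the model frequencies over count values
    0..K. When either frequency vector has zero variance the correlation
    is undefined: ``degenerate`` is set and ``r_squared`` is NaN.
    """

    empirical_freqs: np.ndarray
    model_freqs: np.ndarray
    r_squared: float
    degenerate: bool = False
    mode: str = "analytic"

    def to_dict(self) -> dict:
        return {
            "empirical_freqs": list(map(float, self.empirical_freqs)),
            "model_freqs": list(map(float, self.model_freqs)),
            "r_squared": None if self.degenerate else float(self.r_squared),
            "degenerate": self.degenerate,
            "mode": self.mode,
        }


def _extract_counts(counts) -> np.ndarray:
    """Accept a TS count table (DataFrame with ``ts_count``) or a 1-D array."""
    if isinstance(counts, pd.DataFrame):
        if "ts_count" not in counts.columns:
            raise ValueError("TS count table must have a 'ts_count' column")
        arr = counts["ts_count"].to_numpy()
        ids = counts.get("nucleus_id", pd.RangeIndex(len(counts))).to_numpy()
    else:
        arr = np.asarray(counts)
        ids = np.arange(arr.size)
    if arr.size == 0:
        raise ValueError("empty TS count table")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if np.any(arr < 0) or np.any(arr != np.round(arr)):
            raise ValueError("ts_count values must be non-negative integers")
        arr = arr.astype(int)
    return arr, ids


class BinomialBurstModel(BaseEstimator):
    """Binomial model of per-nucleus transcription-site counts.

    Parameters
    ----------
    n_states : int, default 4
        Number of transcribable cluster states K. Counts above K falsify
        the model and raise at fit time.
    p : float or None
        Per-cluster ON probability. Set directly for a fully specified
        model, or leave None and call :meth:`fit`.

    Attributes
    ----------
    p_ : float
        Estimated per-cluster ON probability, mean(ts_count)/K clamped to
        [0, 1].
    mean_ : float
        Sample mean TS count per nucleus.
    n_nuclei_ : int
        Number of nuclei used in the fit.
    """

    def __init__(self, n_states: int = 4, p: float | None = None):
        self.n_states = n_states
        self.p = p

    # -- estimation -------------------------------------------------------
    def fit(self, counts, y=None) -> "BinomialBurstModel":
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        arr, ids = _extract_counts(counts)
        over = arr > self.n_states
        if np.any(over):
            i = int(np.argmax(over))
            raise ValueError(
                f"nucleus {ids[i]!r} has ts_count={arr[i]} > K={self.n_states}: "
                "the state count is falsified; increase n_states"
            )
        self.mean_ = float(arr.mean())
        self.p_ = min(max(self.mean_ / self.n_states, 0.0), 1.0)
        self.n_nuclei_ = int(arr.size)
        return self

    def _p(self) -> float:
        if self.p is not None:
            return self.p
        if hasattr(self, "p_"):
            return self.p_
        raise ValueError("model has no probability: set p or call fit()")

    # -- model quantities --------------------------------------------------
    def pmf(self) -> np.ndarray:
        """Binomial(K, p) probability mass function over counts 0..K."""
        p = self._p()
        return stats.binom.pmf(np.arange(self.n_states + 1), self.n_states, p)

    def positive_fraction(self) -> float:
        """Expected fraction of nuclei with at least one active TS."""
        p = self._p()
        return 1.0 - (1.0 - p) ** self.n_states

    def expected_mean(self) -> float:
        return self.n_states * self._p()

    def simulate(self, n: int, seed=0) -> np.ndarray:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return rng.binomial(self.n_states, self._p(), size=n)

    def goodness_of_fit(
        self, counts, mode: str = "analytic", n_sim: int = 100_000, seed=0
    ) -> FitReport:
        """Compare the empirical TS histogram with the model distribution.

        ``mode='analytic'`` uses the exact pmf; ``mode='simulated'`` draws
        ``n_sim`` seeded nuclei from the model and uses their relative
        frequencies (mirroring a simulation-based comparison).
        """
        arr, _ = _extract_counts(counts)
        if np.any(arr > self.n_states):
            raise ValueError("observed count exceeds K")
        K = self.n_states
        emp = np.bincount(arr, minlength=K + 1)[: K + 1] / arr.size
        if mode == "analytic":
            mod = self.pmf()
        elif mode == "simulated":
            sim = self.simulate(n_sim, seed=seed)
            mod = np.bincount(sim, minlength=K + 1)[: K + 1] / n_sim
        else:
            raise ValueError("mode must be 'analytic' or 'simulated'")
        if np.ptp(emp) == 0 or np.ptp(mod) == 0:
            return FitReport(emp, mod, float("nan"), degenerate=True, mode=mode)
        r = np.corrcoef(emp, mod)[0, 1]
        return FitReport(emp, mod, float(r * r), mode=mode)

    def score(self, counts, y=None) -> float:
        """R^2 of the analytic goodness of fit (sklearn scoring hook)."""
        return self.goodness_of_fit(counts).r_squared


# -- thin functional wrappers ---------------------------------------------

def estimate_cluster_probability(counts, K: int = 4) -> BinomialBurstModel:
    """Fit the burst model: p = mean(ts_count)/K."""
    return BinomialBurstModel(n_states=K).fit(counts)


def positive_fraction(model: BinomialBurstModel) -> float:
    """Fraction of nuclei expected to show >= 1 TS: 1 - (1-p)^K."""
    return model.positive_fraction()


def model_pmf(model: BinomialBurstModel) -> np.ndarray:
    return model.pmf()


def goodness_of_fit(
    counts, model: BinomialBurstModel, mode: str = "analytic",
    n_sim: int = 100_000, seed=0,
) -> FitReport:
    return model.goodness_of_fit(counts, mode=mode, n_sim=n_sim, seed=seed)


def probability_reduction(model_a: BinomialBurstModel, model_b: BinomialBurstModel) -> float:
    """Fractional reduction of model_b's ON probability relative to model_a.

    Returns ``1 - p_b / p_a``; e.g. wild type vs mutant gives the drop in
    per-cluster transcription probability caused by the mutation. Depends
    only on the ratio of the two mean TS counts when K is shared.
    """
    p_a, p_b = model_a._p(), model_b._p()
    if p_a <= 0:
        raise ValueError("reference model has zero ON probability")
    return 1.0 - p_b / p_a
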