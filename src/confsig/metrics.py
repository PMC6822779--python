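"""Summary statistics of scored trial tables.

Three condensations of a simulated experiment:

* :func:`confidence_curve` — mean confidence as a function of
  discriminability, separately for correct and incorrect choices.  This
  is the object whose shape distinguishes the folded X-pattern
  (confidence rises with discriminability when correct, falls when
  incorrect) from the double-increase pattern (rises in both).
* :func:`classify_pattern` — count-weighted slopes of the two branches
  of a curve and a categorical label.
* :func:`entropy` / :func:`entropy_comparison` — the conditional
  entropy of accuracy given confidence,

      H(A|c) = -(1/n) * sum_j log(A_j c_j + (1 - A_j)(1 - c_j)),

  the mean negative log probability that the stated confidence assigns
  to the realised accuracy (natural log, nats).  Lower is better;
  H(A|c) = 0 means confidence perfectly predicts accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .posterior import PosteriorEngine
from .simulate import ExperimentConfig, TrialTable, simulate_trials

__all__ = [
    "ConfidenceCurve",
    "PatternCall",
    "EntropySummary",
    "confidence_curve",
    "classify_pattern",
    "entropy",
    "entropy_comparison",
]

FOLDED_X = "folded_X"
DOUBLE_INCREASE = "double_increase"
FLAT = "flat"

#: Default slope threshold separating a real trend from Monte Carlo
#: flatness, in confidence units per discriminability unit.
DEFAULT_SLOPE_THRESHOLD = 0.005

#: Default number of equal-width bins for continuous discriminability.
DEFAULT_BINS = 10


@dataclass
class ConfidenceCurve:
    """Mean confidence per discriminability level, split by accuracy.

    ``level`` holds exact support values (discrete priors) or bin
    midpoints (continuous priors), ascending.  Cells with no trials of
    an accuracy class hold NaN means, never zero.
    """

    level: np.ndarray
    mean_conf_correct: np.ndarray
    mean_conf_incorrect: np.ndarray
    n_correct: np.ndarray
    n_incorrect: np.ndarray

    def __len__(self) -> int:
        return len(self.level)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame: ``level, accuracy_class, mean_confidence, n``."""
        rows = []
        for cls, means, ns in (
            ("correct", self.mean_conf_correct, self.n_correct),
            ("incorrect", self.mean_conf_incorrect, self.n_incorrect),
        ):
            for lev, m, n in zip(self.level, means, ns):
                rows.append(
                    {"level": lev, "accuracy_class": cls, "mean_confidence": m, "n": int(n)}
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PatternCall:
    """Classified shape of a confidence curve."""

    slope_correct: float
    slope_incorrect: float
    label: str


@dataclass
class EntropySummary:
    """H(A|c) with and without discriminability evidence, in nats.

    ``se_diff`` is the Monte Carlo standard error of the paired
    per-trial difference of the two negative log scores.
    """

    sigma_d: float
    H_identity_only: float
    H_with_discriminability: float
    se_diff: float


def confidence_curve(trials: TrialTable, binning: str | int = "auto") -> ConfidenceCurve:
    """Aggregate a scored table into a confidence-vs-discriminability curve.

    Parameters
    ----------
    trials:
        A scored table (confidence column filled).
    binning:
        ``"discrete"`` groups by exact discriminability value;
        an integer requests that many equal-width bins over
        ``[0, max(d)]`` labelled by midpoints; ``"auto"`` picks
        discrete grouping when there are at most 25 distinct values
        and 10 bins otherwise.
    """
    if not trials.is_scored:
        raise ValueError("table has no confidence column; score it first")
    d = trials.d
    if binning == "auto":
        uniq = np.unique(d)
        binning = "discrete" if len(uniq) <= 25 else DEFAULT_BINS
    if binning == "discrete":
        levels, idx = np.unique(d, return_inverse=True)
    else:
        n_bins = int(binning)
        if n_bins < 1:
            raise ValueError("number of bins must be >= 1")
        hi = float(d.max())
        edges = np.linspace(0.0, hi, n_bins + 1)
        idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
        levels = 0.5 * (edges[:-1] + edges[1:])
    k = len(levels)
    acc = trials.accuracy.astype(bool)
    conf = trials.confidence
    n_c = np.bincount(idx[acc], minlength=k).astype(np.int64)
    n_i = np.bincount(idx[~acc], minlength=k).astype(np.int64)
    sum_c = np.bincount(idx[acc], weights=conf[acc], minlength=k)
    sum_i = np.bincount(idx[~acc], weights=conf[~acc], minlength=k)
    with np.errstate(invalid="ignore"):
        mean_c = np.where(n_c > 0, sum_c / np.maximum(n_c, 1), np.nan)
        mean_i = np.where(n_i > 0, sum_i / np.maximum(n_i, 1), np.nan)
    return ConfidenceCurve(
        level=np.asarray(levels, dtype=float),
        mean_conf_correct=mean_c,
        mean_conf_incorrect=mean_i,
        n_correct=n_c,
        n_incorrect=n_i,
    )


def _weighted_slope(x: np.ndarray, y: np.ndarray, n: np.ndarray) -> float:
    """Count-weighted least-squares slope of y on x, NaN cells dropped."""
    keep = np.isfinite(y) & (n > 0)
    if keep.sum() < 2:
        raise ValueError("need at least 2 populated levels to fit a slope")
    # polyfit weights multiply residuals, hence sqrt of the counts
    coef = np.polyfit(x[keep], y[keep], 1, w=np.sqrt(n[keep]))
    return float(coef[0])


def classify_pattern(
    curve: ConfidenceCurve, slope_threshold: float = DEFAULT_SLOPE_THRESHOLD
) -> PatternCall:
    """Label a curve folded-X, double-increase or flat.

    Slopes are count-weighted least-squares fits of mean confidence on
    discriminability level, one per accuracy class; levels lacking
    trials of a class are dropped from that fit.  Folded-X requires the
    correct-branch slope above ``slope_threshold`` and the
    incorrect-branch slope below its negative; double-increase requires
    both above the threshold; anything else is flat.
    """
    s_c = _weighted_slope(curve.level, curve.mean_conf_correct, curve.n_correct)
    s_i = _weighted_slope(curve.level, curve.mean_conf_incorrect, curve.n_incorrect)
    if s_c > slope_threshold and s_i < -slope_threshold:
        label = FOLDED_X
    elif s_c > slope_threshold and s_i > slope_threshold:
        label = DOUBLE_INCREASE
    else:
        label = FLAT
    return PatternCall(slope_correct=s_c, slope_incorrect=s_i, label=label)


def entropy(trials: TrialTable) -> float:
    """Conditional entropy of accuracy given confidence, in nats."""
    if not trials.is_scored:
        raise ValueError("table has no confidence column; score it first")
    a = trials.accuracy.astype(float)
    c = trials.confidence
    p_realised = a * c + (1.0 - a) * (1.0 - c)
    bad = np.flatnonzero(p_realised <= 0.0)
    if bad.size:
        j = int(bad[0])
        raise ValueError(
            f"trial {j} assigns zero probability to its realised accuracy "
            f"(accuracy={int(trials.accuracy[j])}, confidence={c[j]}): "
            "log(0) is undefined"
        )
    return float(-np.log(p_realised).mean())


def entropy_comparison(config: ExperimentConfig) -> EntropySummary:
    """Score one general-model experiment with and without ``e_d``.

    Simulates the experiment once, then scores the same trials twice:
    with the full general-model engine (confidence from ``e_I`` and
    ``e_d``) and with a standard-model engine sharing the prior and
    ``sigma_I`` (confidence from ``e_I`` alone — the observer ignores
    the discriminability evidence the trials carry).
    """
    if not config.is_general:
        raise ValueError("entropy comparison requires a general-model config")
    trials = simulate_trials(config)
    full = PosteriorEngine(config.prior, config.sigma_I, config.sigma_d).score(trials)
    ident = PosteriorEngine(config.prior, config.sigma_I).score(trials)
    a = trials.accuracy.astype(float)
    nll_full = -np.log(a * full.confidence + (1 - a) * (1 - full.confidence))
    nll_ident = -np.log(a * ident.confidence + (1 - a) * (1 - ident.confidence))
    diff = nll_ident - nll_full
    return EntropySummary(
        sigma_d=config.sigma_d,
        H_identity_only=float(nll_ident.mean()),
        H_with_discriminability=float(nll_full.mean()),
        se_diff=float(diff.std(ddof=1) / np.sqrt(len(diff))),
    )
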