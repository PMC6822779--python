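"""Trial-level Monte Carlo simulation of the confidence task.

Generative structure of one simulated experiment:

1. identity ``I`` is -1 or 1, each for exactly half of the trials;
2. discriminability ``d`` (nonnegative) is drawn i.i.d. from the
   experiment's :class:`~confsig.priors.DiscriminabilityPrior`;
3. identity evidence ``e_I ~ Normal(d * I, sigma_I)``;
4. under the general model only, discriminability evidence
   ``e_d ~ Normal(d, sigma_d)`` — it depends on ``d`` but not on ``I``;
5. the choice is the sign of ``e_I`` (ties map to +1), and accuracy is
   1 when the choice matches ``I``.

A single seeded generator drives each experiment; draws are consumed in
the fixed order d, e_I, e_d so runs are bit-for-bit reproducible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .priors import DiscriminabilityPrior

__all__ = ["ExperimentConfig", "TrialTable", "choose", "simulate_trials"]

STANDARD = "standard"
GENERAL = "general"


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of one simulated experiment.

    ``sigma_d`` present means the general model (the observer receives
    discriminability evidence); absent means the standard model.
    ``n_trials`` must be even so that both identities occur equally
    often.
    """

    prior: DiscriminabilityPrior
    sigma_I: float = 1.0
    sigma_d: float | None = None
    n_trials: int = 4_000_000
    seed: int = 0
    model: str | None = None

    def __post_init__(self):
        if self.sigma_I <= 0:
            raise ValueError("sigma_I must be positive")
        if self.sigma_d is not None and self.sigma_d <= 0:
            raise ValueError("sigma_d must be positive when present")
        if self.n_trials < 2 or self.n_trials % 2:
            raise ValueError("n_trials must be a positive even count")
        inferred = GENERAL if self.sigma_d is not None else STANDARD
        if self.model is None:
            object.__setattr__(self, "model", inferred)
        elif self.model != inferred:
            raise ValueError(
                f"model={self.model!r} inconsistent with sigma_d="
                f"{self.sigma_d!r} (expected {inferred!r})"
            )

    @property
    def is_general(self) -> bool:
        return self.model == GENERAL

    def with_seed(self, seed: int) -> "ExperimentConfig":
        return replace(self, seed=int(seed))


@dataclass
class TrialTable:
    """Columnar record of simulated trials.

    Columns: identity ``I`` in {-1, 1}; discriminability ``d`` >= 0;
    identity evidence ``e_I``; optional discriminability evidence
    ``e_d``; ``choice`` in {-1, 1}; ``accuracy`` in {0, 1}; and
    ``confidence`` in [0.5, 1], absent until a posterior engine scores
    the table.
    """

    I: np.ndarray
    d: np.ndarray
    e_I: np.ndarray
    choice: np.ndarray
    accuracy: np.ndarray
    e_d: np.ndarray | None = None
    confidence: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.I)
        for name in ("d", "e_I", "choice", "accuracy", "e_d", "confidence"):
            col = getattr(self, name)
            if col is not None and len(col) != n:
                raise ValueError(f"column {name} has length {len(col)}, expected {n}")

    def __len__(self) -> int:
        return len(self.I)

    @property
    def has_e_d(self) -> bool:
        return self.e_d is not None

    @property
    def is_scored(self) -> bool:
        return self.confidence is not None

    def to_frame(self) -> pd.DataFrame:
        cols = {"I": self.I, "d": self.d, "e_I": self.e_I}
        if self.e_d is not None:
            cols["e_d"] = self.e_d
        cols["choice"] = self.choice
        cols["accuracy"] = self.accuracy
        if self.confidence is not None:
            cols["confidence"] = self.confidence
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path | io.IOBase) -> None:
        """Write the table as plain CSV (gzip-transparent via suffix)."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialTable":
        return cls(
            I=df["I"].to_numpy(dtype=np.int8),
            d=df["d"].to_numpy(dtype=float),
            e_I=df["e_I"].to_numpy(dtype=float),
            choice=df["choice"].to_numpy(dtype=np.int8),
            accuracy=df["accuracy"].to_numpy(dtype=np.int8),
            e_d=df["e_d"].to_numpy(dtype=float) if "e_d" in df else None,
            confidence=df["confidence"].to_numpy(dtype=float) if "confidence" in df else None,
        )

    @classmethod
    def from_csv(cls, path: str | Path | io.IOBase) -> "TrialTable":
        return cls.from_frame(pd.read_csv(path))


def choose(e_I):
    """Deterministic choice rule: -1 when ``e_I`` < 0, else 1.

    Zero evidence (a probability-zero event for continuous noise) maps
    to choice 1 so the rule is fully deterministic.
    """
    e_I = np.asarray(e_I)
    out = np.where(e_I < 0, -1, 1).astype(np.int8)
    return out if out.ndim else int(out)


def simulate_trials(config: ExperimentConfig) -> TrialTable:
    """Simulate a full experiment under the given configuration.

    The first half of the trials has identity +1 and the second half
    -1; every downstream analysis is exchangeable over trial order so
    no shuffling is needed.
    """
    n = config.n_trials
    rng = np.random.default_rng(config.seed)
    I = np.empty(n, dtype=np.int8)
    I[: n // 2] = 1
    I[n // 2 :] = -1
    d = config.prior.sample(n, rng)
    e_I = rng.normal(d * I, config.sigma_I)
    e_d = rng.normal(d, config.sigma_d) if config.is_general else None
    theta = choose(e_I)
    accuracy = (theta == I).astype(np.int8)
    return TrialTable(I=I, d=d, e_I=e_I, choice=theta, accuracy=accuracy, e_d=e_d)
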