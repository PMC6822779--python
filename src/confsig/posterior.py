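"""Objective confidence: the Bayesian posterior probability of a
correct choice.

The observer knows the generative model — the discriminability prior
p(d), the identity prior (symmetric, P(I=1)=1/2), and the evidence
noise levels — and computes

    p(I = 1 | e_I, e_d) =
        sum_k p(d_k) N(e_I; d_k, sigma_I) N(e_d; d_k, sigma_d)
        -----------------------------------------------------------
        sum_{j in {-1,1}} sum_k p(d_k) N(e_I; j d_k, sigma_I) N(e_d; d_k, sigma_d)

where N(x; m, s) is the Gaussian density.  Confidence is the posterior
probability of the *chosen* identity: p(I=1|...) when the choice is 1,
its complement otherwise.  Because the choice is the sign of e_I and
the identity prior is symmetric, confidence is always >= 1/2.

The standard model (no discriminability evidence) is the same
expression with the N(e_d; d_k, sigma_d) factor dropped — equivalently
set to a constant across k.  Both variants share one code path.

For continuous priors the sums over k become quadrature sums using the
prior's deterministic rule.  All likelihood products are accumulated in
log space with log-sum-exp normalisation: at d = 10 and sigma_I = 1 the
raw Gaussian densities underflow double precision.
"""

from __future__ import annotations

import numpy as np

from .priors import DiscriminabilityPrior
from .simulate import TrialTable

__all__ = ["PosteriorEngine"]

# Rows per vectorised block; bounds peak memory at roughly
# chunk * n_nodes * 8 bytes per temporary (~25 MB at 384 nodes).
_CHUNK = 8192


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp with max subtraction (stable for -inf rows
    never occurring here: every row retains at least one finite term)."""
    m = a.max(axis=1, keepdims=True)
    return np.log(np.exp(a - m).sum(axis=1)) + m[:, 0]


class PosteriorEngine:
    """Computes objective confidence for one generative configuration.

    Parameters
    ----------
    prior:
        Distribution of discriminability ``|d|``.
    sigma_I:
        Standard deviation of the identity evidence.
    sigma_d:
        Standard deviation of the discriminability evidence; ``None``
        selects the standard model (confidence from ``e_I`` alone).
    """

    def __init__(
        self,
        prior: DiscriminabilityPrior,
        sigma_I: float = 1.0,
        sigma_d: float | None = None,
    ):
        if sigma_I <= 0:
            raise ValueError("sigma_I must be positive")
        if sigma_d is not None and sigma_d <= 0:
            raise ValueError("sigma_d must be positive when present")
        self.prior = prior
        self.sigma_I = float(sigma_I)
        self.sigma_d = None if sigma_d is None else float(sigma_d)
        self.nodes, self.weights = prior.quadrature()
        with np.errstate(divide="ignore"):
            self._log_w = np.log(self.weights)

    @property
    def is_general(self) -> bool:
        return self.sigma_d is not None

    # -- internals -----------------------------------------------------

    def _check_e_d(self, e_d):
        if self.is_general and e_d is None:
            raise ValueError("general-model engine requires e_d")
        if not self.is_general and e_d is not None:
            raise ValueError("standard-model engine accepts no e_d")

    def _log_odds(self, e_I: np.ndarray, e_d: np.ndarray | None) -> np.ndarray:
        """log p(I=1|evidence) - log p(I=-1|evidence), chunked.

        Expanding the identity-evidence exponent, the e_I**2 term is
        common to both identities and cancels in the odds, leaving a
        node-only term folded into the weights and a rank-one cross
        term with opposite signs for I = +1 and I = -1.
        """
        out = np.empty(len(e_I))
        # log w_k - d_k^2 / (2 sigma_I^2): identity-independent part
        g0 = self._log_w - 0.5 * (self.nodes / self.sigma_I) ** 2
        scaled_nodes = self.nodes / self.sigma_I**2
        for start in range(0, len(e_I), _CHUNK):
            sl = slice(start, start + _CHUNK)
            g = g0[None, :]
            if e_d is not None:
                g = g - 0.5 * ((e_d[sl, None] - self.nodes[None, :]) / self.sigma_d) ** 2
            cross = e_I[sl, None] * scaled_nodes[None, :]
            out[sl] = _logsumexp_rows(g + cross) - _logsumexp_rows(g - cross)
        return out

    # -- public API ----------------------------------------------------

    def posterior_identity(self, e_I, e_d=None):
        """Posterior probability that the identity is +1.

        Scalar in, scalar out; arrays are processed element-wise.
        ``e_d`` must be supplied iff the engine is a general-model one.
        """
        self._check_e_d(e_d)
        e_I_arr = np.atleast_1d(np.asarray(e_I, dtype=float))
        e_d_arr = None if e_d is None else np.broadcast_to(
            np.asarray(e_d, dtype=float), e_I_arr.shape
        ).astype(float)
        log_odds = self._log_odds(e_I_arr, e_d_arr)
        # expit of the log odds, stable on both tails
        with np.errstate(over="ignore"):
            p = np.where(
                log_odds >= 0,
                1.0 / (1.0 + np.exp(-log_odds)),
                np.exp(log_odds) / (1.0 + np.exp(log_odds)),
            )
        return p if np.ndim(e_I) else float(p[0])

    def confidence(self, e_I, e_d=None, choice=1):
        """Posterior probability that the given choice is correct.

        Equals ``posterior_identity`` for choice 1 and its complement
        for choice -1; when the choice follows the sign rule the result
        lies in [0.5, 1].
        """
        p1 = self.posterior_identity(e_I, e_d)
        choice_arr = np.asarray(choice)
        out = np.where(choice_arr == 1, p1, 1.0 - np.asarray(p1))
        return out if np.ndim(out) else float(out)

    def score(self, trials: TrialTable) -> TrialTable:
        """Return a copy of ``trials`` with the confidence column filled.

        A standard-model engine ignores any ``e_d`` column — this is
        deliberate and supports comparing identity-only confidence with
        full confidence on the same trials.
        """
        if self.is_general and not trials.has_e_d:
            raise ValueError("general-model engine needs trials with an e_d column")
        e_d = trials.e_d if self.is_general else None
        conf = self.confidence(trials.e_I, e_d, trials.choice)
        return TrialTable(
            I=trials.I,
            d=trials.d,
            e_I=trials.e_I,
            choice=trials.choice,
            accuracy=trials.accuracy,
            e_d=trials.e_d,
            confidence=np.asarray(conf, dtype=float),
        )

    # score_table: operation-style alias
    score_table = score
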