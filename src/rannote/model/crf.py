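"""Linear-chain CRF: forward-algorithm likelihood and Viterbi decoding.

A tag path ``y`` over a sentence with per-token emission scores ``E`` is
scored as

    score(y) = bos[y_1] + sum_t E[t, y_t] + sum_t trans[y_t, y_{t+1}] + eos[y_n]

and ``log p(y | x) = score(y) - logZ`` with the partition function computed
by the forward algorithm in log space.  BOS/EOS boundary scores are modeled
as two extra transition vectors, not emitted tags.  Viterbi ties are broken
toward the lower tag index at every backpointer (argmax takes the first
maximum).
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .layers import Param


class CrfParams:
    """Learned transition scores over the tag set plus BOS/EOS boundaries."""

    def __init__(self, n_tags: int, name: str = "crf"):
        self.name = name
        self.n_tags = n_tags
        self.trans = Param(np.zeros((n_tags, n_tags)))
        self.bos = Param(np.zeros(n_tags))
        self.eos = Param(np.zeros(n_tags))

    def params(self) -> dict[str, Param]:
        return {
            f"{self.name}.trans": self.trans,
            f"{self.name}.bos": self.bos,
            f"{self.name}.eos": self.eos,
        }

    def zero_grad(self) -> None:
        for p in self.params().values():
            p.grad[...] = 0.0


def _check(emissions: np.ndarray) -> None:
    if emissions.ndim != 2 or emissions.shape[0] == 0:
        raise ValueError("emissions must be a non-empty (n_tokens, n_tags) array")
    if not np.all(np.isfinite(emissions)):
        raise ValueError("emission scores must be finite")


def path_score(emissions: np.ndarray, tags: np.ndarray, trans: np.ndarray,
               bos: np.ndarray, eos: np.ndarray) -> float:
    tags = np.asarray(tags)
    s = bos[tags[0]] + eos[tags[-1]] + emissions[np.arange(len(tags)), tags].sum()
    if len(tags) > 1:
        s += trans[tags[:-1], tags[1:]].sum()
    return float(s)


def forward_alphas(emissions: np.ndarray, trans: np.ndarray, bos: np.ndarray
                   ) -> np.ndarray:
    """Log-space forward messages; alphas[t, y] sums all prefixes ending in y."""
    n, T = emissions.shape
    alphas = np.empty((n, T))
    alphas[0] = bos + emissions[0]
    for t in range(1, n):
        alphas[t] = logsumexp(alphas[t - 1][:, None] + trans, axis=0) + emissions[t]
    return alphas


def backward_betas(emissions: np.ndarray, trans: np.ndarray, eos: np.ndarray
                   ) -> np.ndarray:
    n, T = emissions.shape
    betas = np.empty((n, T))
    betas[-1] = eos
    for t in range(n - 2, -1, -1):
        betas[t] = logsumexp(trans + emissions[t + 1] + betas[t + 1], axis=1)
    return betas


def log_partition(emissions: np.ndarray, trans: np.ndarray, bos: np.ndarray,
                  eos: np.ndarray) -> float:
    _check(emissions)
    alphas = forward_alphas(emissions, trans, bos)
    return float(logsumexp(alphas[-1] + eos))


def crf_log_likelihood(emissions: np.ndarray, tags, crf: CrfParams) -> float:
    """``log p(tags | sentence)``; always <= 0."""
    _check(emissions)
    trans, bos, eos = crf.trans.value, crf.bos.value, crf.eos.value
    return path_score(emissions, tags, trans, bos, eos) - log_partition(
        emissions, trans, bos, eos
    )


def crf_nll_grad(emissions: np.ndarray, tags, crf: CrfParams
                 ) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and its gradients.

    Returns ``(nll, d_emissions)`` and accumulates the transition/boundary
    gradients (expected minus observed sufficient statistics, obtained from
    forward-backward marginals) into ``crf``'s params.
    """
    _check(emissions)
    tags = np.asarray(tags)
    n, T = emissions.shape
    trans, bos, eos = crf.trans.value, crf.bos.value, crf.eos.value

    alphas = forward_alphas(emissions, trans, bos)
    betas = backward_betas(emissions, trans, eos)
    log_z = float(logsumexp(alphas[-1] + eos))

    # unary marginals
    mu = np.exp(alphas + betas - log_z)  # (n, T)
    d_emissions = mu.copy()
    d_emissions[np.arange(n), tags] -= 1.0

    crf.bos.grad += mu[0]
    crf.bos.grad[tags[0]] -= 1.0
    crf.eos.grad += mu[-1]
    crf.eos.grad[tags[-1]] -= 1.0

    for t in range(n - 1):
        pair = np.exp(
            alphas[t][:, None] + trans + emissions[t + 1] + betas[t + 1] - log_z
        )
        crf.trans.grad += pair
        crf.trans.grad[tags[t], tags[t + 1]] -= 1.0

    nll = log_z - path_score(emissions, tags, trans, bos, eos)
    return float(nll), d_emissions


def viterbi_decode(emissions: np.ndarray, crf: CrfParams
                   ) -> tuple[list[int], float]:
    """Best-scoring tag path and its score.

    Dynamic program over ``delta[t, y] = max score of any prefix ending in
    tag y``; ``np.argmax`` returns the first maximum, so ties resolve to the
    lowest tag index.
    """
    _check(emissions)
    trans, bos, eos = crf.trans.value, crf.bos.value, crf.eos.value
    n, T = emissions.shape
    delta = bos + emissions[0]
    backptr = np.zeros((n, T), dtype=np.int64)
    for t in range(1, n):
        scores = delta[:, None] + trans  # (from, to)
        backptr[t] = scores.argmax(axis=0)
        delta = scores[backptr[t], np.arange(T)] + emissions[t]
    delta = delta + eos
    last = int(delta.argmax())
    best_score = float(delta[last])
    path = [last]
    for t in range(n - 1, 0, -1):
        path.append(int(backptr[t, path[-1]]))
    path.reverse()
    return path, best_score
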