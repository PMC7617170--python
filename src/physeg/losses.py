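"""Training losses: soft-target cross-entropy, the stratification loss,
and heteroscedastic loss attenuation.

The stratification loss acts on the feature maps of a single-subject,
multi-contrast batch.  Because all batch members share one anatomy and
one label patch, their penultimate feature maps should agree; the loss is
the mean squared element-wise difference averaged over all unique member
pairs, which is zero iff all members are identical.  (The quantity is
penalised with a positive sign: the objective enforces similarity
between members.)

Heteroscedastic loss attenuation perturbs the task logits f with noise
eps_t ~ N(0, sigma^2), where sigma is predicted per voxel and class, and
averages the resulting cross-entropies in the log domain over T draws:

    L = mean_i log (1/T) sum_t exp( c_i . (-eta_t + log sum_c' e^{eta_t,c'}) ),
    eta_t = f + eps_t.

With sigma identically zero every draw coincides and the loss reduces
exactly to the soft-target cross-entropy.  The per-voxel reduction is a
mean so that loss weights are resolution-independent.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .nn.autograd import Tensor, logsumexp

__all__ = [
    "stratification_loss",
    "cross_entropy",
    "total_loss",
    "heteroscedastic_loss",
]


def _coerce(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def stratification_loss(features) -> Tensor:
    """Mean over unique member pairs of the mean squared feature difference.

    ``features``: sequence of n >= 2 equally shaped feature tensors, or a
    single tensor whose leading axis enumerates batch members.
    Non-negative, zero iff all members are equal, permutation-invariant.
    """
    if isinstance(features, (Tensor, np.ndarray)):
        t = _coerce(features)
        members = [t[i] for i in range(t.shape[0])]
    else:
        members = [_coerce(f) for f in features]
    n = len(members)
    if n < 2:
        raise ValueError("stratification loss needs at least 2 batch members")
    shapes = {m.shape for m in members}
    if len(shapes) != 1:
        raise ValueError("feature maps must share one shape")
    pairs = list(combinations(range(n), 2))
    total = None
    for a, b in pairs:
        d = ((members[a] - members[b]) ** 2).mean()
        total = d if total is None else total + d
    return total * (1.0 / len(pairs))


def _check_labels(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.float64)
    if labels.shape[0] != n_classes and labels.ndim >= 2:
        pass
    sums = labels.sum(axis=1) if labels.ndim >= 2 else labels.sum()
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("labels must be normalised (sum to 1 over classes)")
    return labels


def cross_entropy(logits, labels) -> Tensor:
    """Soft-target cross-entropy, -sum_c c log p_c, averaged over voxels.

    ``logits``: (N, C, ...) tensor; ``labels``: (N, C, ...) array of class
    responsibilities summing to 1 over the class axis.
    """
    logits = _coerce(logits)
    labels = _check_labels(np.asarray(labels), logits.shape[1])
    if labels.shape != logits.shape:
        raise ValueError("labels shape must match logits shape")
    lse = logsumexp(logits, axis=1)
    nll = (Tensor(labels) * (lse - logits)).sum(axis=1)
    return nll.mean()


def total_loss(logits, labels, features=None, strat_weight: float = 1.0):
    """Cross-entropy plus the weighted stratification term.

    Returns ``(loss, parts)`` where ``parts`` maps term names to floats.
    """
    ce = cross_entropy(logits, labels)
    parts = {"cross_entropy": float(ce.data)}
    loss = ce
    if features is not None and strat_weight != 0:
        strat = stratification_loss(features)
        parts["stratification"] = float(strat.data)
        loss = loss + strat * strat_weight
    parts["total"] = float(loss.data)
    return loss, parts


def heteroscedastic_loss(logits, sigma, labels, T: int = 10,
                         rng: np.random.Generator | None = None) -> Tensor:
    """Loss-attenuated cross-entropy with T logit-noise draws.

    Differentiable in both ``logits`` and ``sigma`` (reparameterised
    noise).  Averaged over voxels; with sigma = 0 it equals
    :func:`cross_entropy` exactly for any T.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    logits = _coerce(logits)
    sigma = _coerce(sigma)
    if (sigma.data < 0).any():
        raise ValueError("sigma must be non-negative")
    labels = _check_labels(np.asarray(labels), logits.shape[1])
    if rng is None:
        rng = np.random.default_rng(0)

    lab = Tensor(labels)
    # reparameterised draws, vectorised over t: eta (T, N, C, ...)
    z = Tensor(rng.standard_normal((T,) + tuple(logits.shape)))
    eta = logits + sigma * z
    ce_t = (lab * (logsumexp(eta, axis=2) - eta)).sum(axis=2)  # (T, N, ...)
    # log mean exp over draws, per voxel
    lme = logsumexp(ce_t, axis=0) - float(np.log(T))
    return lme.mean()
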