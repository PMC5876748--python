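"""Small independent HMM oracles shared by the unit and acceptance tests.

These deliberately avoid the package's own forward/Viterbi code paths:
sampling is ancestral, and the exhaustive decoder enumerates all 4^T
paths.
"""

import itertools

import numpy as np

from gaitphase.hmm import HmmModel


def cyclic_model(rng, n_mix=1) -> HmmModel:
    """Random model respecting the left-right cyclic structure."""
    A = np.zeros((4, 4))
    for i in range(4):
        a = rng.uniform(0.6, 0.98)
        A[i, i] = a
        A[i, (i + 1) % 4] = 1 - a
    means = np.sort(rng.uniform(-150, 300, (4, n_mix)), axis=1)
    sds = rng.uniform(10, 60, (4, n_mix))
    w = rng.dirichlet(np.ones(n_mix), size=4)
    return HmmModel(A=A, pi=np.full(4, 0.25), weights=w, means=means,
                    sds=sds)


def sample_from(model: HmmModel, T: int, rng):
    """Ancestral sampling of (observations, states)."""
    states = np.empty(T, dtype=int)
    x = np.empty(T)
    s = rng.choice(4, p=model.pi)
    for t in range(T):
        states[t] = s
        m = rng.choice(model.n_mix, p=model.weights[s])
        x[t] = rng.normal(model.means[s, m], model.sds[s, m])
        s = rng.choice(4, p=model.A[s])
    return x, states


def brute_force_path(model: HmmModel, x):
    """Exhaustive max-probability path over all 4^T state sequences."""
    logB = model.log_emissions(x)
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
        logpi = np.log(model.pi)
    best, best_lp = None, -np.inf
    for path in itertools.product(range(4), repeat=len(x)):
        lp = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, len(x)):
            lp += logA[path[t - 1], path[t]] + logB[t, path[t]]
        if lp > best_lp:
            best_lp, best = lp, path
    return np.array(best), best_lp
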