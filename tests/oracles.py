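"""Independent oracles used by the test suite.

These deliberately avoid the package's forward recursion and vectorized
code paths: the likelihood oracle enumerates every latent state path, and
the CJS simulator is a from-scratch Bernoulli process.
"""

from __future__ import annotations

import itertools

import numpy as np

from poachmort.hmm import N_STATES, RELEASE_STATE, build_event_matrix, build_transition
from poachmort.structures import ModelStructure, ParameterIndex, ParameterSet


def brute_force_history_loglik(events, age_at_marking, params: ParameterSet, marking_occasion=None):
    """Exhaustive sum over all latent state sequences (tiny histories only)."""
    ev = np.asarray(events, dtype=int)
    T = ev.size
    if marking_occasion is None:
        f = int(np.flatnonzero(ev)[0])
    else:
        f = int(marking_occasion)
    s0 = RELEASE_STATE[int(ev[f])]
    steps = list(range(f + 1, T))
    total = 0.0
    for path in itertools.product(range(N_STATES), repeat=len(steps)):
        prob = 1.0
        prev = s0
        for t, s in zip(steps, path):
            age = age_at_marking + (t - 1 - f)
            Tm = build_transition(params, params.partition.class_of(age), t - f)
            B = build_event_matrix(params, t)
            prob *= Tm[prev, s] * B[s, ev[t]]
            prev = s
        total += prob
    return np.log(total) if total > 0 else -np.inf


MORTALITIES = ("interactive", "additive", "constant_poach")
RESIGHTS = ("constant", "by_mark", "by_time", "mark_plus_time", "mark_by_time")
RECOVERIES = ("constant", "by_time")


def random_structure(rng: np.random.Generator, sex="F", ages="1,2:7,8+") -> ModelStructure:
    return ModelStructure(
        sex=sex,
        ages=ages,
        mortality=MORTALITIES[rng.integers(len(MORTALITIES))],
        resight=RESIGHTS[rng.integers(len(RESIGHTS))],
        recovery=RECOVERIES[rng.integers(len(RECOVERIES))],
        r_gps=float(rng.random()) if rng.random() < 0.3 else 1.0,
    )


def random_parameter_set(rng: np.random.Generator, n_occasions=5, structure=None,
                         scale=3.0, ages=None):
    """A valid ParameterSet drawn through a random structure's links."""
    if structure is not None:
        st = structure
    elif ages is not None:
        st = random_structure(rng, ages=ages)
    else:
        st = random_structure(rng)
    index = ParameterIndex(st, n_occasions)
    theta = rng.uniform(-scale, scale, index.n_params)
    return index.inflate(theta), theta, index


def sim_cjs_binary(n, T, phi, p, rng, entry_span=None):
    """Time-dependent CJS detection histories, independent of the package.

    ``phi[t]`` is survival over interval (t, t+1); ``p[t]`` detection at
    occasion t.  Entry is uniform over the first ``entry_span`` occasions.
    """
    span = entry_span if entry_span is not None else max(1, T - 2)
    entry = rng.integers(0, span, size=n)
    rows = np.zeros((n, T), dtype=int)
    for i in range(n):
        f = entry[i]
        rows[i, f] = 1
        alive = True
        for t in range(f + 1, T):
            alive = alive and (rng.random() < phi[t - 1])
            if not alive:
                break
            if rng.random() < p[t]:
                rows[i, t] = 1
    return rows[rows.any(axis=1)]
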