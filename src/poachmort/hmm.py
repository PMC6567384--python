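"""Nine-state / eleven-event hidden-Markov core of the multievent model.

Latent states (row/column order used throughout):

====  ============  =====================================================
idx   name          meaning
====  ============  =====================================================
0     A_GPS         alive, working GPS collar
1     A_GPS_OFF     alive, GPS collar no longer transmitting
2     A_COLLAR      alive, optical collar (no GPS)
3     A_TAGS        alive, ear tags only
4     ND_POACH_GPS  newly dead (this interval), poached, working GPS
5     ND_POACH_MARK newly dead, poached, other marks
6     ND_OTHER_GPS  newly dead, other cause, working GPS
7     ND_OTHER_MARK newly dead, other cause, other marks
8     DEAD          long dead (absorbing, never observed again)
====  ============  =====================================================

One annual transition decomposes as mark dynamics first (GPS signal loss
and collar drop-off), then survival/cause-specific mortality; an animal
dying in the interval carries the mark group it holds *after* the mark
step into its newly-dead state.  Newly-dead states emit the recovery
events of their interval and then collapse into the absorbing state.

The likelihood of an encounter history is the standard forward recursion
over these matrices, conditioned on the release (the marking occasion
contributes probability one, or the initial mark-type proportion when
initial states are estimated).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .events import EncounterHistory
from .structures import ModelStructure, ParameterIndex, ParameterSet

N_STATES = 9
N_EVENTS = 11

(A_GPS, A_GPS_OFF, A_COLLAR, A_TAGS,
 ND_POACH_GPS, ND_POACH_MARK, ND_OTHER_GPS, ND_OTHER_MARK, DEAD) = range(9)

ALIVE_STATES = (A_GPS, A_GPS_OFF, A_COLLAR, A_TAGS)
NEWLY_DEAD_STATES = (ND_POACH_GPS, ND_POACH_MARK, ND_OTHER_GPS, ND_OTHER_MARK)

#: release event code -> initial latent state
RELEASE_STATE = {1: A_GPS, 2: A_COLLAR, 3: A_TAGS}
#: release event code -> index into the initial mark-proportion vector
RELEASE_MARK_INDEX = {1: 0, 2: 1, 3: 2}


def build_mark_kernel(params: ParameterSet, deployment_age: int) -> np.ndarray:
    """4x4 transition kernel over the alive-mark states for one interval.

    ``deployment_age`` is the number of years since collar deployment
    (1 for the first interval after marking); signal loss uses two
    deployment-age classes (first year vs later).
    """
    lam = float(params.lam[0] if deployment_age <= 1 else params.lam[1])
    d = float(params.dropoff)
    K = np.zeros((4, 4))
    K[A_GPS, A_GPS] = (1 - lam) * (1 - d)
    K[A_GPS, A_GPS_OFF] = lam * (1 - d)
    K[A_GPS, A_TAGS] = d
    K[A_GPS_OFF, A_GPS_OFF] = 1 - d
    K[A_GPS_OFF, A_TAGS] = d
    K[A_COLLAR, A_COLLAR] = 1.0
    K[A_TAGS, A_TAGS] = 1.0
    return K


def build_transition(params: ParameterSet, age_class: int, deployment_age: int) -> np.ndarray:
    """9x9 one-interval transition matrix for a given age class.

    Mark kernel first, then mortality: from each post-kernel mark state k
    the animal survives in k with probability phi, or moves to the
    newly-dead state matching its cause of death and post-kernel mark
    group (working GPS vs anything else).
    """
    K = build_mark_kernel(params, deployment_age)
    mp, mo = (float(x) for x in params.m[age_class])
    phi = 1.0 - mp - mo
    T = np.zeros((N_STATES, N_STATES))
    for i in ALIVE_STATES:
        for k in ALIVE_STATES:
            pk = K[i, k]
            if pk == 0.0:
                continue
            T[i, k] += pk * phi
            if k == A_GPS:
                T[i, ND_POACH_GPS] += pk * mp
                T[i, ND_OTHER_GPS] += pk * mo
            else:
                T[i, ND_POACH_MARK] += pk * mp
                T[i, ND_OTHER_MARK] += pk * mo
    for s in NEWLY_DEAD_STATES:
        T[s, DEAD] = 1.0
    T[DEAD, DEAD] = 1.0
    return T


def build_event_matrix(params: ParameterSet, occasion: int) -> np.ndarray:
    """9x11 emission matrix P(event | state) at one occasion."""
    pc, pt = (float(x) for x in params.resight[occasion])
    r = float(params.recovery[occasion])
    rg = r if params.r_gps is None else float(params.r_gps)
    d = float(params.delta)
    B = np.zeros((N_STATES, N_EVENTS))
    B[A_GPS, 1] = 1.0
    B[A_GPS_OFF, 4] = pc
    B[A_GPS_OFF, 0] = 1 - pc
    B[A_COLLAR, 2] = pc
    B[A_COLLAR, 0] = 1 - pc
    B[A_TAGS, 3] = pt
    B[A_TAGS, 0] = 1 - pt
    B[ND_POACH_GPS, 5] = rg * d
    B[ND_POACH_GPS, 9] = rg * (1 - d)
    B[ND_POACH_GPS, 0] = 1 - rg
    B[ND_POACH_MARK, 6] = r * d
    B[ND_POACH_MARK, 10] = r * (1 - d)
    B[ND_POACH_MARK, 0] = 1 - r
    B[ND_OTHER_GPS, 7] = rg * d
    B[ND_OTHER_GPS, 9] = rg * (1 - d)
    B[ND_OTHER_GPS, 0] = 1 - rg
    B[ND_OTHER_MARK, 8] = r * d
    B[ND_OTHER_MARK, 10] = r * (1 - d)
    B[ND_OTHER_MARK, 0] = 1 - r
    B[DEAD, 0] = 1.0
    return B


def history_loglik(
    events: Sequence[int] | np.ndarray,
    age_at_marking: int,
    params: ParameterSet,
    marking_occasion: int | None = None,
) -> float:
    """Forward-algorithm log-likelihood of one history, conditional on release.

    Scaled at each step; a structurally impossible history returns -inf.
    The age class advances by one year per occasion (the class of the age
    at the start of each interval governs that interval's mortality) and
    the collar deployment age is tracked from the marking occasion.
    """
    ev = np.asarray(events, dtype=int)
    T = ev.size
    if marking_occasion is None:
        nz = np.flatnonzero(ev)
        if nz.size == 0:
            raise ValueError("history has no events")
        f = int(nz[0])
    else:
        f = int(marking_occasion)
    state0 = RELEASE_STATE[int(ev[f])]
    alpha = np.zeros(N_STATES)
    alpha[state0] = 1.0
    ll = 0.0
    for t in range(f + 1, T):
        age = age_at_marking + (t - 1 - f)
        Tm = build_transition(params, params.partition.class_of(age), t - f)
        B = build_event_matrix(params, t)
        alpha = (alpha @ Tm) * B[:, ev[t]]
        s = alpha.sum()
        if s <= 0.0:
            return -np.inf
        ll += np.log(s)
        alpha /= s
    return ll


class MultieventLikelihood:
    """Vectorized dataset log-likelihood for one candidate structure.

    Individuals differ only through their marking occasion, age at marking
    and initial mark, so per-interval transition matrices are shared
    across a small (age class x deployment class) grid and gathered per
    individual; the forward pass runs over all individuals at once.
    """

    def __init__(
        self,
        histories: Sequence[EncounterHistory],
        structure: ModelStructure,
        n_occasions: int | None = None,
    ):
        if not histories:
            raise ValueError("need at least one history")
        T = n_occasions if n_occasions is not None else histories[0].n_occasions
        if any(h.n_occasions != T for h in histories):
            raise ValueError("all histories must span the same occasions")
        self.structure = structure
        self.n_occasions = T
        self.index = ParameterIndex(structure, T)
        self.partition = structure.partition
        n = len(histories)
        self.ids = [h.id for h in histories]
        self.ev = np.stack([h.events for h in histories])
        self.f = np.array([h.marking_occasion for h in histories])
        self.age0 = np.array([h.age_at_marking for h in histories])
        self.init_state = np.array([RELEASE_STATE[int(h.events[f])] for h, f in zip(histories, self.f)])
        self.init_mark = np.array([RELEASE_MARK_INDEX[int(h.events[f])] for h, f in zip(histories, self.f)])
        # per (individual, occasion) age-class and deployment-class indices
        # for the interval ending at that occasion
        self.active = np.zeros((n, T), dtype=bool)
        self.ac = np.zeros((n, T), dtype=int)
        self.dc = np.zeros((n, T), dtype=int)
        for i in range(n):
            for t in range(self.f[i] + 1, T):
                self.active[i, t] = True
                self.ac[i, t] = self.partition.class_of(int(self.age0[i] + t - 1 - self.f[i]))
                self.dc[i, t] = 0 if t - self.f[i] == 1 else 1
        # individuals sharing (age class, deployment class) at an occasion
        # share a transition matrix; group them once so the forward pass is
        # a handful of small matmuls per occasion
        self._groups: list[list[tuple[int, int, np.ndarray, np.ndarray]]] = [[] for _ in range(T)]
        A = self.partition.n_classes
        for t in range(1, T):
            for a in range(A):
                for d in (0, 1):
                    idx = np.flatnonzero(self.active[:, t] & (self.ac[:, t] == a) & (self.dc[:, t] == d))
                    if idx.size:
                        self._groups[t].append((a, d, idx, self.ev[idx, t]))

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def loglik_per_individual(self, theta: np.ndarray) -> np.ndarray:
        params = self.index.inflate(theta)
        A = self.partition.n_classes
        T = self.n_occasions
        n = self.n_individuals
        Tstack = np.empty((A, 2, N_STATES, N_STATES))
        for a in range(A):
            Tstack[a, 0] = build_transition(params, a, 1)
            Tstack[a, 1] = build_transition(params, a, 2)
        Bstack = np.stack([build_event_matrix(params, t) for t in range(T)])

        alpha = np.zeros((n, N_STATES))
        alpha[np.arange(n), self.init_state] = 1.0
        ll = np.zeros(n)
        dead_end = np.zeros(n, dtype=bool)
        for t in range(1, T):
            Bt = Bstack[t]
            for a_cls, d_cls, idx, evg in self._groups[t]:
                am = alpha[idx] @ Tstack[a_cls, d_cls]
                am *= Bt[:, evg].T
                s = am.sum(axis=1)
                bad = s <= 0.0
                s_safe = np.where(bad, 1.0, s)
                ll[idx] += np.log(s_safe)
                dead_end[idx] |= bad
                alpha[idx] = am / s_safe[:, None]
        ll[dead_end] = -np.inf
        if self.structure.initial_state == "estimated":
            params_pi = params.pi
            ll = ll + np.log(params_pi[self.init_mark])
        return ll

    def loglik(self, theta: np.ndarray) -> float:
        return float(self.loglik_per_individual(theta).sum())

    def nll(self, theta: np.ndarray) -> float:
        ll = self.loglik(theta)
        return np.inf if not np.isfinite(ll) else -ll

    def impossible_ids(self, theta: np.ndarray) -> list[str]:
        """Ids of individuals with zero-probability histories under theta."""
        ll = self.loglik_per_individual(theta)
        return [i for i, v in zip(self.ids, ll) if not np.isfinite(v)]


def dataset_loglik(
    histories: Sequence[EncounterHistory],
    theta: np.ndarray,
    structure: ModelStructure,
    n_occasions: int | None = None,
) -> tuple[float, float]:
    """Total log-likelihood and deviance (-2 logL) of a dataset.

    Raises with the offending individuals' ids if any history has zero
    probability under ``theta``.
    """
    lik = MultieventLikelihood(histories, structure, n_occasions)
    ll = lik.loglik(theta)
    if not np.isfinite(ll):
        raise ValueError(f"zero-probability histories: {lik.impossible_ids(theta)}")
    return ll, -2.0 * ll
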