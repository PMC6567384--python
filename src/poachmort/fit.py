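"""Maximum-likelihood fitting, AICc, and interval estimation.

The free vector is maximized with L-BFGS-B inside a generous link-scale box
(multievent likelihoods are multimodal, so several random starts plus the
null start are tried and the best optimum kept).  Standard errors come from
the inverse of the observed information on the link scale; real-scale
estimates and Wald intervals are obtained by the delta method through the
link functions.  The identifiable-parameter count is the numerical rank of
the observed information, mirroring how multievent software reports ``np``
for models whose nominal parameter count exceeds what the data can
separate.

The effective sample size entering the AICc correction is the total number
of non-zero event codes in the dataset (releases, resightings and
recoveries all contribute one observation each).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from statsmodels.tools.numdiff import approx_hess2

from .events import EncounterHistory
from .hmm import MultieventLikelihood
from .structures import LINK_BOUND, ModelStructure, ParameterIndex, ParameterSet

#: singular values of the observed information below this fraction of the
#: largest are treated as non-identifiable directions
RANK_THRESHOLD = 1e-6
#: link-scale coordinates within this distance of the optimizer box are
#: reported as boundary estimates (no Wald interval)
BOUNDARY_MARGIN = 1.0


def effective_sample_size(histories: Sequence[EncounterHistory]) -> int:
    """Total number of non-zero event codes (releases, resights, recoveries)."""
    return int(sum(np.count_nonzero(h.events) for h in histories))


def compute_aicc(deviance: float, n_params: int, ess: int) -> float:
    """AICc = deviance + 2 np + 2 np (np + 1) / (ess - np - 1)."""
    if ess <= n_params + 1:
        raise ValueError(f"effective sample size {ess} must exceed np + 1 = {n_params + 1}")
    return float(deviance + 2 * n_params + 2 * n_params * (n_params + 1) / (ess - n_params - 1))


_LINKS = {
    "logit": (lambda p: logit(p), lambda x: expit(x)),
    "log": (np.log, np.exp),
    "identity": (lambda x: x, lambda x: x),
}


def wald_interval(estimate: float, se_link: float, link: str = "logit") -> tuple[float, float]:
    """95% Wald interval built on the link scale and back-transformed.

    ``se_link`` is the standard error of the link-transformed estimate, so
    the interval respects the parameter's range (asymmetric around the
    estimate on the probability scale for the logit link).
    """
    fwd, back = _LINKS[link]
    x = fwd(estimate)
    lo, hi = back(x - 1.959963984540054 * se_link), back(x + 1.959963984540054 * se_link)
    return float(lo), float(hi)


def numerical_np(hessian: np.ndarray, rel_threshold: float = RANK_THRESHOLD) -> int:
    """Identifiable-parameter count: rank of the scaled observed information.

    Singular values below ``rel_threshold`` times the largest (on the
    information matrix scaled by its largest singular value) are treated as
    flat, non-identifiable directions; boundary parameters have vanishing
    curvature and are dropped the same way.
    """
    H = np.asarray(hessian, float)
    if H.size == 0:
        return 0
    s = np.linalg.svd(H, compute_uv=False)
    if not np.isfinite(s).all() or s.max() <= 0:
        return H.shape[0]
    return int(np.sum(s > rel_threshold * s.max()))


def _data_fingerprint(lik: MultieventLikelihood) -> str:
    hsh = hashlib.sha1()
    hsh.update(lik.ev.tobytes())
    hsh.update(lik.f.tobytes())
    hsh.update(lik.age0.tobytes())
    hsh.update(np.array([lik.n_occasions]).tobytes())
    return hsh.hexdigest()


@dataclass
class FitResult:
    """One maximized candidate model."""

    structure: ModelStructure
    index: ParameterIndex
    theta: np.ndarray
    loglik: float
    deviance: float
    n_nominal: int
    np_: int
    ess: int
    aicc: float
    vcov: np.ndarray | None
    estimates: pd.DataFrame
    converged: bool
    n_starts: int
    seed: int
    boundary: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    data_fingerprint: str = ""

    @property
    def params(self) -> ParameterSet:
        return self.index.inflate(self.theta)

    def estimate(self, name: str, level: str) -> pd.Series:
        rows = self.estimates[(self.estimates["name"] == name) & (self.estimates["level"] == level)]
        if rows.empty:
            raise KeyError(f"no estimate row ({name!r}, {level!r}) in model {self.structure.label!r}")
        return rows.iloc[0]


def _real_rows(index: ParameterIndex) -> list[tuple[str, str]]:
    """(name, level) rows of the real-scale estimates table.

    Mortality and survival are always expanded to one row per age class so
    that models with coarser mortality structures (constant poaching) align
    with finer ones when averaging.
    """
    st = index.structure
    T = index.n_occasions
    rows: list[tuple[str, str]] = []
    for lab in index.partition.labels:
        rows.append(("survival", lab))
        rows.append(("poach_mortality", lab))
        rows.append(("other_mortality", lab))
    rows += [("gps_signal_loss", "yr1"), ("gps_signal_loss", "yr2+")]
    rows.append(("dropoff", "."))
    if st.resight == "constant":
        rows.append(("resight", "."))
    elif st.resight == "by_mark":
        rows += [("resight", "collar"), ("resight", "tag")]
    elif st.resight == "by_time":
        rows += [("resight", f"t{t}") for t in range(1, T)]
    else:
        rows += [("resight", f"collar:t{t}") for t in range(1, T)]
        rows += [("resight", f"tag:t{t}") for t in range(1, T)]
    if st.recovery == "constant":
        rows.append(("recovery", "."))
    else:
        rows += [("recovery", f"t{t}") for t in range(1, T)]
    rows.append(("cause_determination", "."))
    if st.initial_state == "estimated":
        rows += [("initial_mark", "gps"), ("initial_mark", "collar"), ("initial_mark", "tags")]
    return rows


def _real_vector(index: ParameterIndex, theta: np.ndarray) -> np.ndarray:
    p = index.inflate(theta)
    st = index.structure
    T = index.n_occasions
    vals: list[float] = []
    for a in range(index.partition.n_classes):
        vals += [float(p.phi[a]), float(p.m[a, 0]), float(p.m[a, 1])]
    vals += [float(p.lam[0]), float(p.lam[1]), float(p.dropoff)]
    if st.resight == "constant":
        vals.append(float(p.resight[1, 0]))
    elif st.resight == "by_mark":
        vals += [float(p.resight[1, 0]), float(p.resight[1, 1])]
    elif st.resight == "by_time":
        vals += [float(v) for v in p.resight[1:, 0]]
    else:
        vals += [float(v) for v in p.resight[1:, 0]]
        vals += [float(v) for v in p.resight[1:, 1]]
    if st.recovery == "constant":
        vals.append(float(p.recovery[1]))
    else:
        vals += [float(v) for v in p.recovery[1:]]
    vals.append(float(p.delta))
    if st.initial_state == "estimated":
        vals += [float(x) for x in p.pi]
    return np.asarray(vals)


def real_estimates(
    index: ParameterIndex,
    theta: np.ndarray,
    vcov: np.ndarray | None,
    boundary: np.ndarray | None = None,
) -> pd.DataFrame:
    """Real-scale estimates with delta-method SEs and logit-Wald 95% CIs.

    Rows whose value sits numerically at 0 or 1 (the link box) are flagged
    as boundary estimates and reported without an interval.
    """
    rows = _real_rows(index)
    vals = _real_vector(index, theta)
    k = index.n_params
    se = np.full(len(rows), np.nan)
    if vcov is not None and np.isfinite(vcov).all():
        # central-difference Jacobian of the real vector w.r.t. theta
        J = np.zeros((len(rows), k))
        h = 1e-5
        for j in range(k):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            J[:, j] = (_real_vector(index, tp) - _real_vector(index, tm)) / (2 * h)
        var = np.einsum("ik,kl,il->i", J, vcov, J)
        se = np.sqrt(np.clip(var, 0.0, None))
    lo = np.full(len(rows), np.nan)
    hi = np.full(len(rows), np.nan)
    at_bound = (vals < 1e-6) | (vals > 1 - 1e-6)
    for i, v in enumerate(vals):
        if at_bound[i] or not np.isfinite(se[i]) or se[i] == 0:
            if se[i] == 0 and not at_bound[i]:
                lo[i] = hi[i] = v
            continue
        se_link = se[i] / (v * (1 - v))
        lo[i], hi[i] = wald_interval(v, se_link, "logit")
    return pd.DataFrame(
        {
            "name": [r[0] for r in rows],
            "level": [r[1] for r in rows],
            "estimate": vals,
            "se": se,
            "lo": lo,
            "hi": hi,
            "boundary": at_bound,
        }
    )


def fit_model(
    histories: Sequence[EncounterHistory],
    structure: ModelStructure,
    *,
    n_occasions: int | None = None,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-10,
    start: np.ndarray | None = None,
    compute_se: bool = True,
) -> FitResult:
    """Fit one candidate model by maximum likelihood.

    ``n_starts`` random N(0,1) starting vectors are tried in addition to the
    null (all-zero) start and, when given, an explicit ``start``; the best
    optimum is kept.  With ``compute_se=False`` the Hessian, covariance and
    estimate table are skipped (used by large simulation sweeps that only
    need point estimates and deviances).
    """
    lik = MultieventLikelihood(histories, structure, n_occasions)
    k = lik.index.n_params
    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = [np.zeros(k)]
    if start is not None:
        starts.append(np.asarray(start, float))
    starts += [rng.normal(0.0, 1.0, k) for _ in range(n_starts)]

    bounds = [(-LINK_BOUND, LINK_BOUND)] * k
    best = None
    any_success = False
    for x0 in starts:
        res = minimize(
            lik.nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 3000, "maxfun": 120000, "ftol": tol, "gtol": 1e-7},
        )
        any_success = any_success or bool(res.success)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("no start converged to a finite likelihood")

    theta = np.asarray(best.x, float)
    ll = -float(best.fun)
    deviance = -2.0 * ll
    ess = effective_sample_size(histories)
    boundary = np.abs(theta) > LINK_BOUND - BOUNDARY_MARGIN

    vcov = None
    np_ = k
    estimates = pd.DataFrame()
    if compute_se:
        try:
            H = approx_hess2(theta, lik.nll)
            np_ = numerical_np(H)
            # pseudo-inverse: flat (non-identifiable or boundary) directions
            # contribute nothing rather than exploding the variances
            vcov = np.linalg.pinv(H)
        except Exception:
            vcov = None
        estimates = real_estimates(lik.index, theta, vcov, boundary)
    aicc = compute_aicc(deviance, np_, ess)

    return FitResult(
        structure=structure,
        index=lik.index,
        theta=theta,
        loglik=ll,
        deviance=deviance,
        n_nominal=k,
        np_=np_,
        ess=ess,
        aicc=aicc,
        vcov=vcov,
        estimates=estimates,
        converged=any_success,
        n_starts=len(starts),
        seed=seed,
        boundary=boundary,
        data_fingerprint=_data_fingerprint(lik),
    )
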