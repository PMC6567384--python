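"""AICc model comparison, Akaike weights, and model averaging.

Weights are computed over the *candidate* set only — the hypothesis-driven
models contrasting interactive, additive ("parallel") and constant-poaching
mortality — while structural models fitted during sequential selection
appear in the table without weights.  Averaged estimates use the
probability-scale weighted mean with the Burnham–Anderson unconditional
standard error, which adds the between-model spread to each model's
conditional variance.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fit import FitResult, wald_interval


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """w_j = exp(-delta_j / 2) / sum_k exp(-delta_k / 2)."""
    a = np.asarray(aicc_values, float)
    if a.size == 0:
        raise ValueError("need at least one AICc value")
    if not np.isfinite(a).all():
        raise ValueError("AICc values must be finite")
    d = a - a.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def build_model_table(
    fits: Mapping[str, FitResult],
    candidate_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """AICc table sorted by AICc; weights over the candidate subset only."""
    if not fits:
        raise ValueError("no fits given")
    fps = {f.data_fingerprint for f in fits.values()}
    if len(fps) > 1:
        raise ValueError("fits were not computed on identical data")
    ids = list(fits)
    cand = list(candidate_ids) if candidate_ids is not None else ids
    missing = [c for c in cand if c not in fits]
    if missing:
        raise ValueError(f"candidate ids not among fits: {missing}")
    aicc = np.array([fits[i].aicc for i in ids])
    delta = aicc - aicc.min()
    w_cand = akaike_weights([fits[c].aicc for c in cand])
    weights = {c: w for c, w in zip(cand, w_cand)}
    rows = []
    for i, mid in enumerate(ids):
        f = fits[mid]
        st = f.structure
        rows.append(
            {
                "model": mid,
                "sex": st.sex,
                "mortality": st.mortality,
                "ages": st.ages,
                "resight": st.resight,
                "recovery": st.recovery,
                "np": f.np_,
                "deviance": f.deviance,
                "aicc": f.aicc,
                "delta_aicc": delta[i],
                "weight": weights.get(mid, np.nan),
                "hypothesis": st.label,
            }
        )
    return pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)


def model_average(
    fits: Sequence[FitResult],
    weights: Sequence[float] | None = None,
    parameters: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Model-averaged real-scale estimates with unconditional SEs.

    ``weights`` default to the Akaike weights of the given fits.  Averaging
    requires each (name, level) row in every model's estimate table; the
    expansion of mortality to one row per age class makes the three
    hypothesis structures line up.  The 95% CI is a logit-scale Wald
    interval around the averaged value using the unconditional SE.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to average")
    if weights is None:
        w = akaike_weights([f.aicc for f in fits])
    else:
        w = np.asarray(weights, float)
        if w.shape != (len(fits),):
            raise ValueError("one weight per fit required")
        w = w / w.sum()
    if parameters is None:
        first = fits[0].estimates
        parameters = list(zip(first["name"], first["level"]))
    rows = []
    for name, level in parameters:
        ests, ses = [], []
        for f in fits:
            try:
                r = f.estimate(name, level)
            except KeyError as e:
                raise ValueError(str(e)) from None
            ests.append(float(r["estimate"]))
            # boundary rows carry no usable conditional variance
            ses.append(0.0 if not np.isfinite(r["se"]) else float(r["se"]))
        ests = np.asarray(ests)
        ses = np.asarray(ses)
        avg = float(np.sum(w * ests))
        se_u = float(np.sum(w * np.sqrt(ses**2 + (ests - avg) ** 2)))
        if 1e-6 < avg < 1 - 1e-6 and se_u > 0:
            lo, hi = wald_interval(avg, se_u / (avg * (1 - avg)), "logit")
        else:
            lo = hi = np.nan
        rows.append(
            {"name": name, "level": level, "estimate": avg, "se": se_u, "lo": lo, "hi": hi}
        )
    return pd.DataFrame(rows)


def relative_poaching_mortality(averaged: pd.DataFrame) -> pd.DataFrame:
    """Share of total mortality due to poaching, per age class.

    Computed from averaged poaching and other-cause mortality as
    m_poach / (m_poach + m_other); this is the dashed-line quantity of the
    mortality breakdown figure.
    """
    mp = averaged[averaged["name"] == "poach_mortality"].set_index("level")["estimate"]
    mo = averaged[averaged["name"] == "other_mortality"].set_index("level")["estimate"]
    rel = mp / (mp + mo)
    return pd.DataFrame({"level": rel.index, "relative_poaching": rel.values})
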