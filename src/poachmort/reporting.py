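"""End-to-end pipeline: GOF, sequential structure selection, hypothesis
models, averaging, and report artifacts.

The sequential protocol fits, per sex: (1) the general model under the
alternative age partitions and keeps the AICc-best partition; (2) recovery
time-dependence vs constancy; (3) the resighting-structure ladder
(mark x time, mark + time, time, mark, constant); (4) the three
mortality-hypothesis models (interactive, additive, constant poaching)
under the selected resighting/recovery structure.  Akaike weights and
model-averaged estimates are computed over the hypothesis models only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import EncounterHistory, summarize_dataset
from .fit import FitResult, fit_model
from .gof import GofResult, overall_gof
from .selection import akaike_weights, build_model_table, model_average, relative_poaching_mortality
from .structures import ModelStructure

DEFAULT_AGE_PARTITIONS = ("1,2:7,8+", "1:3,4:7,8+", "1,2:3,4:7,8+")
RESIGHT_LADDER = ("mark_plus_time", "by_time", "by_mark", "constant")

HYPOTHESIS_LABELS = {
    "interactive": "mortalities vary interactively with age",
    "additive": "mortalities vary in parallel with age",
    "constant_poach": "poaching mortality is constant",
}


def default_config() -> dict:
    return {
        "n_starts": 3,
        "seed": 0,
        "gof": True,
        "age_partitions": list(DEFAULT_AGE_PARTITIONS),
        "resight_ladder": list(RESIGHT_LADDER),
        "full_ladder": True,  # False: fit only the three hypothesis models
        "hypothesis_resight": {},  # sex -> resight structure, skips selection
        "hypothesis_recovery": {},  # sex -> recovery structure
    }


@dataclass
class SexAnalysis:
    sex: str
    fits: dict[str, FitResult]
    model_table: pd.DataFrame
    candidate_ids: list[str]
    weights: np.ndarray
    averaged: pd.DataFrame
    selected_partition: str
    selected_resight: str
    selected_recovery: str


@dataclass
class AnalysisBundle:
    summary: object
    gof: GofResult | None
    per_sex: dict[str, SexAnalysis]
    manifest: dict

    def averaged_table(self) -> pd.DataFrame:
        frames = []
        for sex, sa in self.per_sex.items():
            t = sa.averaged.copy()
            t.insert(0, "sex", sex)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for sex, sa in self.per_sex.items():
            sa.model_table.to_csv(path / f"model_table_{sex}.csv", index=False)
            sa.averaged.to_csv(path / f"averaged_estimates_{sex}.csv", index=False)
        if self.gof is not None:
            gof_rows = [
                {"name": c.name, "group": c.group, "chi2": c.chi2, "df": c.df}
                for c in self.gof.components
            ]
            pd.DataFrame(gof_rows).to_csv(path / "gof_components.csv", index=False)
        with open(path / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _fit(histories, structure, config, fits, model_id, start=None):
    fr = fit_model(
        histories,
        structure,
        n_starts=config["n_starts"],
        seed=config["seed"],
        start=start,
    )
    fits[model_id] = fr
    return fr


def run_sex_analysis(
    histories: Sequence[EncounterHistory],
    sex: str,
    config: dict,
) -> SexAnalysis:
    hs = [h for h in histories if h.sex == sex]
    if not hs:
        raise ValueError(f"no histories for sex {sex!r}")
    fits: dict[str, FitResult] = {}
    cfg = config

    if cfg.get("full_ladder", True):
        # stage 1: age partition under the general structure
        stage1 = {}
        for i, ages in enumerate(cfg["age_partitions"], start=1):
            st = ModelStructure(sex=sex, ages=ages, mortality="interactive",
                                resight="mark_by_time", recovery="by_time")
            stage1[f"{i}{sex}"] = _fit(hs, st, cfg, fits, f"{i}{sex}")
        best_ages = min(stage1.values(), key=lambda f: f.aicc).structure.ages

        # stage 2: recovery time-dependence
        base = ModelStructure(sex=sex, ages=best_ages, mortality="interactive",
                              resight="mark_by_time", recovery="constant")
        f_const = _fit(hs, base, cfg, fits, f"4{sex}")
        f_time = min(
            (f for f in stage1.values() if f.structure.ages == best_ages),
            key=lambda f: f.aicc,
        )
        best_recovery = "constant" if f_const.aicc <= f_time.aicc else "by_time"

        # stage 3: resighting ladder
        best_resight = "mark_by_time"
        best_aicc = min(f_const.aicc, f_time.aicc)
        for j, res in enumerate(cfg["resight_ladder"], start=5):
            st = ModelStructure(sex=sex, ages=best_ages, mortality="interactive",
                                resight=res, recovery=best_recovery)
            fr = _fit(hs, st, cfg, fits, f"{j}{sex}")
            if fr.aicc < best_aicc:
                best_aicc = fr.aicc
                best_resight = res
    else:
        best_ages = cfg["age_partitions"][0] if sex == "F" else cfg["age_partitions"][1]
        best_recovery = cfg.get("hypothesis_recovery", {}).get(sex, "constant")
        best_resight = cfg.get("hypothesis_resight", {}).get(sex, "by_mark")

    best_resight = cfg.get("hypothesis_resight", {}).get(sex, best_resight)
    best_recovery = cfg.get("hypothesis_recovery", {}).get(sex, best_recovery)

    # hypothesis models
    candidate_ids = []
    for mortality, mid in (("interactive", f"H1{sex}"), ("additive", f"H2{sex}"), ("constant_poach", f"H3{sex}")):
        st = ModelStructure(sex=sex, ages=best_ages, mortality=mortality,
                            resight=best_resight, recovery=best_recovery,
                            label=HYPOTHESIS_LABELS[mortality])
        _fit(hs, st, cfg, fits, mid)
        candidate_ids.append(mid)

    table = build_model_table(fits, candidate_ids)
    w = akaike_weights([fits[c].aicc for c in candidate_ids])
    averaged = model_average([fits[c] for c in candidate_ids], w)
    return SexAnalysis(
        sex=sex,
        fits=fits,
        model_table=table,
        candidate_ids=candidate_ids,
        weights=w,
        averaged=averaged,
        selected_partition=best_ages,
        selected_resight=best_resight,
        selected_recovery=best_recovery,
    )


def run_full_analysis(histories: Sequence[EncounterHistory], config: dict | None = None) -> AnalysisBundle:
    """GOF, sequential model selection and averaging for both sexes."""
    cfg = default_config()
    cfg.update(config or {})
    gof = overall_gof(histories) if cfg.get("gof", True) else None
    per_sex = {}
    for sex in sorted({h.sex for h in histories}):
        per_sex[sex] = run_sex_analysis(histories, sex, cfg)
    manifest = {
        "seed": cfg["seed"],
        "n_starts": cfg["n_starts"],
        "n_individuals": len(list(histories)),
        "selected": {
            s: {
                "partition": a.selected_partition,
                "resight": a.selected_resight,
                "recovery": a.selected_recovery,
            }
            for s, a in per_sex.items()
        },
    }
    return AnalysisBundle(
        summary=summarize_dataset(histories),
        gof=gof,
        per_sex=per_sex,
        manifest=manifest,
    )


def plot_mortality_breakdown(averaged_by_sex: Mapping[str, pd.DataFrame], path=None):
    """Stacked poaching / other-cause mortality bars per age class and sex,
    with the relative poaching share as a dashed line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(averaged_by_sex), figsize=(5 * len(averaged_by_sex), 4), squeeze=False)
    for ax, (sex, avg) in zip(axes[0], sorted(averaged_by_sex.items())):
        mp = avg[avg["name"] == "poach_mortality"].set_index("level")["estimate"]
        mo = avg[avg["name"] == "other_mortality"].set_index("level")["estimate"]
        x = np.arange(len(mp))
        ax.bar(x, mp.values, color="black", label="poaching")
        ax.bar(x, mo.values, bottom=mp.values, color="0.6", label="other causes")
        rel = mp.values / (mp.values + mo.values)
        ax2 = ax.twinx()
        ax2.plot(x, rel, "--", color="0.4", marker="o", label="relative poaching")
        ax2.set_ylim(0, 1)
        ax2.set_ylabel("relative poaching mortality")
        ax.set_xticks(x, mp.index)
        ax.set_xlabel("age class")
        ax.set_ylabel("annual mortality probability")
        ax.set_title({"M": "males", "F": "females"}.get(sex, sex))
        ax.legend(loc="upper left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
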