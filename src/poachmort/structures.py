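"""Candidate-model structures and the link-scale parameterization.

A candidate model is a declarative recipe: an age partition for mortality,
one of three mortality-effect structures, and effect structures for
resighting and recovery.  The free parameter vector ``theta`` lives on link
scales — logit for binomial probabilities, multinomial logit for the
per-age-class (poach, other, survive) triple and for the initial mark-type
proportions — so that *every* finite ``theta`` maps to a valid probability
set and unconstrained optimizers can be used directly.

Mortality structures (age partition with A classes):

``interactive``
    each cause has its own free parameter in each age class: 2A parameters.
``additive``
    the two causes vary "in parallel" with age: one age effect per class
    shared by both causes plus a single cause offset, on the multinomial
    logit scale: A + 1 parameters.
``constant_poach``
    poaching mortality is constant over age (one parameter) while
    other-cause mortality keeps a free parameter per class: 1 + A.

Resighting distinguishes two mark classes, "collar" (optical collars and
inactive GPS collars, which are detected alike) and "tag" (ear tags only),
and may vary by occasion.  Working-GPS animals are detected with certainty
and have no resighting parameter.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

MORTALITY_STRUCTURES = ("interactive", "additive", "constant_poach")
RESIGHT_STRUCTURES = ("constant", "by_mark", "by_time", "mark_plus_time", "mark_by_time")
RECOVERY_STRUCTURES = ("constant", "by_time")
INITIAL_STATE_MODES = ("estimated", "conditioned")

#: optimizer box for link-scale parameters; expit(15) ~ 1 - 3e-7, so the
#: box covers the open unit interval to well beyond estimable precision
#: while keeping structural-zero emission probabilities strictly positive.
LINK_BOUND = 15.0


def _logit(p: float | np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, float), 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


@dataclass(frozen=True)
class AgePartition:
    """Contiguous age classes covering all ages >= 1, last class open-ended.

    The string grammar is ``range(,range)*`` with ranges ``a``, ``a:b`` and
    ``a+``, e.g. ``"1,2:7,8+"`` for yearlings / prime-aged / old animals.
    """

    spec: str
    bounds: tuple[tuple[int, int | None], ...]

    @classmethod
    def parse(cls, spec: str) -> "AgePartition":
        bounds: list[tuple[int, int | None]] = []
        for part in spec.split(","):
            part = part.strip()
            if m := re.fullmatch(r"(\d+)\+", part):
                bounds.append((int(m.group(1)), None))
            elif m := re.fullmatch(r"(\d+):(\d+)", part):
                lo, hi = int(m.group(1)), int(m.group(2))
                if hi < lo:
                    raise ValueError(f"empty age range {part!r}")
                bounds.append((lo, hi))
            elif m := re.fullmatch(r"\d+", part):
                bounds.append((int(part), int(part)))
            else:
                raise ValueError(f"cannot parse age range {part!r}")
        if bounds[0][0] != 1:
            raise ValueError("age partition must start at age 1")
        for (lo1, hi1), (lo2, _) in zip(bounds, bounds[1:]):
            if hi1 is None:
                raise ValueError("open-ended range must be last")
            if lo2 != hi1 + 1:
                raise ValueError(f"gap or overlap between ages {hi1} and {lo2}")
        if bounds[-1][1] is not None:
            raise ValueError("age partition must end with an open-ended range")
        return cls(spec=spec, bounds=tuple(bounds))

    @property
    def n_classes(self) -> int:
        return len(self.bounds)

    @property
    def labels(self) -> tuple[str, ...]:
        out = []
        for lo, hi in self.bounds:
            if hi is None:
                out.append(f"{lo}+")
            elif hi == lo:
                out.append(f"{lo}")
            else:
                out.append(f"{lo}-{hi}")
        return tuple(out)

    def class_of(self, age: int) -> int:
        """0-based class index of an age (years, >= 1)."""
        if age < 1:
            raise ValueError(f"age must be >= 1, got {age}")
        for i, (lo, hi) in enumerate(self.bounds):
            if age >= lo and (hi is None or age <= hi):
                return i
        raise AssertionError("unreachable: partition covers all ages >= 1")


@dataclass(frozen=True)
class ModelStructure:
    """Declarative description of one candidate model."""

    sex: str
    ages: str = "1+"
    mortality: str = "interactive"
    resight: str = "by_mark"
    recovery: str = "constant"
    initial_state: str = "estimated"
    #: recovery probability for deaths of working-GPS animals; a failing
    #: collar is itself conspicuous, so by default such deaths are always
    #: detected.  Set to None to share the estimated recovery probability.
    r_gps: float | None = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.mortality not in MORTALITY_STRUCTURES:
            raise ValueError(f"unknown mortality structure {self.mortality!r}")
        if self.resight not in RESIGHT_STRUCTURES:
            raise ValueError(f"unknown resight structure {self.resight!r}")
        if self.recovery not in RECOVERY_STRUCTURES:
            raise ValueError(f"unknown recovery structure {self.recovery!r}")
        if self.initial_state not in INITIAL_STATE_MODES:
            raise ValueError(f"unknown initial-state mode {self.initial_state!r}")
        AgePartition.parse(self.ages)  # validate eagerly

    @property
    def partition(self) -> AgePartition:
        return AgePartition.parse(self.ages)

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "ages": self.ages,
            "mortality": self.mortality,
            "resight": self.resight,
            "recovery": self.recovery,
            "initial_state": self.initial_state,
            "r_gps": self.r_gps,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelStructure":
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        """Serialize to a YAML block, e.g. for run configs."""
        import yaml

        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ModelStructure":
        """Read a structure from YAML text or a file path."""
        import os
        import yaml

        if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
            with open(source) as fh:
                return cls.from_dict(yaml.safe_load(fh))
        return cls.from_dict(yaml.safe_load(source))


@dataclass
class ParameterSet:
    """Real-scale probabilities of the full process.

    Attributes
    ----------
    m : (A, 2) array
        Annual mortality probability by age class; columns are
        (poached, other cause).
    lam : (2,) array
        GPS signal-loss probability by collar deployment age
        (first year, second and later years).
    dropoff : float
        Annual probability that a GPS collar drops off, reverting the
        animal to ear tags only.
    resight : (T, 2) array
        Resighting probability per occasion; columns are
        (collar-like marks, ear tags only).  Entry 0 (the first occasion)
        is never used in the likelihood and is kept only for shape.
    recovery : (T,) array
        Probability that a death in the interval ending at occasion t is
        recovered and reported.
    delta : float
        Probability that a recovered carcass is assigned a known cause.
    r_gps : float or None
        Recovery probability for deaths of working-GPS animals; None means
        the estimated per-occasion recovery probability is shared.
    pi : (3,) array or None
        Initial mark-type proportions (gps, collar, tags), when estimated.
    """

    partition: AgePartition
    m: np.ndarray
    lam: np.ndarray
    dropoff: float
    resight: np.ndarray
    recovery: np.ndarray
    delta: float
    r_gps: float | None = 1.0
    pi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.m = np.atleast_2d(np.asarray(self.m, float))
        self.lam = np.asarray(self.lam, float)
        self.resight = np.atleast_2d(np.asarray(self.resight, float))
        self.recovery = np.atleast_1d(np.asarray(self.recovery, float))
        if self.pi is not None:
            self.pi = np.asarray(self.pi, float)

    @property
    def phi(self) -> np.ndarray:
        """Annual survival per age class (complement of total mortality)."""
        return 1.0 - self.m.sum(axis=1)

    @property
    def n_occasions(self) -> int:
        return int(self.resight.shape[0])

    def is_valid(self, tol: float = 1e-10) -> bool:
        def in01(x):
            x = np.asarray(x, float)
            return bool(np.all(x >= -tol) and np.all(x <= 1 + tol))

        ok = (
            in01(self.m)
            and np.all(self.m.sum(axis=1) <= 1 + tol)
            and in01(self.lam)
            and in01(self.dropoff)
            and in01(self.resight)
            and in01(self.recovery)
            and in01(self.delta)
            and (self.r_gps is None or in01(self.r_gps))
        )
        if self.pi is not None:
            ok = ok and in01(self.pi) and abs(self.pi.sum() - 1.0) < 1e-8
        return ok


@dataclass(frozen=True)
class Block:
    name: str
    labels: tuple[str, ...]
    link: str
    sl: slice


class ParameterIndex:
    """Mapping between the free link-scale vector and a ParameterSet.

    The deterministic block order is: initial mark proportions (when
    estimated), mortality, GPS signal loss, drop-off, resighting,
    recovery, cause determination.  Time levels run over occasions
    1..T-1 (occasion 0 carries releases only).
    """

    def __init__(self, structure: ModelStructure, n_occasions: int):
        if n_occasions < 2:
            raise ValueError("need at least 2 occasions")
        self.structure = structure
        self.n_occasions = int(n_occasions)
        self.partition = structure.partition
        A = self.partition.n_classes
        T = self.n_occasions
        tlabels = tuple(f"t{t}" for t in range(1, T))

        blocks: list[Block] = []
        pos = 0

        def add(name, labels, link):
            nonlocal pos
            blocks.append(Block(name, tuple(labels), link, slice(pos, pos + len(labels))))
            pos += len(labels)

        if structure.initial_state == "estimated":
            add("pi", ("gps", "collar"), "mlogit")  # reference: tags
        alab = self.partition.labels
        if structure.mortality == "interactive":
            add("mortality", [f"poach:{a}" for a in alab] + [f"other:{a}" for a in alab], "mlogit")
        elif structure.mortality == "additive":
            add("mortality", [f"age:{a}" for a in alab] + ["cause:other"], "mlogit")
        else:  # constant_poach
            add("mortality", ["poach:."] + [f"other:{a}" for a in alab], "mlogit")
        add("gps_loss", ("yr1", "yr2+"), "logit")
        add("dropoff", (".",), "logit")
        if structure.resight == "constant":
            add("resight", (".",), "logit")
        elif structure.resight == "by_mark":
            add("resight", ("collar", "tag"), "logit")
        elif structure.resight == "by_time":
            add("resight", tlabels, "logit")
        elif structure.resight == "mark_plus_time":
            add("resight", tlabels + ("tag-offset",), "logit")
        else:  # mark_by_time
            add("resight", tuple(f"collar:{t}" for t in tlabels) + tuple(f"tag:{t}" for t in tlabels), "logit")
        if structure.recovery == "constant":
            add("recovery", (".",), "logit")
        else:
            add("recovery", tlabels, "logit")
        add("delta", (".",), "logit")

        self.blocks = tuple(blocks)
        self.n_params = pos
        self._by_name = {b.name: b for b in self.blocks}

    def labels(self) -> list[str]:
        return [f"{b.name}[{lab}]" for b in self.blocks for lab in b.labels]

    def block(self, name: str) -> Block:
        return self._by_name[name]

    def take(self, theta: np.ndarray, name: str) -> np.ndarray:
        return np.asarray(theta, float)[self.block(name).sl]

    # -- inflate ---------------------------------------------------------

    @staticmethod
    def _mortality_from_eta(ep: np.ndarray, eo: np.ndarray) -> np.ndarray:
        # multinomial logit with survival as the reference category
        log_den = np.logaddexp(0.0, np.logaddexp(ep, eo))
        return np.column_stack([np.exp(ep - log_den), np.exp(eo - log_den)])

    def inflate(self, theta: np.ndarray) -> ParameterSet:
        """Map a finite link-scale vector to a valid ParameterSet."""
        theta = np.asarray(theta, float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"theta must have shape ({self.n_params},), got {theta.shape}")
        st = self.structure
        A = self.partition.n_classes
        T = self.n_occasions

        pi = None
        if st.initial_state == "estimated":
            x = self.take(theta, "pi")
            log_den = np.logaddexp(0.0, np.logaddexp(x[0], x[1]))
            pi = np.array([math.exp(x[0] - log_den), math.exp(x[1] - log_den), math.exp(-log_den)])

        x = self.take(theta, "mortality")
        if st.mortality == "interactive":
            ep, eo = x[:A], x[A:]
        elif st.mortality == "additive":
            ep, eo = x[:A], x[:A] + x[A]
        else:
            ep, eo = np.full(A, x[0]), x[1:]
        m = self._mortality_from_eta(ep, eo)

        lam = _expit(self.take(theta, "gps_loss"))
        dropoff = float(_expit(self.take(theta, "dropoff"))[0])

        x = self.take(theta, "resight")
        resight = np.empty((T, 2))
        if st.resight == "constant":
            resight[:, :] = _expit(x[0])
        elif st.resight == "by_mark":
            resight[:, 0] = _expit(x[0])
            resight[:, 1] = _expit(x[1])
        elif st.resight == "by_time":
            pt = _expit(x)
            resight[1:, 0] = pt
            resight[1:, 1] = pt
            resight[0] = resight[1]
        elif st.resight == "mark_plus_time":
            resight[1:, 0] = _expit(x[:-1])
            resight[1:, 1] = _expit(x[:-1] + x[-1])
            resight[0] = resight[1]
        else:  # mark_by_time
            resight[1:, 0] = _expit(x[: T - 1])
            resight[1:, 1] = _expit(x[T - 1 :])
            resight[0] = resight[1]

        x = self.take(theta, "recovery")
        recovery = np.empty(T)
        if st.recovery == "constant":
            recovery[:] = _expit(x[0])
        else:
            recovery[1:] = _expit(x)
            recovery[0] = recovery[1]

        delta = float(_expit(self.take(theta, "delta"))[0])
        # r_gps=None on the structure means GPS deaths share the estimated
        # recovery probability; the event matrix resolves None per occasion.
        r_gps = float(st.r_gps) if st.r_gps is not None else None

        return ParameterSet(
            partition=self.partition,
            m=m,
            lam=lam,
            dropoff=dropoff,
            resight=resight,
            recovery=recovery,
            delta=delta,
            r_gps=r_gps,
            pi=pi,
        )

    # -- deflate ---------------------------------------------------------

    def deflate(self, params: ParameterSet, atol: float = 1e-8) -> np.ndarray:
        """Exact inverse of :meth:`inflate` for conforming parameter sets.

        Probabilities at 0 or 1 are clipped to the optimizer box, so the
        round trip holds only in the interior.  Raises if the real-scale
        values cannot be produced by this structure (e.g. a non-parallel
        mortality pattern deflated under the additive structure).
        """
        st = self.structure
        A = self.partition.n_classes
        T = self.n_occasions
        theta = np.empty(self.n_params)

        if st.initial_state == "estimated":
            if params.pi is None:
                raise ValueError("structure estimates initial proportions but params.pi is None")
            p = np.clip(params.pi, 1e-12, None)
            theta[self.block("pi").sl] = [math.log(p[0] / p[2]), math.log(p[1] / p[2])]

        phi = np.clip(params.phi, 1e-12, None)
        m = np.clip(params.m, 1e-12, None)
        ep = np.log(m[:, 0] / phi)
        eo = np.log(m[:, 1] / phi)
        if st.mortality == "interactive":
            x = np.concatenate([ep, eo])
        elif st.mortality == "additive":
            gamma = eo - ep
            if np.ptp(gamma) > 1e-6:
                raise ValueError("mortality pattern is not additive on the multinomial-logit scale")
            x = np.concatenate([ep, [gamma.mean()]])
        else:
            if np.ptp(ep) > 1e-6:
                raise ValueError("poaching mortality is not constant across age classes")
            x = np.concatenate([[ep.mean()], eo])
        theta[self.block("mortality").sl] = x

        theta[self.block("gps_loss").sl] = _logit(params.lam)
        theta[self.block("dropoff").sl] = _logit(params.dropoff)

        r = params.resight
        if st.resight == "constant":
            x = np.atleast_1d(_logit(r[1:, :].mean()))
        elif st.resight == "by_mark":
            x = _logit([r[1:, 0].mean(), r[1:, 1].mean()])
        elif st.resight == "by_time":
            x = _logit(r[1:, 0])
        elif st.resight == "mark_plus_time":
            lc = _logit(r[1:, 0])
            lt = _logit(r[1:, 1])
            off = lt - lc
            if np.ptp(off) > 1e-6:
                raise ValueError("resight pattern is not additive in mark and time")
            x = np.concatenate([lc, [off.mean()]])
        else:
            x = np.concatenate([_logit(r[1:, 0]), _logit(r[1:, 1])])
        theta[self.block("resight").sl] = x

        if st.recovery == "constant":
            theta[self.block("recovery").sl] = _logit(params.recovery[1:].mean())
        else:
            theta[self.block("recovery").sl] = _logit(params.recovery[1:])
        theta[self.block("delta").sl] = _logit(params.delta)
        return np.clip(theta, -LINK_BOUND, LINK_BOUND)
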