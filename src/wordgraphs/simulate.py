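"""Synthetic transcripts and cohorts with controllable graph structure.

No public corpus of the kind of free-speech memory reports this analysis
targets exists, so the pipeline ships a generator whose dials map directly
onto the three recurrence axes the graph attributes measure:

* ``theta_new``    — probability of emitting a previously unseen word;
  drives lexical diversity (N) up;
* ``theta_persev`` — probability of re-emitting the word that followed the
  current word's previous occurrence; reproduces whole bigrams and drives
  repeated edges (RE) up;
* ``theta_return`` — probability of jumping back to a uniformly chosen
  earlier word; closes long loops and drives the largest strongly
  connected component (LSC) up;
* residual mass    — re-emits one of the few most recent words (local
  rehearsal).

Novel words come from a Zipf-distributed unbounded pool, giving a
realistic frequency spectrum without any lexicon dependency.

A cohort couples the dials to demographics: for typical (control)
subjects each dial follows the saturating-exponential maturation curve in
*education years*, so discourse structure matures with schooling; for
psychosis-like subjects the dials stay at the child-like level regardless
of age or education. Education itself is coupled to age (schooling starts
at six) with group-specific school-dropout rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import Group, Sex, Transcript
from .maturation import BinnedSeries, bin_series, model_f

__all__ = [
    "GeneratorParams",
    "CohortSpec",
    "generate_transcript",
    "generate_cohort",
    "generate_binned_series",
    "DEFAULT_TRAJECTORIES",
]

_RECENT_K = 5  # residual mass re-emits one of the last K tokens


@dataclass
class GeneratorParams:
    """Dials of the token-sequence generator (see module docstring)."""

    theta_new: float = 0.3
    theta_persev: float = 0.2
    theta_return: float = 0.1
    length: int = 300
    zipf_exponent: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("theta_new", "theta_persev", "theta_return"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.theta_new + self.theta_persev + self.theta_return > 1 + 1e-12:
            raise ValueError("theta_new + theta_persev + theta_return must "
                             "not exceed 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.zipf_exponent <= 1.0:
            raise ValueError("zipf_exponent must be > 1")


def _novel_word(rng: np.random.Generator, seen: set[str], a: float) -> str:
    """Draw an unseen word from the Zipf-ranked pool (advance past used ranks)."""
    rank = int(rng.zipf(a))
    word = f"w{rank}"
    while word in seen:
        rank += 1
        word = f"w{rank}"
    return word


def generate_transcript(
    params: GeneratorParams,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Emit ``params.length`` tokens by the novelty/perseveration/return mixture.

    Deterministic given the seed (or a supplied generator). The first two
    tokens seed the process with a novel bigram, after which each step
    draws one branch of the mixture; branches that are impossible at the
    current state (no previous occurrence to persevere from, nothing to
    return to) fall back to the most recent alternative.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    a = params.zipf_exponent
    seq: list[str] = []
    seen: set[str] = set()
    positions: dict[str, list[int]] = {}

    def emit(word: str) -> None:
        positions.setdefault(word, []).append(len(seq))
        seq.append(word)
        seen.add(word)

    while len(seq) < params.length:
        if len(seq) < 2:
            emit(_novel_word(rng, seen, a))
            continue
        u = rng.random()
        if u < params.theta_new:
            emit(_novel_word(rng, seen, a))
        elif u < params.theta_new + params.theta_persev:
            # replay the successor of the current word's previous occurrence
            cur = seq[-1]
            occ = positions[cur]
            prev = occ[-2] if len(occ) >= 2 else None
            if prev is not None and prev + 1 < len(seq):
                emit(seq[prev + 1])
            else:
                emit(seq[-2])  # no history yet: bounce to the previous word
        elif u < params.theta_new + params.theta_persev + params.theta_return:
            emit(str(rng.choice(sorted(seen))))
        else:
            k = min(_RECENT_K, len(seq))
            emit(seq[-1 - int(rng.integers(k))])
    return seq


#: control-group maturation curves (f0, f_inf, T in education years) for each
#: generator dial; chosen so N/LSC/ASP rise and RE falls with schooling, with
#: fast early dynamics for novelty/perseveration and slow dynamics for return,
#: mirroring the qualitative ordering of characteristic times the attributes
#: show in typical development
DEFAULT_TRAJECTORIES: dict[str, tuple[float, float, float]] = {
    "theta_new": (0.15, 0.55, 2.0),
    "theta_persev": (0.50, 0.08, 1.5),
    "theta_return": (0.04, 0.22, 9.0),
}


@dataclass
class CohortSpec:
    """Cohort-level design of the synthetic study population."""

    n_control: int = 135
    n_psychosis: int = 65
    age_range: tuple[float, float] = (2.0, 58.0)
    trajectory_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORIES))
    dropout_prob_control: float = 0.28
    dropout_prob_psychosis: float = 0.62
    noise_sd: float = 0.02
    length: int = 300
    zipf_exponent: float = 1.5
    schooling_start: float = 6.0
    max_education: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_psychosis < 1:
            raise ValueError("both groups must be non-empty")
        if not 0 <= self.dropout_prob_control <= 1:
            raise ValueError("dropout_prob_control must be in [0, 1]")
        if not 0 <= self.dropout_prob_psychosis <= 1:
            raise ValueError("dropout_prob_psychosis must be in [0, 1]")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise ValueError("invalid age_range")
        missing = set(DEFAULT_TRAJECTORIES) - set(self.trajectory_params)
        if missing:
            raise ValueError(f"trajectory_params missing dials: {missing}")


def _thetas_at(spec: CohortSpec, education: float, flat: bool,
               rng: np.random.Generator) -> dict[str, float]:
    """Dial values for one subject: maturation curve (controls) or flat child
    level (psychosis-like), plus Gaussian jitter, renormalized into a valid
    mixture."""
    out = {}
    for name, (f0, f_inf, T) in spec.trajectory_params.items():
        base = f0 if flat else model_f(education, f0, f_inf, T)
        out[name] = float(np.clip(base + rng.normal(0.0, spec.noise_sd),
                                  0.0, 1.0))
    total = sum(out.values())
    if total > 1.0:
        out = {k: v / total for k, v in out.items()}
    return out


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[Transcript], pd.DataFrame]:
    """Draw a full synthetic cohort: transcripts plus metadata table.

    Ages are uniform over ``age_range``. Education is age minus the
    schooling start (floored at 0, capped at ``max_education``); subjects
    drawn as school dropouts have it truncated to a uniform fraction of
    that ceiling. Control dials follow the maturation curves in education
    years; psychosis-like dials stay at the child level. The metadata frame
    is in exactly the dialect :func:`wordgraphs.corpus.read_cohort` and
    :func:`wordgraphs.corpus.write_cohort` use.
    """
    rng = np.random.default_rng(spec.seed)
    transcripts: list[Transcript] = []
    rows = []
    plan = [(Group.CONTROL, spec.n_control, spec.dropout_prob_control),
            (Group.PSYCHOSIS, spec.n_psychosis, spec.dropout_prob_psychosis)]
    for group, n, p_drop in plan:
        for i in range(n):
            sid = f"{group.value[:4]}{i:04d}"
            age = float(rng.uniform(*spec.age_range))
            edu_full = float(np.clip(age - spec.schooling_start, 0.0,
                                     spec.max_education))
            dropout = bool(rng.random() < p_drop)
            if dropout and edu_full > 0:
                education = float(rng.uniform(0.0, edu_full))
            else:
                education = edu_full
            thetas = _thetas_at(spec, education, group is Group.PSYCHOSIS, rng)
            tokens = generate_transcript(
                GeneratorParams(
                    theta_new=thetas["theta_new"],
                    theta_persev=thetas["theta_persev"],
                    theta_return=thetas["theta_return"],
                    length=spec.length,
                    zipf_exponent=spec.zipf_exponent,
                ),
                rng=rng,
            )
            sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
            transcripts.append(Transcript(
                subject_id=sid, tokens=tokens, group=group,
                age_years=age, education_years=education, sex=sex,
                dropout=dropout,
            ))
            rows.append({
                "subject_id": sid, "group": group.value, "age_years": age,
                "education_years": education, "sex": sex.value,
                "income": None, "panss_negative": None, "cpz_dose": None,
                "dropout": dropout,
            })
    return transcripts, pd.DataFrame(rows)


def generate_reference_group(
    spec: CohortSpec,
    level: str,
    n: int,
    seed: int = 0,
) -> list[Transcript]:
    """Generate a maturity-matched reference group.

    ``level="child"`` puts every control dial at the start of its maturation
    curve (education 0), ``"adult"`` at saturation (``max_education``), and
    ``"psychosis"`` at the flat child-like level psychosis-like subjects
    keep. Child and psychosis groups are therefore structurally
    indistinguishable by construction, while both differ from adults — the
    contrast the group tests are expected to recover.
    """
    if level not in ("child", "adult", "psychosis"):
        raise ValueError(f"unknown level: {level!r}")
    rng = np.random.default_rng(seed)
    education = 0.0 if level != "adult" else spec.max_education
    flat = level == "psychosis"
    group = Group.PSYCHOSIS if flat else Group.CONTROL
    out = []
    for i in range(n):
        thetas = _thetas_at(spec, education, flat, rng)
        tokens = generate_transcript(
            GeneratorParams(
                theta_new=thetas["theta_new"],
                theta_persev=thetas["theta_persev"],
                theta_return=thetas["theta_return"],
                length=spec.length,
                zipf_exponent=spec.zipf_exponent,
            ),
            rng=rng,
        )
        age = 8.0 if level == "child" else 30.0
        out.append(Transcript(
            subject_id=f"{level}{i:04d}", tokens=tokens, group=group,
            age_years=age, education_years=education,
        ))
    return out


def generate_binned_series(
    f0: float,
    f_inf: float,
    T: float,
    bins: int = 20,
    per_bin: int = 10,
    noise_sd: float = 0.2,
    seed: int = 0,
    variable: str = "education_years",
) -> BinnedSeries:
    """Simulate subject values on the maturation curve and bin them.

    ``per_bin`` subjects sit at each integer year t = 0..bins-1 with value
    f(t) + N(0, noise_sd); the returned bin means therefore scatter around
    the curve with sd noise_sd/sqrt(per_bin) and the SEMs estimate exactly
    that. The direct route for parameter-recovery checks of the fitter.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if per_bin < 1 or bins < 1:
        raise ValueError("bins and per_bin must be >= 1")
    rng = np.random.default_rng(seed)
    times = np.repeat(np.arange(bins, dtype=float), per_bin)
    values = model_f(times, f0, f_inf, T) + rng.normal(0.0, noise_sd,
                                                       times.size)
    return bin_series(values, times, variable)
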