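"""Seeded generators for synthetic cohorts and expression matrices.

The cohort generator draws three latent IHC patterns (exact quotas
85/85/20 by default), marker grades from separated per-pattern
categorical distributions, histology conditional on pattern matching the
printed pattern-wise frequencies, stage/sex/age from the printed
marginals (independent of pattern, which showed no significant
association), and exponential survival with pattern-specific hazard
ratios (1 / 1.9 / 3.5 by default, calibrated so the univariate
expression-type hazard ratio lands near the printed 1.89 in expectation)
under independent uniform censoring tuned to a target censoring rate.

The expression generator draws negative-binomial counts with configured
log2 effects on the five signature genes between a "basal" and a
"classical" sample group.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .cohort import (
    CaseRecord,
    Cohort,
    Histology,
    Marker,
    MarkerStain,
    Pattern,
    Sex,
    Stage,
)
from .errors import ConfigError
from .expression import ExpressionMatrix, TransformState

import pandas as pd

_PATTERNS = (Pattern.CLASSICAL, Pattern.TRANSITIONAL, Pattern.BASAL_LIKE)

#: Per-pattern grade distributions (probabilities over grades 0..3) for
#: each marker.  Classical mass sits at high GATA6/HNF4a and absent
#: CK5/6/p63; basal-like is the mirror image; transitional is
#: intermediate.  Classical and transitional place no CK5/6 mass at
#: grade >= 2, so the basal decision rule cannot false-positive.
DEFAULT_GRADE_DISTS = {
    Pattern.CLASSICAL: {
        "CK56": (0.97, 0.03, 0.0, 0.0),
        "P63": (0.95, 0.05, 0.0, 0.0),
        "GATA6": (0.0, 0.0, 0.05, 0.95),
        "HNF4A": (0.0, 0.0, 0.10, 0.90),
    },
    Pattern.TRANSITIONAL: {
        "CK56": (0.75, 0.25, 0.0, 0.0),
        "P63": (0.15, 0.75, 0.10, 0.0),
        "GATA6": (0.0, 0.60, 0.40, 0.0),
        "HNF4A": (0.45, 0.50, 0.05, 0.0),
    },
    Pattern.BASAL_LIKE: {
        "CK56": (0.0, 0.02, 0.18, 0.80),
        "P63": (0.0, 0.05, 0.35, 0.60),
        "GATA6": (0.70, 0.30, 0.0, 0.0),
        "HNF4A": (0.80, 0.20, 0.0, 0.0),
    },
}

#: Histology given pattern, from the printed pattern-wise counts
#: (e.g. basal-like: 16/20 squamous differentiation, 4/20 poorly
#: differentiated, none glandular).
DEFAULT_HISTOLOGY_GIVEN_PATTERN = {
    Pattern.CLASSICAL: (61 / 85, 24 / 85, 0.0),
    Pattern.TRANSITIONAL: (73 / 85, 12 / 85, 0.0),
    Pattern.BASAL_LIKE: (0.0, 4 / 20, 16 / 20),
}

DEFAULT_STAGE_PROBS = (15 / 182, 23 / 182, 37 / 182, 107 / 182)
DEFAULT_STAGE_MISSING_RATE = 8 / 190
DEFAULT_MALE_PROB = 96 / 190
DEFAULT_AGE_LT70_PROB = 86 / 190


def _check_probs(probs, what: str) -> None:
    p = np.asarray(probs, dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ConfigError(f"{what} must be non-negative and sum to 1, got {probs}")


@dataclass(frozen=True)
class CohortSimConfig:
    n: int = 190
    #: exact per-pattern quotas; set to None to draw multinomially from
    #: pattern_probs instead
    quotas: tuple[int, int, int] | None = (85, 85, 20)
    pattern_probs: tuple[float, float, float] = (85 / 190, 85 / 190, 20 / 190)
    grade_dists: dict = field(default_factory=lambda: DEFAULT_GRADE_DISTS)
    histology_given_pattern: dict = field(
        default_factory=lambda: DEFAULT_HISTOLOGY_GIVEN_PATTERN)
    stage_probs: tuple[float, float, float, float] = DEFAULT_STAGE_PROBS
    stage_missing_rate: float = DEFAULT_STAGE_MISSING_RATE
    male_prob: float = DEFAULT_MALE_PROB
    age_lt70_prob: float = DEFAULT_AGE_LT70_PROB
    #: exponential baseline hazard per day (median survival ~= 400 days
    #: for the classical reference group)
    baseline_hazard: float = np.log(2) / 400.0
    hazard_ratios: tuple[float, float, float] = (1.0, 1.9, 3.5)
    censoring_rate: float = 0.4
    seed: int = 20240706

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be positive")
        if self.quotas is not None:
            if len(self.quotas) != 3 or any(q < 0 for q in self.quotas):
                raise ConfigError("quotas must be 3 non-negative counts")
            if sum(self.quotas) != self.n:
                raise ConfigError(
                    f"quotas {self.quotas} do not sum to n={self.n}")
        _check_probs(self.pattern_probs, "pattern_probs")
        for pattern in _PATTERNS:
            for marker in ("CK56", "P63", "GATA6", "HNF4A"):
                _check_probs(self.grade_dists[pattern][marker],
                             f"grade_dists[{pattern.value}][{marker}]")
            _check_probs(self.histology_given_pattern[pattern],
                         f"histology_given_pattern[{pattern.value}]")
        _check_probs(self.stage_probs, "stage_probs")
        if not (0 <= self.stage_missing_rate <= 1):
            raise ConfigError("stage_missing_rate outside [0, 1]")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if any(h <= 0 for h in self.hazard_ratios):
            raise ConfigError("hazard ratios must be positive")
        if not (0 <= self.censoring_rate < 1):
            raise ConfigError("censoring_rate outside [0, 1)")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["grade_dists"] = {
            p.value: {m: list(v) for m, v in d.items()}
            for p, d in self.grade_dists.items()
        }
        payload["histology_given_pattern"] = {
            p.value: list(v) for p, v in self.histology_given_pattern.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSimConfig":
        payload = json.loads(Path(path).read_text())
        payload["grade_dists"] = {
            Pattern(p): {m: tuple(v) for m, v in d.items()}
            for p, d in payload["grade_dists"].items()
        }
        payload["histology_given_pattern"] = {
            Pattern(p): tuple(v)
            for p, v in payload["histology_given_pattern"].items()
        }
        for key in ("quotas", "pattern_probs", "stage_probs", "hazard_ratios"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def null_cohort_config(seed: int = 20240706, n: int = 190) -> CohortSimConfig:
    """Zero-effect configuration: identical grade distributions across
    patterns and all hazard ratios 1 (latent labels carry no signal)."""
    flat = {m: (0.25, 0.25, 0.25, 0.25) for m in ("CK56", "P63", "GATA6", "HNF4A")}
    # intensity 0 <-> proportion 0 still holds per grade; distribution shared
    shared_hist = (0.7, 0.2, 0.1)
    return CohortSimConfig(
        n=n,
        quotas=None,
        grade_dists={p: dict(flat) for p in _PATTERNS},
        histology_given_pattern={p: shared_hist for p in _PATTERNS},
        hazard_ratios=(1.0, 1.0, 1.0),
        seed=seed,
    )


def _sample_stain(rng: np.random.Generator, marker: str, probs) -> MarkerStain:
    grade = int(rng.choice(4, p=np.asarray(probs, dtype=float)))
    if grade == 0:
        return MarkerStain(Marker(marker), 0, 0)
    # draw a total consistent with the grade, then split it into a valid
    # (intensity, proportion) pair uniformly
    totals = {1: (3, 4, 5), 2: (6, 7), 3: (8,)}[grade]
    total = int(rng.choice(totals))
    lo = max(1, total - 5)
    hi = min(3, total - 1)
    intensity = int(rng.integers(lo, hi + 1))
    return MarkerStain(Marker(marker), intensity, total - intensity)


def _censoring_horizon(rates: np.ndarray, weights: np.ndarray, target: float) -> float:
    """Horizon u of the Uniform(0, u) censoring law achieving the target
    expected censoring fraction against mixture-exponential event times."""
    if target <= 0:
        return np.inf

    def frac(u: float) -> float:
        lam_u = rates * u
        return float(np.sum(weights * (1 - np.exp(-lam_u)) / lam_u))

    lo, hi = 1e-9, 1e-6
    while frac(hi) > target:
        hi *= 10
        if hi > 1e12:
            break
    return brentq(lambda u: frac(u) - target, lo, hi)


def generate_cohort(config: CohortSimConfig | None = None) -> Cohort:
    """Deterministic (given seed) synthetic cohort with latent patterns."""
    config = config or CohortSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    if config.quotas is not None:
        patterns = [p for p, q in zip(_PATTERNS, config.quotas) for _ in range(q)]
        patterns = [patterns[i] for i in rng.permutation(config.n)]
    else:
        idx = rng.choice(3, size=config.n, p=np.asarray(config.pattern_probs))
        patterns = [_PATTERNS[i] for i in idx]

    rates = np.array([config.baseline_hazard * h for h in config.hazard_ratios])
    weights = (np.array(config.quotas) / config.n if config.quotas is not None
               else np.asarray(config.pattern_probs))
    horizon = _censoring_horizon(rates, weights, config.censoring_rate)

    histologies = (Histology.GLANDULAR, Histology.POR_COMP, Histology.SQ_DIFF)
    stages = (Stage.I, Stage.II, Stage.III, Stage.IV)
    cases = []
    for i, pattern in enumerate(patterns):
        stains = {
            m: _sample_stain(rng, m, config.grade_dists[pattern][m])
            for m in ("CK56", "P63", "GATA6", "HNF4A")
        }
        histology = histologies[int(rng.choice(
            3, p=np.asarray(config.histology_given_pattern[pattern])))]
        if rng.random() < config.stage_missing_rate:
            stage = Stage.UNKNOWN
        else:
            stage = stages[int(rng.choice(4, p=np.asarray(config.stage_probs)))]
        sex = Sex.M if rng.random() < config.male_prob else Sex.F
        if rng.random() < config.age_lt70_prob:
            age = int(rng.integers(40, 70))
        else:
            age = int(rng.integers(70, 88))
        rate = rates[_PATTERNS.index(pattern)]
        t_event = rng.exponential(1.0 / rate)
        t_censor = rng.uniform(0.0, horizon) if np.isfinite(horizon) else np.inf
        time = min(t_event, t_censor)
        cases.append(CaseRecord(
            case_id=f"SYN{i + 1:04d}",
            stains=stains,
            histology=histology,
            stage=stage,
            sex=sex,
            age_years=age,
            time_days=max(1.0, float(round(time))),  # day resolution -> ties
            event=bool(t_event <= t_censor),
            latent_pattern=pattern,
        ))
    return Cohort(cases=tuple(cases))


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExprSimConfig:
    n_genes: int = 200
    n_per_group: int = 50
    #: log2 mean of baseline expression drawn per gene ~ N(mean, sd)
    base_log2_mean: float = 5.0
    base_log2_sd: float = 1.5
    #: negative-binomial dispersion alpha (variance = mu + alpha mu^2)
    dispersion: float = 0.2
    #: log2 shift in the basal group for TP63/KRT5/KRT6A (+) and
    #: GATA6/HNF4A (-)
    up_effect: float = 1.0
    down_effect: float = 1.0
    seed: int = 20240706

    def validate(self) -> None:
        if self.n_genes < 5:
            raise ConfigError("need at least the 5 signature genes")
        if self.n_per_group < 2:
            raise ConfigError("group sizes must be >= 2")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")


SIGNATURE_UP = ("TP63", "KRT5", "KRT6A")
SIGNATURE_DOWN = ("GATA6", "HNF4A")


def generate_expression(config: ExprSimConfig | None = None
                        ) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Negative-binomial counts for a basal and a classical group.

    Returns the COUNTS-state matrix and a sample -> group label map
    ('basal' / 'classical').
    """
    config = config or ExprSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = list(SIGNATURE_UP + SIGNATURE_DOWN)
    genes += [f"GENE{i:04d}" for i in range(1, config.n_genes - 4)]
    samples = ([f"BAS{i:03d}" for i in range(1, config.n_per_group + 1)]
               + [f"CLA{i:03d}" for i in range(1, config.n_per_group + 1)])
    groups = {s: ("basal" if s.startswith("BAS") else "classical")
              for s in samples}

    log2_mu = rng.normal(config.base_log2_mean, config.base_log2_sd,
                         size=config.n_genes)
    shift = np.zeros(config.n_genes)
    shift[:3] = config.up_effect / 2.0
    shift[3:5] = -config.down_effect / 2.0
    mu = np.empty((config.n_genes, 2 * config.n_per_group))
    mu[:, :config.n_per_group] = 2.0 ** (log2_mu + shift)[:, None]
    mu[:, config.n_per_group:] = 2.0 ** (log2_mu - shift)[:, None]

    # gamma-Poisson mixture == negative binomial with the given dispersion
    lam = rng.gamma(shape=1.0 / config.dispersion,
                    scale=mu * config.dispersion)
    counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    return ExpressionMatrix(values=df, state=TransformState.COUNTS), groups
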