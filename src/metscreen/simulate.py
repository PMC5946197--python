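"""Synthetic cohort generation with stratum-level control.

Each sex x age-group stratum is drawn from a correlated joint distribution
whose marginal means and SDs default to the published Colombian-cohort
descriptives (:mod:`metscreen.reference`).  Traits are jointly Gaussian
(via a common correlation matrix) except triglycerides, which default to a
moment-matched log-normal margin on the same Gaussian copula — TG is
strongly right-skewed (SD/mean around 0.5-0.6) and a Gaussian truncated at
zero would visibly inflate its mean.  Draws are rejection-sampled against
per-trait bounds plus the SBP > DBP constraint.

The inter-trait correlation matrix is a documented, editable default (the
source cohort's correlation structure is not public): adiposity traits
inter-correlate positively (~0.5-0.8), HDL correlates negatively with
adiposity, pressures and lipids carry conventional physiological signs.

Seeding: a master seed expands to per-stratum streams via a CRC32 of the
stratum key, so adding or reordering strata never perturbs the draws of
the others.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    AgeGroup,
    Cohort,
    DEFAULT_AGE_GROUPS,
    Sex,
    SubjectRecord,
)
from .errors import BoundsTooTightError, SpecError
from . import reference

#: trait order used by correlation matrices and bounds
TRAITS: tuple[str, ...] = (
    "age",
    "weight",
    "height",
    "waist",
    "body_fat_pct",
    "sbp",
    "dbp",
    "triglycerides",
    "hdl",
    "ldl",
    "total_cholesterol",
    "glucose",
)

# physiologically signed pairwise correlations; unlisted pairs are 0
_DEFAULT_PAIRS: dict[tuple[str, str], float] = {
    ("age", "weight"): 0.40,
    ("age", "height"): 0.45,
    ("age", "waist"): 0.25,
    ("weight", "height"): 0.55,
    ("weight", "waist"): 0.75,
    ("weight", "body_fat_pct"): 0.55,
    ("height", "waist"): 0.30,
    ("height", "sbp"): 0.20,
    ("waist", "body_fat_pct"): 0.60,
    ("sbp", "dbp"): 0.65,
    ("sbp", "weight"): 0.30,
    ("sbp", "waist"): 0.30,
    ("dbp", "weight"): 0.20,
    ("dbp", "waist"): 0.20,
    ("triglycerides", "waist"): 0.30,
    ("triglycerides", "weight"): 0.25,
    ("triglycerides", "body_fat_pct"): 0.25,
    ("triglycerides", "hdl"): -0.35,
    ("triglycerides", "total_cholesterol"): 0.30,
    ("triglycerides", "ldl"): 0.20,
    ("triglycerides", "glucose"): 0.15,
    ("hdl", "waist"): -0.30,
    ("hdl", "weight"): -0.25,
    ("hdl", "body_fat_pct"): -0.20,
    ("hdl", "total_cholesterol"): 0.25,
    ("ldl", "total_cholesterol"): 0.85,
    ("glucose", "waist"): 0.20,
    ("glucose", "weight"): 0.15,
    ("glucose", "sbp"): 0.10,
}


def _build_default_correlation() -> np.ndarray:
    idx = {t: i for i, t in enumerate(TRAITS)}
    c = np.eye(len(TRAITS))
    for (a, b), v in _DEFAULT_PAIRS.items():
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = v
    return c


DEFAULT_CORRELATION: np.ndarray = _build_default_correlation()

#: loose validity bounds; age bounds come from the stratum's age group
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "weight": (1e-6, 250.0),
    "height": (0.5, 2.5),
    "waist": (1e-6, 200.0),
    "body_fat_pct": (1.0, 60.0),
    "sbp": (1e-6, 250.0),
    "dbp": (1e-6, 180.0),
    "triglycerides": (1e-6, 1500.0),
    "hdl": (1e-6, 150.0),
    "ldl": (1e-6, 400.0),
    "total_cholesterol": (1e-6, 500.0),
    "glucose": (1e-6, 300.0),
}

#: default marginal families; everything else is Gaussian
DEFAULT_DISTRIBUTIONS: dict[str, str] = {"triglycerides": "lognormal"}


@dataclass
class StratumSpec:
    """Generator parameters for one sex x age-group stratum."""

    sex: Sex
    age_group: AgeGroup
    n: int
    means: dict[str, float]
    sds: dict[str, float]
    correlation: np.ndarray = field(
        default_factory=lambda: DEFAULT_CORRELATION.copy()
    )
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    distributions: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DISTRIBUTIONS)
    )

    def __post_init__(self):
        missing = set(TRAITS) - set(self.means) | set(TRAITS) - set(self.sds)
        if missing:
            raise SpecError(f"means/sds missing trait(s): {sorted(missing)}")
        if any(self.sds[t] <= 0 for t in TRAITS):
            raise SpecError("all sds must be > 0")
        c = np.asarray(self.correlation, dtype=float)
        if c.shape != (len(TRAITS), len(TRAITS)):
            raise SpecError(f"correlation must be {len(TRAITS)}x{len(TRAITS)}")
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise SpecError("correlation must be symmetric with unit diagonal")
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError as exc:
            raise SpecError("correlation matrix is not positive definite") from exc
        self.correlation = c
        if self.n < 0:
            raise SpecError("n must be >= 0")
        full = dict(DEFAULT_BOUNDS)
        full["age"] = (self.age_group.lower, self.age_group.upper)
        full.update(self.bounds)
        self.bounds = full

    @property
    def key(self) -> str:
        return f"{self.sex.value}:{self.age_group.label}"

    def to_dict(self) -> dict:
        return {
            "sex": self.sex.value,
            "age_group": {
                "label": self.age_group.label,
                "lower": self.age_group.lower,
                "upper": self.age_group.upper,
            },
            "n": int(self.n),
            "means": {t: float(self.means[t]) for t in TRAITS},
            "sds": {t: float(self.sds[t]) for t in TRAITS},
            "correlation": np.asarray(self.correlation).tolist(),
            "bounds": {k: [float(a), float(b)] for k, (a, b) in self.bounds.items()},
            "distributions": dict(self.distributions),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StratumSpec":
        ag = d["age_group"]
        return cls(
            sex=Sex(d["sex"]),
            age_group=AgeGroup(ag["label"], float(ag["lower"]), float(ag["upper"])),
            n=int(d["n"]),
            means=dict(d["means"]),
            sds=dict(d["sds"]),
            correlation=np.asarray(d["correlation"], dtype=float),
            bounds={k: tuple(v) for k, v in d.get("bounds", {}).items()},
            distributions=dict(d.get("distributions", DEFAULT_DISTRIBUTIONS)),
        )


def default_stratum_specs(n_scale: float = 1.0) -> list[StratumSpec]:
    """The six published strata at their reported sizes (optionally scaled)."""
    by_label = {g.label: g for g in DEFAULT_AGE_GROUPS}
    specs = []
    for (sex, label), stats in reference.STRATA.items():
        specs.append(
            StratumSpec(
                sex=Sex(sex),
                age_group=by_label[label],
                n=max(1, round(stats["n"] * n_scale)),
                means=dict(stats["means"]),
                sds=dict(stats["sds"]),
            )
        )
    return specs


def save_specs(specs: Sequence[StratumSpec], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"strata": [s.to_dict() for s in specs]}, fh, sort_keys=False)


def load_specs(path) -> list[StratumSpec]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [StratumSpec.from_dict(d) for d in doc["strata"]]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) matching an arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


_MAX_REJECTION_ROUNDS = 100


def _truncation_adjusted_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Pre-truncation location whose [lo, hi)-truncated normal mean is ``mean``.

    Bounds that clip a non-negligible tail (e.g. age bins one SD from the
    mean) would otherwise bias the realized mean away from the target.
    """
    from scipy import stats as _st
    from scipy.optimize import brentq

    if not (lo < mean < hi):
        raise BoundsTooTightError(
            f"target mean {mean} lies outside the bounds ({lo}, {hi})"
        )

    def trunc_mean(m: float) -> float:
        a, b = (lo - m) / sd, (hi - m) / sd
        return float(_st.truncnorm.mean(a, b, loc=m, scale=sd))

    outside = _st.norm.cdf(lo, mean, sd) + _st.norm.sf(hi, mean, sd)
    if outside < 1e-4:
        return mean
    span = hi - lo if np.isfinite(hi - lo) else 10 * sd
    return float(brentq(lambda m: trunc_mean(m) - mean,
                        mean - 2 * span - 5 * sd, mean + 2 * span + 5 * sd,
                        xtol=1e-10))


def generate_stratum(spec: StratumSpec, seed) -> Cohort:
    """Draw one stratum; deterministic given (spec, seed).

    Correlated standard normals are transformed per-trait (Gaussian or
    moment-matched log-normal margins) and rejection-sampled against the
    bounds and the SBP > DBP constraint; exhausting the rejection budget
    raises :class:`BoundsTooTightError`.
    """
    from scipy import stats as _st

    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(spec.correlation)
    mu = np.array([spec.means[t] for t in TRAITS])
    sd = np.array([spec.sds[t] for t in TRAITS])
    lo = np.array([spec.bounds[t][0] for t in TRAITS])
    hi = np.array([spec.bounds[t][1] for t in TRAITS])
    lognormal = np.array(
        [spec.distributions.get(t) == "lognormal" for t in TRAITS]
    )
    ln_mu = np.zeros(len(TRAITS))
    ln_sigma = np.ones(len(TRAITS))
    loc = mu.copy()
    for i, t in enumerate(TRAITS):
        if lognormal[i]:
            ln_mu[i], ln_sigma[i] = _lognormal_params(mu[i], sd[i])
        else:
            # exact truncated-normal margin with mean matched to the target;
            # applying it through the copula (rather than rejecting draws)
            # avoids selection bias leaking into correlated traits
            loc[i] = _truncation_adjusted_loc(mu[i], sd[i], lo[i], hi[i])

    kept: list[np.ndarray] = []
    total = 0
    rounds = 0
    while total < spec.n:
        rounds += 1
        if rounds > _MAX_REJECTION_ROUNDS:
            raise BoundsTooTightError(
                f"stratum {spec.key}: bounds rejected essentially all draws"
            )
        batch = max(2 * (spec.n - total), 256)
        z = rng.standard_normal((batch, len(TRAITS))) @ L.T
        x = np.empty_like(z)
        for i in range(len(TRAITS)):
            if lognormal[i]:
                x[:, i] = np.exp(ln_mu[i] + ln_sigma[i] * z[:, i])
            else:
                a = (lo[i] - loc[i]) / sd[i]
                b = (hi[i] - loc[i]) / sd[i]
                x[:, i] = _st.truncnorm.ppf(
                    _st.norm.cdf(z[:, i]), a, b, loc=loc[i], scale=sd[i]
                )
        isbp = TRAITS.index("sbp")
        idbp = TRAITS.index("dbp")
        ok = np.all((x >= lo) & (x < hi), axis=1) & (x[:, isbp] > x[:, idbp])
        x = x[ok]
        if len(x):
            kept.append(x)
            total += len(x)
    draws = np.vstack(kept)[: spec.n]
    df = pd.DataFrame(draws, columns=list(TRAITS))
    df.insert(0, "sex", spec.sex.value)
    df.insert(
        0, "id", [f"{spec.sex.value[0]}-{spec.age_group.label}-{i:05d}"
                  for i in range(spec.n)]
    )
    df["age_group"] = spec.age_group.label
    cols = ["id", "sex"] + list(TRAITS) + ["age_group"]
    return Cohort(df[cols], provenance=f"synthetic:{spec.key}:seed={seed}")


def _stratum_seed(master_seed: int, key: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), zlib.crc32(key.encode())])


def generate_full_cohort(
    specs: Sequence[StratumSpec] | None = None, seed: int = 0
) -> Cohort:
    """Concatenate strata drawn from independent per-stratum streams."""
    if specs is None:
        specs = default_stratum_specs()
    frames = []
    for spec in specs:
        sub = generate_stratum(spec, _stratum_seed(seed, spec.key))
        frames.append(sub.data)
    if frames:
        data = pd.concat(frames, ignore_index=True)
    else:
        data = pd.DataFrame(columns=["id", "sex", *TRAITS, "age_group"])
    return Cohort(data, provenance=f"synthetic:full:seed={seed}")


@dataclass(frozen=True)
class PlantedEffectSpec:
    """Logistic label-planting: P(positive | x) = expit(slope * (x - theta)).

    ``index`` names the score column (tmi or fmi), ``theta`` the true
    cutoff in index units; an infinite slope plants a hard threshold.
    """

    index: str = "tmi"
    theta: float = 13.2
    slope: float = 10.0
    target: str = "mets"

    def __post_init__(self):
        # slope 0 is the null (labels independent of the index); negative
        # slopes would silently flip orientation, so they are rejected
        if not self.slope >= 0:
            raise SpecError("slope must be >= 0 (use np.inf for a hard threshold)")


def plant_effect(
    df: pd.DataFrame, effect: PlantedEffectSpec, seed
) -> pd.DataFrame:
    """Assign Bernoulli labels driven by a logistic in the index."""
    from scipy.special import expit

    x = df[effect.index].to_numpy(dtype=float)
    if np.isinf(effect.slope):
        p = (x >= effect.theta).astype(float)
    else:
        p = expit(effect.slope * (x - effect.theta))
    rng = np.random.default_rng(seed)
    out = df.copy()
    out[effect.target] = rng.random(len(x)) < p
    return out
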