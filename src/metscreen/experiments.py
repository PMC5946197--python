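"""Reusable simulation experiments (parameter recovery, oracle checks).

These drive both the test suite and the acceptance script, so the study
conditions (stratum, sample size, replicate count) are defined once here.
"""
from __future__ import annotations

import numpy as np

from .cohort import Sex, YOUNG_ADULTS
from .indices import add_indices
from .reference import STRATA
from .roc import build_roc, youden_optimal_cutoff
from .simulate import (
    PlantedEffectSpec,
    StratumSpec,
    generate_stratum,
    plant_effect,
)


def _women_spec(n: int) -> StratumSpec:
    stats = STRATA[("female", "young_adults")]
    return StratumSpec(
        sex=Sex.FEMALE,
        age_group=YOUNG_ADULTS,
        n=n,
        means=dict(stats["means"]),
        sds=dict(stats["sds"]),
    )


def recover_planted_cutoff(
    theta: float = 13.2,
    slope: float = 10.0,
    n: int = 2000,
    replicates: int = 200,
    seed: int = 0,
    index: str = "tmi",
) -> tuple[float, np.ndarray]:
    """Median Youden-recovered cutoff under a planted logistic effect.

    Each replicate simulates a young-adult women stratum of size ``n``
    (their published mean TMI, 14.6 kg/m^3, brackets the planted cutoff),
    plants MetS labels with success probability expit(slope*(index-theta)),
    and recovers the Youden-optimal cutoff.  Returns the median and the
    per-replicate cutoffs.
    """
    spec = _women_spec(n)
    master = np.random.SeedSequence([int(seed), 0x7EC0])
    cutoffs = np.empty(replicates)
    for i, child in enumerate(master.spawn(replicates)):
        gen_seed, label_seed = child.spawn(2)
        cohort = generate_stratum(spec, gen_seed)
        df = add_indices(cohort.data)
        df = plant_effect(
            df, PlantedEffectSpec(index=index, theta=theta, slope=slope), label_seed
        )
        curve = build_roc(
            df[index].to_numpy(dtype=float), df["mets"].to_numpy(dtype=bool)
        )
        cutoffs[i], _, _, _, _ = youden_optimal_cutoff(
            curve, scores=df[index].to_numpy(dtype=float)
        )
    return float(np.median(cutoffs)), cutoffs


def pairwise_concordance_auc(scores, labels) -> float:
    """Brute-force Mann-Whitney AUC oracle: concordant pairs plus half ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos = s[y][:, None]
    neg = s[~y][None, :]
    n_pairs = pos.shape[0] * neg.shape[1]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum()) / n_pairs)


def exhaustive_youden_scan(scores, labels) -> tuple[float, float]:
    """Oracle: maximum J over every possible ``score >= t`` rule.

    Scans all unique scores plus sentinels by direct counting; returns
    (best J, a threshold attaining it).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    uniq = np.unique(s)
    cands = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    best_j, best_t = -np.inf, np.nan
    for t in cands:
        pred = s >= t
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        j = sens + spec - 1.0
        if j > best_j + 1e-15:
            best_j, best_t = j, t
    return float(best_j), float(best_t)
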