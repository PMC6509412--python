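"""Error and uncertainty statistics for prediction/observation comparison.

Quantitative prediction error is the L2 distance between predicted and
observed composition vectors divided by sqrt(2), the maximum attainable
distance between two compositions (a species predicted extinct in fact
dominating). Qualitative error is the fraction of species miscalled
present/absent. Endpoint colony counts carry a Bayesian beta-posterior
standard deviation; competitive scores carry bootstrap standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractViolation

__all__ = [
    "MAX_L2_ERROR",
    "CommunityCase",
    "quantitative_error",
    "aggregate_errors",
    "qualitative_error_rate",
    "beta_sd",
    "competitive_score",
    "growth_score_regression",
]

#: L2 distance between (1,0,...,0) and (0,1,...,0); the normalization constant
MAX_L2_ERROR = math.sqrt(2.0)

_COMP_TOL = 1e-6


def _check_composition(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or np.any(x < -_COMP_TOL) or abs(x.sum() - 1.0) > 1e-4:
        raise ContractViolation(f"{name} must be a composition (nonnegative, sums to 1)")
    return x


def quantitative_error(predicted, observed) -> float:
    """Normalized L2 error between two compositions, in [0, 1].

    Both arguments must cover the same species in the same order. The
    maximum (error 1) occurs when a species predicted extinct dominates.
    """
    p = _check_composition(predicted, "predicted")
    o = _check_composition(observed, "observed")
    if p.shape != o.shape:
        raise ContractViolation("predicted and observed cover different species lists")
    return float(np.linalg.norm(p - o) / MAX_L2_ERROR)


@dataclass
class CommunityCase:
    """One multispecies competition to score: what was predicted, what happened.

    ``predicted_states`` lists the allowed states (survivor set, composition
    over ``species``); bistable pairwise inputs yield more than one.
    ``observed`` holds one entry per starting composition of the same
    biological replicate: (start label, endpoint survivor set, endpoint
    composition).
    """

    case_id: str
    stratum: str  # e.g. "trio", "quad"
    species: tuple
    predicted_states: list  # [(frozenset, ndarray), ...]
    observed: list  # [(label, frozenset, ndarray), ...]
    prediction_type: str = "assembly"


def _case_error(case: CommunityCase) -> tuple[float, bool]:
    """Score one case: group starts by final state, average within group,
    match each group to the predicted state with the same survivor set
    (else the best-scoring state, flagged), and take the smaller group
    error for bistable observations."""
    if not case.predicted_states or not case.observed:
        raise ContractViolation(f"case {case.case_id}: empty prediction or observation")
    groups: dict[frozenset, list[np.ndarray]] = {}
    for _label, surv, comp in case.observed:
        groups.setdefault(frozenset(surv), []).append(np.asarray(comp, dtype=float))
    matched_all = True
    errors = []
    for surv, comps in groups.items():
        mean = np.mean(comps, axis=0)
        tot = mean.sum()
        if tot <= 0:
            continue
        mean = mean / tot
        same = [c for s, c in case.predicted_states if frozenset(s) == surv]
        if same:
            err = min(quantitative_error(c, mean) for c in same)
        else:
            matched_all = False
            err = min(quantitative_error(c, mean) for _s, c in case.predicted_states)
        errors.append(err)
    if not errors:
        raise ContractViolation(f"case {case.case_id}: no usable observed group")
    return min(errors), matched_all


def aggregate_errors(cases: Sequence[CommunityCase]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a batch of cases and summarize by stratum and prediction type.

    Returns (per-case table, summary table). The summary reports the mean
    normalized error with its SEM over cases (the biological-replicate unit,
    starts having been averaged within each case) for each stratum and for
    all cases pooled ("overall").
    """
    rows = []
    for case in cases:
        err, matched = _case_error(case)
        rows.append(
            {
                "case_id": case.case_id,
                "stratum": case.stratum,
                "prediction_type": case.prediction_type,
                "error": err,
                "observed_state_matched": matched,
            }
        )
    per_case = pd.DataFrame(rows)
    summary_rows = []
    for ptype, sub in per_case.groupby("prediction_type", sort=True):
        strata = [(s, g) for s, g in sub.groupby("stratum", sort=True)]
        strata.append(("overall", sub))
        for stratum, g in strata:
            e = g["error"].to_numpy()
            summary_rows.append(
                {
                    "prediction_type": ptype,
                    "stratum": stratum,
                    "mean_error": float(e.mean()),
                    "sem": float(e.std(ddof=1) / math.sqrt(len(e))) if len(e) > 1 else 0.0,
                    "n": int(len(e)),
                }
            )
    return per_case, pd.DataFrame(summary_rows)


def qualitative_error_rate(
    predicted_states: Sequence[frozenset] | Sequence[Sequence[frozenset]],
    observed_states,
    species,
) -> float:
    """Fraction of species miscalled present/absent.

    For a single case pass lists of survivor sets; for a batch pass parallel
    sequences of per-case lists plus per-case species tuples. Multi-state
    predictions are scored against each observed state by their
    best-matching allowed state (the convention that also governs bistable
    quantitative scoring).
    """
    if predicted_states and isinstance(next(iter(predicted_states)), frozenset):
        predicted_states = [predicted_states]
        observed_states = [observed_states]
        species = [species]
    rates = []
    for preds, obss, sp in zip(predicted_states, observed_states, species):
        if not preds or not obss:
            raise ContractViolation("empty predicted or observed state list")
        n = len(sp)
        per_obs = []
        for obs in obss:
            obs = frozenset(obs)
            per_obs.append(min(len(frozenset(p) ^ obs) for p in preds) / n)
        rates.append(float(np.mean(per_obs)))
    return float(np.mean(rates))


def beta_sd(a: int, b: int) -> float:
    """Standard deviation of the Beta(a+1, b+1) posterior for a fraction.

    ``a`` is the focal species' colony count and ``b`` the summed count of
    all other species (a uniform Bayes prior adds one pseudo-count to each).
    """
    if a < 0 or b < 0 or a != int(a) or b != int(b):
        raise ContractViolation("colony counts must be nonnegative integers")
    a, b = float(a), float(b)
    return math.sqrt((a + 1.0) * (b + 1.0) / ((a + b + 2.0) ** 2 * (a + b + 3.0)))


def competitive_score(
    pair_fractions: Mapping[str, Mapping[str, Sequence[float]]],
    n_boot: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean equilibrium fraction of each species over all its pairs.

    ``pair_fractions[species][opponent]`` is the list of replicate endpoint
    fractions of ``species`` in that pair. The score averages replicates
    within each pair first, then averages over pairs. The standard error is
    the SD of ``n_boot`` bootstrap scores obtained by resampling each pair's
    replicate outcomes with replacement (seeded).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sp, pairs in pair_fractions.items():
        pair_reps = [np.asarray(v, dtype=float) for v in pairs.values() if len(v)]
        if not pair_reps:
            import warnings

            warnings.warn(f"species {sp!r} has no pair outcomes; excluded")
            continue
        score = float(np.mean([reps.mean() for reps in pair_reps]))
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = np.mean(
                [
                    reps[rng.integers(0, len(reps), len(reps))].mean()
                    for reps in pair_reps
                ]
            )
        rows.append(
            {
                "species": sp,
                "score": score,
                "bootstrap_se": float(boots.std(ddof=0)),
                "n_pairs": len(pair_reps),
                "n_replicates": int(sum(len(r) for r in pair_reps)),
            }
        )
    return pd.DataFrame(rows)


def growth_score_regression(growth_rates, scores) -> tuple[float, float]:
    """OLS slope (and its standard error) of competitive score on growth rate.

    A negative slope is the growth/competitive-ability tradeoff signature at
    low mortality; the sign flips once mortality is high enough to favor
    fast growers. Accepts parallel arrays or two mappings keyed by species.
    """
    import statsmodels.api as sm

    if isinstance(growth_rates, Mapping):
        keys = sorted(growth_rates)
        if not isinstance(scores, Mapping) or set(scores) != set(keys):
            raise ContractViolation("growth_rates and scores must cover the same species")
        x = np.array([growth_rates[k] for k in keys], dtype=float)
        y = np.array([scores[k] for k in keys], dtype=float)
    else:
        x = np.asarray(growth_rates, dtype=float)
        y = np.asarray(scores, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ContractViolation("need >= 3 paired (growth rate, score) points")
    if np.ptp(x) == 0:
        raise ContractViolation("growth rates are constant; slope undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.bse[1])
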