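"""Predict multispecies states from pairwise outcomes.

Qualitative rule: in a multispecies coculture a species survives if and
only if it coexists in pairwise coculture with every other surviving
species. A candidate survivor set S is therefore allowed when (i) every
pair inside S coexists and (ii) every species outside S is excluded by at
least one member of S on some branch -- an exclusion outcome, or the losing
side of a bistable pair. Bistable pairs can make several sets allowed.

Quantitative rule: a pair's predicted coexisting fraction carries over to
the community unchanged; for three or more coexisting species the fraction
of species i is the weighted geometric mean of its pairwise fractions,

    f_i = (prod_{j != i} f_ij ^ w_j) ^ (1 / sum_{j != i} w_j),

with weight w_j the geometric mean of j's own pairwise fractions over the
set (for a trio, w_2 = sqrt(f_21 f_23)), then normalized to sum to one.
The weight definition for sets of four or more is the natural extension of
the printed trio weights; see docs/methods.md, where it is flagged as an
extrapolation.

Two baselines: the carrying-capacity prediction assumes every species
always coexists at a fraction proportional to its monoculture density, and
the random baseline draws uniformly from the composition simplex.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractViolation, DataError
from .phase_analysis import Outcome

__all__ = [
    "PairResult",
    "pair_key",
    "allowed_survivor_sets",
    "predict_fractions",
    "carrying_capacity_prediction",
    "random_prediction",
    "pair_table_to_frame",
    "pair_table_from_frame",
]


def pair_key(a, b) -> frozenset:
    return frozenset((a, b))


@dataclass(frozen=True)
class PairResult:
    """Outcome of one unordered pair at one dilution factor.

    ``fraction_a`` is the equilibrium fraction of ``species[0]`` on the
    coexistence branch (None for exclusion/bistability).
    """

    species: tuple  # (a, b)
    category: Outcome
    fraction_a: float | None = None

    def __post_init__(self):
        if len(self.species) != 2 or self.species[0] == self.species[1]:
            raise ContractViolation("PairResult needs two distinct species")
        if self.category is Outcome.COEXISTENCE:
            if self.fraction_a is None or not (0.0 < self.fraction_a < 1.0):
                raise ContractViolation(
                    f"coexistence of {self.species} needs fraction_a in (0, 1)"
                )

    @property
    def key(self) -> frozenset:
        return pair_key(*self.species)

    def fraction_of(self, species) -> float:
        """Coexisting fraction of the named species (f_ij of the pair)."""
        if self.category is not Outcome.COEXISTENCE:
            raise ContractViolation(f"pair {self.species} has no coexistence branch")
        if species == self.species[0]:
            return float(self.fraction_a)
        if species == self.species[1]:
            return 1.0 - float(self.fraction_a)
        raise ContractViolation(f"{species!r} not in pair {self.species}")

    def coexists(self) -> bool:
        return self.category is Outcome.COEXISTENCE

    def winner(self):
        if self.category is Outcome.EXCLUSION_1:
            return self.species[0]
        if self.category is Outcome.EXCLUSION_2:
            return self.species[1]
        return None

    def can_exclude(self, loser) -> bool:
        """Does some branch of this pair eliminate ``loser``?"""
        if loser not in self.species:
            raise ContractViolation(f"{loser!r} not in pair {self.species}")
        if self.category is Outcome.BISTABILITY:
            return True  # either species loses on one branch
        w = self.winner()
        return w is not None and w != loser


def _get_pair(pairs, a, b) -> PairResult:
    try:
        return pairs[pair_key(a, b)]
    except KeyError:
        raise ContractViolation(f"pair table missing pair ({a}, {b})") from None


def allowed_survivor_sets(pairs: dict, species) -> list[frozenset]:
    """Enumerate every survivor set the assembly rules allow.

    ``pairs`` maps frozenset({a, b}) -> PairResult covering all pairs of
    ``species`` (n <= 5 in practice; enumeration over 2^n subsets is
    exhaustive, no heuristics). An empty result means the pairwise topology
    is non-transitive under the rules; a warning is emitted rather than an
    exception so callers can fall back to best-effort scoring.
    """
    species = list(species)
    for a, b in itertools.combinations(species, 2):
        _get_pair(pairs, a, b)
    allowed = []
    for size in range(len(species), 0, -1):
        for subset in itertools.combinations(species, size):
            S = frozenset(subset)
            if not all(
                _get_pair(pairs, a, b).coexists()
                for a, b in itertools.combinations(subset, 2)
            ):
                continue
            if all(
                any(_get_pair(pairs, k, s).can_exclude(k) for s in subset)
                for k in species
                if k not in S
            ):
                allowed.append(S)
    if not allowed:
        warnings.warn(
            "assembly rules allow no survivor set (non-transitive pairwise topology)"
        )
    return sorted(set(allowed), key=lambda s: (-len(s), sorted(s)))


def predict_fractions(survivors, pairs: dict, species) -> np.ndarray:
    """Predicted equilibrium composition for a given survivor set.

    Returns the composition over the full ``species`` list (zeros outside
    the survivor set). Every pair inside the set must carry a coexisting
    fraction strictly inside (0, 1); anything else means the set was not a
    valid coexisting set and is a contract violation.
    """
    species = list(species)
    S = sorted(frozenset(survivors), key=species.index)
    if not S:
        raise ContractViolation("survivor set must be nonempty")
    out = np.zeros(len(species))
    if len(S) == 1:
        out[species.index(S[0])] = 1.0
        return out
    for a, b in itertools.combinations(S, 2):
        pr = _get_pair(pairs, a, b)
        if not pr.coexists():
            raise ContractViolation(
                f"pair ({a}, {b}) does not coexist; {S} is not a valid coexisting set"
            )
    if len(S) == 2:
        a, b = S
        out[species.index(a)] = _get_pair(pairs, a, b).fraction_of(a)
        out[species.index(b)] = _get_pair(pairs, a, b).fraction_of(b)
        return out
    # weights: geometric mean of each species' pairwise fractions in the set
    w = {
        j: float(
            np.exp(
                np.mean(
                    [np.log(_get_pair(pairs, j, k).fraction_of(j)) for k in S if k != j]
                )
            )
        )
        for j in S
    }
    f = {}
    for i in S:
        ws = np.array([w[j] for j in S if j != i])
        logs = np.array([np.log(_get_pair(pairs, i, j).fraction_of(i)) for j in S if j != i])
        f[i] = float(np.exp((ws * logs).sum() / ws.sum()))
    total = sum(f.values())
    for i in S:
        out[species.index(i)] = f[i] / total
    return out


def carrying_capacity_prediction(densities) -> np.ndarray:
    """Baseline: composition proportional to monoculture endpoint densities.

    This assumes all species always coexist, each at a share set by its
    carrying capacity at the given dilution factor (0 for a species extinct
    in monoculture there).
    """
    d = np.asarray(densities, dtype=float)
    if d.ndim != 1 or np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ContractViolation("densities must be a nonnegative finite vector")
    total = d.sum()
    if total == 0:
        raise DataError("all species extinct in monoculture; no prediction possible")
    return d / total


def random_prediction(n: int, seed=None) -> np.ndarray:
    """Baseline: a uniform (flat Dirichlet) draw from the composition simplex."""
    if n < 2:
        raise ContractViolation("need n >= 2 species")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.dirichlet(np.ones(n))


# ---- CSV round-trip ----------------------------------------------------

def pair_table_to_frame(pairs_by_df: dict) -> pd.DataFrame:
    """Serialize {dilution_factor: {key: PairResult}} to a long table."""
    rows = []
    for df_, pairs in sorted(pairs_by_df.items()):
        for pr in pairs.values():
            rows.append(
                {
                    "dilution_factor": df_,
                    "species_a": pr.species[0],
                    "species_b": pr.species[1],
                    "category": pr.category.value,
                    "fraction_a": pr.fraction_a,
                }
            )
    return pd.DataFrame(rows)


def pair_table_from_frame(frame: pd.DataFrame) -> dict:
    """Inverse of :func:`pair_table_to_frame`."""
    need = {"dilution_factor", "species_a", "species_b", "category", "fraction_a"}
    if not need <= set(frame.columns):
        raise DataError(f"pair table missing columns: {sorted(need - set(frame.columns))}")
    out: dict = {}
    for _, row in frame.iterrows():
        fa = row["fraction_a"]
        pr = PairResult(
            species=(row["species_a"], row["species_b"]),
            category=Outcome(row["category"]),
            fraction_a=None if pd.isna(fa) else float(fa),
        )
        out.setdefault(row["dilution_factor"], {})[pr.key] = pr
    return out
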