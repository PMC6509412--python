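"""Infer qualitative outcomes from serial-dilution colony-count time series.

The experiment table is long-format: one row per
(condition_id, dilution_factor, replicate, starting_composition, cycle,
species) with a nonnegative integer ``colony_count``. Endpoint compositions
come from the final cycle; a species is called extinct in a condition when
its endpoint count is zero (the detection limit) or its fraction falls
below a configurable threshold (default 0.005, under one colony at the
typical ~42-colony plating). A pair is called coexisting when all starting
fractions converge on the same interior fraction, bistable when different
starts reach different survivor sets, and an exclusion when one species is
extinct from every start. A mixture of coexistence and exclusion across
starts is flagged ``non_LV`` -- it is not an allowed outcome of the LV
model and must never be coerced into one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractViolation, DataError
from .metrics import beta_sd
from .phase_analysis import Outcome

__all__ = [
    "REQUIRED_COLUMNS",
    "OutcomeCall",
    "endpoint_fractions",
    "call_pair_outcome",
    "call_community_state",
    "subway_table",
]

REQUIRED_COLUMNS = (
    "condition_id",
    "dilution_factor",
    "replicate",
    "starting_composition",
    "cycle",
    "species",
    "colony_count",
)

#: endpoint fraction below which a nonzero count is still called extinct
EXTINCTION_CALL_THRESHOLD = 0.005
#: starts whose endpoint fractions lie within this band of their mean share an attractor
CONVERGENCE_WINDOW = 0.10
#: cycles over which the per-condition convergence flag is evaluated
LAST_K_CYCLES = 3


def _validate(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise DataError(f"experiment table missing columns: {sorted(missing)}")
    counts = table["colony_count"]
    if (counts < 0).any() or not np.allclose(counts, counts.round()):
        raise DataError("colony counts must be nonnegative integers")


@dataclass
class OutcomeCall:
    """Endpoint interpretation of one condition set (a pair or community x DF).

    ``survivor_sets`` holds every distinct endpoint survivor set seen across
    starting compositions (two or more means alternative stable states).
    ``stable_fraction`` is the mean endpoint fraction of ``species[0]`` over
    converged conditions of a coexisting pair, with a beta-posterior SD from
    the pooled endpoint counts.
    """

    species: tuple
    survivor_sets: list
    category: Outcome | None = None
    stable_fraction: float | None = None
    stable_fraction_sd: float | None = None
    converged: bool = True
    non_LV: bool = False
    ambiguous: bool = False
    notes: str = ""
    per_start: dict = field(default_factory=dict)  # start label -> frozenset


def endpoint_fractions(
    table: pd.DataFrame,
    last_k_cycles: int = LAST_K_CYCLES,
    convergence_tol: float = CONVERGENCE_WINDOW,
) -> pd.DataFrame:
    """Per-condition endpoint composition estimates with beta-SD error bars.

    Returns one row per (condition, species): the final-cycle fraction, its
    beta-posterior SD (focal count vs. summed others), endpoint totals, a
    convergence flag (no species' fraction moved more than
    ``convergence_tol`` over the last ``last_k_cycles`` cycles) and a
    ``usable`` flag, False when the endpoint plating held zero colonies.
    """
    _validate(table)
    rows = []
    for cond, sub in table.groupby("condition_id", sort=True):
        cycles = np.sort(sub["cycle"].unique())
        if len(cycles) < last_k_cycles:
            raise ContractViolation(
                f"condition {cond!r} has {len(cycles)} cycles < last_k_cycles={last_k_cycles}"
            )
        last = cycles[-1]
        end = sub[sub["cycle"] == last].groupby("species")["colony_count"].sum()
        species = sorted(sub["species"].unique())
        counts = np.array([end.get(s, 0) for s in species], dtype=float)
        total = counts.sum()
        usable = total > 0

        # convergence over the trailing window
        converged = True
        if usable:
            window = []
            for c in cycles[-last_k_cycles:]:
                cyc = sub[sub["cycle"] == c].groupby("species")["colony_count"].sum()
                ctot = cyc.sum()
                if ctot > 0:
                    window.append(np.array([cyc.get(s, 0) for s in species]) / ctot)
            if len(window) >= 2:
                w = np.array(window)
                converged = bool(np.max(w.max(0) - w.min(0)) < convergence_tol)

        meta = sub.iloc[0]
        for s, c in zip(species, counts):
            rows.append(
                {
                    "condition_id": cond,
                    "dilution_factor": meta["dilution_factor"],
                    "replicate": meta["replicate"],
                    "starting_composition": meta["starting_composition"],
                    "species": s,
                    "colony_count": int(c),
                    "total_colonies": int(total),
                    "fraction": c / total if usable else np.nan,
                    "beta_sd": beta_sd(int(c), int(total - c)) if usable else np.nan,
                    "converged": converged,
                    "usable": usable,
                }
            )
    return pd.DataFrame(rows)


def _condition_survivors(
    end: pd.DataFrame, extinction_threshold: float
) -> frozenset:
    alive = end[
        (end["colony_count"] > 0) & (end["fraction"] >= extinction_threshold)
    ]["species"]
    return frozenset(alive)


def _start_profiles(
    table: pd.DataFrame, last_k_cycles: int, extinction_threshold: float
) -> dict:
    """Per starting composition: pooled (replicate-summed) endpoint survivors,
    the pooled fraction trajectory over the second half of the run (used for
    trend detection), and replicate-level survivor sets for ambiguity
    detection."""
    species = sorted(table["species"].unique())
    out = {}
    for start, sub in table.groupby("starting_composition", sort=True):
        cycles = np.sort(sub["cycle"].unique())
        trend_cycles = cycles[len(cycles) // 2 :]
        window, totals = [], []
        for c in trend_cycles:
            cyc = sub[sub["cycle"] == c].groupby("species")["colony_count"].sum()
            tot = cyc.sum()
            window.append(
                {s: cyc.get(s, 0) / tot for s in species} if tot > 0 else None
            )
            totals.append(int(tot))
        end_counts = sub[sub["cycle"] == cycles[-1]].groupby("species")[
            "colony_count"
        ].sum()
        tot = end_counts.sum()
        if tot > 0:
            surv = frozenset(
                s
                for s in species
                if end_counts.get(s, 0) > 0
                and end_counts.get(s, 0) / tot >= extinction_threshold
            )
        else:
            surv = frozenset()
        rep_sets = set()
        endcyc = sub[sub["cycle"] == cycles[-1]]
        for _rep, g in endcyc.groupby("condition_id", sort=True):
            gtot = g["colony_count"].sum()
            rep_sets.add(
                frozenset(
                    r["species"]
                    for _, r in g.iterrows()
                    if gtot > 0
                    and r["colony_count"] > 0
                    and r["colony_count"] / gtot >= extinction_threshold
                )
            )
        out[start] = {
            "survivors": surv,
            "end_counts": {s: int(end_counts.get(s, 0)) for s in species},
            "window": window,
            "window_totals": totals,
            "rep_sets": rep_sets,
        }
    return out


def _declining(profile: dict, sp) -> bool:
    """Did this species' pooled fraction fall significantly over the trend
    window? Significant means the net drop exceeds twice the multinomial
    standard error of an endpoint fraction (and at least 0.02 absolute), the
    signature of an exclusion still in progress rather than a plateau."""
    window = [w for w in profile["window"] if w is not None]
    if len(window) < 3:
        return False
    totals = [t for t, w in zip(profile["window_totals"], profile["window"]) if w]
    f0, f1 = window[0][sp], window[-1][sp]
    fbar = 0.5 * (f0 + f1)
    n = max(float(np.mean(totals)), 1.0)
    se = np.sqrt(max(fbar * (1.0 - fbar), 1e-6) / n)
    return (f0 - f1) > max(0.02, 2.0 * se)


def _is_transient(profile: dict, target: frozenset) -> bool:
    """Is this start's endpoint plausibly still en route to ``target``?

    True when every species that distinguishes its survivor set from
    ``target`` is significantly declining; divergence of starts only counts
    as bistability when it is divergence to stable states."""
    extra = profile["survivors"] - target
    return bool(extra) and all(_declining(profile, s) for s in extra)


def call_pair_outcome(
    table: pd.DataFrame,
    extinction_threshold: float = EXTINCTION_CALL_THRESHOLD,
    convergence_window: float = CONVERGENCE_WINDOW,
    last_k_cycles: int = LAST_K_CYCLES,
) -> OutcomeCall:
    """Call the outcome of one pair at one dilution factor.

    ``table`` must contain every starting composition (>= 2) and replicate
    of a single pair/DF combination; replicate plates are pooled per start
    before calling survivors. A start whose endpoint has not converged and
    whose excess species are still declining toward another start's
    survivor set is treated as a slow-exclusion transient, not as evidence
    of an alternative stable state (bistability requires divergence to
    *stable* states). Categories follow the LV taxonomy, oriented so
    EXCLUSION_1 means the alphabetically first species excludes the second.
    """
    _validate(table)
    species = tuple(sorted(table["species"].unique()))
    if len(species) != 2:
        raise ContractViolation(f"expected 2 species, found {species}")
    if table["starting_composition"].nunique() < 2:
        raise ContractViolation("need >= 2 distinct starting compositions")

    profiles = _start_profiles(table, last_k_cycles, extinction_threshold)
    ambiguous = False
    notes = []
    for start, prof in profiles.items():
        if len(prof["rep_sets"]) > 1:
            ambiguous = True
            notes.append(
                f"start {start!r}: replicates disagree "
                f"{sorted(map(sorted, prof['rep_sets']))}"
            )

    raw_sets = {p["survivors"] for p in profiles.values()}
    per_start: dict[str, frozenset] = {}
    for start, prof in profiles.items():
        surv = prof["survivors"]
        targets = sorted(
            (t for t in raw_sets if t < surv), key=len, reverse=True
        )
        resolved = surv
        for t in targets:
            if _is_transient(prof, t):
                resolved = t
                notes.append(
                    f"start {start!r}: endpoint {sorted(surv)} treated as "
                    f"transient toward {sorted(t)}"
                )
                break
        per_start[start] = resolved

    survivor_sets = sorted(set(per_start.values()), key=lambda s: sorted(s))
    call = OutcomeCall(
        species=species,
        survivor_sets=survivor_sets,
        ambiguous=ambiguous,
        per_start=per_start,
        notes="; ".join(notes),
    )

    if len(survivor_sets) == 1:
        surv = survivor_sets[0]
        if len(surv) == 0:
            call.category = Outcome.ALL_EXTINCT
        elif len(surv) == 1:
            call.category = (
                Outcome.EXCLUSION_1 if species[0] in surv else Outcome.EXCLUSION_2
            )
        elif all(
            _declining(prof, sp)
            for prof in profiles.values()
            for sp in (species[0],)
        ) or all(
            _declining(prof, sp)
            for prof in profiles.values()
            for sp in (species[1],)
        ):
            # every start shows the same species still falling: a slow
            # exclusion that has not finished, not an interior plateau
            loser = (
                species[0]
                if all(_declining(p, species[0]) for p in profiles.values())
                else species[1]
            )
            winner = species[1] if loser == species[0] else species[0]
            call.survivor_sets = [frozenset({winner})]
            call.per_start = {s: frozenset({winner}) for s in per_start}
            call.category = (
                Outcome.EXCLUSION_1 if winner == species[0] else Outcome.EXCLUSION_2
            )
            call.converged = False
            call.notes = (call.notes + "; " if call.notes else "") + (
                f"{loser} declining from every start: called slow exclusion"
            )
        else:
            # interior endpoint from every start: coexistence if the starts
            # actually converged onto a common fraction
            focal_fr = []
            a_count = b_count = 0
            converged = True
            for prof in profiles.values():
                end = prof["end_counts"]
                tot = sum(end.values())
                focal_fr.append(end[species[0]] / tot)
                a_count += end[species[0]]
                b_count += tot - end[species[0]]
                window = [w for w in prof["window"] if w is not None]
                if len(window) >= 2:
                    moved = max(
                        abs(window[-1][s] - window[0][s]) for s in species
                    )
                    converged = converged and moved < convergence_window
            fr = np.asarray(focal_fr)
            same_attractor = np.max(np.abs(fr - fr.mean())) <= convergence_window
            call.category = Outcome.COEXISTENCE
            call.converged = bool(same_attractor and converged)
            if not same_attractor:
                call.notes = (call.notes + "; " if call.notes else "") + (
                    "interior endpoints not converged across starts"
                )
            call.stable_fraction = float(fr.mean())
            call.stable_fraction_sd = beta_sd(a_count, b_count)
    else:
        sizes = {len(s) for s in survivor_sets}
        call.category = Outcome.BISTABILITY
        if sizes != {1}:
            # coexistence-vs-exclusion bistability: not an LV outcome
            call.non_LV = True
    return call


def call_community_state(
    table: pd.DataFrame,
    extinction_threshold: float = EXTINCTION_CALL_THRESHOLD,
    convergence_window: float = CONVERGENCE_WINDOW,
    last_k_cycles: int = LAST_K_CYCLES,
) -> OutcomeCall:
    """Endpoint survivor set(s) of a multispecies condition set at one DF.

    One survivor set per starting composition (replicates vote); distinct
    sets across starts are reported as multiple stable states. Non-converged
    conditions are flagged via ``converged``.
    """
    _validate(table)
    species = tuple(sorted(table["species"].unique()))
    ends = endpoint_fractions(table, last_k_cycles, convergence_window)
    usable = ends[ends["usable"]]
    per_start: dict[str, frozenset] = {}
    ambiguous = False
    for start, sub in ends.groupby("starting_composition", sort=True):
        rep_sets = {
            rep: _condition_survivors(g, extinction_threshold)
            for rep, g in sub.groupby("condition_id", sort=True)
        }
        if len(set(rep_sets.values())) > 1:
            ambiguous = True
        counts: dict[frozenset, int] = {}
        for s in rep_sets.values():
            counts[s] = counts.get(s, 0) + 1
        per_start[start] = max(counts, key=lambda s: (counts[s], len(s)))
    survivor_sets = sorted(set(per_start.values()), key=lambda s: sorted(s))
    return OutcomeCall(
        species=species,
        survivor_sets=survivor_sets,
        converged=bool(usable["converged"].all()),
        ambiguous=ambiguous,
        per_start=per_start,
    )


def subway_table(calls: dict, species) -> pd.DataFrame:
    """Flatten per-DF outcome calls into subway-map data.

    ``calls`` maps dilution factor -> OutcomeCall. Output rows are
    (dilution_factor, state_index, species, present); coexistence appears
    as several species sharing a state, bistability as state_index 0 and 1.
    """
    rows = []
    for df_ in sorted(calls):
        call = calls[df_]
        for k, surv in enumerate(call.survivor_sets):
            for s in species:
                rows.append(
                    {
                        "dilution_factor": df_,
                        "state_index": k,
                        "species": s,
                        "present": s in surv,
                    }
                )
    return pd.DataFrame(rows)
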