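"""Run configuration, the end-to-end pipeline, and text rendering.

The pipeline ties the stages together: generate a ground-truth community
(``synth``), simulate the serial-dilution design (``simulate``), infer
pairwise and community outcomes from the colony counts (``infer``), apply
the assembly rules and baselines (``predict``), and score predictions
against the observed communities (``score``). Every stage reads and writes
plain CSV/YAML artifacts in one output directory, and a manifest records
the configuration, seeds and output checksums so a run is reproducible
from its config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly_rules, metrics, outcome_inference
from .errors import ConfigError, ContractViolation, DataError
from .growth_rates import estimate_growth_rates
from .phase_analysis import Outcome
from .synthetic_data import (
    DesignSpec,
    GroundTruth,
    sample_params,
    simulate_community_experiment,
    simulate_monocultures,
    simulate_od_curves,
    simulate_pairwise_experiments,
)

__all__ = ["RunConfig", "run_pipeline", "render_subway"]

logger = logging.getLogger("dilucomp")

STAGES = ("synth", "simulate", "infer", "predict", "score")

_STRATA = {2: "pair", 3: "trio", 4: "quad", 5: "quintet"}


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    outdir: str = "runs/demo"
    seed: int = 0
    stages: tuple = STAGES
    # generator
    n_species: int = 3
    tradeoff: float = 2.5
    noise: float = 0.35
    r_range: tuple = (0.25, 1.0)
    alpha_scale: float = 0.75
    ground_truth: str | None = None  # path to an existing truth file, skips synth
    # design
    design: DesignSpec = field(default_factory=DesignSpec)
    od_noise_sd: float = 0.002
    # inference thresholds
    extinction_call: float = 0.005
    convergence_window: float = 0.10
    last_k_cycles: int = 3
    # scoring
    n_boot: int = 1000

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if self.ground_truth is not None and not Path(self.ground_truth).exists():
            raise ConfigError(f"ground_truth path does not exist: {self.ground_truth}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["r_range"] = list(self.r_range)
        d["design"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self.design).items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "design" in d:
            design_d = dict(d["design"] or {})
            dknown = {f.name for f in dataclasses.fields(DesignSpec)}
            dunknown = set(design_d) - dknown
            if dunknown:
                raise ConfigError(f"unknown design keys: {sorted(dunknown)}")
            design_d = {
                k: (tuple(v) if isinstance(v, list) else v) for k, v in design_d.items()
            }
            d["design"] = DesignSpec(**design_d)
        for key in ("stages", "r_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        try:
            return cls(**d)
        except TypeError as e:
            raise ConfigError(str(e)) from None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(d)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.6g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------- stages


def _stage_synth(config: RunConfig, outdir: Path) -> GroundTruth:
    if config.ground_truth is not None:
        truth = GroundTruth.from_yaml(config.ground_truth)
        logger.info("synth: loaded ground truth from %s", config.ground_truth)
    else:
        truth = sample_params(
            config.n_species,
            tradeoff=config.tradeoff,
            noise=config.noise,
            seed=config.seed,
            r_range=config.r_range,
            alpha_scale=config.alpha_scale,
        )
        logger.info(
            "synth: sampled %d-species community (tradeoff=%g, noise=%g)",
            config.n_species,
            config.tradeoff,
            config.noise,
        )
    truth.to_yaml(outdir / "ground_truth.yaml")
    return truth


def _stage_simulate(config: RunConfig, outdir: Path) -> None:
    truth = GroundTruth.from_yaml(outdir / "ground_truth.yaml")
    design = config.design
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(2**31, size=4)
    _write_csv(
        simulate_pairwise_experiments(truth, design, seed=int(seeds[0])),
        outdir / "experiments_pairwise.csv",
    )
    _write_csv(
        simulate_community_experiment(truth, design, seed=int(seeds[1])),
        outdir / "experiments_community.csv",
    )
    _write_csv(
        simulate_monocultures(truth, design, seed=int(seeds[2])),
        outdir / "experiments_monoculture.csv",
    )
    _write_csv(
        simulate_od_curves(truth, design, noise_sd=config.od_noise_sd, seed=int(seeds[3])),
        outdir / "od_curves.csv",
    )
    logger.info(
        "simulate: %d DFs x %d cycles, extinction threshold %g, mean colonies %s",
        len(design.dilution_factors),
        design.n_cycles,
        design.extinction_threshold,
        design.mean_colonies,
    )


def _require(outdir: Path, name: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise DataError(f"missing pipeline artifact {p}; run the earlier stages first")
    return p


def _stage_infer(config: RunConfig, outdir: Path) -> None:
    pair_df = pd.read_csv(_require(outdir, "experiments_pairwise.csv"))
    comm_df = pd.read_csv(_require(outdir, "experiments_community.csv"))
    kw = dict(
        extinction_threshold=config.extinction_call,
        convergence_window=config.convergence_window,
        last_k_cycles=config.last_k_cycles,
    )
    logger.info(
        "infer: extinction call %g, convergence window %g, last %d cycles",
        config.extinction_call,
        config.convergence_window,
        config.last_k_cycles,
    )

    _write_csv(
        outcome_inference.endpoint_fractions(
            comm_df, config.last_k_cycles, config.convergence_window
        ),
        outdir / "endpoint_fractions.csv",
    )

    pairs_by_df: dict = {}
    rows = []
    species = sorted(pair_df["species"].unique())
    for (df_,), sub_df in pair_df.groupby(["dilution_factor"]):
        for a, b in itertools.combinations(species, 2):
            sub = sub_df[sub_df["species"].isin((a, b))]
            sub = sub[sub["condition_id"].str.startswith(f"{a}-{b}|")]
            if sub.empty:
                continue
            call = outcome_inference.call_pair_outcome(sub, **kw)
            pr = assembly_rules.PairResult(
                species=call.species,
                category=call.category,
                fraction_a=call.stable_fraction
                if call.category is Outcome.COEXISTENCE
                else None,
            )
            pairs_by_df.setdefault(df_, {})[pr.key] = pr
            rows.append(
                {
                    "dilution_factor": df_,
                    "species_a": call.species[0],
                    "species_b": call.species[1],
                    "category": call.category.value,
                    "fraction_a": call.stable_fraction,
                    "fraction_sd": call.stable_fraction_sd,
                    "converged": call.converged,
                    "non_LV": call.non_LV,
                    "ambiguous": call.ambiguous,
                    "notes": call.notes,
                }
            )
    _write_csv(pd.DataFrame(rows), outdir / "pair_outcomes.csv")

    comm_calls = {}
    state_rows = []
    comm_species = sorted(comm_df["species"].unique())
    for (df_,), sub in comm_df.groupby(["dilution_factor"]):
        call = outcome_inference.call_community_state(sub, **kw)
        comm_calls[df_] = call
        for k, surv in enumerate(call.survivor_sets):
            state_rows.append(
                {
                    "dilution_factor": df_,
                    "state_index": k,
                    "survivors": "+".join(sorted(surv)),
                    "converged": call.converged,
                    "ambiguous": call.ambiguous,
                }
            )
    _write_csv(pd.DataFrame(state_rows), outdir / "community_states.csv")
    _write_csv(
        outcome_inference.subway_table(comm_calls, comm_species),
        outdir / "subway_community.csv",
    )


def _stage_predict(config: RunConfig, outdir: Path) -> None:
    truth = GroundTruth.from_yaml(outdir / "ground_truth.yaml")
    species = list(truth.params.species_ids)
    pairs_by_df = assembly_rules.pair_table_from_frame(
        pd.read_csv(_require(outdir, "pair_outcomes.csv"))
    )
    mono = pd.read_csv(_require(outdir, "experiments_monoculture.csv"))
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for df_, pairs in sorted(pairs_by_df.items()):
        # assembly rules
        try:
            allowed = assembly_rules.allowed_survivor_sets(pairs, species)
        except ContractViolation as e:
            logger.warning("predict: DF %g skipped (%s)", df_, e)
            allowed = []
        for k, S in enumerate(allowed):
            comp = assembly_rules.predict_fractions(S, pairs, species)
            rows += _prediction_rows(df_, "assembly", k, species, S, comp)
        # carrying-capacity baseline
        end = mono[(mono["dilution_factor"] == df_)]
        last = end[end["cycle"] == end["cycle"].max()]
        dens = np.array(
            [
                last[last["species"] == s]["abs_density"].mean() if s in set(last["species"]) else 0.0
                for s in species
            ]
        )
        if dens.sum() > 0:
            comp = assembly_rules.carrying_capacity_prediction(dens)
            rows += _prediction_rows(
                df_, "carrying-capacity", 0, species, frozenset(
                    s for s, d in zip(species, dens) if d > 0
                ), comp
            )
        # random baseline
        comp = assembly_rules.random_prediction(len(species), rng)
        rows += _prediction_rows(df_, "random", 0, species, frozenset(species), comp)
    _write_csv(pd.DataFrame(rows), outdir / "predictions.csv")


def _prediction_rows(df_, ptype, state_index, species, survivors, comp):
    return [
        {
            "dilution_factor": df_,
            "prediction_type": ptype,
            "state_index": state_index,
            "species": s,
            "survives": s in survivors,
            "fraction": float(f),
        }
        for s, f in zip(species, comp)
    ]


def _observed_cases(endpoints: pd.DataFrame, species, extinction_call: float):
    """Yield (replicate, [(start, survivor set, composition), ...]) per DF."""
    for (df_,), sub in endpoints.groupby(["dilution_factor"]):
        by_rep: dict = {}
        for (start, rep), g in sub.groupby(["starting_composition", "replicate"]):
            g = g[g["usable"]]
            if g.empty:
                continue
            frac = np.array(
                [g[g["species"] == s]["fraction"].sum() for s in species]
            )
            count = np.array(
                [g[g["species"] == s]["colony_count"].sum() for s in species]
            )
            surv = frozenset(
                s
                for s, f, c in zip(species, frac, count)
                if c > 0 and f >= extinction_call
            )
            by_rep.setdefault(rep, []).append((start, surv, frac))
        yield df_, by_rep


def _stage_score(config: RunConfig, outdir: Path) -> None:
    species = sorted(
        pd.read_csv(_require(outdir, "experiments_community.csv"))["species"].unique()
    )
    stratum = _STRATA.get(len(species), f"{len(species)}-species")
    endpoints = pd.read_csv(_require(outdir, "endpoint_fractions.csv"))
    preds = pd.read_csv(_require(outdir, "predictions.csv"))

    cases = []
    pred_sets_by = {}
    obs_sets_by = {}
    for df_, by_rep in _observed_cases(endpoints, species, config.extinction_call):
        psub = preds[preds["dilution_factor"] == df_]
        for ptype, g in psub.groupby("prediction_type"):
            states = []
            for _k, st in g.groupby("state_index"):
                st = st.set_index("species").reindex(species)
                states.append(
                    (
                        frozenset(st.index[st["survives"].fillna(False)]),
                        st["fraction"].fillna(0.0).to_numpy(),
                    )
                )
            if not states:
                continue
            for rep, observed in by_rep.items():
                if not observed:
                    continue
                cases.append(
                    metrics.CommunityCase(
                        case_id=f"DF{df_:g}|rep{rep}",
                        stratum=stratum,
                        species=tuple(species),
                        predicted_states=states,
                        observed=observed,
                        prediction_type=ptype,
                    )
                )
                pred_sets_by.setdefault(ptype, []).append([s for s, _ in states])
                obs_sets_by.setdefault(ptype, []).append([s for _, s, _ in observed])

    if cases:
        per_case, summary = metrics.aggregate_errors(cases)
        _write_csv(per_case, outdir / "errors_per_case.csv")
        _write_csv(summary, outdir / "error_report.csv")
        qual_rows = [
            {
                "prediction_type": ptype,
                "qualitative_error_rate": metrics.qualitative_error_rate(
                    pred_sets_by[ptype],
                    obs_sets_by[ptype],
                    [tuple(species)] * len(pred_sets_by[ptype]),
                ),
                "n_cases": len(pred_sets_by[ptype]),
            }
            for ptype in sorted(pred_sets_by)
        ]
        _write_csv(pd.DataFrame(qual_rows), outdir / "qualitative_error_rates.csv")
    else:
        logger.warning("score: no scorable community cases")

    # competitive scores and the growth-rate regression
    pair_ends = outcome_inference.endpoint_fractions(
        pd.read_csv(_require(outdir, "experiments_pairwise.csv")),
        config.last_k_cycles,
        config.convergence_window,
    )
    growth = estimate_growth_rates(
        pd.read_csv(_require(outdir, "od_curves.csv")),
        stock_od=config.design.stock_od,
    )
    _write_csv(growth, outdir / "growth_rate_estimates.csv")
    rate_by_species = dict(zip(growth["species"], growth["rate"]))

    score_frames = []
    reg_rows = []
    for (df_,), sub in pair_ends[pair_ends["usable"]].groupby(["dilution_factor"]):
        pair_fr: dict = {}
        for cond, g in sub.groupby("condition_id"):
            pair_label = cond.split("|")[0]
            a, b = pair_label.split("-")
            for sp in (a, b):
                row = g[g["species"] == sp]
                if row.empty:
                    continue
                pair_fr.setdefault(sp, {}).setdefault(
                    (pair_label, int(g["replicate"].iloc[0])), []
                ).append(float(row["fraction"].iloc[0]))
        # replicate unit: mean over starts within (pair, replicate)
        collapsed = {
            sp: {}
            for sp in pair_fr
        }
        for sp, d in pair_fr.items():
            for (pair_label, rep), vals in d.items():
                collapsed[sp].setdefault(pair_label, []).append(float(np.mean(vals)))
        scores = metrics.competitive_score(
            collapsed, n_boot=config.n_boot, seed=config.seed + 2
        )
        scores.insert(0, "dilution_factor", df_)
        score_frames.append(scores)
        common = [s for s in scores["species"] if s in rate_by_species]
        if len(common) >= 3:
            sc = scores.set_index("species")
            slope, se = metrics.growth_score_regression(
                {s: rate_by_species[s] for s in common},
                {s: float(sc.loc[s, "score"]) for s in common},
            )
            reg_rows.append(
                {"dilution_factor": df_, "slope": slope, "slope_se": se, "n": len(common)}
            )
    if score_frames:
        _write_csv(pd.concat(score_frames, ignore_index=True), outdir / "competitive_scores.csv")
    if reg_rows:
        _write_csv(pd.DataFrame(reg_rows), outdir / "growth_score_regression.csv")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages and write a checksummed manifest.

    Returns the output directory. Any stage failure propagates with the
    stage named in the log; artifacts written before the failure remain.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    for stage in STAGES:
        if stage not in config.stages:
            continue
        logger.info("stage %s: start", stage)
        fn = {
            "synth": _stage_synth,
            "simulate": _stage_simulate,
            "infer": _stage_infer,
            "predict": _stage_predict,
            "score": _stage_score,
        }[stage]
        try:
            fn(config, outdir)
        except Exception:
            logger.error("stage %s: failed", stage)
            raise
        logger.info("stage %s: done", stage)

    from . import __version__

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "config": config.to_dict(),
        "files": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


# ---------------------------------------------------------------- rendering


def render_subway(subway: pd.DataFrame, species_order=None) -> str:
    """ASCII subway map: one row block per species, one column per DF.

    ``species_order`` should list species fastest grower first (the fast
    grower's line is drawn above the slow grower's). A filled circle marks
    presence in a state, a dot absence; dilution factors with two stable
    states get two stacked rows per species (split rows).
    """
    need = {"dilution_factor", "state_index", "species", "present"}
    if not need <= set(subway.columns):
        raise DataError(f"subway table missing columns: {sorted(need - set(subway.columns))}")
    dfs = sorted(subway["dilution_factor"].unique())
    species = list(species_order) if species_order else sorted(subway["species"].unique())
    n_states = {
        df_: int(subway[subway["dilution_factor"] == df_]["state_index"].max()) + 1
        for df_ in dfs
    }
    max_states = max(n_states.values())
    width = 9
    lines = ["DF".ljust(10) + "".join(f"{df_:^{width}g}" for df_ in dfs)]
    for sp in species:
        for k in range(max_states):
            cells = []
            for df_ in dfs:
                if k >= n_states[df_]:
                    cells.append(" " * width)
                    continue
                row = subway[
                    (subway["dilution_factor"] == df_)
                    & (subway["state_index"] == k)
                    & (subway["species"] == sp)
                ]
                mark = "●" if (not row.empty and bool(row["present"].iloc[0])) else "·"
                cells.append(f"{mark:^{width}}")
            label = sp if k == 0 else f"  [alt]"
            if k == 0 or any(c.strip() for c in cells):
                lines.append(label.ljust(10) + "".join(cells))
    return "\n".join(lines)
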