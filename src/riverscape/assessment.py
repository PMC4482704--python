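"""Species-level assessment: habitat suitability × re-colonization potential.

Each species ends up as a point in a two-axis plane: a standardized habitat
metric (WUA share of bankfull wetted area for fish; relative abundance
against natural reference substrate for macroinvertebrates) and a
re-colonization potential (reachable share of the river network). Species
are ranked per axis within their group and classified into four quadrants —
whether the species is likely to (re)populate a restored reach, and on what
time horizon:

* high habitat, high re-colonization → "likely, short term"
* high habitat, low re-colonization  → "likely, long term"
* low habitat, high re-colonization  → "unlikely, access not limiting"
* low habitat, low re-colonization   → "unlikely, long term"

Thresholds default to the within-group median of each axis (the
classification is semi-quantitative; any fixed thresholds can be supplied).

``run_chain`` orchestrates the full model chain — flow regime → channel
geometry and rating curve → habitat (fish + macroinvertebrates) →
dispersal → assessment — from a single config, writing per-stage artifacts
and a deterministic log of parameters and output checksums.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .channel import build_rating_curve, fit_regime, predict_width
from .dispersal import (DispersalKernel, ModeConfig, recolonize_fish,
                        recolonize_invert)
from .flow import monthly_regime
from .fuzzy import standardize_wua, wua
from .het import apply_water_quality, predict_abundance, relative_abundance
from .synthetic import (SynthConfig, _parabolic_section, example_fish_species,
                        example_invert_species, example_reference_ranges,
                        synth_hydraulic_grid, synth_hydrographs, synth_network,
                        synth_regime_data, synth_substrate)

__all__ = ["SpeciesAssessment", "rank_species", "classify_quadrant",
           "ChainError", "run_chain"]

QUADRANT_LABELS = {
    (True, True): "likely, short term",
    (True, False): "likely, long term",
    (False, True): "unlikely, access not limiting",
    (False, False): "unlikely, long term",
}


@dataclass
class SpeciesAssessment:
    """One species' position on the habitat × re-colonization plane."""

    species: str
    group: str                     # "fish" | "macroinvertebrate"
    habitat: float                 # % (median of monthly WUA shares / relative abundance)
    habitat_low: float
    habitat_high: float
    habitat_min: float | None      # monthly bottleneck (fish only)
    recolonization: float          # % of network length
    recol_low: float
    recol_high: float
    habitat_rank: int | None = None
    recol_rank: int | None = None
    quadrant: str | None = None

    def __post_init__(self):
        if self.group not in {"fish", "macroinvertebrate"}:
            raise ValueError(f"unknown group {self.group!r}")
        if self.habitat < 0 or self.recolonization < 0:
            raise ValueError("axis values must be non-negative")


def _dense_rank_desc(values: Sequence[float]) -> list[int]:
    """Dense descending ranks: largest value gets rank 1, ties share a rank."""
    distinct = sorted(set(values), reverse=True)
    lookup = {v: i + 1 for i, v in enumerate(distinct)}
    return [lookup[v] for v in values]


def rank_species(records: Sequence[SpeciesAssessment]) -> list[SpeciesAssessment]:
    """Rank one group of species independently on both axes (dense, descending)."""
    if not records:
        raise ValueError("no records to rank")
    groups = {r.group for r in records}
    if len(groups) > 1:
        raise ValueError("rank within a single group; got " + ", ".join(sorted(groups)))
    h_ranks = _dense_rank_desc([r.habitat for r in records])
    r_ranks = _dense_rank_desc([r.recolonization for r in records])
    out = []
    for rec, hr, rr in zip(records, h_ranks, r_ranks):
        out.append(replace(rec, habitat_rank=hr, recol_rank=rr))
    return out


def classify_quadrant(record: SpeciesAssessment,
                      thresholds: tuple[float, float]) -> SpeciesAssessment:
    """Assign the four-quadrant class; boundary values count as "high"."""
    t_h, t_r = thresholds
    if not (math.isfinite(t_h) and math.isfinite(t_r)):
        raise ValueError("thresholds must be finite")
    label = QUADRANT_LABELS[(record.habitat >= t_h, record.recolonization >= t_r)]
    return replace(record, quadrant=label)


def assess_group(records: Sequence[SpeciesAssessment],
                 thresholds: tuple[float, float] | None = None) -> list[SpeciesAssessment]:
    """Rank a group and classify quadrants (median split by default)."""
    ranked = rank_species(records)
    if thresholds is None:
        thresholds = (float(np.median([r.habitat for r in ranked])),
                      float(np.median([r.recolonization for r in ranked])))
    return [classify_quadrant(r, thresholds) for r in ranked]


class ChainError(RuntimeError):
    """A chain stage failed; ``stage`` names the failing stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {},          # SynthConfig overrides
    "flow": {"n_runs": 10},
    "channel": {"regime_n": 14, "regime_noise_sd": 0.1, "rating_steps": 8},
    "habitat_fish": {"statistic": "Q50"},
    "habitat_invert": {
        "reach_area": 2800.0,             # ~260 m reach × ~11 m width
        "wq": {"nitrate_mg_l": 3.0},
        "n_reference_samples": 500,
    },
    "dispersal": {
        "fish_kernels": {
            "riffle_minnow": {"sigma_stat": 120.0, "sigma_mob": 1200.0,
                              "p_mobile": 0.33, "ci_factor": 1.6},
            "pool_roach": {"sigma_stat": 250.0, "sigma_mob": 3000.0,
                           "p_mobile": 0.33, "ci_factor": 1.6},
        },
        "years": 3.0,
        "invert_modes": {
            "sand_mayfly": {"aerial": [1500.0, 4000.0],
                            "aquatic_upstream": [300.0, 1000.0],
                            "aquatic_downstream": [2000.0, 6000.0]},
            "gravel_caddis": {"aerial": [1000.0, 3000.0],
                              "aquatic_upstream": [200.0, 800.0],
                              "aquatic_downstream": [1500.0, 5000.0]},
        },
    },
    "assessment": {"thresholds": None},   # None = within-group median split
}


def _merge(base: Mapping, override: Mapping) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_chain(config: Mapping | None = None, outdir: str | Path = "chain_out") -> pd.DataFrame:
    """Run the full reach-to-network assessment chain on synthetic inputs.

    Stages execute in order — flow regime, channel model, fish habitat,
    invertebrate habitat, dispersal, assessment — each writing its artifact
    into ``outdir``. The run is a pure function of the config (seed
    included): rerunning with the same config produces byte-identical
    outputs, which the log records via sha256 checksums.

    Returns the assessment table (one row per species).
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    for stage in ("flow", "channel", "habitat_fish", "habitat_invert",
                  "dispersal", "assessment"):
        if cfg.get(stage) is None:
            raise ChainError(stage, "configuration section missing")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    scfg = SynthConfig(seed=seed, **cfg.get("synthetic", {}))
    log: dict = {"config": cfg, "stages": {}, "outputs": {}}

    def record(stage: str, path: Path, **params):
        log["stages"].setdefault(stage, {}).update(params)
        log["outputs"][str(path.relative_to(outdir))] = _sha256(path)

    # --- stage 1: flow regime -----------------------------------------------
    try:
        runs = synth_hydrographs(scfg, n_runs=int(cfg["flow"]["n_runs"]))
        summary = monthly_regime(runs)
        p = outdir / "flow_regime.csv"
        summary.to_csv(p)
        record("flow", p, n_runs=summary.n_runs, q10=summary.q10)
    except ChainError:
        raise
    except Exception as exc:
        raise ChainError("flow", str(exc)) from exc

    # --- stage 2: channel model ---------------------------------------------
    try:
        ch = cfg["channel"]
        w_obs, q_obs = synth_regime_data(scfg, n=int(ch["regime_n"]),
                                         noise_sd=float(ch["regime_noise_sd"]))
        fit = fit_regime(w_obs, q_obs)
        pred = predict_width(fit, summary.q10)
        xs = _parabolic_section(scfg)
        q_grid = np.linspace(0.3, max(summary.q10, 1.0), int(ch["rating_steps"]))
        rating = build_rating_curve(xs, q_grid)
        p = outdir / "rating_curve.csv"
        pd.DataFrame({"q": rating.q, "stage": rating.stage}).to_csv(
            p, index=False, float_format="%.6f")
        record("channel", p, a=fit.a, b=fit.b, r2=fit.r2,
               width=pred.width, pi_low=pred.pi_low, pi_high=pred.pi_high)
    except ChainError:
        raise
    except Exception as exc:
        raise ChainError("channel", str(exc)) from exc

    # --- stage 3: fish habitat ----------------------------------------------
    try:
        stat = cfg["habitat_fish"]["statistic"]
        monthly_q = summary.monthly[stat].to_numpy()
        grids = {}
        for m, q in zip(range(1, 13), monthly_q):
            grids[m] = synth_hydraulic_grid(scfg, float(q))
        bankfull_grid = synth_hydraulic_grid(scfg, summary.q10)
        bankfull_area = bankfull_grid.wetted_area
        fish_species = example_fish_species()
        fish_rows = []
        fish_results = {}
        for name, system in fish_species.items():
            monthly_wua = [wua(grids[m], system) for m in range(1, 13)]
            res = standardize_wua(monthly_wua, bankfull_area)
            fish_results[name] = res
            for m in range(1, 13):
                fish_rows.append({"species": name, "month": m,
                                  "wua_m2": monthly_wua[m - 1],
                                  "relative_pct": res.relative[m - 1]})
        p = outdir / "habitat_fish.csv"
        pd.DataFrame(fish_rows).to_csv(p, index=False, float_format="%.6f")
        record("habitat_fish", p, statistic=stat, bankfull_wetted_area=bankfull_area)
    except ChainError:
        raise
    except Exception as exc:
        raise ChainError("habitat_fish", str(exc)) from exc

    # --- stage 4: macroinvertebrate habitat ---------------------------------
    try:
        hv = cfg["habitat_invert"]
        present = synth_substrate(scfg, degenerate="sand")
        ref = example_reference_ranges()
        invert_species = example_invert_species()
        invert_rows = []
        invert_results = {}
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10,)))
        for name, params in invert_species.items():
            raw = predict_abundance(params["preference"], present,
                                    float(hv["reach_area"]))
            corrected = apply_water_quality(raw, params["dose_response"],
                                            hv["wq"])
            med, lo, hi = relative_abundance(
                params["preference"], present, ref,
                reach_area=float(hv["reach_area"]),
                n_samples=int(hv["n_reference_samples"]), seed=rng)
            invert_results[name] = (med, lo, hi)
            invert_rows.append({"species": name, "abundance": raw,
                                "corrected": corrected, "relative_median": med,
                                "relative_low": lo, "relative_high": hi})
        p = outdir / "habitat_invert.csv"
        pd.DataFrame(invert_rows).to_csv(p, index=False, float_format="%.6f")
        record("habitat_invert", p, reach_area=hv["reach_area"], wq=hv["wq"])
    except ChainError:
        raise
    except Exception as exc:
        raise ChainError("habitat_invert", str(exc)) from exc

    # --- stage 5: dispersal ---------------------------------------------------
    try:
        dv = cfg["dispersal"]
        net, sources = synth_network(scfg)
        years = float(dv["years"])
        fish_recol = {}
        for name, kp in dv["fish_kernels"].items():
            base = DispersalKernel(kp["sigma_stat"], kp["sigma_mob"],
                                   kp["p_mobile"]).scaled(years)
            f = float(kp.get("ci_factor", 1.0))
            low = DispersalKernel(base.sigma_stat / f, base.sigma_mob / f, base.p_mobile)
            high = DispersalKernel(base.sigma_stat * f, base.sigma_mob * f, base.p_mobile)
            fish_recol[name] = recolonize_fish(net, sources, base, low, high)
        invert_recol = {}
        for name, thr in dv["invert_modes"].items():
            modes = [ModeConfig(mode=m, friction=1.0,
                                threshold_conservative=thr[m][0],
                                threshold_progressive=thr[m][1])
                     for m in ("aerial", "aquatic_upstream", "aquatic_downstream")]
            cons = recolonize_invert(net, sources, modes, "conservative")
            prog = recolonize_invert(net, sources, modes, "progressive")
            invert_recol[name] = (cons, prog)
        disp_rows = [{"species": n, "group": "fish", "share": r.share,
                      "low": r.ci_low, "high": r.ci_high}
                     for n, r in fish_recol.items()]
        disp_rows += [{"species": n, "group": "macroinvertebrate",
                       "share": c.share, "low": c.share, "high": p_.share}
                      for n, (c, p_) in invert_recol.items()]
        p = outdir / "dispersal.csv"
        pd.DataFrame(disp_rows).to_csv(p, index=False, float_format="%.6f")
        record("dispersal", p, total_length_m=net.total_length,
               n_barriers=len(net.barriers), n_sources=len(sources))
    except ChainError:
        raise
    except Exception as exc:
        raise ChainError("dispersal", str(exc)) from exc

    # --- stage 6: assessment --------------------------------------------------
    try:
        thresholds = cfg["assessment"].get("thresholds")
        fish_records = []
        for name, res in fish_results.items():
            r = fish_recol[name]
            fish_records.append(SpeciesAssessment(
                species=name, group="fish", habitat=res.median,
                habitat_low=res.value_range[0], habitat_high=res.value_range[1],
                habitat_min=res.minimum, recolonization=r.share,
                recol_low=r.ci_low, recol_high=r.ci_high))
        invert_records = []
        for name, (med, lo, hi) in invert_results.items():
            cons, prog = invert_recol[name]
            invert_records.append(SpeciesAssessment(
                species=name, group="macroinvertebrate", habitat=med,
                habitat_low=lo, habitat_high=hi, habitat_min=None,
                recolonization=cons.share, recol_low=cons.share,
                recol_high=prog.share))
        assessed = (assess_group(fish_records, thresholds) +
                    assess_group(invert_records, thresholds))
        table = pd.DataFrame([{
            "species": r.species, "group": r.group,
            "habitat_pct": r.habitat, "habitat_low": r.habitat_low,
            "habitat_high": r.habitat_high,
            "habitat_min": r.habitat_min if r.habitat_min is not None else "",
            "recolonization_pct": r.recolonization,
            "recol_low": r.recol_low, "recol_high": r.recol_high,
            "habitat_rank": r.habitat_rank, "recol_rank": r.recol_rank,
            "quadrant": r.quadrant,
        } for r in assessed])
        p = outdir / "assessment.csv"
        table.to_csv(p, index=False, float_format="%.6f")
        record("assessment", p, thresholds=thresholds or "median-split")
    except ChainError:
        raise
    except Exception as exc:
        raise ChainError("assessment", str(exc)) from exc

    rio.write_json(outdir / "chain_log.json", log)
    return table
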