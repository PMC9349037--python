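"""Orchestration of the full Monte-Carlo experiment.

A :class:`SimulationStudy` is built from a :class:`StudyConfig` (geography,
scenarios, methods, replicate count, master seed); ``run()`` executes the
replicate loop — one Gaussian-random-field draw, outcome generation, all
requested exposure predictions, one logistic fit per method — and returns a
:class:`StudyResults` whose ``summary()`` is the operating-characteristics
table (mean RR, bias/RMSE/ASE x100, CP, TPR per method x scenario).

Seeding is counter-based: the stream for (scenario, replicate) is derived
from ``SeedSequence(master_seed, spawn_key=(scenario_index, replicate))``, so
results do not depend on execution order and a resumed run reproduces an
uninterrupted one exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assign import (METHOD_CODES, aggregate_district_mean,
                     assign_area_average, assign_idwa, assign_nearest_monitor,
                     assign_uk_point)
from .exposure import ExposureField, GrfSimulator, get_scenario
from .geography import RegionConfig, StudyRegion, build_geography
from .geostat import empirical_variogram, fit_lur, fit_variogram, krige_universal
from .metrics import (FitResult, compute_tpr, fit_health_model,
                      summarize_performance)
from .outcome import HealthParams, calibrate_intercept, generate_outcomes

__all__ = ["StudyConfig", "SimulationStudy", "StudyResults",
           "run_replicate", "run_study", "predict_all_methods"]

SCENARIO_IDS = ("ES1", "ES2", "ES3", "ES4", "ES5", "ES6", "ES7", "ES8")
_UK_METHODS = ("UK", "UKD", "UKNA", "UKCA", "UKGA")


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce one experiment."""

    region: RegionConfig = dc_field(default_factory=RegionConfig)
    scenarios: tuple[str, ...] = SCENARIO_IDS
    methods: tuple[str, ...] = METHOD_CODES
    n_replicates: int = 200
    master_seed: int = 0
    health: HealthParams = dc_field(default_factory=HealthParams)
    detrend: bool = True
    range_convention: str = "practical"
    overall_mean: float = 52.0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        bad = set(self.scenarios) - set(SCENARIO_IDS)
        if bad:
            raise ValueError(f"unknown scenarios: {sorted(bad)}")
        bad = set(self.methods) - set(METHOD_CODES)
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")
        if "TE" not in self.methods:
            object.__setattr__(self, "methods", ("TE",) + tuple(self.methods))

    def to_dict(self) -> dict:
        return {
            "region": self.region.to_dict(),
            "scenarios": list(self.scenarios),
            "methods": list(self.methods),
            "n_replicates": self.n_replicates,
            "master_seed": self.master_seed,
            "health": {"true_rr": self.health.true_rr,
                       "baseline_prevalence": self.health.baseline_prevalence},
            "detrend": self.detrend,
            "range_convention": self.range_convention,
            "overall_mean": self.overall_mean,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "region" in d:
            d["region"] = RegionConfig.from_dict(d["region"])
        if "health" in d:
            d["health"] = HealthParams(**d["health"])
        for key in ("scenarios", "methods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def replicate_seed(master_seed: int, scenario_index: int, replicate: int) -> np.random.SeedSequence:
    """Order-independent seed stream for one (scenario, replicate) cell."""
    return np.random.SeedSequence(entropy=master_seed,
                                  spawn_key=(scenario_index, replicate))


def predict_all_methods(
    region: StudyRegion,
    field: ExposureField,
    methods: Sequence[str],
    detrend: bool = True,
    range_convention: str = "practical",
    diagnostics: dict | None = None,
) -> dict[str, np.ndarray]:
    """All requested per-mother exposure assignments for one replicate.

    Measurement-based methods (NM, IDWA, AA) see the 25-style background
    monitors only; LUR and UK are fitted on all monitors (background +
    roadside) with the geographic covariates.
    """
    mothers = region.points["mother_home"]
    mother_xy = region.coords_for("mother_home")
    mother_districts = mothers["district_id"].to_numpy()
    nd = region.n_districts

    bg_xy = region.coords_for("monitor_background")
    bg_vals = field["monitor_background"]

    out: dict[str, np.ndarray] = {}
    if "TE" in methods:
        out["TE"] = field["mother_home"]
    if "NM" in methods:
        out["NM"] = assign_nearest_monitor(mother_xy, bg_xy, bg_vals)
    if "IDWA" in methods:
        out["IDWA"] = assign_idwa(mother_xy, bg_xy, bg_vals)
    if "AA" in methods:
        out["AA"] = assign_area_average(
            mother_districts, region.points["monitor_background"]["district_id"].to_numpy(),
            bg_vals, nd)

    needs_model = [m for m in methods if m in ("LUR",) + _UK_METHODS]
    if not needs_model:
        return out

    mon_xy = np.vstack([bg_xy, region.coords_for("monitor_roadside")])
    mon_vals = np.concatenate([bg_vals, field["monitor_roadside"]])
    mon_X = np.vstack([region.covariates_for("monitor_background"),
                       region.covariates_for("monitor_roadside")])

    if "LUR" in methods:
        lur = fit_lur(mon_vals, mon_X)
        out["LUR"] = lur.predict(region.covariates_for("mother_home"))

    uk_requested = [m for m in methods if m in _UK_METHODS]
    if uk_requested:
        if detrend:
            resid = mon_vals - fit_lur(mon_vals, mon_X).predict(mon_X)
        else:
            resid = mon_vals - mon_vals.mean()
        try:
            emp = empirical_variogram(mon_xy, resid)
            vgm = fit_variogram(emp, convention=range_convention)
        except ValueError:
            # sparse network: quantile bins over every pair, none empty
            from scipy.spatial.distance import pdist
            emp = empirical_variogram(mon_xy, resid, n_bins=3,
                                      max_distance=float(pdist(mon_xy).max()),
                                      bin_edges="quantile")
            vgm = fit_variogram(emp, convention=range_convention)
        if diagnostics is not None:
            diagnostics.update(nugget=vgm.nugget, partial_sill=vgm.partial_sill,
                               range_m=vgm.range_m, fallback=vgm.fallback)

        # predict once at every unique coordinate, then index per target set
        uk_unique = krige_universal(mon_xy, mon_vals, mon_X, vgm,
                                    region.coords, region.covariates.values)

        def at(role: str) -> np.ndarray:
            return uk_unique[region.points[role]["u_idx"].to_numpy()]

        if "UK" in uk_requested:
            out["UK"] = at("mother_home")
        if "UKD" in uk_requested:
            out["UKD"] = assign_uk_point(mother_districts, at("district_office"))
        for code, role in (("UKNA", "neighbourhood_centre"),
                           ("UKCA", "tract_centroid"),
                           ("UKGA", "grid_centroid")):
            if code in uk_requested:
                out[code] = aggregate_district_mean(
                    at(role), region.points[role]["district_id"].to_numpy(),
                    mother_districts, nd)
    return out


def run_replicate(
    region: StudyRegion,
    simulator: GrfSimulator,
    health: HealthParams,
    methods: Sequence[str],
    seed: np.random.SeedSequence,
    detrend: bool = True,
    range_convention: str = "practical",
    diagnostics: dict | None = None,
) -> dict[str, FitResult]:
    """One replicate: GRF draw -> outcomes -> predictions -> logistic fits."""
    field_seed, outcome_seed = seed.spawn(2)
    field = simulator.simulate(field_seed)
    true_x = field["mother_home"]
    intercept = calibrate_intercept(true_x, health)
    y = generate_outcomes(true_x, health, outcome_seed, intercept=intercept)
    assignments = predict_all_methods(region, field, methods,
                                      detrend=detrend,
                                      range_convention=range_convention,
                                      diagnostics=diagnostics)

    def safe_fit(x):
        # degenerate assignments (e.g. a one-district region where every
        # mother shares the single monitor value) leave the slope
        # unidentified; flag rather than abort the replicate
        if np.ptp(x) == 0:
            return FitResult(np.nan, np.nan, np.nan, np.nan, np.nan, False)
        return fit_health_model(x, y)

    return {m: safe_fit(x) for m, x in assignments.items()}


@dataclass
class StudyResults:
    """Per-replicate fits plus derived summaries for one study run."""

    config: StudyConfig
    fits: pd.DataFrame  # scenario, replicate, method, slope, se, ci_*, p_value, converged
    manifest: dict
    variograms: pd.DataFrame | None = None  # per-replicate fitted parameters

    def summary(self) -> pd.DataFrame:
        """Operating-characteristics table, one row per scenario x method."""
        rows = []
        beta = self.config.health.true_beta
        for scenario, sub in self.fits.groupby("scenario", sort=False):
            by_method = {m: _frame_to_fits(g.sort_values("replicate"))
                         for m, g in sub.groupby("method", sort=False)}
            te = by_method.get("TE")
            for m in self.config.methods:
                if m not in by_method:
                    continue
                tpr = (compute_tpr(by_method[m], te)
                       if te is not None and len(te) == len(by_method[m]) else None)
                rows.append(summarize_performance(
                    by_method[m], beta, method=m, scenario=scenario, tpr=tpr
                ).to_row())
        return pd.DataFrame(rows)

    def to_csv(self, output_dir: str | Path) -> None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        self.fits.to_csv(output_dir / "fits.csv", index=False)
        self.summary().to_csv(output_dir / "summary.csv", index=False)
        if self.variograms is not None:
            self.variograms.to_csv(output_dir / "variograms.csv", index=False)
        with open(output_dir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)


def _frame_to_fits(frame: pd.DataFrame) -> list[FitResult]:
    return [FitResult(r.slope, r.se, r.ci_low, r.ci_high, r.p_value, bool(r.converged))
            for r in frame.itertuples(index=False)]


_FIT_COLUMNS = ["scenario", "replicate", "method", "slope", "se",
                "ci_low", "ci_high", "p_value", "converged"]


class SimulationStudy:
    """Model-like front end: configure, ``run()``, inspect results.

    The geography is built once (mothers' homes are fixed over the
    simulation) and the GRF Cholesky factor is cached per scenario.
    """

    def __init__(self, config: StudyConfig | None = None):
        self.config = config or StudyConfig()
        self.region = build_geography(self.config.region)
        self._simulators: dict[str, GrfSimulator] = {}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationStudy":
        return cls(StudyConfig.from_yaml(path))

    def simulator(self, scenario_id: str) -> GrfSimulator:
        if scenario_id not in self._simulators:
            params = get_scenario(
                scenario_id,
                covariate_count=self.config.region.covariate_count,
                overall_mean=self.config.overall_mean,
                convention=self.config.range_convention,
            )
            self._simulators[scenario_id] = GrfSimulator(self.region, params)
        return self._simulators[scenario_id]

    def run(
        self,
        checkpoint: str | Path | None = None,
        checkpoint_every: int = 50,
        progress: bool = False,
    ) -> StudyResults:
        """Execute the replicate loop over all configured scenarios.

        With ``checkpoint`` set, per-replicate fits are appended to a CSV as
        the run progresses and already-present (scenario, replicate) cells
        are skipped on restart; counter-based seeding makes the resumed run
        identical to an uninterrupted one.
        """
        cfg = self.config
        t0 = time.time()
        done: set[tuple[str, int]] = set()
        rows: list[dict] = []
        if checkpoint is not None and Path(checkpoint).exists():
            prev = pd.read_csv(checkpoint)
            rows = prev.to_dict("records")
            done = {(r["scenario"], int(r["replicate"])) for r in rows}

        n_fallback = 0
        vgm_rows: list[dict] = []
        for scenario in cfg.scenarios:
            scen_idx = SCENARIO_IDS.index(scenario)
            sim = self.simulator(scenario)
            fresh: list[dict] = []
            for rep in range(cfg.n_replicates):
                if (scenario, rep) in done:
                    continue
                diag: dict = {}
                fits = run_replicate(
                    self.region, sim, cfg.health, cfg.methods,
                    replicate_seed(cfg.master_seed, scen_idx, rep),
                    detrend=cfg.detrend, range_convention=cfg.range_convention,
                    diagnostics=diag,
                )
                if diag:
                    vgm_rows.append({"scenario": scenario, "replicate": rep, **diag})
                for m, f in fits.items():
                    fresh.append({"scenario": scenario, "replicate": rep, "method": m,
                                  "slope": f.slope, "se": f.se, "ci_low": f.ci_low,
                                  "ci_high": f.ci_high, "p_value": f.p_value,
                                  "converged": f.converged})
                if progress and (rep + 1) % 50 == 0:  # pragma: no cover
                    print(f"{scenario}: replicate {rep + 1}/{cfg.n_replicates}")
                if checkpoint is not None and (rep + 1) % checkpoint_every == 0:
                    pd.DataFrame(rows + fresh, columns=_FIT_COLUMNS).to_csv(
                        checkpoint, index=False)
            rows.extend(fresh)
            if checkpoint is not None:
                pd.DataFrame(rows, columns=_FIT_COLUMNS).to_csv(checkpoint, index=False)

        fits = pd.DataFrame(rows, columns=_FIT_COLUMNS)
        fits = fits.sort_values(["scenario", "replicate", "method"]).reset_index(drop=True)
        n_fallback = sum(1 for r in vgm_rows if r.get("fallback"))
        manifest = {
            "config": cfg.to_dict(),
            "version": __version__,
            "elapsed_s": round(time.time() - t0, 3),
            "n_nonconverged": int((~fits["converged"]).sum()),
            "n_variogram_fallbacks": n_fallback,
            "seed_scheme": "SeedSequence(master_seed, spawn_key=(scenario_index, replicate))",
        }
        return StudyResults(config=cfg, fits=fits, manifest=manifest,
                            variograms=pd.DataFrame(vgm_rows) if vgm_rows else None)


def run_study(config: StudyConfig, output_dir: str | Path | None = None,
              **run_kwargs) -> StudyResults:
    """Build, run, and optionally write a study in one call."""
    results = SimulationStudy(config).run(**run_kwargs)
    if output_dir is not None:
        results.to_csv(output_dir)
    return results
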