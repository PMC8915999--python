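"""End-to-end orchestration: clean -> tabulate -> smooth -> life tables ->
Monte Carlo CIs -> representativeness, from one declarative configuration.

Every run writes delimited-text artifacts plus a manifest recording the
configuration hash, all seeds, and a content hash per output, so that two
runs with identical configuration and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ingest, lexis, lifetable, represent, smoothing, uncertainty

log = logging.getLogger("genlife")


@dataclass
class RunConfig:
    """Declarative configuration for a full analysis run."""

    records_path: str = ""
    roster_path: str | None = None
    population_path: str | None = None
    output_dir: str = "results/run"
    territory_substrings: list = field(default_factory=list)
    max_age: float = 100.0
    last_year: float = 1910.0
    drop_inexact_dates: bool = False
    right_censoring: bool = False
    age_start: float = 30.0
    age_open: float = 80.0
    age_max: float = 100.0
    age_width: float = 5.0
    period_start: float = 1500.0
    period_end: float = 1910.0
    period_width: float = 10.0
    spline_degree: int = 3
    knot_spacing_age: float = 5.0
    knot_spacing_period: float = 10.0
    penalty_order: int = 2
    lambda_grid: list = field(default_factory=lambda: [1.0, 10.0, 100.0])
    smooth: bool = True
    n_sims: int = 1000
    seed: int = 1
    year_tolerance: int = 1
    place_threshold: float = 0.85

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def age_edges(self) -> np.ndarray:
        closed = np.arange(self.age_start, self.age_open + 1e-9, self.age_width)
        return np.append(closed, self.age_max)

    def period_edges(self) -> np.ndarray:
        return np.arange(self.period_start, self.period_end + 1e-9, self.period_width)

    def config_hash(self) -> str:
        """Hash of the analysis configuration (where outputs go is excluded)."""
        d = asdict(self)
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _territory_rule(substrings):
    subs = [ingest.normalize_place(s) for s in substrings]

    def rule(place: str) -> bool:
        return any(s in place for s in subs) if subs else True

    return rule


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "seeds": {"root": config.seed},
        "outputs": {},
        "notes": [],
    }
    stage = "ingest"
    try:
        records, rejects = ingest.read_records(config.records_path)
        if len(rejects):
            rejects.to_csv(out / "rejects.csv", index=False)
            manifest["outputs"]["rejects"] = "rejects.csv"
        in_territory = ingest.assign_territory(
            records, _territory_rule(config.territory_substrings)
        )
        n_after_territory = int(in_territory.sum())
        records = records.loc[in_territory].reset_index(drop=True)

        stage = "clean"
        cleaned, report = ingest.clean_records(
            records,
            max_age=config.max_age,
            last_year=config.last_year,
            drop_inexact_dates=config.drop_inexact_dates,
        )
        report.n_after_territory = n_after_territory
        report.to_frame().to_csv(out / "cleaning_report.csv", index=False)
        log.info("cleaning: %s", report)
        if len(cleaned) == 0:
            raise RuntimeError("no records survived cleaning")

        stage = "lexis"
        age_edges = config.age_edges()
        period_edges = config.period_edges()
        censor = config.last_year + 1.0 if config.right_censoring else None
        grid = lexis.tabulate(
            cleaned, age_edges, period_edges, right_censor_to=censor
        )
        lexis.write_grid(grid, out / "lexis_sample.csv")

        scholars = cleaned.loc[np.isfinite(cleaned["entry_age"].to_numpy(float))]
        grids = {"sample": grid}
        if len(scholars):
            grids["scholars_wLT"] = lexis.tabulate(
                scholars, age_edges, period_edges, use_entry_age=True
            )
            grids["scholars_woLT"] = lexis.tabulate(
                scholars, age_edges, period_edges, use_entry_age=False
            )
            lexis.write_grid(grids["scholars_wLT"], out / "lexis_scholars_wlt.csv")
            lexis.write_grid(grids["scholars_woLT"], out / "lexis_scholars_wolt.csv")

        stage = "smoothing"
        surfaces = {}
        if config.smooth:
            spec = smoothing.PsplineSpec(
                spline_degree=config.spline_degree,
                knot_spacing_age=config.knot_spacing_age,
                knot_spacing_period=config.knot_spacing_period,
                penalty_order=config.penalty_order,
            )
            best = smoothing.select_lambdas(grid, spec, config.lambda_grid)
            manifest["notes"].append(
                f"selected lambdas: age={best.lambda_age} period={best.lambda_period}"
            )
            surfaces["sample"] = smoothing.fit_psplines_2d(grid, best)
            surfaces["sample"].to_frame().to_csv(out / "surface_sample.csv", index=False)

        stage = "lifetables"
        periods = [
            (float(period_edges[j]), float(period_edges[j + 1]))
            for j in range(len(period_edges) - 1)
        ]
        lt_rows = []
        estimates = {}
        rng_seeds = np.random.SeedSequence(config.seed).spawn(len(periods))
        for j, period in enumerate(periods):
            sub = grid.period_slice(period)
            d, e, _ = sub.marginal_by_age()
            if np.any(e <= 0) or d.sum() < 10:
                manifest["notes"].append(f"period {period}: too sparse, skipped")
                continue
            if config.smooth and "sample" in surfaces:
                mx = smoothing.surface_to_mx(surfaces["sample"], age_edges, period)
                lt = lifetable.mx_to_lifetable(mx, age_edges)
            else:
                lt = lifetable.grid_to_lifetable(sub)
            lt_rows.append(lt.to_frame().assign(period_lo=period[0], period_hi=period[1]))
            sub_seed = int(rng_seeds[j].generate_state(1)[0] % (2**31))
            manifest["seeds"][f"period_{period[0]:.0f}"] = sub_seed
            estimates[period] = uncertainty.resample_lifetables(
                sub, n_sims=config.n_sims, seed=sub_seed, age=config.age_start
            )
        if lt_rows:
            pd.concat(lt_rows, ignore_index=True).to_csv(
                out / "lifetables.csv", index=False
            )
            uncertainty.ci_table(estimates, out / "ci_estimates.csv")

        stage = "representativeness"
        if config.population_path:
            points = pd.read_csv(config.population_path)
            n_zero = int((points["count"] <= 0).sum())
            if n_zero:
                manifest["notes"].append(
                    f"{n_zero} zero population anchors outside the observed span dropped"
                )
                points = points.loc[points["count"] > 0]
            years = np.arange(points["year"].min(), points["year"].max() + 1)
            pop = represent.interpolate_population(points, years)
            cov = represent.coverage_series(cleaned, pop)
            cov.to_csv(out / "coverage.csv", index=False)
        else:
            manifest["notes"].append("no population input: coverage skipped")

        if config.roster_path:
            roster = pd.read_csv(config.roster_path)
            matches, unmatched = represent.match_scholars(
                cleaned,
                roster,
                year_tolerance=config.year_tolerance,
                place_threshold=config.place_threshold,
            )
            pd.DataFrame(
                [
                    {
                        "roster_id": m.roster_id,
                        "genealogy_id": m.genealogy_id,
                        "match_score": m.match_score,
                        "matched_on": "|".join(m.matched_on),
                    }
                    for m in matches
                ]
            ).to_csv(out / "matches.csv", index=False)
            manifest["notes"].append(f"unmatched roster entries: {len(unmatched)}")
        else:
            manifest["notes"].append(
                "no roster input: scholar matching and oversampling skipped"
            )
    except Exception as exc:  # noqa: BLE001 - abort with stage name + partial manifest
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for f in sorted(out.glob("*.csv")):
        manifest["outputs"][f.stem] = {"file": f.name, "sha256": _sha256(f)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
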