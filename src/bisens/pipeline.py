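"""Stage orchestration: simulate -> pairstats -> famreg -> cohort.

Each stage reads and writes flat TSV tables so every number in the final
summaries is traceable to an intermediate file, and a JSON run manifest
records the configuration, input checksums, package versions and per-stage
row counts.  All floats are written with 8 significant digits; two runs
with the same configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import BisensError, FormatError
from . import cohort as cohort_mod
from . import famreg, simdata

FLOAT_FORMAT = "%.8g"

STAGES = ("simulate", "pairstats", "famreg", "cohort")


@dataclass
class RunConfig:
    """Configuration of a pipeline run; thresholds default to the study's."""

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    out_dir: str = "bisens_out"
    scenario_file: str | None = None  # None -> built-in benchmark cohort
    seed: int = 0
    n_families: int = 73
    p_score_threshold: float = 3.0
    alpha: float = 0.01
    sng_standard_length: float = 100.0
    subset_r_min: float = 0.75
    min_obs: int = 10
    disulfide_threshold: float = 1.5
    log_level: str = "info"

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise FormatError(f"unknown stage(s): {unknown}")
        if self.p_score_threshold < 0 or not 0 < self.alpha <= 1:
            raise FormatError("thresholds out of range")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def load_scenarios(path: str | Path) -> list[simdata.FamilyScenario]:
    """Read family scenarios from a YAML file (a list of mappings)."""
    with open(path) as fh:
        blocks = yaml.safe_load(fh)
    if not isinstance(blocks, list):
        raise FormatError("scenario file must contain a list of scenario mappings")
    scenarios = []
    for blk in blocks:
        if "pni_range" in blk:
            blk["pni_range"] = tuple(blk["pni_range"])
        if "n_algn_range" in blk:
            blk["n_algn_range"] = tuple(blk["n_algn_range"])
        scenarios.append(simdata.FamilyScenario(**blk))
    return scenarios


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep=".")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(config: RunConfig, msg: str) -> None:
    if config.log_level != "quiet":
        print(f"[bisens] {msg}", file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "checksums": {},
    }

    paths = {
        "stats_raw": out / "stats_raw.tsv",
        "stats": out / "stats.tsv",
        "truth": out / "truth.tsv",
        "family_fits": out / "family_fits.tsv",
        "adequacy": out / "adequacy.tsv",
        "cohort_summary": out / "cohort_summary.tsv",
        "correlations": out / "correlations.tsv",
        "group_tests": out / "group_tests.tsv",
    }

    def require(path: Path, producer: str) -> None:
        if not path.exists():
            raise BisensError(
                f"missing input {path.name}; run the '{producer}' stage first"
            )

    if "simulate" in config.stages:
        t0 = time.perf_counter()
        if config.scenario_file:
            scenarios = load_scenarios(config.scenario_file)
        else:
            scenarios = simdata.benchmark_cohort(
                seed=config.seed, n_families=config.n_families
            )
        stats, truth = simdata.simulate_cohort(scenarios)
        _write_tsv(stats, paths["stats_raw"])
        _write_tsv(truth, paths["truth"])
        manifest["stages"]["simulate"] = {
            "n_families": len(scenarios),
            "n_rows": len(stats),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        _log(config, f"simulate: {len(scenarios)} families, {len(stats)} alignments")

    if "pairstats" in config.stages:
        t0 = time.perf_counter()
        require(paths["stats_raw"], "simulate")
        stats = pd.read_csv(paths["stats_raw"], sep="\t", na_values=["."])
        kept = stats[stats["p_score"] > config.p_score_threshold]
        _write_tsv(kept, paths["stats"])
        manifest["stages"]["pairstats"] = {
            "n_rows_in": len(stats),
            "n_rows_accurate": len(kept),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        _log(config, f"pairstats: kept {len(kept)}/{len(stats)} accurate alignments")

    if "famreg" in config.stages:
        t0 = time.perf_counter()
        require(paths["stats"], "pairstats")
        stats = pd.read_csv(paths["stats"], sep="\t", na_values=["."])
        fits = famreg.fit_families(stats, min_obs=config.min_obs)
        adeq = famreg.adequacy_by_family(stats, min_obs=config.min_obs)
        _write_tsv(fits, paths["family_fits"])
        _write_tsv(adeq, paths["adequacy"])
        manifest["stages"]["famreg"] = {
            "n_families": len(fits),
            "n_adequacy_rows": len(adeq),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        _log(config, f"famreg: fitted {len(fits)} families")

    if "cohort" in config.stages:
        t0 = time.perf_counter()
        require(paths["family_fits"], "famreg")
        fits = pd.read_csv(paths["family_fits"], sep="\t", na_values=["."])
        summary = cohort_mod.summarize_cohort(fits, alpha=config.alpha)
        subset = cohort_mod.sss_sids_subset(
            fits, r_min=config.subset_r_min, alpha=config.alpha
        )
        summary_df = pd.DataFrame(
            [
                {
                    "n_families": summary.n_families,
                    "n_families_significant": summary.n_families_significant,
                    "median_R": summary.median_R,
                    "upper_quartile_R": summary.upper_quartile_R,
                    "lower_quartile_R": summary.lower_quartile_R,
                    "frac_both_partials_significant": summary.frac_both_partials_significant,
                    "n_subset_sss_sids": len(subset),
                }
            ]
        )
        _write_tsv(summary_df, paths["cohort_summary"])
        corr = cohort_mod.cross_family_correlations(fits)
        _write_tsv(corr, paths["correlations"])
        group_rows = []
        for variable in ("R", "b1", "b2"):
            source = fits if variable == "R" else subset
            try:
                g = cohort_mod.compare_disulfide_groups(
                    source, threshold=config.disulfide_threshold, variable=variable
                )
                group_rows.append(
                    {
                        "variable": variable,
                        "on": "all_fitted" if variable == "R" else "sss_sids_subset",
                        "mean_diff": g.mean_diff,
                        "t_statistic": g.t_statistic,
                        "p_value": g.p_value,
                        "n_rich": g.group_sizes[0],
                        "n_poor": g.group_sizes[1],
                    }
                )
            except BisensError as exc:
                group_rows.append({"variable": variable, "on": "", "mean_diff": math.nan,
                                   "t_statistic": math.nan, "p_value": math.nan,
                                   "n_rich": 0, "n_poor": 0})
        _write_tsv(pd.DataFrame(group_rows), paths["group_tests"])
        manifest["stages"]["cohort"] = {
            "n_families_significant": summary.n_families_significant,
            "n_subset": len(subset),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        _log(
            config,
            f"cohort: {summary.n_families_significant}/{summary.n_families} "
            f"significant, median R = {summary.median_R:.3f}",
        )

    for name, path in paths.items():
        if path.exists():
            manifest["checksums"][name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
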