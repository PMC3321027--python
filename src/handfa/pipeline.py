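"""End-to-end orchestration: simulate/load -> distances -> mixed-model fits ->
summaries -> integration -> composites -> life-history associations.

A run is driven by a :class:`PipelineConfig` (YAML/JSON-friendly); identical
config + seed gives byte-identical report files.  All outputs are CSV plus a
JSON run manifest.  On any stage failure the partially written output
directory is cleaned up and the stage is named in the error.
"""

from __future__ import annotations

import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import fit_multivariate_lm
from .composite import composite_fa, select_non_da_traits
from .fa_model import SignedFAEstimates, fit_all_traits, summarize_traits
from .integration import signed_fa_correlations
from .landmarks import compute_distances, default_hand_scheme, read_landmark_table
from .repeatability import estimate_R
from .simulate import default_config, simulate_life_history, simulate_measurements

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger("handfa")

#: traits shown in the integration report (digit lengths + palm width)
INTEGRATION_SUBSET = ["D2", "D3", "D4", "D5", "P"]


@dataclass
class PipelineConfig:
    output_dir: str
    simulation: dict | None = None  # kwargs for default_config
    measurements_path: str | None = None
    landmarks_path: str | None = None
    landmarks_format: str = "csv"
    life_history_path: str | None = None
    scheme: str = "default"
    signed_fa_mode: str = "blup"
    da_alpha: float = 0.05
    min_traits: int | None = None
    bmi_squared: bool = False
    interactions: list[str] = field(default_factory=list)
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        has_inputs = bool(self.measurements_path or self.landmarks_path)
        has_sim = self.simulation is not None
        if has_inputs == has_sim:
            raise ValueError(
                "config must have exactly one of: input paths, a simulation block"
            )
        if has_sim and self.seed is None:
            raise ValueError("a seed is required when simulating")
        if self.signed_fa_mode not in ("blup", "raw"):
            raise ValueError("signed_fa_mode must be 'blup' or 'raw'")
        if self.scheme != "default":
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for path in (self.measurements_path, self.landmarks_path, self.life_history_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }


@dataclass
class ReportBundle:
    output_dir: Path
    files: dict[str, Path]
    trait_summary: pd.DataFrame
    composites: pd.DataFrame
    associations: dict[str, pd.DataFrame] = field(default_factory=dict)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.10g")


def _infer_sessions(measurements: pd.DataFrame) -> int:
    counts = measurements.groupby(["individual", "side", "trait"], sort=False)[
        "session"
    ].count()
    return int(counts.mode().iloc[0])


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage and write the report CSVs plus a run manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    stage = "setup"
    tmp = Path(tempfile.mkdtemp(prefix="handfa_"))
    files: dict[str, Path] = {}
    try:
        # ---- acquire data ------------------------------------------------
        stage = "data"
        life = None
        if config.simulation is not None:
            sim_cfg = default_config(**config.simulation)
            measurements, truth = simulate_measurements(sim_cfg, seed=config.seed)
            life = simulate_life_history(sim_cfg, truth, seed=config.seed + 1)
            log.info(
                "simulated %d individuals x %d traits x %d sessions",
                sim_cfg.n_individuals, len(sim_cfg.trait_ids), sim_cfg.n_sessions,
            )
        elif config.measurements_path:
            measurements = pd.read_csv(config.measurements_path)
        else:
            lm = read_landmark_table(
                config.landmarks_path,
                format=config.landmarks_format,
                landmark_names=(
                    list(default_hand_scheme().landmarks)
                    if config.landmarks_format == "tps"
                    else None
                ),
            )
            measurements = compute_distances(lm, default_hand_scheme())
        if life is None and config.life_history_path:
            life = pd.read_csv(config.life_history_path)
        K = _infer_sessions(measurements)

        # ---- per-trait mixed models --------------------------------------
        stage = "fa_model"
        fits, da_tests, fa_tests, signed_table = fit_all_traits(measurements)
        estimates = SignedFAEstimates(table=signed_table, flag=config.signed_fa_mode)
        raw_wide = estimates.values("raw")

        stage = "repeatability"
        repeats = []
        for fit in fits:
            try:
                est = estimate_R(
                    raw_wide[fit.trait_id].dropna().to_numpy(), fit.sigma_me, K
                )
                repeats.append(est.R if est.defined else np.nan)
            except ValueError:
                repeats.append(np.nan)

        stage = "summary"
        summary = summarize_traits(fits, da_tests, repeats)
        summary["real_fa_chi2"] = [t.chi2 for t in fa_tests]
        summary["real_fa_p"] = [t.p for t in fa_tests]
        files["trait_summary"] = tmp / "trait_summary.csv"
        _write_csv(summary, files["trait_summary"])
        files["signed_fa"] = tmp / "signed_fa.csv"
        _write_csv(signed_table, files["signed_fa"])

        stage = "integration"
        subset = [t for t in INTEGRATION_SUBSET if t in raw_wide.columns]
        if len(subset) >= 2:
            corr = signed_fa_correlations(estimates.values()[subset])
            files["integration_r"] = tmp / "integration_correlations.csv"
            _write_csv(corr.r, files["integration_r"], index=True)
            files["integration_p"] = tmp / "integration_pvalues.csv"
            _write_csv(corr.p, files["integration_p"], index=True)

        stage = "composite"
        da_map = {f.trait_id: t for f, t in zip(fits, da_tests)}
        comp_all = composite_fa(estimates, min_traits=config.min_traits)
        non_da = select_non_da_traits(da_map, alpha=config.da_alpha)
        composites = pd.DataFrame({"composite_all": comp_all.scores})
        comp_nonda = None
        if non_da:
            comp_nonda = composite_fa(
                estimates, subset=non_da, min_traits=config.min_traits
            )
            composites["composite_non_da"] = comp_nonda.scores
        composites.index.name = "individual"
        files["composites"] = tmp / "composites.csv"
        _write_csv(composites, files["composites"], index=True)

        # ---- associations -------------------------------------------------
        associations: dict[str, pd.DataFrame] = {}
        if life is not None:
            stage = "associations"
            for label, comp in (
                ("all_traits", comp_all),
                ("non_da_traits", comp_nonda),
            ):
                if comp is None:
                    continue
                res = fit_multivariate_lm(
                    life, comp, bmi_squared=config.bmi_squared
                )
                pr = res.per_response.copy()
                pr.insert(0, "index_type", label)
                bt = res.block_tests.copy()
                bt.insert(0, "index_type", label)
                bt["n_complete"] = res.n_complete
                associations[f"per_response_{label}"] = pr
                associations[f"blocks_{label}"] = bt
                for factor in config.interactions:
                    from .associations import interaction_tests

                    it = interaction_tests(life, comp, factor)
                    associations[f"blocks_{label}"] = pd.concat(
                        [
                            associations[f"blocks_{label}"],
                            pd.DataFrame(
                                [{
                                    "index_type": label,
                                    "block": it.block,
                                    "pillai": it.pillai,
                                    "F": it.F,
                                    "df1": it.df1,
                                    "df2": it.df2,
                                    "p": it.p,
                                    "n_complete": res.n_complete,
                                }]
                            ),
                        ],
                        ignore_index=True,
                    )
            per_resp = pd.concat(
                [v for k, v in associations.items() if k.startswith("per_response")],
                ignore_index=True,
            )
            blocks = pd.concat(
                [v for k, v in associations.items() if k.startswith("blocks")],
                ignore_index=True,
            )
            files["association_per_response"] = tmp / "association_per_response.csv"
            _write_csv(per_resp, files["association_per_response"])
            files["association_blocks"] = tmp / "association_blocks.csv"
            _write_csv(blocks, files["association_blocks"])

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "handfa_version": __version__,
            "non_da_traits": non_da,
        }
        files["manifest"] = tmp / "manifest.json"
        files["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))

        # ---- publish atomically -------------------------------------------
        out_dir.mkdir(parents=True, exist_ok=True)
        final = {}
        for key, path in files.items():
            dest = out_dir / path.name
            shutil.copyfile(path, dest)
            final[key] = dest
        return ReportBundle(
            output_dir=out_dir,
            files=final,
            trait_summary=summary,
            composites=composites,
            associations=associations,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
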