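"""End-to-end orchestration and file I/O.

``run_pipeline`` executes the full analysis — generate or ingest a
cohort, residualize covariates, build each group's covariance network
across the density sweep, compute global and nodal topology, run the
permutation test with FDR correction, identify betweenness hubs, and fit
the ROI morphometry models — writing every stage artifact plus a run
manifest into an output directory.  All randomness flows from one master
seed through per-stage ``numpy.random.SeedSequence`` children, so a
re-run with the same seed is byte-identical and stages can be reproduced
in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import Atlas, aal90, write_atlas
from .inference import (
    GLOBAL_METRICS,
    NODAL_METRICS,
    auc_table,
    identify_hubs,
    metric_curves,
    normalized_bc_profile,
    permutation_test,
    region_columns_of,
)
from .morphometry import group_contrast, psqi_regression
from .network import (
    correlation_matrix,
    density_sweep,
    min_connected_density,
    zero_negatives,
    binarize_at_density,
)
from .residualize import DEFAULT_COVARIATES, residualize
from .synthetic import CohortConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "validate_cohort", "read_cohort_file"]

log = logging.getLogger("scngraph")


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run."""

    input_path: str | None = None  # cohort CSV; None -> generate synthetically
    cohort: CohortConfig = field(default_factory=CohortConfig)
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    d_min: float = 0.10
    d_max: float = 0.50
    d_step: float = 0.02
    n_perm: int = 1000
    n_random_refs: int = 100
    n_refs_perm: int = 0  # rewired refs per permutation; 0 skips sigma in the test
    seed: int = 0
    out_dir: str = "scn_run"
    residualize_scope: str = "pooled"
    repermute_residuals: bool = False
    sd_ddof: int = 1  # hub-threshold SD convention (1 = sample SD)
    write_adjacency: bool = True
    permute_metrics: tuple[str, ...] = NODAL_METRICS

    def validate(self) -> None:
        if not (0 < self.d_min < self.d_max < 1) or self.d_step <= 0:
            raise ValueError("need 0 < d_min < d_max < 1 and d_step > 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.residualize_scope not in ("pooled", "per-group"):
            raise ValueError("residualize_scope must be 'pooled' or 'per-group'")

    def sweep(self) -> np.ndarray:
        return density_sweep(self.d_min, self.d_max, self.d_step)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["cohort"] = yaml.safe_load(self.cohort.to_yaml())
        d["permute_metrics"] = list(self.permute_metrics)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in d and d["cohort"] is not None:
            d["cohort"] = CohortConfig.from_yaml(yaml.safe_dump(d["cohort"]))
        if "permute_metrics" in d:
            d["permute_metrics"] = tuple(d["permute_metrics"])
        return cls(**d)


def validate_cohort(df: pd.DataFrame, atlas: Atlas | None = None) -> list[str]:
    """Check a cohort table; returns the region columns.

    Verifies the required metadata/covariate columns, matches region
    columns against the atlas when given, and checks volumes are numeric,
    positive and complete.  Errors name the offending columns.
    """
    required = ["subject_id", "group"] + DEFAULT_COVARIATES + ["psqi"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    bad_groups = set(df["group"]) - {"patient", "control"}
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    regions = region_columns_of(df)
    if atlas is not None:
        unknown = [r for r in regions if r not in set(atlas.names)]
        if unknown:
            raise ValueError(f"region columns not in atlas: {unknown}")
        absent = [r for r in atlas.names if r not in regions]
        if absent:
            raise ValueError(f"atlas regions missing from table: {absent}")
        regions = list(atlas.names)  # atlas order
    vols = df[regions]
    non_numeric = [c for c in regions if not pd.api.types.is_numeric_dtype(vols[c])]
    if non_numeric:
        raise ValueError(f"non-numeric volume columns: {non_numeric}")
    if vols.isna().any().any():
        bad = vols.columns[vols.isna().any()].tolist()
        raise ValueError(f"missing values in volume columns: {bad}")
    if (vols <= 0).any().any():
        bad = vols.columns[(vols <= 0).any()].tolist()
        raise ValueError(f"non-positive volumes in columns: {bad}")
    return regions


def read_cohort_file(path, atlas: Atlas | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_cohort(df, atlas=atlas)
    return df


def _write_matrix_tsv(values: np.ndarray, names, path) -> None:
    pd.DataFrame(values, index=names, columns=names).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write artifacts to ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    sweep = config.sweep()
    master = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["generate", "curves", "permute"], master.spawn(3)
        )
    }
    timings = {}

    def stage(name):
        t0 = time.perf_counter()

        def done():
            timings[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s finished in %.2fs", name, timings[name])

        return done

    # 1. cohort --------------------------------------------------------
    end = stage("cohort")
    if config.input_path is None:
        cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["generate"])
        cohort = generate_cohort(cohort_cfg)
        atlas = cohort_cfg.atlas()
        cohort.to_csv(out / "cohort.csv", index=False)
    else:
        atlas = aal90()
        cohort = read_cohort_file(config.input_path, atlas=atlas)
    regions = validate_cohort(cohort, atlas=atlas)
    write_atlas(atlas, out / "atlas.csv")
    end()

    # 2. residualize ---------------------------------------------------
    end = stage("residualize")
    residuals = residualize(
        cohort, config.covariates, scope=config.residualize_scope,
        region_columns=regions,
    )
    residuals.to_csv(out / "residuals.csv", index=False)
    end()

    # 3. networks ------------------------------------------------------
    end = stage("networks")
    corrs = {}
    for group in ("patient", "control"):
        corr = zero_negatives(correlation_matrix(residuals, group, regions))
        corrs[group] = corr
        _write_matrix_tsv(corr.values, regions, out / f"corr_{group}.tsv")
    d_connected, connectivity = min_connected_density(
        corrs["patient"], corrs["control"], sweep
    )
    connectivity.to_csv(out / "connectivity.csv", index=False)
    manifest_nets = []
    if config.write_adjacency:
        for group, corr in corrs.items():
            for d in sweep:
                net = binarize_at_density(corr, float(d))
                _write_matrix_tsv(
                    net.adjacency.astype(int), regions,
                    out / f"adjacency_{group}_{d:.2f}.tsv",
                )
                manifest_nets.append(
                    {"group": group, "density": float(d), "n_edges": net.n_edges,
                     "connected": bool(net.is_connected())}
                )
    end()

    # 4. metric curves + AUC ------------------------------------------
    end = stage("metrics")
    curves = metric_curves(
        residuals, sweep, NODAL_METRICS + GLOBAL_METRICS,
        n_refs=config.n_random_refs, seed=seeds["curves"],
        region_columns=regions,
    )
    curves.to_csv(out / "metric_curves.csv", index=False)
    aucs = auc_table(curves)
    aucs.to_csv(out / "auc_results.csv", index=False)
    end()

    # 5. permutation inference ----------------------------------------
    end = stage("permutation")
    perm_metrics = tuple(config.permute_metrics)
    if config.n_refs_perm == 0:
        perm_metrics = tuple(m for m in perm_metrics if m != "sigma")
    perm = permutation_test(
        cohort, config.covariates, sweep, perm_metrics,
        n_perm=config.n_perm, seed=seeds["permute"],
        scope=config.residualize_scope,
        repermute_residuals=config.repermute_residuals,
        n_refs=config.n_refs_perm, region_columns=regions,
    )
    perm.to_csv(out / "permutation_results.csv", index=False)
    end()

    # 6. hubs ----------------------------------------------------------
    end = stage("hubs")
    hubs = pd.concat(
        [
            identify_hubs(
                normalized_bc_profile(curves, group), atlas, group,
                sd_ddof=config.sd_ddof,
            )
            for group in ("patient", "control")
        ],
        ignore_index=True,
    )
    hubs.to_csv(out / "hubs.csv", index=False)
    end()

    # 7. morphometry ---------------------------------------------------
    end = stage("morphometry")
    morpho = pd.concat(
        [
            group_contrast(cohort, config.covariates, regions),
            psqi_regression(cohort, config.covariates, regions),
        ],
        ignore_index=True,
    )
    morpho.to_csv(out / "morphometry.csv", index=False)
    end()

    # 8. summary -------------------------------------------------------
    sig = perm[perm["q_value"] < 0.05].sort_values("q_value")
    summary = {
        "n_patients": int((cohort["group"] == "patient").sum()),
        "n_controls": int((cohort["group"] == "control").sum()),
        "n_regions": len(regions),
        "sweep": [float(d) for d in sweep],
        "min_connected_density": float(d_connected),
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_perm": config.n_perm,
        "covariates": list(config.covariates),
        "global_auc": {
            f"{row.metric}:{row.group}": row.auc
            for row in aucs[aucs["node"] == "global"].itertuples()
        },
        "significant_nodal": sig[["metric", "node", "observed_diff", "q_value"]]
        .to_dict(orient="records"),
        "hubs": {
            group: hubs[(hubs["group"] == group) & hubs["is_hub"]]["region"].tolist()
            for group in ("patient", "control")
        },
        "networks": manifest_nets,
        "timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(summary, indent=2))
    report = [
        f"SCN pipeline run (seed {config.seed})",
        f"  cohort: {summary['n_patients']} patients vs {summary['n_controls']} "
        f"controls, {summary['n_regions']} regions",
        f"  sweep: {sweep[0]:.2f}-{sweep[-1]:.2f} step {config.d_step} "
        f"({len(sweep)} densities); min connected density {d_connected:.2f}",
        f"  permutation: {config.n_perm} shuffles on {', '.join(perm_metrics)}",
        f"  significant nodal effects (q < 0.05): "
        f"{len(summary['significant_nodal'])}",
    ]
    for rec in summary["significant_nodal"]:
        report.append(
            f"    {rec['metric']} @ {rec['node']}: diff {rec['observed_diff']:+.3f} "
            f"(q = {rec['q_value']:.4f})"
        )
    for group in ("patient", "control"):
        report.append(f"  hubs ({group}): {', '.join(summary['hubs'][group]) or 'none'}")
    (out / "report.txt").write_text("\n".join(report) + "\n")
    return out
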