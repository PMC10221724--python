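"""End-to-end orchestration: simulate or load tables, build networks,
compute metric curves, run the permutation comparisons, write a run
directory with a manifest.

All randomness flows from one root seed through named substreams
(cohort generation, permutations, rewiring), so a run directory is
reproducible bit-for-bit from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, generate_cohort
from .comparison import (
    MEASURE_CLASS,
    NODAL_METRICS,
    ComparisonReport,
    compare_all,
)
from .construction import (
    ThicknessTable,
    adjust_for_mean_thickness,
    binarize_at_density,
    minimum_connected_density,
    pearson_matrix,
    read_thickness_tables,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one full analysis run."""

    input_table: str | None = None
    delimiter: str | None = None
    cohort: CohortConfig | None = None
    density_step: float = 0.05
    density_upper: float = 0.5
    d_min_resolution: float = 0.01
    n_perm: int = 1000
    sigma_n_null: int = 20
    include_sigma: bool = True
    node_fdr: bool = False
    seed: int = 0
    output_dir: str = "covnet_run"
    force: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValidationError("n_perm must be at least 1")
        if self.sigma_n_null < 1:
            raise ValidationError("sigma_n_null must be at least 1")
        if not (0 < self.density_step <= self.density_upper <= 1):
            raise ValidationError("invalid density step/upper")
        if (self.input_table is None) == (self.cohort is None):
            raise ValidationError(
                "exactly one of input_table or cohort must be given"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", None)
        cohort = None
        if cohort_raw is not None:
            if "region_labels" in cohort_raw:
                cohort_raw["region_labels"] = tuple(cohort_raw["region_labels"])
            if "module_assignment" in cohort_raw:
                cohort_raw["module_assignment"] = tuple(
                    cohort_raw["module_assignment"]
                )
            cohort = CohortConfig(**cohort_raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(cohort=cohort, **raw)


def _load_tables(config: RunConfig) -> dict[str, ThicknessTable]:
    if config.cohort is not None:
        cohort_seed = int(
            np.random.SeedSequence(
                entropy=config.seed, spawn_key=(0,)
            ).generate_state(1)[0] % (2**31)
        )
        cohort = dataclasses.replace(config.cohort, seed=cohort_seed)
        return generate_cohort(cohort)
    path = Path(config.input_table)
    if not path.exists():
        raise ValidationError(f"input table not found: {path}")
    return read_thickness_tables(path, sep=config.delimiter)


def _write_nodal_tsv(report: ComparisonReport, path: Path) -> None:
    """Nodal results in the report-table schema: contrast, measure class,
    cortical node, per-group averages across densities, p_FDA."""
    rows = []
    for contrast in report.contrasts:
        la, lb = contrast.contrast
        for metric, results in contrast.nodal_results.items():
            avg_a = contrast.average_across_densities(metric, la)
            avg_b = contrast.average_across_densities(metric, lb)
            for j, res in enumerate(results):
                rows.append(
                    {
                        "contrast": f"{la} vs {lb}",
                        "measure_class": MEASURE_CLASS[metric],
                        "metric": metric,
                        "cortical_node": res.node,
                        f"avg_{la}": avg_a[j],
                        f"avg_{lb}": avg_b[j],
                        "observed_stat": res.observed_stat,
                        "p_fda": res.p_fda,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")


def _write_global_tsv(report: ComparisonReport, path: Path) -> None:
    rows = []
    for contrast in report.contrasts:
        la, lb = contrast.contrast
        for metric, res in contrast.global_results.items():
            curve_a = contrast.observed_curves[metric][la].values
            curve_b = contrast.observed_curves[metric][lb].values
            rows.append(
                {
                    "contrast": f"{la} vs {lb}",
                    "measure_class": MEASURE_CLASS[metric],
                    "metric": metric,
                    f"avg_{la}": float(curve_a.mean()),
                    f"avg_{lb}": float(curve_b.mean()),
                    "observed_stat": res.observed_stat,
                    "p_fda": res.p_fda,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")


def _write_curves_tsv(report: ComparisonReport, path: Path,
                      region_labels: Sequence[str]) -> None:
    """Long-format observed metric curves: one row per (contrast, metric,
    group, density[, node])."""
    rows = []
    for contrast in report.contrasts:
        la, lb = contrast.contrast
        for metric, by_group in contrast.observed_curves.items():
            for group, curve in by_group.items():
                for i, d in enumerate(curve.densities):
                    vals = np.atleast_1d(curve.values[i])
                    if vals.size == 1:
                        rows.append({
                            "contrast": f"{la} vs {lb}", "metric": metric,
                            "group": group, "density": d, "node": "",
                            "value": float(vals[0]),
                        })
                    else:
                        for node, v in zip(region_labels, vals):
                            rows.append({
                                "contrast": f"{la} vs {lb}", "metric": metric,
                                "group": group, "density": d, "node": node,
                                "value": float(v),
                            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write a deterministic run directory.

    Layout: ``tables/`` (input or simulated thickness tables),
    ``covariance/`` (per-group correlation matrices), ``networks/``
    (adjacency edge lists and GraphML at each grid density),
    ``comparisons/`` (global and nodal result TSVs, metric curves),
    ``manifest.json`` (version, config, seeds, D_min, warnings).
    """
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()):
        if not config.force:
            raise ValidationError(
                f"output directory {out} exists and is not empty; "
                "pass force=True (--force) to overwrite"
            )
    for sub in ("tables", "covariance", "networks", "comparisons"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    tables = _load_tables(config)
    labels = sorted(tables)
    for label in labels:
        tables[label].write(out / "tables" / f"thickness_{label}.tsv")

    d_min: dict[str, float] = {}
    for label in labels:
        adjusted = adjust_for_mean_thickness(tables[label])
        cov = pearson_matrix(adjusted)
        cov.write(out / "covariance" / f"correlation_{label}.tsv")
        d_min[label] = minimum_connected_density(cov, config.d_min_resolution)

    comparison_seed = int(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
        .generate_state(1)[0] % (2**31)
    )
    global_metric_names = ["clustering_global", "path_length", "efficiency_global"]
    if config.include_sigma:
        global_metric_names.append("sigma")
    report = compare_all(
        tables,
        n_perm=config.n_perm,
        seed=comparison_seed,
        step=config.density_step,
        upper=config.density_upper,
        d_min_resolution=config.d_min_resolution,
        global_metrics=global_metric_names,
        nodal_metrics=NODAL_METRICS,
        sigma_n_null=config.sigma_n_null,
        node_fdr=config.node_fdr,
    )

    # adjacency exports at every density of every contrast grid
    for contrast in report.contrasts:
        for label in contrast.contrast:
            adjusted = adjust_for_mean_thickness(tables[label])
            cov = pearson_matrix(adjusted)
            for d in contrast.grid.densities:
                adj = binarize_at_density(cov, d)
                stem = out / "networks" / f"{label}_d{d:.2f}"
                adj.write_edge_list(Path(f"{stem}.edges.tsv"))
                adj.write_graphml(Path(f"{stem}.graphml"))

    _write_global_tsv(report, out / "comparisons" / "global_results.tsv")
    _write_nodal_tsv(report, out / "comparisons" / "nodal_results.tsv")
    _write_curves_tsv(report, out / "comparisons" / "metric_curves.tsv",
                      tables[labels[0]].region_labels)

    manifest = {
        "covnet_version": __version__,
        "seed": config.seed,
        "substream_seeds": {"comparison": comparison_seed},
        "n_perm": config.n_perm,
        "sigma_n_null": config.sigma_n_null,
        "node_fdr": config.node_fdr,
        "d_min": d_min,
        "density_grids": {
            " vs ".join(c.contrast): list(c.grid.densities)
            for c in report.contrasts
        },
        "decisions": {
            "adjustment": "per-region OLS residualization on subject mean "
                          "thickness, within group",
            "edge_ranking": "signed r, ties broken by lexicographic label order",
            "edge_count_rounding": "round half away from zero of density * P",
            "path_length": "mean of finite distances; unreachable pairs "
                           "counted and excluded",
            "p_value": "add-one two-tailed permutation estimator",
        },
        "config": _config_dict(config),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    # run-environment fields; not part of the analysis definition
    d.pop("output_dir", None)
    d.pop("force", None)
    if d.get("cohort") is not None:
        d["cohort"]["region_labels"] = list(d["cohort"]["region_labels"])
        d["cohort"]["module_assignment"] = list(d["cohort"]["module_assignment"])
        d["cohort"]["group_effects"] = dict(d["cohort"]["group_effects"])
    return d
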