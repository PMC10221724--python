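"""Synthetic cohort generation.

Structural covariance studies correlate a regional morphometric measure
(here: mean cortical thickness per parcel) across subjects.  This module
generates seeded cohorts whose thickness tables carry exactly the
statistical structure the downstream analysis assumes:

* a per-region baseline mean (mm),
* one shared latent "global thickness" factor loading on every region —
  the nuisance that the mean-thickness adjustment is meant to remove,
* a block-structured correlated signal: regions within a module correlate
  at ``rho_within``, regions in different modules at ``rho_between``,
* independent Gaussian measurement noise.

The correlated part is built from a factor representation

    s_j = sqrt(rho_b) * f0 + sqrt(rho_w - rho_b) * f_{m(j)} + sqrt(1 - rho_w) * e_j

with independent standard-normal factors, so the implied region-level
correlation matrix is positive semi-definite by construction whenever
``rho_between <= rho_within``, and the within/between-module correlations
of the non-global component equal the nominal parameters exactly.

Group differences are injected by a per-group multiplier on ``rho_within``
(a multiplier below 1 de-segregates that group's network, lowering its
clustering coefficient — the direction of the deficit-schizophrenia
finding the pipeline is designed to detect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .construction import ThicknessTable
from .errors import ValidationError
from .regions import DESIKAN_KILLIANY_68, default_module_assignment

DEFAULT_GROUPS = ("HC", "SZND", "SZD")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic three-group thickness cohort.

    Defaults mirror the study design the pipeline targets: three groups of
    21 subjects, 68 Desikan-Killiany regions, modular covariance.  Thickness
    scale parameters (baseline 2.5 mm, noise SD 0.12 mm, global factor SD
    0.08 mm) are typical of adult cortical thickness data.
    """

    n_subjects_per_group: int = 21
    n_regions: int = 68
    region_labels: tuple[str, ...] = DESIKAN_KILLIANY_68
    module_assignment: tuple[int, ...] | None = None
    rho_within: float = 0.5
    rho_between: float = 0.15
    global_factor_sd: float = 0.08
    noise_sd: float = 0.12
    group_effects: Mapping[str, float] = field(
        default_factory=lambda: {g: 1.0 for g in DEFAULT_GROUPS}
    )
    baseline_mean: float | tuple[float, ...] = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValidationError("n_subjects_per_group must be positive")
        if self.n_regions < 2:
            raise ValidationError("n_regions must be at least 2")
        if len(self.region_labels) != self.n_regions:
            raise ValidationError(
                f"{len(self.region_labels)} region labels for "
                f"{self.n_regions} regions"
            )
        if len(set(self.region_labels)) != self.n_regions:
            raise ValidationError("region labels must be unique")
        if self.module_assignment is None:
            object.__setattr__(
                self,
                "module_assignment",
                default_module_assignment(self.n_regions),
            )
        if len(self.module_assignment) != self.n_regions:
            raise ValidationError("module_assignment length != n_regions")
        if not (0.0 <= self.rho_within < 1.0):
            raise ValidationError("rho_within must lie in [0, 1)")
        if not (0.0 <= self.rho_between < 1.0):
            raise ValidationError("rho_between must lie in [0, 1)")
        if self.rho_between > self.rho_within:
            raise ValidationError(
                "rho_between > rho_within: implied block covariance is not "
                "guaranteed positive semi-definite"
            )
        if self.global_factor_sd < 0:
            raise ValidationError("global_factor_sd must be nonnegative")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        for label, mult in self.group_effects.items():
            if not (0.0 <= mult <= 1.0):
                raise ValidationError(
                    f"group_effects[{label!r}] must lie in [0, 1]"
                )
            if mult * self.rho_within < self.rho_between:
                raise ValidationError(
                    f"group {label!r}: effective within-module correlation "
                    f"{mult * self.rho_within:.4f} falls below rho_between "
                    f"{self.rho_between:.4f}; the block covariance of this "
                    "group is not positive semi-definite by construction"
                )
        means = self.baseline_means()
        if np.any(means <= 0):
            raise ValidationError("baseline_mean values must be positive (mm)")

    def baseline_means(self) -> np.ndarray:
        """Per-region baseline thickness as an array of length ``n_regions``."""
        if np.isscalar(self.baseline_mean):
            return np.full(self.n_regions, float(self.baseline_mean))
        arr = np.asarray(self.baseline_mean, dtype=float)
        if arr.shape != (self.n_regions,):
            raise ValidationError("baseline_mean must be scalar or length n_regions")
        return arr

    def latent_correlation(self, group_label: str) -> np.ndarray:
        """Closed-form correlation matrix of the non-global signal component.

        Block-constant: ``effect * rho_within`` on the diagonal blocks,
        ``rho_between`` elsewhere, unit diagonal.  Used both by the sampler
        (through its factor representation) and by tests as the generating
        truth.
        """
        mult = float(self.group_effects.get(group_label, 1.0))
        rho_w = mult * self.rho_within
        modules = np.asarray(self.module_assignment)
        same = modules[:, None] == modules[None, :]
        corr = np.where(same, rho_w, self.rho_between)
        np.fill_diagonal(corr, 1.0)
        return corr


def generate_cohort(config: CohortConfig) -> dict[str, ThicknessTable]:
    """Draw one :class:`ThicknessTable` per group, reproducibly from the seed.

    Identical configs (including seed) regenerate identical tables.  The
    per-subject ``mean_thickness`` column is set to the exact row mean of
    the regional values.
    """
    modules = np.asarray(config.module_assignment)
    n_modules = int(modules.max()) + 1
    baseline = config.baseline_means()
    n, r = config.n_subjects_per_group, config.n_regions
    rho_b = config.rho_between

    tables: dict[str, ThicknessTable] = {}
    for g_idx, (label, mult) in enumerate(sorted(config.group_effects.items())):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(g_idx,))
        )
        rho_w = float(mult) * config.rho_within
        a_common = np.sqrt(rho_b)
        a_module = np.sqrt(rho_w - rho_b)
        a_unique = np.sqrt(1.0 - rho_w)

        f_common = rng.standard_normal((n, 1))
        f_module = rng.standard_normal((n, n_modules))
        unique = rng.standard_normal((n, r))
        g_factor = rng.standard_normal((n, 1))

        signal = (
            a_common * f_common
            + a_module * f_module[:, modules]
            + a_unique * unique
        )
        values = (
            baseline[None, :]
            + config.global_factor_sd * g_factor
            + config.noise_sd * signal
        )
        subject_ids = [f"{label}_{i + 1:03d}" for i in range(n)]
        tables[label] = ThicknessTable(
            group_label=label,
            subject_ids=subject_ids,
            region_labels=list(config.region_labels),
            values=values,
            mean_thickness=values.mean(axis=1),
        )
    return tables


def write_cohort(tables: Mapping[str, ThicknessTable], out_dir: str | Path) -> list[Path]:
    """Write one delimited table per group into ``out_dir``; return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label in sorted(tables):
        path = out_dir / f"thickness_{label}.tsv"
        tables[label].write(path)
        paths.append(path)
    return paths


def two_group_config(
    effect: float = 1.0,
    n_subjects_per_group: int = 21,
    seed: int = 0,
    **kwargs,
) -> CohortConfig:
    """Convenience two-group design: group ``A`` at full within-module
    correlation, group ``B`` at multiplier ``effect`` (1.0 = null)."""
    return CohortConfig(
        n_subjects_per_group=n_subjects_per_group,
        group_effects={"A": 1.0, "B": float(effect)},
        seed=seed,
        **kwargs,
    )
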