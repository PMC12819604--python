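"""Synthetic two-group cohorts with modular regional covariance.

The generator emulates the tabular product of a volumetric morphometry
pipeline: one row per subject carrying a group label (patient/control),
clinical covariates, and mean gray-matter volume (GMV, mm^3) for each
atlas region.  Regional volumes are drawn from a multivariate normal
whose correlation matrix has

* a *floor* correlation shared by all region pairs (global morphometric
  covariance: body/head size, tissue quality),
* *modules* — blocks of neighbouring homotopic pairs with elevated
  within-block correlation (local structural covariance), and
* an extra *homotopic boost* between left/right homologs, reproducing the
  strong mirror-symmetric covariance seen in empirical gray-matter
  correlation matrices.

Module size is deliberately small (three homotopic pairs, i.e. six
regions, by default) so that at 10% network density the strongest
correlations do not exhaust the edge budget within modules: roughly 225
of the top 400 edges are intramodular and the remaining ~175 bridge
modules, which keeps the thresholded network connected at the bottom of
the density sweep.  Coarser modules (whole lobes) would own more pairs
than the 10% edge budget and fragment the network.

Group effects are configurable and echoed by :func:`ground_truth` so
recovery experiments can be scored:

* ``group_effect`` — per-region mean shift (in units of that region's
  noise SD) added for patients; visible to morphometry, invisible to the
  correlation network.
* ``group_decoupling`` — per-region factor ``f`` in [0, 1] scaling the
  patient-group correlations of that region (``f=1`` no change, ``f=0``
  fully decorrelated); this is the knob that moves network topology.
  Positive semi-definiteness is preserved by construction
  (``C' = D C D + (I - D^2)`` with ``D = diag(f_i)``).
* ``psqi_effect`` — within-patient slope of volume on the PSQI score
  (SD units per point), for the regression-recovery experiments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .atlas import Atlas, aal90, generic_atlas

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "ground_truth",
    "build_correlation",
    "default_modules",
    "write_cohort",
    "read_cohort",
    "COVARIATE_COLUMNS",
]

COVARIATE_COLUMNS = ["age", "sex", "education", "tiv", "hama", "hamd", "psqi"]

#: reference values at which covariate effects are centred, so that the
#: per-region baseline mean stays the mean volume of an average subject.
_COVARIATE_REFERENCE = {
    "age": 37.5,
    "sex": 0.67,
    "education": 15.0,
    "tiv": 1445.0,
    "hama": 0.0,
    "hamd": 0.0,
    "psqi": 0.0,
}


@dataclass
class CohortConfig:
    """Full parameterisation of a synthetic cohort.

    Defaults encode the study conditions: 82 patients vs 73 controls, 90
    AAL regions, patient PSQI >= 8 and control PSQI <= 7, and anxiety /
    depression scores strongly elevated in patients.
    """

    n_patients: int = 82
    n_controls: int = 73
    n_regions: int = 90
    module_assignment: np.ndarray | None = None  # region -> module id, 0-based
    within_block_correlation: float = 0.8
    between_block_correlation: float = 0.55
    homotopic_boost: float = 0.2
    kernel_amplitude: float = 0.25  # smooth distance-decaying covariance
    kernel_scale_pairs: float = 6.0  # decay scale, in homotopic-pair steps
    heterogeneity_weight: float = 0.3  # blend weight of the random-factor part
    heterogeneity_rank: int = 6  # number of latent anatomical factors
    structure_seed: int = 2021  # fixes the anatomy, independent of the cohort seed
    baseline_mean: float | np.ndarray = 6000.0  # mm^3
    noise_sd: float | np.ndarray = 600.0  # mm^3
    group_effect: dict[str, float] = field(default_factory=dict)  # SD units
    group_decoupling: dict[str, float] = field(default_factory=dict)  # [0,1]
    psqi_effect: dict[str, float] = field(default_factory=dict)  # SD / point
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": -6.0, "tiv": 1.5, "sex": -120.0}
    )  # mm^3 per covariate unit, same slope for every region
    correlation_override: np.ndarray | None = None
    seed: int = 0

    def atlas(self) -> Atlas:
        return aal90() if self.n_regions == 90 else generic_atlas(self.n_regions)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.n_patients < 3 or self.n_controls < 3:
            raise ValueError("need at least 3 subjects per group")
        if not (0 <= self.within_block_correlation < 1):
            raise ValueError("within_block_correlation must be in [0, 1)")
        if not (0 <= self.between_block_correlation <= self.within_block_correlation):
            raise ValueError(
                "between_block_correlation must be in [0, within_block_correlation]"
            )
        names = set(self.atlas().names)
        for label, mapping in [
            ("group_effect", self.group_effect),
            ("group_decoupling", self.group_decoupling),
            ("psqi_effect", self.psqi_effect),
        ]:
            unknown = set(mapping) - names
            if unknown:
                raise ValueError(f"{label} names unknown regions: {sorted(unknown)}")
        for region, f in self.group_decoupling.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"group_decoupling[{region}] must be in [0, 1]")
        unknown_cov = set(self.covariate_effects) - set(COVARIATE_COLUMNS)
        if unknown_cov:
            raise ValueError(f"covariate_effects names unknown covariates: {sorted(unknown_cov)}")
        build_correlation(self)  # raises on non-PSD

    # -- (de)serialisation ----------------------------------------------

    def to_yaml(self) -> str:
        d = asdict(self)
        for key in ("module_assignment", "correlation_override"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        if isinstance(d["baseline_mean"], np.ndarray):
            d["baseline_mean"] = d["baseline_mean"].tolist()
        if isinstance(d["noise_sd"], np.ndarray):
            d["noise_sd"] = d["noise_sd"].tolist()
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortConfig":
        d = yaml.safe_load(io.StringIO(text)) or {}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("module_assignment", "correlation_override"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key])
        return cls(**d)


def default_modules(atlas: Atlas, pairs_per_module: int = 3) -> np.ndarray:
    """Assign regions to covariance modules of consecutive homotopic pairs.

    With the AAL ordering (left/right alternating) this groups
    ``2 * pairs_per_module`` neighbouring regions per module, keeping each
    homotopic pair inside one module.
    """
    n = atlas.n_regions
    return np.arange(n) // (2 * pairs_per_module)


def build_correlation(config: CohortConfig) -> np.ndarray:
    """The population correlation matrix implied by a config (control group).

    Raises ``ValueError`` naming the offending parameters if the implied
    matrix is not positive semi-definite.
    """
    R = config.n_regions
    if config.correlation_override is not None:
        C = np.asarray(config.correlation_override, dtype=float)
        if C.shape != (R, R):
            raise ValueError(f"correlation_override must be {R}x{R}")
        source = "correlation_override"
    else:
        atlas = config.atlas()
        modules = (
            np.asarray(config.module_assignment)
            if config.module_assignment is not None
            else default_modules(atlas)
        )
        if modules.shape != (R,):
            raise ValueError("module_assignment must give one module id per region")
        C = np.full((R, R), config.between_block_correlation)
        same = modules[:, None] == modules[None, :]
        C[same] = config.within_block_correlation
        if config.kernel_amplitude > 0:
            # smooth distance-decaying component: homotopic pairs share an
            # angle on a ring, the Gaussian kernel of the chordal distance
            # gives every pair a graded correlation instead of a flat floor
            n_pairs = max((R + 1) // 2, 2)
            angle = 2 * np.pi * (np.arange(R) // 2) / n_pairs
            xy = np.column_stack([np.cos(angle), np.sin(angle)])
            D2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
            s = 2 * np.sin(np.pi * config.kernel_scale_pairs / n_pairs)
            C = C + config.kernel_amplitude * np.exp(-D2 / s**2)
        for i, j in atlas.homotopic_pairs():
            C[i, j] = C[j, i] = C[i, j] + config.homotopic_boost
        C = np.minimum(C, 0.95)
        np.fill_diagonal(C, 1.0)
        w = config.heterogeneity_weight
        if w > 0:
            # fixed random-factor component: graded pair-level heterogeneity
            # plus long-range shortcuts, the same "anatomy" for every cohort
            if not (0 <= w < 1) or config.heterogeneity_rank < 1:
                raise ValueError(
                    "need 0 <= heterogeneity_weight < 1 and heterogeneity_rank >= 1"
                )
            srng = np.random.default_rng(config.structure_seed)
            G = srng.standard_normal((R, config.heterogeneity_rank))
            S = G @ G.T
            d = np.sqrt(np.diag(S))
            H = S / np.outer(d, d)
            C = (1 - w) * C + w * H  # convex blend of correlation matrices
            np.fill_diagonal(C, 1.0)
        source = (
            f"within_block_correlation={config.within_block_correlation}, "
            f"between_block_correlation={config.between_block_correlation}, "
            f"homotopic_boost={config.homotopic_boost}, "
            f"kernel_amplitude={config.kernel_amplitude}, "
            f"kernel_scale_pairs={config.kernel_scale_pairs}"
        )
    if not np.allclose(C, C.T):
        raise ValueError(f"implied correlation matrix not symmetric ({source})")
    eigvals = np.linalg.eigvalsh(C)
    min_eig = float(eigvals[0])
    tol = -1e-8 if config.correlation_override is not None else -5e-3
    if min_eig < tol:
        raise ValueError(
            f"implied correlation matrix is not positive semi-definite "
            f"(min eigenvalue {min_eig:.3g}); offending parameters: {source}"
        )
    if min_eig < 0:
        # additive boosts can leave a numerically marginal deficit; project
        # onto the nearest PSD correlation (eigenvalue clip + renormalize)
        vals, vecs = np.linalg.eigh(C)
        C = (vecs * np.maximum(vals, 1e-8)) @ vecs.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
    return C


def _patient_correlation(config: CohortConfig, C: np.ndarray) -> np.ndarray:
    """Apply per-region decoupling to the patient group's correlation."""
    if not config.group_decoupling:
        return C
    names = config.atlas().names
    d = np.ones(config.n_regions)
    for region, f in config.group_decoupling.items():
        d[names.index(region)] = f
    Cp = (d[:, None] * C * d[None, :]) + np.diag(1.0 - d**2)
    return Cp


def _draw_scores(rng, n, mean, sd, lo, hi):
    return np.clip(np.round(rng.normal(mean, sd, n)), lo, hi).astype(int)


def _simulate_covariates(rng: np.random.Generator, n: int, patient: bool) -> pd.DataFrame:
    """Covariates drawn independently, group-shifted for the clinical scores."""
    age = np.round(np.clip(rng.normal(37.5, 11.0, n), 18, 70), 1)
    sex = (rng.random(n) < 0.67).astype(int)  # 1 = female
    education = _draw_scores(rng, n, 15.0, 3.0, 6, 22)
    tiv = np.round(rng.normal(1445.0, 115.0, n), 1)
    if patient:
        hama = _draw_scores(rng, n, 13.0, 5.0, 0, 56)
        hamd = _draw_scores(rng, n, 11.5, 5.0, 0, 52)
        psqi = _draw_scores(rng, n, 15.0, 2.5, 8, 21)
    else:
        hama = _draw_scores(rng, n, 1.5, 1.5, 0, 56)
        hamd = _draw_scores(rng, n, 1.0, 1.5, 0, 52)
        psqi = _draw_scores(rng, n, 2.0, 1.5, 0, 7)
    return pd.DataFrame(
        {"age": age, "sex": sex, "education": education, "tiv": tiv,
         "hama": hama, "hamd": hamd, "psqi": psqi}
    )


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a full cohort table; identical seeds give identical tables.

    Returns a DataFrame with columns ``subject_id, group, age, sex,
    education, tiv, hama, hamd, psqi`` followed by one volume column per
    atlas region (mm^3, strictly positive).  Patients come first.
    """
    config.validate()
    atlas = config.atlas()
    R = config.n_regions
    rng = np.random.default_rng(config.seed)

    C = build_correlation(config)
    C_patient = _patient_correlation(config, C)
    # cholesky with a whisper of jitter to tolerate exactly-singular PSD inputs
    jitter = 1e-10 * np.eye(R)
    L_pat = np.linalg.cholesky(C_patient + jitter)
    L_con = np.linalg.cholesky(C + jitter)

    baseline = np.broadcast_to(np.asarray(config.baseline_mean, float), (R,))
    sd = np.broadcast_to(np.asarray(config.noise_sd, float), (R,))

    names = atlas.names
    shift = np.zeros(R)
    for region, s in config.group_effect.items():
        shift[names.index(region)] = s
    psqi_slope = np.zeros(R)
    for region, s in config.psqi_effect.items():
        psqi_slope[names.index(region)] = s

    frames = []
    for group, n, L in [
        ("patient", config.n_patients, L_pat),
        ("control", config.n_controls, L_con),
    ]:
        cov = _simulate_covariates(rng, n, patient=group == "patient")
        z = rng.standard_normal((n, R)) @ L.T
        vol = baseline + sd * z
        for c, slope in config.covariate_effects.items():
            vol = vol + slope * (
                np.asarray(cov[c], float) - _COVARIATE_REFERENCE[c]
            )[:, None]
        if group == "patient":
            vol = vol + sd * shift
            # centre the PSQI effect at the patient mean so it does not
            # double as an extra group mean shift
            psqi_c = np.asarray(cov["psqi"], float) - cov["psqi"].mean()
            vol = vol + psqi_c[:, None] * (sd * psqi_slope)
        vol = np.maximum(vol, 0.01 * baseline)  # anatomical positivity floor
        df = pd.DataFrame(vol, columns=names)
        df.insert(0, "group", group)
        frames.append(pd.concat([df[["group"]], cov, df[names]], axis=1))

    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject_id", [f"sub-{i + 1:03d}" for i in range(len(out))])
    return out


def ground_truth(config: CohortConfig) -> pd.DataFrame:
    """Echo the injected effects, one row per region, for recovery scoring."""
    config.validate()
    names = config.atlas().names
    gt = pd.DataFrame(
        {
            "region": names,
            "mean_shift_sd": [config.group_effect.get(r, 0.0) for r in names],
            "psqi_slope_sd": [config.psqi_effect.get(r, 0.0) for r in names],
            "decoupling": [config.group_decoupling.get(r, 1.0) for r in names],
        }
    )
    return gt


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path, atlas: Atlas | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV (see :mod:`scngraph.pipeline` checks)."""
    from .pipeline import validate_cohort

    df = pd.read_csv(path)
    validate_cohort(df, atlas=atlas)
    return df
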