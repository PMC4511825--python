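"""Synthetic trait tables and balance logs with the statistical structure
the analysis stages assume.

Tree-level trait values are drawn from a Gaussian copula with lognormal
marginals: per zone, a multivariate normal is sampled on the log scale
with standard deviation sigma_log = sqrt(ln(1 + CV^2)) per trait and the
configured correlation matrix applied on the log scale, then
exponentiated with the log-mean chosen so the marginal *mean* equals the
configured trait mean exactly (mu_log = ln(mean) - sigma_log^2 / 2).
Lognormal marginals guarantee positivity — densities, LMA and
conductivities are all positive quantities — and make the generator
consistent with the integration stage, which correlates log-transformed
tree means.

Replicate-level values scatter around each tree value with a
configurable within-tree CV (same lognormal construction, mean equal to
the tree value).

Seeding: a single master seed; each (patch, zone) gets an independent
stream derived from ``SeedSequence([master, crc32(patch_id), zone_index,
stream])`` so adding or removing one patch never perturbs the draws of
another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data_model import ZONES, TraitTable
from .hydraulics import FlowLog
from .integration import CorrelationMatrix


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


class NotPositiveDefiniteError(ConfigError):
    """Target correlation matrix is not positive definite.

    Pass ``repair=True`` to :func:`generate_trait_data` to project the
    matrix onto the nearest positive-definite correlation matrix
    (eigenvalue clipping); the repair is reported in the table metadata.
    """


def _sigma_log(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _lognormal_around(mean: float, cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Lognormal draws with exact population mean ``mean`` and CV ``cv``."""
    if cv == 0:
        return np.full(size, float(mean))
    s = _sigma_log(cv)
    return rng.lognormal(np.log(mean) - 0.5 * s * s, s, size=size)


def nearest_positive_definite(r: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix onto a nearby PD correlation matrix by
    clipping eigenvalues at ``floor`` and renormalising the diagonal."""
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    fixed = (v * np.clip(w, floor, None)) @ v.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


@dataclass(frozen=True)
class ZoneConfig:
    """Generating distribution for the trees of one zone of one patch."""

    zone: str
    n_trees: int
    trait_means: dict[str, float]
    trait_cvs: dict[str, float]
    correlation: CorrelationMatrix | None = None
    n_replicates: dict[str, int] = field(default_factory=dict)
    within_tree_cv: float = 0.1

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ConfigError(f"unknown zone {self.zone!r}; expected one of {list(ZONES)}")
        if self.n_trees <= 0:
            raise ConfigError(f"n_trees must be positive, got {self.n_trees}")
        for trait, mean in self.trait_means.items():
            if mean <= 0:
                raise ConfigError(f"mean of {trait!r} must be positive, got {mean}")
        for trait, cv in self.trait_cvs.items():
            if trait not in self.trait_means:
                raise ConfigError(f"CV given for unknown trait {trait!r}")
            if not 0 <= cv < 2:
                raise ConfigError(
                    f"CV of {trait!r} must be in [0, 2) for a sane lognormal, got {cv}"
                )
        if self.correlation is not None:
            extra = set(self.correlation.trait_names) - set(self.trait_means)
            if extra:
                raise ConfigError(f"correlated traits missing from trait_means: {sorted(extra)}")
        for trait, n in self.n_replicates.items():
            if n <= 0:
                raise ConfigError(f"n_replicates of {trait!r} must be positive, got {n}")
        if self.within_tree_cv < 0:
            raise ConfigError("within_tree_cv must be >= 0")


@dataclass(frozen=True)
class PatchConfig:
    patch_id: str
    size_class: str
    zones: dict[str, ZoneConfig]

    def __post_init__(self) -> None:
        if self.size_class not in ("small", "large"):
            raise ConfigError(f"size_class must be small or large, got {self.size_class!r}")
        for name, zc in self.zones.items():
            if name != zc.zone:
                raise ConfigError(f"zone key {name!r} disagrees with ZoneConfig.zone {zc.zone!r}")


@dataclass(frozen=True)
class SimulationConfig:
    patches: list[PatchConfig]
    seed: int

    def __post_init__(self) -> None:
        ids = [p.patch_id for p in self.patches]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"patch_ids must be unique, got {ids}")
        if not self.patches:
            raise ConfigError("at least one patch required")


def _zone_seed(master: int, patch_id: str, zone: str, stream: int) -> np.random.Generator:
    """Independent, order-insensitive stream per (patch, zone, purpose)."""
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(master), zlib.crc32(patch_id.encode()), ZONES.index(zone), stream]
        )
    )


def _draw_tree_values(zc: ZoneConfig, rng: np.random.Generator, repair: bool) -> pd.DataFrame:
    """Tree-level latent trait values for one zone (rows = trees)."""
    traits = list(zc.trait_means)
    out = {}
    correlated: tuple[str, ...] = ()
    if zc.correlation is not None:
        correlated = zc.correlation.trait_names
        r = zc.correlation.r
        sigmas = np.array([_sigma_log(zc.trait_cvs.get(t, 0.0)) for t in correlated])
        # zero-CV traits are degenerate: drop them from the copula draw
        active = sigmas > 0
        r_act = r[np.ix_(active, active)]
        try:
            chol = np.linalg.cholesky(r_act)
        except np.linalg.LinAlgError:
            if not repair:
                raise NotPositiveDefiniteError(
                    "target correlation matrix is not positive definite; "
                    "pass repair=True to project onto the nearest PD correlation matrix"
                ) from None
            chol = np.linalg.cholesky(nearest_positive_definite(r_act))
        z = rng.standard_normal((zc.n_trees, int(active.sum()))) @ chol.T
        log_values = np.zeros((zc.n_trees, len(correlated)))
        log_values[:, active] = z * sigmas[active]
        for j, trait in enumerate(correlated):
            mean, s = zc.trait_means[trait], sigmas[j]
            out[trait] = np.exp(np.log(mean) - 0.5 * s * s + log_values[:, j])
    for trait in traits:
        if trait in correlated:
            continue
        out[trait] = _lognormal_around(zc.trait_means[trait], zc.trait_cvs.get(trait, 0.0),
                                       zc.n_trees, rng)
    return pd.DataFrame(out, columns=traits)


def generate_trait_data(cfg: SimulationConfig, repair: bool = False) -> TraitTable:
    """Simulate a replicate-level trait table from a stated design.

    Deterministic: the same config and seed reproduce the table bit for
    bit.  ``repair=True`` opts in to nearest-PD repair of a
    non-positive-definite target correlation.
    """
    rows = []
    for patch in cfg.patches:
        for zone in ZONES:
            if zone not in patch.zones:
                continue
            zc = patch.zones[zone]
            tree_rng = _zone_seed(cfg.seed, patch.patch_id, zone, 0)
            rep_rng = _zone_seed(cfg.seed, patch.patch_id, zone, 1)
            trees = _draw_tree_values(zc, tree_rng, repair)
            for i in range(zc.n_trees):
                tree_id = f"{patch.patch_id}-{zone}-t{i + 1:03d}"
                for trait in trees.columns:
                    n_rep = zc.n_replicates.get(trait, 1)
                    tree_value = trees.iloc[i][trait]
                    reps = _lognormal_around(tree_value, zc.within_tree_cv, n_rep, rep_rng)
                    for j in range(n_rep):
                        rows.append(
                            (patch.patch_id, patch.size_class, zone, tree_id,
                             trait, f"r{j + 1:02d}", reps[j])
                        )
    df = pd.DataFrame(
        rows,
        columns=["patch_id", "patch_size_class", "zone", "tree_id",
                 "trait_name", "replicate_id", "value"],
    )
    return TraitTable(df)


def generate_flow_log(
    true_flow: float,
    duration_s: float,
    interval_s: float = 15.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FlowLog:
    """Simulate a balance log: cumulative mass = flow * t + Gaussian noise.

    The 15 s default matches the cadence at which a lab balance is read
    during a conductivity measurement.
    """
    if true_flow < 0:
        raise ConfigError(f"true_flow must be >= 0, got {true_flow}")
    if duration_s < interval_s:
        raise ConfigError("duration must cover at least one interval")
    if noise_sd < 0:
        raise ConfigError(f"noise_sd must be >= 0, got {noise_sd}")
    t = np.arange(0.0, duration_s + 1e-9, interval_s)
    mass = true_flow * t
    if noise_sd > 0:
        mass = mass + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.size)
    return FlowLog(t, mass)


def generate_null_cv_groups(
    n_groups: int,
    n_per_group: int,
    common_cv: float,
    mean: float,
    seed: int = 0,
) -> list[np.ndarray]:
    """Lognormal groups sharing one population CV — a null world for
    calibrating the CV-equality test's type-I error."""
    if n_per_group < 3:
        raise ConfigError(f"n_per_group must be >= 3, got {n_per_group}")
    if n_groups < 1:
        raise ConfigError("need at least one group")
    if common_cv <= 0 or mean <= 0:
        raise ConfigError("common_cv and mean must be positive")
    rng = np.random.default_rng(seed)
    return [_lognormal_around(mean, common_cv, n_per_group, rng) for _ in range(n_groups)]


# ---------------------------------------------------------------------------
# YAML config loading


def _zone_config_from_dict(zone: str, d: dict) -> ZoneConfig:
    corr = None
    if "correlation" in d and d["correlation"] is not None:
        c = d["correlation"]
        corr = CorrelationMatrix.from_upper_triangle(c["traits"], c["upper_triangle"])
    return ZoneConfig(
        zone=zone,
        n_trees=int(d["n_trees"]),
        trait_means={k: float(v) for k, v in d["trait_means"].items()},
        trait_cvs={k: float(v) for k, v in d.get("trait_cvs", {}).items()},
        correlation=corr,
        n_replicates={k: int(v) for k, v in d.get("n_replicates", {}).items()},
        within_tree_cv=float(d.get("within_tree_cv", 0.1)),
    )


def load_simulation_config(path, seed: int | None = None) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML.

    Layout: top-level ``seed`` and ``patches`` (list of mappings with
    ``patch_id``, ``size_class`` and ``zones``); each zone mapping gives
    ``n_trees``, ``trait_means``, ``trait_cvs``, optional ``correlation``
    (``traits`` + row-major ``upper_triangle``), ``n_replicates`` and
    ``within_tree_cv``.  ``seed`` overrides the file's value when given.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "patches" not in raw:
        raise ConfigError("config must be a mapping with a 'patches' list")
    patches = []
    for p in raw["patches"]:
        zones = {z: _zone_config_from_dict(z, zd) for z, zd in p["zones"].items()}
        patches.append(PatchConfig(p["patch_id"], p["size_class"], zones))
    if seed is None:
        seed = int(raw.get("seed", 0))
    return SimulationConfig(patches=patches, seed=int(seed))
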