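"""Domain types and I/O for long-format trait tables.

The sampling design this package targets is a nested field layout: trees
sampled in three fog-exposure zones (windward edge, patch core, leeward
edge) within forest patches of two size classes.  Measurements arrive as
replicate-level records (e.g. ten leaves per tree) and are collapsed to
tree-level means before any downstream statistics: the tree is the
sampling unit for CV comparison and integration analyses.

Water-potential traits are stored as positive magnitudes of -psi (MPa),
so a drier tree has a *larger* stored value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ZONES: tuple[str, ...] = ("windward", "core", "leeward")
PATCH_SIZE_CLASSES: tuple[str, ...] = ("small", "large")

#: canonical trait symbols; all are stored as positive magnitudes
TRAIT_NAMES: tuple[str, ...] = (
    "SM",      # volumetric soil moisture, %
    "psi_PD",  # predawn water potential magnitude, MPa
    "psi_MD",  # midday water potential magnitude, MPa
    "SD",      # stomatal density, mm^-2
    "TD",      # trichome density, mm^-2
    "LMA",     # leaf mass per area, g m^-2
    "VD",      # vessel density, mm^-2
    "VDi",     # vessel diameter, um
    "Ks",      # sapwood-specific hydraulic conductivity, kg m^-1 s^-1 MPa^-1
)

#: five morphological traits used for correlation matrices, in table order
MORPHOLOGICAL_TRAITS: tuple[str, ...] = ("SD", "TD", "LMA", "VD", "VDi")

REQUIRED_COLUMNS: tuple[str, ...] = (
    "patch_id",
    "patch_size_class",
    "zone",
    "tree_id",
    "trait_name",
    "replicate_id",
    "value",
)

KEY_COLUMNS: tuple[str, ...] = (
    "patch_id",
    "zone",
    "tree_id",
    "trait_name",
    "replicate_id",
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A record violates a domain invariant (zone label, sign, uniqueness)."""


@dataclass(frozen=True)
class TraitTable:
    """Long-format replicate-level trait measurements.

    One row per (patch, zone, tree, trait, replicate).  Validated on
    construction: zones and patch size classes come from closed sets, the
    key is unique, and all values are positive magnitudes (strictly
    positive except water potentials, which may be zero at saturation).
    """

    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.records
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column: {col!r}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        for col in KEY_COLUMNS + ("patch_size_class",):
            df[col] = df[col].astype(str)

        bad_zone = set(df["zone"]) - set(ZONES)
        if bad_zone:
            raise ValidationError(
                f"unknown zone label(s) {sorted(bad_zone)}; expected one of {list(ZONES)}"
            )
        bad_size = set(df["patch_size_class"]) - set(PATCH_SIZE_CLASSES)
        if bad_size:
            raise ValidationError(
                f"unknown patch_size_class {sorted(bad_size)}; "
                f"expected one of {list(PATCH_SIZE_CLASSES)}"
            )

        raw = df["value"].tolist()
        values = np.empty(len(raw))
        for row, v in enumerate(raw):
            try:
                values[row] = float(v)  # exact: to_numeric's parser is lossy
            except (TypeError, ValueError):
                raise ValidationError(f"non-numeric value at row {row}: {v!r}") from None
        if np.isnan(values).any():
            row = int(np.flatnonzero(np.isnan(values))[0])
            raise ValidationError(f"non-numeric value at row {row}: {raw[row]!r}")
        df["value"] = values

        if df.duplicated(list(KEY_COLUMNS)).any():
            dup = df[df.duplicated(list(KEY_COLUMNS), keep=False)]
            key = tuple(dup.iloc[0][list(KEY_COLUMNS)])
            raise ValidationError(f"duplicate measurement key {key}")

        psi = df["trait_name"].str.startswith("psi")
        if (df.loc[psi, "value"] < 0).any():
            raise ValidationError("water-potential magnitudes must be >= 0")
        if (df.loc[~psi, "value"] <= 0).any():
            bad = df.loc[~psi & (df["value"] <= 0)].iloc[0]
            raise ValidationError(
                f"trait {bad['trait_name']!r} requires strictly positive values, "
                f"got {bad['value']}"
            )

        object.__setattr__(self, "records", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def trait_names(self) -> list[str]:
        return sorted(self.records["trait_name"].unique())

    def filter(
        self,
        *,
        zones: list[str] | None = None,
        patch_size_class: str | None = None,
        patches: list[str] | None = None,
    ) -> "TraitTable":
        """Subset records by zone, patch size class, and/or patch id."""
        df = self.records
        if zones is not None:
            df = df[df["zone"].isin(zones)]
        if patch_size_class is not None:
            df = df[df["patch_size_class"] == patch_size_class]
        if patches is not None:
            df = df[df["patch_id"].isin(patches)]
        return TraitTable(df.reset_index(drop=True))


@dataclass(frozen=True)
class TreeTraitMatrix:
    """Tree-by-trait matrix of per-tree replicate means.

    ``data`` is indexed by (patch_id, zone, tree_id) with one column per
    trait; a cell is NaN when the tree had no replicate for that trait.
    ``patch_size_class`` maps patch_id to its size class.
    """

    data: pd.DataFrame = field(repr=False)
    patch_size_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.names != ["patch_id", "zone", "tree_id"]:
            raise ValidationError(
                "TreeTraitMatrix index must be (patch_id, zone, tree_id), "
                f"got {list(self.data.index.names)}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)

    def zone_values(self, zone: str, trait: str) -> np.ndarray:
        """Tree-level values of one trait in one zone, NaN cells dropped."""
        col = self.data.xs(zone, level="zone")[trait]
        return col.dropna().to_numpy()

    def zone_frame(self, zone: str, traits: list[str] | None = None) -> pd.DataFrame:
        """Trees-by-traits frame for one zone (rows may contain NaN)."""
        df = self.data.xs(zone, level="zone")
        return df if traits is None else df.loc[:, list(traits)]

    def restrict_patches(self, size_class: str | None = None) -> "TreeTraitMatrix":
        """Keep only trees from patches of the given size class."""
        if size_class is None:
            return self
        keep = [p for p, s in self.patch_size_class.items() if s == size_class]
        data = self.data[self.data.index.get_level_values("patch_id").isin(keep)]
        sizes = {p: s for p, s in self.patch_size_class.items() if p in keep}
        return TreeTraitMatrix(data, sizes)

    def to_csv(self, path) -> None:
        self.data.to_csv(path)


def read_trait_table(path) -> TraitTable:
    """Read and validate a long-format trait CSV.

    Expects UTF-8, comma-separated, decimal point, with a header row of
    at least ``REQUIRED_COLUMNS``.  Raises :class:`SchemaError` for a
    missing column and :class:`ValidationError` for bad values.
    """
    df = pd.read_csv(path, dtype=str, float_precision="round_trip")
    return TraitTable(df)


def write_trait_table(table: TraitTable, path) -> None:
    """Write a trait table as CSV with full float round-trip precision."""
    df = table.records.copy()
    df["value"] = df["value"].map(lambda v: np.format_float_positional(v, trim="0"))
    df.to_csv(path, index=False)


def tree_level_means(table: TraitTable) -> TreeTraitMatrix:
    """Collapse replicate measurements to one mean per tree and trait.

    Replicate leaves (or readings) average arithmetically within each
    tree; a trait missing for a tree stays absent (NaN), never zero.
    """
    if len(table) == 0:
        raise ValidationError("trait table is empty")
    df = table.records
    wide = df.pivot_table(
        index=["patch_id", "zone", "tree_id"],
        columns="trait_name",
        values="value",
        aggfunc="mean",
    )
    wide.columns.name = None
    # stable trait ordering: canonical names first, extras alphabetically
    order = [t for t in TRAIT_NAMES if t in wide.columns]
    order += sorted(c for c in wide.columns if c not in TRAIT_NAMES)
    sizes = dict(zip(df["patch_id"], df["patch_size_class"]))
    return TreeTraitMatrix(wide.loc[:, order], sizes)
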