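"""Bundled example inputs.

The numbers here are the published summary statistics of a field study of
*Aextoxicon punctatum* across fog-driven moisture gradients (windward
edge, core, leeward edge) in semiarid-Chile forest patches: per-zone
pairwise Pearson correlations among five morphological traits (stomatal
density SD, trichome density TD, leaf mass per area LMA, vessel density
VD, vessel diameter VDi), reported to two decimals, for trees pooled from
the two large patches (10 trees per zone).  Printed correlation tables
like these are valid direct inputs to the integration stage — no raw
trait data are needed to compute integration indices, mean r² or matrix
similarity from them.

The companion ``fray_jorge_like.yaml`` simulation config combines these
correlations with the study's zone means and CVs to emulate the field
design (5 trees x 3 zones x 4 patches).  Its values are realistic
paper-derived defaults for a stated synthetic world, not ground truth.
"""

from __future__ import annotations

from importlib import resources

from .data_model import MORPHOLOGICAL_TRAITS
from .integration import CorrelationMatrix

# upper triangle, row-major, trait order SD, TD, LMA, VD, VDi
_ZONE_UPPER_TRIANGLES: dict[str, tuple[float, ...]] = {
    "windward": (0.55, -0.03, -0.56, 0.16,
                 -0.22, -0.76, 0.11,
                 0.00, -0.27,
                 -0.16),
    "core": (0.34, -0.87, 0.04, 0.01,
             -0.25, 0.04, 0.05,
             -0.18, 0.06,
             -0.90),
    "leeward": (0.74, -0.75, 0.32, -0.29,
                -0.76, 0.41, -0.46,
                -0.75, 0.63,
                -0.73),
}


def zone_correlation_matrix(zone: str) -> CorrelationMatrix:
    """Published trait-correlation matrix for one moisture zone."""
    if zone not in _ZONE_UPPER_TRIANGLES:
        raise KeyError(f"no bundled matrix for zone {zone!r}")
    return CorrelationMatrix.from_upper_triangle(
        MORPHOLOGICAL_TRAITS, _ZONE_UPPER_TRIANGLES[zone]
    )


def zone_correlation_matrices() -> dict[str, CorrelationMatrix]:
    """All three published per-zone matrices, keyed by zone."""
    return {z: zone_correlation_matrix(z) for z in _ZONE_UPPER_TRIANGLES}


def fray_jorge_config_path():
    """Path to the bundled fog-forest-like simulation config (YAML)."""
    return resources.files("traitgrad") / "configs" / "fray_jorge_like.yaml"
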