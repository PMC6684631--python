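"""Global seafloor habitability and redox-zonation calculations.

Implements the conductive two-layer geotherm used to map depth to the
122 degC isotherm, spherical-area integration of per-area fields to global
volumes, the basement porosity column, depth-averaged sedimentation rates,
and the sediment-thickness / sedimentation-rate classifier that partitions
the seafloor into oxygen-to-basement, sulfate-to-basement and
sulfate-depleted zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EARTH_RADIUS_KM",
    "Grid",
    "GeothermParams",
    "BasementPorosityModel",
    "ZoneThresholds",
    "ZONES",
    "global_grid_edges",
    "isotherm_depth",
    "habitable_basement_thickness",
    "basement_pore_column",
    "mean_sedimentation_rate",
    "classify_zone",
    "integrate_volume",
    "zone_areas",
]

EARTH_RADIUS_KM = 6371.0

ZONES = ("oxic_to_basement", "sulfate_to_basement", "sulfate_depleted")


def global_grid_edges(resolution_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Regular global lat/lon cell edges at the given resolution."""
    n_lat = round(180.0 / resolution_deg)
    if abs(n_lat * resolution_deg - 180.0) > 1e-9:
        raise ValueError("resolution must divide 180 evenly")
    lat_edges = np.linspace(-90.0, 90.0, n_lat + 1)
    lon_edges = np.linspace(-180.0, 180.0, 2 * n_lat + 1)
    return lat_edges, lon_edges


@dataclass
class Grid:
    """Regular lat/lon field on cell centers with spherical cell areas.

    ``values`` has shape (nlat, nlon) ordered south-to-north along the edge
    arrays; longitudes live in [-180, 180).
    """

    lat_edges: np.ndarray
    lon_edges: np.ndarray
    values: np.ndarray
    units: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lat_edges = np.asarray(self.lat_edges, dtype=float)
        self.lon_edges = np.asarray(self.lon_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.lat_edges) <= 0) or np.any(np.diff(self.lon_edges) <= 0):
            raise ValueError("grid edges must be strictly increasing")
        expected = (self.lat_edges.size - 1, self.lon_edges.size - 1)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    def cell_areas_km2(self) -> np.ndarray:
        """Spherical cell areas R^2 * dlambda * (sin phi2 - sin phi1), km^2."""
        phi = np.radians(self.lat_edges)
        lam = np.radians(self.lon_edges)
        band = EARTH_RADIUS_KM**2 * np.diff(np.sin(phi))  # per radian of lon
        return np.outer(band, np.diff(lam))

    def same_layout(self, other: "Grid") -> bool:
        return (
            self.lat_edges.shape == other.lat_edges.shape
            and self.lon_edges.shape == other.lon_edges.shape
            and np.allclose(self.lat_edges, other.lat_edges)
            and np.allclose(self.lon_edges, other.lon_edges)
        )

    def like(self, values: np.ndarray, units: str = "") -> "Grid":
        """New grid with the same layout and different values."""
        return Grid(
            lat_edges=self.lat_edges,
            lon_edges=self.lon_edges,
            values=np.asarray(values, dtype=float),
            units=units,
        )


@dataclass(frozen=True)
class GeothermParams:
    """Two-layer conductive geotherm configuration."""

    t_seafloor: float = 2.0  # deg C
    k_sediment: float = 1.0  # W m^-1 K^-1
    k_basement: float = 2.0  # W m^-1 K^-1
    t_limit: float = 122.0  # deg C

    def __post_init__(self) -> None:
        if self.k_sediment <= 0 or self.k_basement <= 0:
            raise ValueError("conductivities must be positive")
        if self.t_limit <= self.t_seafloor:
            raise ValueError("temperature limit must exceed seafloor temperature")


@dataclass(frozen=True)
class BasementPorosityModel:
    """Basement porosity: constant in the upper layer, linear to zero below."""

    phi_upper: float = 0.10
    z_break: float = 500.0  # m into basement
    z_zero: float = 1000.0  # m into basement

    def __post_init__(self) -> None:
        if not (0 < self.phi_upper < 1):
            raise ValueError("phi_upper must be in (0, 1)")
        if not (0 < self.z_break < self.z_zero):
            raise ValueError("need 0 < z_break < z_zero")


@dataclass(frozen=True)
class ZoneThresholds:
    """Sediment-thickness / sedimentation-rate boundaries for zonation.

    A species disappears within the sediment column when thickness or rate
    *exceeds* its thresholds (strict comparisons; boundary cells stay in the
    less-reduced category).
    """

    o2_thickness_max: float = 150.0  # m
    o2_rate_max: float = 15.0  # m Myr^-1
    so4_thickness_max: float = 500.0  # m
    so4_rate_max: float = 35.0  # m Myr^-1

    def __post_init__(self) -> None:
        if (
            self.o2_thickness_max > self.so4_thickness_max
            or self.o2_rate_max > self.so4_rate_max
        ):
            raise ValueError("O2 thresholds must not exceed SO4 thresholds")


def isotherm_depth(heatflow, sediment_thickness, params: GeothermParams = GeothermParams()):
    """Depth below seafloor (m) where the conductive geotherm reaches t_limit.

    ``heatflow`` in mW m^-2; temperature rises at q/k_sediment within the
    sediment and q/k_basement below it. Vectorized over arrays.
    """
    q = np.asarray(heatflow, dtype=float) * 1e-3  # W m^-2
    h_sed = np.asarray(sediment_thickness, dtype=float)
    if np.any(q <= 0):
        raise ValueError("heat flow must be positive")
    if np.any(h_sed < 0):
        raise ValueError("sediment thickness must be non-negative")
    dt = params.t_limit - params.t_seafloor
    depth_in_sediment = params.k_sediment * dt / q
    within = depth_in_sediment <= h_sed
    t_base = params.t_seafloor + q * h_sed / params.k_sediment
    depth_below = h_sed + params.k_basement * (params.t_limit - t_base) / q
    result = np.where(within, depth_in_sediment, depth_below)
    return float(result) if result.shape == () else result


def habitable_basement_thickness(isotherm_depth_m, sediment_thickness):
    """Thickness of basement cooler than the limit: max(0, isotherm - sediment)."""
    iso = np.asarray(isotherm_depth_m, dtype=float)
    h_sed = np.asarray(sediment_thickness, dtype=float)
    if np.any(iso < 0) or np.any(h_sed < 0):
        raise ValueError("inputs must be non-negative")
    result = np.maximum(0.0, iso - h_sed)
    return float(result) if result.shape == () else result


def basement_pore_column(
    habitable_thickness, model: BasementPorosityModel = BasementPorosityModel()
):
    """Pore volume per unit area (m) in the habitable basement column.

    Integrates phi(z): phi_upper down to z_break, then linear to zero at
    z_zero; nothing below z_zero contributes.
    """
    h = np.asarray(habitable_thickness, dtype=float)
    if np.any(h < 0):
        raise ValueError("habitable thickness must be non-negative")
    h_eff = np.minimum(h, model.z_zero)
    upper = model.phi_upper * np.minimum(h_eff, model.z_break)
    # linear segment: phi(z) = phi_upper * (z_zero - z)/(z_zero - z_break)
    z1 = np.clip(h_eff, model.z_break, model.z_zero)
    span = model.z_zero - model.z_break
    lower = (
        model.phi_upper
        / span
        * ((model.z_zero - model.z_break) * (z1 - model.z_break) - 0.5 * (z1 - model.z_break) ** 2)
    )
    result = upper + lower
    return float(result) if result.shape == () else result


def mean_sedimentation_rate(thickness, basement_age):
    """Depth-averaged sedimentation rate, m Myr^-1 = thickness / age."""
    h = np.asarray(thickness, dtype=float)
    age = np.asarray(basement_age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("basement age must be positive")
    result = h / age
    return float(result) if result.shape == () else result


def classify_zone(
    thickness, sed_rate, thresholds: ZoneThresholds = ZoneThresholds()
):
    """Classify seafloor cells by electron-acceptor penetration.

    Returns string category for scalars, or an integer array indexing
    :data:`ZONES` for array inputs.
    """
    h = np.asarray(thickness, dtype=float)
    r = np.asarray(sed_rate, dtype=float)
    if np.any(h < 0) or np.any(r < 0):
        raise ValueError("inputs must be non-negative")
    sulfate_gone = (h > thresholds.so4_thickness_max) | (r > thresholds.so4_rate_max)
    oxic = (h <= thresholds.o2_thickness_max) & (r <= thresholds.o2_rate_max)
    codes = np.where(sulfate_gone, 2, np.where(oxic, 0, 1))
    if codes.shape == ():
        return ZONES[int(codes)]
    return codes


def integrate_volume(per_area_field: Grid, mask: Grid | None = None) -> float:
    """Spatially integrate a per-area field (m) to a volume in km^3."""
    areas = per_area_field.cell_areas_km2()
    values_km = per_area_field.values * 1e-3  # m -> km
    if mask is not None:
        if not per_area_field.same_layout(mask):
            raise ValueError("mask grid layout does not match field")
        weights = np.asarray(mask.values, dtype=float)
        values_km = values_km * weights
    return float(np.sum(areas * values_km))


def zone_areas(
    thickness: Grid,
    age: Grid,
    thresholds: ZoneThresholds = ZoneThresholds(),
    ocean_mask: Grid | None = None,
) -> dict[str, dict[str, float]]:
    """Per-zone spherical areas (km^2) and fractional coverage of the mask.

    ``ocean_mask`` values are 0/1 weights; without one, the whole grid is
    treated as ocean. Fractions sum to 1 over the masked area.
    """
    if not thickness.same_layout(age):
        raise ValueError("thickness and age grids are not co-registered")
    if ocean_mask is not None and not thickness.same_layout(ocean_mask):
        raise ValueError("ocean mask layout does not match grids")

    rate = mean_sedimentation_rate(thickness.values, age.values)
    codes = classify_zone(thickness.values, rate, thresholds)
    areas = thickness.cell_areas_km2()
    weights = ocean_mask.values if ocean_mask is not None else np.ones_like(areas)

    total = float(np.sum(areas * weights))
    out: dict[str, dict[str, float]] = {}
    for idx, zone in enumerate(ZONES):
        zone_area = float(np.sum(areas * weights * (codes == idx)))
        out[zone] = {
            "area_km2": zone_area,
            "fraction": zone_area / total if total > 0 else float("nan"),
        }
    return out
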