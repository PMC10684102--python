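"""Synthetic cortical sheet generator.

Produces every input the covariance pipeline consumes — a sphere-topology
mesh with inflated/sphere companions, a contiguous parcellation, 6-layer
thickness fields with a planted supra-to-infragranular axis and a
curvature coupling, depth-intensity profiles, directed connectivity with
a planted node hierarchy, and SC/FC matrices with planted distance and
similarity dependencies — so each downstream stage can be validated
against known ground truth.

The planted structure mirrors what the analyses assume about real cortex:
relative thickness of layers II-IV rises monotonically along one spatial
axis while layers V-VI fall; curvature locally depresses superficial
thickness; hierarchically higher regions exert more directed influence
than they receive; structural connections are more likely, and functional
connections stronger, between nearby and laminar-similar regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import trimesh
from scipy.sparse.csgraph import dijkstra
from scipy.special import sph_harm_y

from ._rng import child_rng
from .surface import (
    OFF_PARCEL,
    CORTICAL_TYPES,
    Parcellation,
    SurfaceMesh,
    VertexMap,
    disk_smooth,
    parcel_centroids,
)

__all__ = [
    "SimulationConfig",
    "LaminarThicknessMap",
    "IntensityProfileMap",
    "DirectedConnectivity",
    "make_icosphere",
    "make_parcellation",
    "sample_laminar_thickness",
    "sample_intensity_profiles",
    "sample_effective_connectivity",
    "sample_sc_fc",
    "assign_cortical_types",
]

#: Baseline relative thickness of layers I..VI (fractions of total depth).
BASE_FRACTIONS = np.array([0.08, 0.08, 0.22, 0.08, 0.24, 0.30])

#: Per-layer trend of relative thickness along the planted axis a(v) in [0, 1]:
#: each layer follows a logistic transition with its own amplitude and
#: midpoint (different layers shift at different cortical loci), and the mean
#: deviation across layers is subtracted at every a, so the fractions remain a
#: probability vector. Supragranular II-III and granular IV rise monotonically
#: in a, infragranular V-VI fall; layer I stays nearly flat. The staggered
#: midpoints make the profile family trace a curved (not affine) trajectory in
#: layer space — as real laminar profiles do — which is what lets profile
#: covariance recover the full ordering instead of collapsing the partial
#: correlation to a two-block sign pattern.
AXIS_TREND_AMPLITUDE = np.array([0.00, 0.06, 0.12, 0.07, -0.10, -0.15])
AXIS_TREND_MIDPOINT = np.array([0.50, 0.35, 0.55, 0.70, 0.45, 0.60])
AXIS_TREND_WIDTH = 0.18


def axis_profile_deviation(a: np.ndarray) -> np.ndarray:
    """Deviation of the 6-layer fraction profile from baseline at axis position a."""
    a = np.asarray(a, dtype=float)
    t = (a[..., None] - AXIS_TREND_MIDPOINT) / AXIS_TREND_WIDTH
    dev = AXIS_TREND_AMPLITUDE / (1.0 + np.exp(-t))
    return dev - dev.mean(axis=-1, keepdims=True)

#: Superficial layers affected by the curvature coupling.
SUPERFICIAL = slice(0, 3)

#: Baseline staining-intensity level per layer (unitless; layer IV densest).
BASE_INTENSITY = np.array([0.30, 0.60, 0.50, 0.90, 0.55, 0.45])

#: Per-layer intensity slope along the planted axis (layer IV strongest).
INTENSITY_SLOPES = np.array([0.05, 0.10, 0.10, 0.30, 0.05, 0.05])


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cortex; the seed fully determines every output."""

    seed: int = 0
    n_parcels: int = 500
    mesh_subdivisions: int = 5
    radius_mm: float = 70.0
    inflated_radius_mm: float = 70.0
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    curvature_coupling: float = 0.015
    spatial_smoothness_mm: float = 10.0
    noise_sd: float = 0.02
    total_thickness_mm: float = 2.5
    total_thickness_sd: float = 0.15
    # directed-connectivity generator
    hierarchy_spread: float = 1.0
    ec_distance_scale_mm: float = 40.0
    ec_asymmetry_gain: float = 0.5
    ec_noise_sd: float = 0.05
    # SC / FC generator
    sc_beta0: float = -1.0
    sc_beta_ltc: float = 2.0
    sc_beta_gd: float = -2.0
    fc_decay_mm: float = 30.0
    fc_ltc_gain: float = 0.3
    fc_noise_sd: float = 0.05
    # cortical-type assignment
    type_label_noise: float = 0.05

    def __post_init__(self) -> None:
        for name in ("radius_mm", "inflated_radius_mm", "spatial_smoothness_mm",
                     "total_thickness_mm", "fc_decay_mm", "ec_distance_scale_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        axis = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("axis_direction must be nonzero")
        self.axis_direction = tuple(axis / n)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LaminarThicknessMap:
    """Per-vertex absolute thickness of layers I..VI in mm."""

    thickness: np.ndarray
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.thickness.ndim != 2 or self.thickness.shape[1] != 6:
            raise ValueError("thickness must be (V, 6)")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.thickness).all(axis=1)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        valid = self.thickness[self.valid_mask]
        if valid.size and (not np.isfinite(valid).all() or (valid <= 0).any()):
            raise ValueError("valid laminar thicknesses must be finite and positive")

    @property
    def total(self) -> np.ndarray:
        return self.thickness.sum(axis=1)


@dataclass
class IntensityProfileMap:
    """Per-vertex intensity sampled at D equispaced depth fractions (pial->white)."""

    profile: np.ndarray
    depth_fractions: np.ndarray

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        self.depth_fractions = np.asarray(self.depth_fractions, dtype=float)
        if self.profile.shape[1] != len(self.depth_fractions):
            raise ValueError("profile depth dimension mismatch")
        if not (np.diff(self.depth_fractions) > 0).all():
            raise ValueError("depth_fractions must be strictly increasing")


@dataclass
class DirectedConnectivity:
    """Directed influence matrix; entry (i, j) = influence of source i on target j."""

    weights: np.ndarray
    parcel_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if self.parcel_ids is None:
            self.parcel_ids = np.arange(w.shape[0])


# ---------------------------------------------------------------------------
# Mesh and parcellation
# ---------------------------------------------------------------------------


def make_icosphere(subdivisions: int, radius: float = 70.0,
                   inflated_radius: float | None = None) -> SurfaceMesh:
    """Icosphere mesh with "sphere" (unit) and "inflated" companion coordinates."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if subdivisions == 0:
        tm = trimesh.creation.icosahedron()
        tm.vertices *= radius
    else:
        tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    coords = np.asarray(tm.vertices, dtype=float)
    unit = coords / np.linalg.norm(coords, axis=1, keepdims=True)
    inflated = unit * (radius if inflated_radius is None else inflated_radius)
    return SurfaceMesh(coords, np.asarray(tm.faces),
                       {"sphere": unit, "inflated": inflated})


def make_parcellation(mesh: SurfaceMesh, n_parcels: int, seed: int = 0) -> Parcellation:
    """Contiguous Voronoi-like parcels by farthest-point seeding on mesh geodesics.

    The first seed is drawn at random; each subsequent seed is the vertex
    farthest (graph-geodesically) from all previous seeds; vertices are then
    assigned to their nearest seed. Parcels are contiguous by construction.
    """
    V = mesh.n_vertices
    if n_parcels < 1 or n_parcels > V:
        raise ValueError(f"n_parcels must be in [1, {V}]")
    rng = child_rng(seed, "parcellation")
    graph = mesh.adjacency(n_ring=1)
    seeds = [int(rng.integers(V))]
    min_dist = dijkstra(graph, directed=False, indices=seeds[0])
    for _ in range(n_parcels - 1):
        nxt = int(np.argmax(min_dist))
        seeds.append(nxt)
        min_dist = np.minimum(min_dist, dijkstra(graph, directed=False, indices=nxt))
    dist_from_seeds = dijkstra(graph, directed=False, indices=seeds)
    labels = np.argmin(dist_from_seeds, axis=0).astype(np.int64)
    centroids = parcel_centroids(mesh, labels, parcels=range(n_parcels))
    return Parcellation(labels, np.ones(n_parcels, dtype=bool), centroids)


# ---------------------------------------------------------------------------
# Fields on the mesh
# ---------------------------------------------------------------------------


def planted_axis(mesh: SurfaceMesh, config: SimulationConfig) -> np.ndarray:
    """Planted axis a(v): projection on axis_direction rescaled to [0, 1]."""
    proj = mesh.vertex_coords @ np.asarray(config.axis_direction)
    lo, hi = proj.min(), proj.max()
    return (proj - lo) / (hi - lo)


def synthetic_curvature(mesh: SurfaceMesh, config: SimulationConfig) -> VertexMap:
    """Analytic band-limited spherical-harmonic curvature stand-in.

    A fixed-seed mixture of real spherical harmonics whose angular
    wavelength (~18-24 mm on the default sphere) sits below the 10 mm disk
    diameter scale, emulating the fine spatial scale of real folding
    relative to the planted axis; standardized to zero mean, unit sd.
    """
    rng = child_rng(config.seed, "curvature")
    xyz = mesh.companion_coords["sphere"]
    theta = np.arccos(np.clip(xyz[:, 2], -1, 1))  # polar
    phi = np.arctan2(xyz[:, 1], xyz[:, 0])  # azimuth
    fld = np.zeros(mesh.n_vertices)
    for ell in (18, 24):
        orders = rng.choice(np.arange(1, ell + 1), size=4, replace=False)
        coefs = rng.normal(size=4)
        for m, cm in zip(orders, coefs):
            y = sph_harm_y(ell, int(m), theta, phi)
            fld += cm * np.sqrt(2.0) * y.real
    fld = (fld - fld.mean()) / fld.std()
    return VertexMap(fld)


def _smooth_noise(mesh: SurfaceMesh, shape, sd: float, radius: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Spatially autocorrelated Gaussian noise: disk-smoothed white noise,
    rescaled so the marginal sd equals ``sd``."""
    white = rng.normal(size=shape)
    if sd == 0:
        return np.zeros(shape)
    smoothed = disk_smooth(VertexMap(white) if white.ndim == 1 else white,
                           mesh, radius_mm=radius)
    vals = smoothed.values if isinstance(smoothed, VertexMap) else smoothed
    vals = np.asarray(vals)
    scale = vals.std(axis=0, keepdims=True)
    scale[scale == 0] = 1.0
    return sd * vals / scale


def sample_laminar_thickness(
    mesh: SurfaceMesh, config: SimulationConfig
) -> tuple[LaminarThicknessMap, np.ndarray, VertexMap]:
    """Generate the 6-layer thickness field; returns (map, planted axis, curvature).

    Relative thickness of each layer varies linearly along the planted
    axis (II-IV up, V-VI down), superficial layers are depressed in
    proportion to curvature_coupling x curvature (the mass moving to the
    infragranular layers), spatially correlated noise with the configured
    correlation length is added in fraction space, and fractions are
    converted to absolute thickness via a smoothly varying total depth.
    """
    rng = child_rng(config.seed, "laminar")
    V = mesh.n_vertices
    a = planted_axis(mesh, config)
    curv = synthetic_curvature(mesh, config)

    fractions = BASE_FRACTIONS[None, :] + axis_profile_deviation(a)

    # curvature compresses superficial layers; total mass is conserved by
    # crediting the infragranular layers
    delta = config.curvature_coupling * curv.values
    sup_w = BASE_FRACTIONS[SUPERFICIAL] / BASE_FRACTIONS[SUPERFICIAL].sum()
    inf_w = BASE_FRACTIONS[4:] / BASE_FRACTIONS[4:].sum()
    fractions[:, SUPERFICIAL] -= delta[:, None] * sup_w[None, :]
    fractions[:, 4:] += delta[:, None] * inf_w[None, :]

    if config.noise_sd > 0:
        fractions = fractions + _smooth_noise(
            mesh, (V, 6), config.noise_sd, config.spatial_smoothness_mm, rng
        )

    fractions = np.clip(fractions, 0.01, None)

    total = np.full(V, config.total_thickness_mm)
    if config.total_thickness_sd > 0:
        total = total + _smooth_noise(
            mesh, (V,), config.total_thickness_sd, config.spatial_smoothness_mm, rng
        )
    total = np.clip(total, 0.5, None)

    thickness = fractions * total[:, None]
    return LaminarThicknessMap(thickness), a, curv


def sample_intensity_profiles(
    mesh: SurfaceMesh,
    laminar_map: LaminarThicknessMap,
    config: SimulationConfig,
    n_depths: int = 50,
) -> IntensityProfileMap:
    """Piecewise-constant-per-layer intensity profiles sampled at equispaced depths.

    Layer boundaries in depth-fraction space equal the cumulative relative
    thickness; each layer's level varies linearly along the planted axis
    (layer IV strongest), emulating density variation of stained tissue.
    """
    a = planted_axis(mesh, config)
    levels = BASE_INTENSITY[None, :] + INTENSITY_SLOPES[None, :] * (a[:, None] - 0.5)
    rel = laminar_map.thickness / laminar_map.total[:, None]
    bounds = np.cumsum(rel, axis=1)  # (V, 6), last column ~ 1
    depths = (np.arange(n_depths) + 0.5) / n_depths
    # layer index of each depth sample: first boundary >= depth
    layer_idx = (depths[None, :, None] > bounds[:, None, :]).sum(axis=2)
    layer_idx = np.clip(layer_idx, 0, 5)
    profile = np.take_along_axis(
        np.repeat(levels[:, None, :], n_depths, axis=1), layer_idx[:, :, None], axis=2
    )[:, :, 0]
    return IntensityProfileMap(profile, depths)


# ---------------------------------------------------------------------------
# Connectivity generators
# ---------------------------------------------------------------------------


def sample_effective_connectivity(
    parcellation: Parcellation,
    gd: np.ndarray,
    config: SimulationConfig,
) -> tuple[DirectedConnectivity, np.ndarray]:
    """Directed connectivity with a planted node hierarchy.

    Magnitudes decay exponentially with geodesic distance; the asymmetry
    A_ij - A_ji of each pair is proportional to the planted hierarchy
    difference h*_i - h*_j (higher regions drive lower ones) plus noise.
    Returns (connectivity, planted hierarchy).
    """
    idx = parcellation.included
    P = len(idx)
    if P < 2:
        raise ValueError("need at least 2 included parcels")
    rng = child_rng(config.seed, "effective-connectivity")
    h = rng.normal(scale=config.hierarchy_spread, size=P)
    # 0.5 floor keeps most weights positive so the unsigned-degree asymmetry
    # remains linear in the planted hierarchy
    base = 0.5 + np.exp(-gd[np.ix_(idx, idx)] / config.ec_distance_scale_mm)
    asym = 0.5 * config.ec_asymmetry_gain * (h[:, None] - h[None, :])
    noise = rng.normal(scale=config.ec_noise_sd, size=(P, P))
    A = base + asym + noise
    np.fill_diagonal(A, 0.0)
    full = np.zeros((parcellation.n_parcels, parcellation.n_parcels))
    full[np.ix_(idx, idx)] = A
    h_full = np.full(parcellation.n_parcels, np.nan)
    h_full[idx] = h
    return DirectedConnectivity(full), h_full


def sample_sc_fc(
    ltc_edges: np.ndarray,
    gd_edges: np.ndarray,
    config: SimulationConfig,
    n_parcels: int | None = None,
    edge_index: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary SC and continuous FC over edges with planted dependencies.

    SC_ij ~ Bernoulli(logit^-1(b0 + b_ltc * z(LTC_ij) + b_gd * z(GD_ij)));
    FC_ij = exp(-GD_ij / lambda) + gamma * z(LTC_ij) + Gaussian noise.
    Standardized predictors keep the coefficients on a common scale. If
    ``n_parcels``/``edge_index`` are given, edge vectors are also placed
    into symmetric matrices; otherwise edge vectors are returned.
    """
    ltc_edges = np.asarray(ltc_edges, dtype=float)
    gd_edges = np.asarray(gd_edges, dtype=float)
    if ltc_edges.shape != gd_edges.shape:
        raise ValueError("edge tables are not aligned")
    rng = child_rng(config.seed, "sc-fc")

    def z(x):
        s = x.std()
        return (x - x.mean()) / (s if s > 0 else 1.0)

    logits = (config.sc_beta0 + config.sc_beta_ltc * z(ltc_edges)
              + config.sc_beta_gd * z(gd_edges))
    p = 1.0 / (1.0 + np.exp(-logits))
    sc = (rng.random(len(p)) < p).astype(int)
    fc = (np.exp(-gd_edges / config.fc_decay_mm)
          + config.fc_ltc_gain * z(ltc_edges)
          + rng.normal(scale=config.fc_noise_sd, size=len(p)))

    if n_parcels is None:
        return sc, fc
    i, j = edge_index
    sc_m = np.zeros((n_parcels, n_parcels))
    fc_m = np.full((n_parcels, n_parcels), np.nan)
    sc_m[i, j] = sc_m[j, i] = sc
    fc_m[i, j] = fc_m[j, i] = fc
    np.fill_diagonal(fc_m, np.nan)
    return sc_m, fc_m


def assign_cortical_types(
    parcellation: Parcellation,
    parcel_axis: np.ndarray,
    seed: int = 0,
    label_noise: float = 0.05,
) -> np.ndarray:
    """Six ordered cortical types from axis sextiles with optional label noise.

    Agranular/dysgranular labels concentrate at the low pole of the
    planted axis, so type-based exclusion removes a contiguous band.
    """
    parcel_axis = np.asarray(parcel_axis, dtype=float)
    rng = child_rng(seed, "cortical-types")
    idx = parcellation.included
    vals = parcel_axis[idx]
    order = np.argsort(np.argsort(vals))
    sextile = np.minimum((order * 6) // len(vals), 5)
    if label_noise > 0:
        flip = rng.random(len(vals)) < label_noise
        jitter = rng.choice([-1, 1], size=len(vals))
        sextile = np.where(flip, np.clip(sextile + jitter, 0, 5), sextile)
    types = np.full(parcellation.n_parcels, CORTICAL_TYPES[2], dtype=object)
    types[idx] = np.asarray(CORTICAL_TYPES, dtype=object)[sextile]
    return types
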