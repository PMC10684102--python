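"""Laminar covariance matrices.

Relative-thickness profiles and the similarity matrices built from them:
laminar thickness covariance (LTC) via pairwise partial correlation of
6-layer relative-thickness profiles controlling for the cortex-average
profile, with Fisher z-transform; the same machinery applied to
depth-intensity profiles (MPC) and per-layer mean intensities (LIC);
rank-fusion of LTC and LIC; and intraregional homogeneity scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "RelativeLaminarMap",
    "CovarianceMatrix",
    "relative_thickness",
    "profile_partial_correlation",
    "build_ltc",
    "build_profile_covariance",
    "laminar_intensity",
    "fuse_matrices",
    "intraregional_homogeneity",
]


@dataclass
class RelativeLaminarMap:
    """Depth fractions per location; each valid row sums to 1."""

    fractions: np.ndarray
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.fractions).all(axis=1)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        rows = self.fractions[self.valid_mask]
        if rows.size:
            if (rows < -1e-12).any() or (rows > 1 + 1e-12).any():
                raise ValueError("fractions must lie in [0, 1]")
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("valid rows must sum to 1")


@dataclass
class CovarianceMatrix:
    """Symmetric similarity matrix with an undefined (NaN) diagonal.

    ``kind`` records the construction (ltc / mpc / lic / pearson /
    euclidean); ``fisher_z`` whether values are arctanh-transformed.
    """

    values: np.ndarray
    kind: str = "ltc"
    fisher_z: bool = True
    parcel_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("covariance matrix must be square")
        off = ~np.eye(v.shape[0], dtype=bool)
        both = np.isfinite(v) & np.isfinite(v.T)
        if not np.allclose(v[off & both], v.T[off & both], atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        if self.parcel_ids is None:
            self.parcel_ids = np.arange(v.shape[0])

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def defined_mask(self) -> np.ndarray:
        m = np.isfinite(self.values)
        np.fill_diagonal(m, False)
        return m


def relative_thickness(laminar_map) -> RelativeLaminarMap:
    """Divide each layer's thickness by the total cortical thickness."""
    thickness = np.asarray(laminar_map.thickness, dtype=float)
    mask = np.asarray(laminar_map.valid_mask, dtype=bool)
    total = thickness.sum(axis=1)
    bad = mask & ~(total > 0)
    if bad.any():
        raise ValueError(f"non-positive total thickness at vertex {np.flatnonzero(bad)[0]}")
    out = np.full_like(thickness, np.nan)
    out[mask] = thickness[mask] / total[mask, None]
    return RelativeLaminarMap(out, mask)


def profile_partial_correlation(x, y, z) -> float:
    """First-order partial correlation r_xy.z of profile vectors.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if len(x) < 4:
        raise ValueError("profiles must have at least 4 entries")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.ptp(v) == 0:
            raise ValueError(f"input vector {name} is constant; correlation undefined")

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    r_xy, r_xz, r_yz = corr(x, y), corr(x, z), corr(y, z)
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 1e-24:
        raise ValueError("profile perfectly collinear with covariate; partial correlation undefined")
    return float(np.clip((r_xy - r_xz * r_yz) / np.sqrt(denom), -1.0, 1.0))


def _pairwise_partial(profiles: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Vectorized pairwise partial correlation of rows against one covariate."""
    X = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError(f"constant profile at parcel {int(np.argmin(norms))}")
    Xn = X / norms[:, None]
    z = covariate - covariate.mean()
    zn = z / np.linalg.norm(z)
    r_xz = Xn @ zn
    R = Xn @ Xn.T
    denom2 = (1 - r_xz[:, None] ** 2) * (1 - r_xz[None, :] ** 2)
    if (denom2 <= 1e-24).any():
        bad = np.flatnonzero(1 - r_xz**2 <= 1e-12)
        raise ValueError(
            f"profile(s) perfectly collinear with the covariate at parcel(s) {bad.tolist()}"
        )
    return np.clip((R - np.outer(r_xz, r_xz)) / np.sqrt(denom2), -1.0, 1.0)


def _fisher_z(r: np.ndarray) -> np.ndarray:
    # guard exact +/-1 which would map to +/-inf
    return np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))


def build_ltc(
    rel_profiles: np.ndarray,
    covariate: np.ndarray | None = None,
    metric: str = "partial",
    kind: str = "ltc",
    parcel_ids: np.ndarray | None = None,
) -> CovarianceMatrix:
    """Laminar thickness covariance over parcel profiles.

    Parameters
    ----------
    rel_profiles : (P, K) array
        Per-parcel relative-thickness (or intensity) profiles; rows with
        any non-finite entry are treated as undefined parcels.
    covariate : (K,) array, optional
        Control profile for the partial correlation; defaults to the
        unweighted mean profile over defined parcels.
    metric : {"partial", "pearson", "euclidean"}
        "partial": partial correlation against the covariate + Fisher z.
        "pearson": plain correlation + Fisher z.
        "euclidean": negated Euclidean distance (larger = more similar).
    """
    profiles = np.asarray(rel_profiles, dtype=float)
    ok = np.isfinite(profiles).all(axis=1)
    if ok.sum() < 3:
        raise ValueError("need at least 3 defined parcels")
    P = len(profiles)
    out = np.full((P, P), np.nan)
    sub = profiles[ok]

    if metric == "partial":
        cov = sub.mean(axis=0) if covariate is None else np.asarray(covariate, float)
        r = _pairwise_partial(sub, cov)
        vals = _fisher_z(r)
        fisher = True
    elif metric == "pearson":
        r = np.corrcoef(sub)
        vals = _fisher_z(r)
        fisher = True
    elif metric == "euclidean":
        d = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=2)
        vals = -d
        fisher = False
    else:
        raise ValueError(f"unknown metric {metric!r}")

    idx = np.flatnonzero(ok)
    out[np.ix_(idx, idx)] = vals
    np.fill_diagonal(out, np.nan)
    return CovarianceMatrix(out, kind=kind if metric == "partial" else metric,
                            fisher_z=fisher, parcel_ids=parcel_ids)


def build_profile_covariance(
    profiles: np.ndarray, parcel_ids: np.ndarray | None = None, kind: str = "mpc"
) -> CovarianceMatrix:
    """Microstructural profile covariance: partial correlation of depth
    profiles against the mean profile, Fisher z-transformed."""
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[1] < 10:
        raise ValueError("need at least 10 depth samples")
    return build_ltc(profiles, metric="partial", kind=kind, parcel_ids=parcel_ids)


def laminar_intensity(
    profile_map, rel: RelativeLaminarMap, samples_per_layer: int = 10
) -> np.ndarray:
    """Mean intensity of each layer from a depth profile.

    For each of the 6 layers, the intensity profile is linearly
    interpolated at ``samples_per_layer`` equally spaced interior points
    of the layer's depth-fraction interval and averaged;
    ``samples_per_layer=1`` samples the layer midpoint. Zero-thickness
    layers yield NaN.
    """
    profile = np.asarray(profile_map.profile, dtype=float)
    depths = np.asarray(profile_map.depth_fractions, dtype=float)
    fractions = rel.fractions
    V = len(profile)
    bounds = np.concatenate([np.zeros((V, 1)), np.cumsum(fractions, axis=1)], axis=1)
    offsets = (np.arange(samples_per_layer) + 0.5) / samples_per_layer
    out = np.full((V, 6), np.nan)
    for v in range(V):
        if not rel.valid_mask[v]:
            continue
        for k in range(6):
            lo, hi = bounds[v, k], bounds[v, k + 1]
            if hi - lo <= 0:
                continue
            pts = lo + offsets * (hi - lo)
            out[v, k] = np.interp(pts, depths, profile[v]).mean()
    return out


def _rank_offdiag(values: np.ndarray) -> np.ndarray:
    """Rank the defined off-diagonal entries; NaN stays NaN."""
    out = np.full_like(values, np.nan)
    mask = np.isfinite(values)
    np.fill_diagonal(mask, False)
    out[mask] = rankdata(values[mask])
    return out


def fuse_matrices(ltc: CovarianceMatrix, lic: CovarianceMatrix) -> np.ndarray:
    """Horizontally fuse two covariance matrices on a common rank scale.

    Off-diagonal entries of each matrix are replaced by their ranks, the
    second matrix's ranks are min-max rescaled to the range of the
    first's, and the matrices are concatenated side by side (P x 2P).
    """
    if ltc.n != lic.n or not np.array_equal(ltc.parcel_ids, lic.parcel_ids):
        raise ValueError("matrices are over different parcel sets")
    r1 = _rank_offdiag(ltc.values)
    r2 = _rank_offdiag(lic.values)
    lo1, hi1 = np.nanmin(r1), np.nanmax(r1)
    lo2, hi2 = np.nanmin(r2), np.nanmax(r2)
    if hi2 > lo2:
        r2 = lo1 + (r2 - lo2) * (hi1 - lo1) / (hi2 - lo2)
    return np.concatenate([r1, r2], axis=1)


def intraregional_homogeneity(
    vertex_cov: CovarianceMatrix, region_labels: np.ndarray
) -> dict[int, float]:
    """Within- minus between-region mean covariance per region.

    score_r = mean cov over vertex pairs both in region r minus mean cov
    over pairs with exactly one vertex in r (diagonal excluded). Regions
    with fewer than 2 vertices are undefined (NaN).
    """
    labels = np.asarray(region_labels)
    vals = vertex_cov.values
    regions = [r for r in np.unique(labels)]
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    scores: dict[int, float] = {}
    for r in regions:
        inside = labels == r
        if inside.sum() < 2:
            scores[r] = float("nan")
            continue
        within = vals[np.ix_(inside, inside)]
        m = np.isfinite(within)
        np.fill_diagonal(m, False)
        within_mean = within[m].mean()
        between = vals[np.ix_(inside, ~inside)]
        between_mean = between[np.isfinite(between)].mean()
        scores[r] = float(within_mean - between_mean)
    return scores
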