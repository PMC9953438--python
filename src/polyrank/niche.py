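"""Ecological niche comparison: environmental PCA rasters, a pluggable
suitability model, Schoener's D / Warren's I overlap, and the
niche-equivalency permutation test.

The default suitability model is a deterministic multivariate Gaussian
envelope: the Mahalanobis distance of each cell's environmental-PC vector
to the occurrence centroid, mapped to [0, 1] via the chi-squared survival
function.  MaxEnt is deliberately not reimplemented; an adapter can read a
pre-computed suitability grid instead, and a presence-background
regularised logistic model is available as an alternative.  A taxon whose
occurrences all fall in a single raster cell cannot be modelled
(NICHE_UNDEFINED) and propagates as "n/a" through the pairwise tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .formats_io import EnvStack, OccurrenceSet

__all__ = [
    "NicheUndefinedError",
    "SuitabilityMap",
    "NicheOverlap",
    "env_pca_rasters",
    "fit_suitability",
    "niche_overlap",
    "niche_equivalency_test",
]

EARTH_RADIUS_KM = 6371.0


class NicheUndefinedError(ValueError):
    """All occurrences fall into a single raster cell; no model is fittable."""


@dataclass
class SuitabilityMap:
    grid: np.ndarray  # values in [0, 1], NaN at nodata
    extent: tuple[float, float, float, float]
    resolution: float
    model: str = "envelope"
    metadata: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        return ~np.isfinite(self.grid)


@dataclass
class NicheOverlap:
    D: float  # Schoener's statistic
    I: float  # Warren's statistic


# ---------------------------------------------------------------------------
# environmental PCA
# ---------------------------------------------------------------------------

def average_depth_layers(stack: EnvStack, depth_groups: dict[str, list[str]]) -> EnvStack:
    """Average soil-depth triplets (e.g. 0-5, 5-15, 15-30 cm) into one layer
    per variable; non-grouped layers pass through unchanged."""
    grouped = {name for names in depth_groups.values() for name in names}
    layers = {n: a for n, a in stack.layers.items() if n not in grouped}
    for var, names in depth_groups.items():
        layers[var] = np.mean([stack.layers[n] for n in names], axis=0)
    return EnvStack(layers=layers, extent=stack.extent, resolution=stack.resolution)


def env_pca_rasters(stack: EnvStack, n_components: int = 3) -> EnvStack:
    """Standardise each layer over its valid cells and return the first
    principal-component rasters as a new stack (constant layers dropped)."""
    valid = ~stack.mask
    names, cols = [], []
    for name in stack.layer_names:
        vals = stack.layers[name][valid]
        sd = vals.std()
        if sd == 0:
            import warnings

            warnings.warn(f"constant layer {name!r} dropped from PCA", stacklevel=2)
            continue
        names.append(name)
        cols.append((vals - vals.mean()) / sd)
    if len(names) < n_components:
        raise ValueError(f"only {len(names)} usable layers for {n_components} components")
    X = np.column_stack(cols)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = (U * s)[:, :n_components]
    layers = {}
    for i in range(n_components):
        grid = np.full(stack.shape, np.nan)
        grid[valid] = scores[:, i]
        layers[f"PC{i + 1}"] = grid
    return EnvStack(layers=layers, extent=stack.extent, resolution=stack.resolution)


# ---------------------------------------------------------------------------
# suitability models
# ---------------------------------------------------------------------------

def _occupied_cells(occ_xy: np.ndarray, env: EnvStack) -> set[tuple[int, int]]:
    return {env.cell_of(lon, lat) for lon, lat in occ_xy}


def _env_at(env: EnvStack, occ_xy: np.ndarray) -> np.ndarray:
    arr = env.as_array()
    rows, cols = zip(*(env.cell_of(lon, lat) for lon, lat in occ_xy))
    return arr[:, list(rows), list(cols)].T


def draw_background_points(
    occ_xy: np.ndarray, env: EnvStack, n: int = 1000, range_km: float = 20.0,
    seed: int | None = None,
) -> np.ndarray:
    """Uniform background points within ``range_km`` of any occurrence
    (latitude-corrected), restricted to valid raster cells."""
    rng = np.random.default_rng(seed)
    lon_min, lon_max, lat_min, lat_max = env.extent
    pts = []
    lat0 = occ_xy[:, 1].mean()
    deg_per_km_lat = 1.0 / 111.195
    deg_per_km_lon = deg_per_km_lat / max(math.cos(math.radians(lat0)), 1e-6)
    max_tries = 200 * n
    tries = 0
    while len(pts) < n and tries < max_tries:
        tries += 1
        lon = rng.uniform(lon_min, lon_max)
        lat = rng.uniform(lat_min, lat_max)
        d_km = np.min(
            np.hypot((occ_xy[:, 0] - lon) / deg_per_km_lon,
                     (occ_xy[:, 1] - lat) / deg_per_km_lat)
        )
        if d_km > range_km:
            continue
        try:
            r, c = env.cell_of(lon, lat)
        except ValueError:
            continue
        if env.mask[r, c]:
            continue
        pts.append((lon, lat))
    return np.array(pts).reshape(-1, 2)


def fit_suitability(
    occ: OccurrenceSet | np.ndarray,
    env: EnvStack,
    model: str = "envelope",
    background_n: int = 1000,
    bg_range_km: float = 20.0,
    seed: int | None = None,
    taxon: str | None = None,
) -> SuitabilityMap:
    """Fit a suitability surface on the environmental-PC stack.

    ``model='envelope'``: chi-squared survival of Mahalanobis distance to
    the occurrence centroid in PC space.  ``model='logistic'``: L2-
    regularised presence-background logistic regression using background
    points drawn within ``bg_range_km`` of the occurrences.  Raises
    :class:`NicheUndefinedError` when all occurrences share one cell.
    """
    if isinstance(occ, OccurrenceSet):
        if taxon is None:
            taxa = occ.taxa
            if len(taxa) != 1:
                raise ValueError("pass a single-taxon OccurrenceSet or specify taxon")
            taxon = taxa[0]
        occ_xy = occ.for_taxon(taxon)
    else:
        occ_xy = np.asarray(occ, dtype=float).reshape(-1, 2)
    occ_xy = np.unique(occ_xy, axis=0)
    if len(occ_xy) == 0:
        raise ValueError("no occurrences")
    cells = _occupied_cells(occ_xy, env)
    if len(cells) < 2:
        raise NicheUndefinedError(
            f"taxon {taxon!r}: all occurrences fall into a single raster cell"
        )
    E = _env_at(env, occ_xy)  # (n_occ, n_layers)
    arr = env.as_array()
    valid = ~env.mask
    cellsX = arr[:, valid].T  # (n_cells, n_layers)
    grid = np.full(env.shape, np.nan)

    if model == "envelope":
        mu = E.mean(axis=0)
        cov = np.cov(E.T)
        cov = np.atleast_2d(cov) + 1e-6 * np.eye(E.shape[1])
        inv = np.linalg.inv(cov)
        diff = cellsX - mu
        maha2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
        suit = stats.chi2.sf(maha2, df=E.shape[1])
        meta = {"mu": mu, "cov": cov, "n_occ": len(occ_xy)}
    elif model == "logistic":
        from sklearn.linear_model import LogisticRegression

        bg = draw_background_points(occ_xy, env, background_n, bg_range_km, seed)
        if len(bg) == 0:
            raise ValueError("no background points could be drawn")
        Eb = _env_at(env, bg)
        X = np.vstack([E, Eb])
        y = np.concatenate([np.ones(len(E)), np.zeros(len(Eb))])
        clf = LogisticRegression(C=1.0, max_iter=1000).fit(X, y)
        suit = clf.predict_proba(cellsX)[:, 1]
        meta = {"n_occ": len(occ_xy), "n_background": len(bg)}
    else:
        raise ValueError(f"unknown model {model!r}")
    # scale to [0, 1]
    hi = suit.max()
    if hi > 0:
        suit = suit / hi
    grid[valid] = suit
    return SuitabilityMap(
        grid=grid, extent=env.extent, resolution=env.resolution,
        model=model, metadata={**meta, "taxon": taxon},
    )


def read_suitability_grid(path, model_name: str = "external") -> SuitabilityMap:
    """Adapter for an externally computed suitability grid (e.g. a MaxEnt
    output exported as ESRI ASCII)."""
    from .formats_io import read_esri_ascii

    arr, extent, res = read_esri_ascii(path)
    lo, hi = np.nanmin(arr), np.nanmax(arr)
    if lo < 0 or hi > 1:
        arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    return SuitabilityMap(grid=arr, extent=extent, resolution=res, model=model_name)


# ---------------------------------------------------------------------------
# overlap statistics
# ---------------------------------------------------------------------------

def niche_overlap(map1: SuitabilityMap, map2: SuitabilityMap) -> NicheOverlap:
    """Schoener's D and Warren's I over the shared valid cells.

    Each surface is normalised to sum 1; D = 1 - 0.5 sum|p - q|,
    I = 1 - 0.5 sum(sqrt(p) - sqrt(q))^2; both in [0, 1] with D <= I.
    """
    if map1.grid.shape != map2.grid.shape:
        raise ValueError("suitability grids are not aligned")
    shared = np.isfinite(map1.grid) & np.isfinite(map2.grid)
    p = map1.grid[shared]
    q = map2.grid[shared]
    sp, sq = p.sum(), q.sum()
    if sp <= 0 or sq <= 0:
        raise ValueError("all-zero suitability map")
    p = p / sp
    q = q / sq
    D = 1.0 - 0.5 * np.abs(p - q).sum()
    I = 1.0 - 0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum()
    return NicheOverlap(D=float(D), I=float(I))


# ---------------------------------------------------------------------------
# niche-equivalency permutation test
# ---------------------------------------------------------------------------

def niche_equivalency_test(
    occ_a: np.ndarray,
    occ_b: np.ndarray,
    env: EnvStack,
    n_reps: int = 200,
    seed: int | None = None,
    model: str = "envelope",
) -> tuple[float, float, float, float]:
    """Warren-style niche-equivalency test.

    Pools the two taxa's occurrences, re-splits them at random preserving
    group sizes, refits both suitability models per replicate, and compares
    observed overlap to the pooled null one-tailed (equivalency is rejected
    when the observed overlap is LOWER than expected under the null):
    p = (1 + #{stat* <= stat_obs}) / (n_reps + 1).
    Returns (D_obs, I_obs, p_D, p_I).
    """
    occ_a = np.asarray(occ_a, dtype=float).reshape(-1, 2)
    occ_b = np.asarray(occ_b, dtype=float).reshape(-1, 2)
    map_a = fit_suitability(occ_a, env, model=model)
    map_b = fit_suitability(occ_b, env, model=model)
    obs = niche_overlap(map_a, map_b)
    pool = np.vstack([occ_a, occ_b])
    n_a = len(occ_a)
    rng = np.random.default_rng(seed)
    count_d = count_i = 0
    n_eval = 0
    for _ in range(n_reps):
        perm = rng.permutation(len(pool))
        try:
            ma = fit_suitability(pool[perm[:n_a]], env, model=model)
            mb = fit_suitability(pool[perm[n_a:]], env, model=model)
        except NicheUndefinedError:
            continue
        null = niche_overlap(ma, mb)
        n_eval += 1
        if null.D <= obs.D + 1e-12:
            count_d += 1
        if null.I <= obs.I + 1e-12:
            count_i += 1
    p_d = (1 + count_d) / (n_eval + 1)
    p_i = (1 + count_i) / (n_eval + 1)
    return obs.D, obs.I, p_d, p_i
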