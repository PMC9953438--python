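"""Synthetic-data generators with the statistical structure the analyses
assume, so every stage is testable without external downloads.

Genotypes follow a Balding-Nichols-style model: an ancestral allele
frequency per site, taxon frequencies drifted with a single
differentiation parameter F, and binomial dosage sampling at each
sample's ploidy.  Allotetraploids add one binomial draw from each parent
taxon's frequencies; autotetraploids draw four alleles from their own
taxon's frequencies.  Leaves are superformula-like radial outlines with
controllable elongation, dissection amplitude, lobe count, and smooth
bending (the unbent ground-truth mask is retained).  Landscapes are
gradient-plus-correlated-noise environmental layers with Gaussian niches
per taxon and suitability-proportional occurrence sampling under
allopatric / sympatric / parapatric / point-endemic scenarios.

Every generator is deterministic under a fixed seed, and the SimTruth
object records everything needed to regenerate a dataset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .formats_io import EnvStack, GenotypeMatrix, LeafAnnotation, OccurrenceSet

__all__ = [
    "SimTruth",
    "simulate_genotypes",
    "simulate_leaves",
    "simulate_landscape",
]


@dataclass
class SimTruth:
    """Ground truth and parameters serialised alongside generated data."""

    params: dict = field(default_factory=dict)
    taxon_of: dict = field(default_factory=dict)
    parental_pairs: dict = field(default_factory=dict)
    niche_centers: dict = field(default_factory=dict)
    niche_widths: dict = field(default_factory=dict)
    dissection_of: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        Path(path).write_text(json.dumps(self.__dict__, default=default, indent=1))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_taxa: int = 4,
    samples_per_taxon: int = 10,
    n_sites: int = 2000,
    divergence_F: float = 0.2,
    polyploid_specs: dict[str, tuple[str, str] | str] | None = None,
    missing_rate: float = 0.0,
    seed: int | None = None,
    taxon_freqs: dict[str, np.ndarray] | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Taxon-structured mixed-ploidy biallelic genotypes.

    Diploid taxa are named ``taxon00..``; ``polyploid_specs`` maps extra
    tetraploid taxon names to a diploid parent pair (allotetraploid), the
    string ``"auto:<parent>"`` (autotetraploid of one diploid pool), or
    ``"auto"`` (autotetraploid of a fresh drifted frequency vector).
    ``taxon_freqs`` can pin taxon allele frequencies exactly (e.g. fixed
    0/1 profiles for a fully diverged construction).
    """
    if not 0 < divergence_F < 1:
        raise ValueError("divergence_F must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    polyploid_specs = polyploid_specs or {}
    diploid_taxa = [f"taxon{i:02d}" for i in range(n_taxa)]
    p0 = rng.uniform(0.05, 0.95, size=n_sites)
    a = p0 * (1 - divergence_F) / divergence_F
    b = (1 - p0) * (1 - divergence_F) / divergence_F
    freqs: dict[str, np.ndarray] = {}
    for t in diploid_taxa:
        freqs[t] = rng.beta(a, b)
    if taxon_freqs:
        freqs.update({k: np.asarray(v, dtype=float) for k, v in taxon_freqs.items()})

    sample_ids: list[str] = []
    taxon_of: dict[str, str] = {}
    ploidy_of: dict[str, int] = {}
    dosage_rows: list[np.ndarray] = []
    parental: dict[str, tuple[str, str] | str] = {}

    def add_samples(taxon: str, ploidy: int, draw) -> None:
        for i in range(samples_per_taxon):
            sid = f"{taxon}_{i:02d}"
            sample_ids.append(sid)
            taxon_of[sid] = taxon
            ploidy_of[sid] = ploidy
            dosage_rows.append(draw())

    for t in diploid_taxa:
        p = freqs[t]
        add_samples(t, 2, lambda p=p: rng.binomial(2, p))

    for name, spec in polyploid_specs.items():
        if isinstance(spec, tuple):
            p1, p2 = spec
            for par in (p1, p2):
                if par not in freqs:
                    raise ValueError(f"parent {par!r} of {name!r} is not a diploid taxon")
            parental[name] = (p1, p2)
            f1, f2 = freqs[p1], freqs[p2]
            add_samples(
                name, 4,
                lambda f1=f1, f2=f2: rng.binomial(2, f1) + rng.binomial(2, f2),
            )
        elif spec == "auto" or (isinstance(spec, str) and spec.startswith("auto")):
            src = spec.partition(":")[2]
            if src:
                if src not in freqs:
                    raise ValueError(f"parent {src!r} of {name!r} is not a diploid taxon")
                p = freqs[src]
                parental[name] = src
            else:
                p = rng.beta(a, b)
                freqs[name] = p
                parental[name] = "auto"
            add_samples(name, 4, lambda p=p: rng.binomial(4, p))
        else:
            raise ValueError(f"bad polyploid spec for {name!r}: {spec!r}")

    alt = np.stack(dosage_rows).astype(float)  # (n, L) alt-allele dosages
    ploidy_arr = np.array([ploidy_of[s] for s in sample_ids], dtype=float)
    dos = np.stack([ploidy_arr[:, None] - alt, alt], axis=2)  # (n, L, 2): ref, alt
    if missing_rate > 0:
        miss = rng.random((len(sample_ids), n_sites)) < missing_rate
        dos[miss] = np.nan

    sites = [("chr1", l + 1, "A", ("G",)) for l in range(n_sites)]
    g = GenotypeMatrix(
        sample_ids=sample_ids, taxon_of=taxon_of, ploidy_of=ploidy_of,
        sites=sites, dosages=dos,
    )
    truth = SimTruth(
        params={
            "n_taxa": n_taxa, "samples_per_taxon": samples_per_taxon,
            "n_sites": n_sites, "divergence_F": divergence_F,
            "missing_rate": missing_rate,
        },
        taxon_of=dict(taxon_of), parental_pairs=dict(parental), seed=seed,
    )
    return g, truth


# ---------------------------------------------------------------------------
# leaves
# ---------------------------------------------------------------------------

def _leaf_outline(
    n_points: int, R: float, elongation: float, a: float, m: int,
    phase: float,
) -> np.ndarray:
    theta = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    radial = 1.0 + a * np.sin(m * theta + phase)
    x = elongation * R * np.cos(theta) * radial
    y = R * np.sin(theta) * radial
    return np.column_stack([x, y])


def _bend(points: np.ndarray, curvature: float) -> np.ndarray:
    """Bend the x-axis onto a circular arc of the given curvature, keeping
    arc length along y=0 and offsets perpendicular to the arc."""
    if curvature == 0:
        return points.copy()
    r = 1.0 / curvature
    x, y = points[:, 0], points[:, 1]
    return np.column_stack([(r - y) * np.sin(x / r), r - (r - y) * np.cos(x / r)])


def simulate_leaves(
    n_per_taxon: int = 30,
    elongation: float = 2.5,
    dissection_amplitude: float = 0.2,
    lobe_count: int = 8,
    bend_curvature: float = 0.0,
    resolution: int = 256,
    seed: int | None = None,
    taxon: str = "taxonA",
    n_points: int = 720,
    jitter: float = 0.05,
) -> tuple[list[LeafAnnotation], list[np.ndarray], SimTruth]:
    """Synthetic leaves: annotations (possibly bent), unbent ground-truth
    masks, and the SimTruth record.

    Outline r(theta) = R e(theta) (1 + a sin(m theta)); midvein = major
    axis; per-leaf multiplicative jitter on elongation and amplitude
    emulates biological variation.
    """
    if dissection_amplitude >= 1:
        raise ValueError("dissection amplitude >= 1 risks self-intersection")
    rng = np.random.default_rng(seed)
    R = resolution / (2.5 * max(elongation, 1.0))
    annots: list[LeafAnnotation] = []
    masks: list[np.ndarray] = []
    for i in range(n_per_taxon):
        e_i = elongation * (1 + jitter * rng.standard_normal())
        a_i = min(abs(dissection_amplitude * (1 + jitter * rng.standard_normal())), 0.95)
        phase = rng.uniform(0, 2 * np.pi)
        outline = _leaf_outline(n_points, R, max(e_i, 0.2), a_i, lobe_count, phase)
        x_min, x_max = outline[:, 0].min(), outline[:, 0].max()
        vein = np.column_stack([
            np.linspace(x_min, x_max, 64), np.zeros(64),
        ])
        # ground-truth unbent mask
        masks.append(_rasterize(outline))
        bent_outline = _bend(outline, bend_curvature)
        bent_vein = _bend(vein, bend_curvature)
        shift = np.minimum(bent_outline.min(axis=0), bent_vein.min(axis=0)) - 2.0
        bent_outline = bent_outline - shift
        bent_vein = bent_vein - shift
        h = int(math.ceil(max(bent_outline[:, 1].max(), bent_vein[:, 1].max()))) + 2
        w = int(math.ceil(max(bent_outline[:, 0].max(), bent_vein[:, 0].max()))) + 2
        annots.append(
            LeafAnnotation(
                specimen_id=f"{taxon}_{i:03d}", outline=bent_outline,
                midvein=bent_vein, image_size=(h, w),
            )
        )
    truth = SimTruth(
        params={
            "n_per_taxon": n_per_taxon, "elongation": elongation,
            "dissection_amplitude": dissection_amplitude,
            "lobe_count": lobe_count, "bend_curvature": bend_curvature,
            "resolution": resolution, "jitter": jitter,
        },
        dissection_of={taxon: dissection_amplitude}, seed=seed,
    )
    return annots, masks, truth


def _rasterize(outline: np.ndarray) -> np.ndarray:
    shifted = outline - outline.min(axis=0) + 1.0
    h = int(math.ceil(shifted[:, 1].max())) + 2
    w = int(math.ceil(shifted[:, 0].max())) + 2
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw_polygon(shifted[:, 1], shifted[:, 0], shape=mask.shape)
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def simulate_landscape(
    grid_shape: tuple[int, int] = (40, 60),
    n_env: int = 4,
    taxa_niches: dict[str, tuple[np.ndarray, float]] | None = None,
    n_occ_per_taxon: int = 40,
    scenario: str = "sympatric",
    seed: int | None = None,
    extent: tuple[float, float, float, float] = (0.0, 6.0, 40.0, 44.0),
    noise_sigma: float = 3.0,
) -> tuple[EnvStack, OccurrenceSet, SimTruth]:
    """Gradient environmental rasters, Gaussian niches, and occurrences
    sampled proportionally to suitability.

    Scenarios: ``sympatric`` (all taxa sample from the whole grid),
    ``allopatric`` (taxon i restricted to its own longitudinal band),
    ``parapatric`` (bands overlap by half a band), ``point_endemic``
    (first taxon confined to a single cell, the rest sympatric).
    """
    nrow, ncol = grid_shape
    lon_min, lon_max, lat_min, lat_max = extent
    res = (lon_max - lon_min) / ncol
    exp_lat = lat_max - nrow * res
    extent = (lon_min, lon_max, exp_lat, lat_max)
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:nrow, 0:ncol]
    layers: dict[str, np.ndarray] = {}
    for i in range(n_env):
        ang = rng.uniform(0, 2 * np.pi)
        grad = np.cos(ang) * cols / ncol + np.sin(ang) * rows / nrow
        noise = gaussian_filter(rng.standard_normal(grid_shape), noise_sigma)
        arr = grad + 0.8 * noise
        layers[f"env{i + 1}"] = (arr - arr.mean()) / arr.std()
    env = EnvStack(layers=layers, extent=extent, resolution=res)

    if taxa_niches is None:
        taxa_niches = {
            "taxonA": (rng.standard_normal(n_env) * 0.5, 0.8),
            "taxonB": (rng.standard_normal(n_env) * 0.5, 0.8),
        }
    taxa = list(taxa_niches)
    arr = env.as_array()
    flat = arr.reshape(n_env, -1).T  # (cells, n_env)
    lon_c, lat_c = env.cell_centers()
    lon_f, lat_f = lon_c.ravel(), lat_c.ravel()
    col_f = cols.ravel()

    records: list[tuple[str, float, float]] = []
    centers, widths = {}, {}
    n_bands = max(len(taxa), 1)
    for i, t in enumerate(taxa):
        center, width = taxa_niches[t]
        center = np.asarray(center, dtype=float)
        centers[t], widths[t] = center, float(width)
        suit = np.exp(-0.5 * (((flat - center) / width) ** 2).sum(axis=1))
        allowed = np.ones(len(flat), dtype=bool)
        if scenario == "allopatric":
            band = ncol / n_bands
            allowed = (col_f >= i * band) & (col_f < (i + 1) * band)
        elif scenario == "parapatric":
            band = ncol / n_bands
            lo = max(i * band - band / 2, 0)
            hi = min((i + 1) * band + band / 2, ncol)
            allowed = (col_f >= lo) & (col_f < hi)
        elif scenario == "point_endemic" and i == 0:
            best = int(np.argmax(suit))
            allowed = np.zeros(len(flat), dtype=bool)
            allowed[best] = True
        elif scenario not in {"sympatric", "point_endemic"}:
            raise ValueError(f"unknown scenario {scenario!r}")
        w = suit * allowed
        if w.sum() <= 0:
            raise ValueError(f"taxon {t!r}: no cells available in scenario region")
        prob = w / w.sum()
        n_avail = int((prob > 0).sum())
        if scenario != "point_endemic" and n_occ_per_taxon > 50 * n_avail:
            raise ValueError("occurrences requested exceed available cells")
        cells = rng.choice(len(flat), size=n_occ_per_taxon, p=prob)
        for c in cells:
            # jitter inside the cell so duplicates are rare but cell stays fixed
            if scenario == "point_endemic" and i == 0:
                jlon = jlat = 0.0
            else:
                jlon = rng.uniform(-0.49, 0.49) * res
                jlat = rng.uniform(-0.49, 0.49) * res
            records.append((t, float(lon_f[c] + jlon), float(lat_f[c] + jlat)))

    occ = OccurrenceSet(records=records)
    truth = SimTruth(
        params={
            "grid_shape": list(grid_shape), "n_env": n_env,
            "n_occ_per_taxon": n_occ_per_taxon, "scenario": scenario,
            "extent": list(extent), "resolution": res,
        },
        niche_centers={k: v.tolist() for k, v in centers.items()},
        niche_widths=widths, seed=seed,
    )
    return env, occ, truth
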