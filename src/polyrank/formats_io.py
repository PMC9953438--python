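"""Readers and writers for the standard formats the pipeline touches.

Genotypes come in as VCF (GT field only; diploid ``0/1`` and tetraploid
``0/0/0/1`` calls are both accepted), occurrences as ``taxon,lon,lat`` CSV,
environmental layers as ESRI ASCII grids, leaf annotations as CVAT XML or a
small JSON dialect, and pairwise distances go out as NEXUS or PHYLIP.

Missing genotypes stay MISSING (encoded as NaN dosage vectors); nothing is
imputed at I/O time.  Multiallelic sites are retained with dosage vectors
over all alleles, because downstream SNP-category classification needs
third alleles.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "OccurrenceSet",
    "EnvStack",
    "LeafAnnotation",
    "read_vcf_genotypes",
    "write_vcf_genotypes",
    "read_occurrence_table",
    "read_env_rasters",
    "read_esri_ascii",
    "write_esri_ascii",
    "write_distance_nexus",
    "read_distance_nexus",
    "write_distance_phylip",
    "read_leaf_annotations_json",
    "read_leaf_annotations_cvat",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x sites allele-dosage matrix with per-sample ploidy.

    ``dosages`` has shape ``(n_samples, n_sites, max_alleles)``; the vector
    for a non-missing call sums to the sample's ploidy, missing calls are
    all-NaN vectors.
    """

    sample_ids: list[str]
    taxon_of: dict[str, str]
    ploidy_of: dict[str, int]
    sites: list[tuple[str, int, str, tuple[str, ...]]]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        for s in self.sample_ids:
            p = self.ploidy_of.get(s)
            if p not in (2, 4):
                raise ValueError(f"sample {s!r}: ploidy must be 2 or 4, got {p}")
        seen: set[tuple[str, int]] = set()
        for chrom, pos, _, _ in self.sites:
            if (chrom, pos) in seen:
                raise ValueError(f"duplicate site {chrom}:{pos}")
            seen.add((chrom, pos))
        if self.dosages.shape[:2] != (len(self.sample_ids), len(self.sites)):
            raise ValueError("dosage array shape disagrees with samples/sites")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def ploidy_array(self) -> np.ndarray:
        return np.array([self.ploidy_of[s] for s in self.sample_ids])

    def samples_of_taxon(self, taxon: str) -> list[str]:
        return [s for s in self.sample_ids if self.taxon_of.get(s) == taxon]

    def index_of(self, sample: str) -> int:
        return self.sample_ids.index(sample)


@dataclass
class OccurrenceSet:
    """Geographic occurrence records, one (taxon, lon, lat) per row."""

    records: list[tuple[str, float, float]]
    crs: str = "EPSG:4326"

    def for_taxon(self, taxon: str) -> np.ndarray:
        return np.array([(lo, la) for t, lo, la in self.records if t == taxon]).reshape(-1, 2)

    @property
    def taxa(self) -> list[str]:
        out: list[str] = []
        for t, _, _ in self.records:
            if t not in out:
                out.append(t)
        return out


@dataclass
class EnvStack:
    """Aligned named 2-D raster layers on a shared geographic grid.

    Row 0 is the northernmost row; cell membership is half-open
    ``[edge, edge + res)``.  ``mask`` is True where a cell is nodata in any
    layer (union-of-nodata convention).
    """

    layers: dict[str, np.ndarray]
    extent: tuple[float, float, float, float]  # lon_min, lon_max, lat_min, lat_max
    resolution: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers have differing shapes: {shapes}")
        if self.mask is None:
            self.mask = np.zeros(self.shape, dtype=bool)
        for name, arr in self.layers.items():
            nan = ~np.isfinite(arr)
            if nan.any():
                self.mask = self.mask | nan

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a lon/lat point (row 0 = north)."""
        lon_min, lon_max, lat_min, lat_max = self.extent
        col = int(math.floor((lon - lon_min) / self.resolution))
        row = int(math.floor((lat_max - lat) / self.resolution))
        nrow, ncol = self.shape
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise ValueError(f"point ({lon}, {lat}) outside raster extent {self.extent}")
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) center coordinate arrays, each of grid shape."""
        lon_min, _, _, lat_max = self.extent
        nrow, ncol = self.shape
        lons = lon_min + (np.arange(ncol) + 0.5) * self.resolution
        lats = lat_max - (np.arange(nrow) + 0.5) * self.resolution
        return np.meshgrid(lons, lats)

    def as_array(self) -> np.ndarray:
        """Stack layers into (n_layers, nrow, ncol)."""
        return np.stack([self.layers[n] for n in self.layer_names])


@dataclass
class LeafAnnotation:
    """A leaf outline polygon plus main-vein polyline, in pixel coordinates."""

    specimen_id: str
    outline: np.ndarray  # (n, 2) closed polygon (first vertex not repeated)
    midvein: np.ndarray  # (m, 2) open polyline
    image_size: tuple[int, int]  # (height, width)

    def __post_init__(self) -> None:
        self.outline = np.asarray(self.outline, dtype=float)
        self.midvein = np.asarray(self.midvein, dtype=float)
        if self.outline.ndim != 2 or self.outline.shape[1] != 2 or len(self.outline) < 3:
            raise ValueError("outline must be an (n>=3, 2) polygon")
        if self.midvein.ndim != 2 or self.midvein.shape[1] != 2 or len(self.midvein) < 2:
            raise ValueError("midvein must have >= 2 vertices")


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

MISSING = float("nan")


def read_vcf_genotypes(
    path: str | Path,
    taxon_map: Mapping[str, str],
    ploidy_map: Mapping[str, int],
    *,
    dosage_coded: bool = False,
) -> GenotypeMatrix:
    """Parse GT fields of a (possibly mixed-ploidy) VCF into dosage vectors.

    ``0/1`` for a diploid becomes (1, 1); ``0/0/0/1`` for a tetraploid
    becomes (3, 1); any call containing ``.`` becomes MISSING.  A GT arity
    that disagrees with the declared ploidy is a hard error naming sample
    and site.  With ``dosage_coded=True`` tetraploids encoded as diploid GT
    plus a ``DS``/``AD``-free convention (each GT allele counted twice) are
    accepted.
    """
    path = Path(path)
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        unknown = [s for s in samples if s not in ploidy_map]
        if unknown:
            raise ValueError(f"samples missing from ploidy_map: {unknown}")
        sites: list[tuple[str, int, str, tuple[str, ...]]] = []
        rows: list[np.ndarray] = []
        for rec in vf:
            alts = tuple(rec.alts or ())
            n_alleles = 1 + len(alts)
            sites.append((rec.chrom, rec.pos, rec.ref, alts))
            site_dos = np.full((len(samples), n_alleles), np.nan)
            for j, s in enumerate(samples):
                ploidy = ploidy_map[s]
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                arity = len(gt)
                mult = 1
                if arity != ploidy:
                    if dosage_coded and arity == 2 and ploidy == 4:
                        mult = 2
                    else:
                        raise ValueError(
                            f"GT arity {arity} disagrees with ploidy {ploidy} "
                            f"for sample {s!r} at {rec.chrom}:{rec.pos}"
                        )
                vec = np.zeros(n_alleles)
                for a in gt:
                    if not 0 <= a < n_alleles:
                        raise ValueError(
                            f"allele index {a} out of range at {rec.chrom}:{rec.pos}"
                        )
                    vec[a] += mult
                site_dos[j] = vec
            rows.append(site_dos)

    max_alleles = max((r.shape[1] for r in rows), default=2)
    dosages = np.full((len(samples), len(rows), max_alleles), np.nan)
    for l, r in enumerate(rows):
        dosages[:, l, : r.shape[1]] = r
        # pad absent alleles with 0 for non-missing calls so vectors sum to ploidy
        called = np.isfinite(r[:, 0])
        dosages[called, l, r.shape[1]:] = 0.0

    return GenotypeMatrix(
        sample_ids=samples,
        taxon_of={s: taxon_map.get(s, "unknown") for s in samples},
        ploidy_of={s: int(ploidy_map[s]) for s in samples},
        sites=sites,
        dosages=dosages,
    )


def write_vcf_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF (GT only)."""
    path = Path(path)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chroms: list[str] = []
    for chrom, _, _, _ in g.sites:
        if chrom not in chroms:
            chroms.append(chrom)
    for chrom in chroms:
        header.add_line(f"##contig=<ID={chrom}>")
    for s in g.sample_ids:
        header.add_sample(s)
    ploidies = g.ploidy_array()
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for l, (chrom, pos, ref, alts) in enumerate(g.sites):
            rec = vf.new_record(contig=chrom, start=pos - 1, stop=pos,
                                alleles=(ref, *alts) if alts else (ref,))
            for j, s in enumerate(g.sample_ids):
                vec = g.dosages[j, l]
                if not np.isfinite(vec[0]):
                    rec.samples[s]["GT"] = tuple([None] * ploidies[j])
                else:
                    alleles: list[int] = []
                    for a, cnt in enumerate(vec):
                        alleles.extend([a] * int(round(cnt)))
                    rec.samples[s]["GT"] = tuple(alleles)
            vf.write(rec)


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

def read_occurrence_table(path: str | Path) -> OccurrenceSet:
    """Read a ``taxon,lon,lat`` CSV, validating ranges and de-duplicating."""
    path = Path(path)
    records: list[tuple[str, float, float]] = []
    seen: set[tuple[str, float, float]] = set()
    dropped = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        need = {"taxon", "lon", "lat"}
        if reader.fieldnames is None or not need.issubset(reader.fieldnames):
            raise ValueError(f"occurrence CSV must have columns {sorted(need)}")
        for i, row in enumerate(reader, start=2):
            lon, lat = float(row["lon"]), float(row["lat"])
            if not -180.0 <= lon <= 180.0:
                raise ValueError(f"row {i}: longitude {lon} out of [-180, 180]")
            if not -90.0 <= lat <= 90.0:
                raise ValueError(f"row {i}: latitude {lat} out of [-90, 90]")
            key = (row["taxon"], lon, lat)
            if key in seen:
                dropped += 1
                continue
            seen.add(key)
            records.append(key)
    if dropped:
        logger.info("dropped %d duplicate occurrence rows", dropped)
    if not records:
        warnings.warn(f"occurrence table {path} is empty", stacklevel=2)
    return OccurrenceSet(records=records)


def write_occurrence_table(occ: OccurrenceSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["taxon", "lon", "lat"])
        for t, lo, la in occ.records:
            w.writerow([t, repr(lo), repr(la)])


# ---------------------------------------------------------------------------
# ESRI ASCII rasters
# ---------------------------------------------------------------------------

def read_esri_ascii(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float, float], float]:
    """Read a single ESRI ASCII grid; nodata cells become NaN.

    Returns (array, extent, resolution) with extent = (lon_min, lon_max,
    lat_min, lat_max) of cell edges.
    """
    header: dict[str, float] = {}
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                values.extend(float(v) for v in parts)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    res = header["cellsize"]
    arr = np.array(values).reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    x0, y0 = header["xllcorner"], header["yllcorner"]
    extent = (x0, x0 + ncols * res, y0, y0 + nrows * res)
    return arr, extent, res


def write_esri_ascii(
    arr: np.ndarray,
    extent: tuple[float, float, float, float],
    resolution: float,
    path: str | Path,
    nodata: float = -9999.0,
) -> None:
    nrows, ncols = arr.shape
    lon_min, _, lat_min, _ = extent
    out = np.where(np.isfinite(arr), arr, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {lon_min!r}\nyllcorner {lat_min!r}\n")
        fh.write(f"cellsize {resolution!r}\nNODATA_value {nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _crop_to(arr: np.ndarray, extent, res, target_extent) -> np.ndarray:
    lon_min, lon_max, lat_min, lat_max = extent
    t_lon_min, t_lon_max, t_lat_min, t_lat_max = target_extent
    c0 = int(round((t_lon_min - lon_min) / res))
    c1 = int(round((t_lon_max - lon_min) / res))
    r0 = int(round((lat_max - t_lat_max) / res))
    r1 = int(round((lat_max - t_lat_min) / res))
    return arr[r0:r1, c0:c1]


def read_env_rasters(paths: Sequence[str | Path] | Mapping[str, str | Path]) -> EnvStack:
    """Read ESRI ASCII grids and align them onto their shared extent.

    Layers must share cell size; extents may differ, in which case every
    layer is cropped to the intersection rectangle.  Disjoint extents are
    an error.  The stack mask is the union of the layers' nodata cells.
    """
    if isinstance(paths, Mapping):
        items = [(str(k), Path(v)) for k, v in paths.items()]
    else:
        items = [(Path(p).stem, Path(p)) for p in paths]
    read = [(name, *read_esri_ascii(p)) for name, p in items]
    res = read[0][3]
    for name, _, _, r in read:
        if not math.isclose(r, res, rel_tol=1e-9):
            raise ValueError(f"layer {name!r}: cell size {r} differs from {res}")
    lon_min = max(e[0] for _, _, e, _ in read)
    lon_max = min(e[1] for _, _, e, _ in read)
    lat_min = max(e[2] for _, _, e, _ in read)
    lat_max = min(e[3] for _, _, e, _ in read)
    if lon_min >= lon_max or lat_min >= lat_max:
        raise ValueError("raster extents are disjoint; no shared area")
    target = (lon_min, lon_max, lat_min, lat_max)
    layers = {name: _crop_to(arr, ext, res, target) for name, arr, ext, _ in read}
    return EnvStack(layers=layers, extent=target, resolution=res)


# ---------------------------------------------------------------------------
# distance matrices: NEXUS and PHYLIP
# ---------------------------------------------------------------------------

def _check_distance_matrix(labels: Sequence[str], D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError(f"distance matrix shape {D.shape} != ({n}, {n})")
    if np.nanmax(np.abs(D - D.T)) > 1e-9:
        raise ValueError("distance matrix asymmetric beyond 1e-9")
    return D


def _quote(label: str) -> str:
    if re.search(r"[\s'()\[\]{}/\\,;:=*\"`+<>-]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_distance_nexus(labels: Sequence[str], D: np.ndarray, path: str | Path) -> None:
    """Write a full symmetric distance matrix as NEXUS TAXA + DISTANCES blocks."""
    D = _check_distance_matrix(labels, D)
    n = len(labels)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"  DIMENSIONS NTAX={n};\n  TAXLABELS\n")
        for lab in labels:
            fh.write(f"    {_quote(lab)}\n")
        fh.write("  ;\nEND;\n\nBEGIN DISTANCES;\n")
        fh.write("  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n  MATRIX\n")
        for i, lab in enumerate(labels):
            row = " ".join(format(D[i, j], ".12g") for j in range(n))
            fh.write(f"    {_quote(lab)} {row}\n")
        fh.write("  ;\nEND;\n")


def read_distance_nexus(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Re-read a NEXUS DISTANCES file written by :func:`write_distance_nexus`."""
    text = Path(path).read_text()
    m = re.search(r"BEGIN DISTANCES;.*?MATRIX\s*(.*?);\s*END;", text, re.S | re.I)
    if not m:
        raise ValueError("no DISTANCES block found")
    labels: list[str] = []
    rows: list[list[float]] = []
    for line in m.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            end = line.index("'", 1)
            while end + 1 < len(line) and line[end + 1] == "'":
                end = line.index("'", end + 2)
            label = line[1:end].replace("''", "'")
            rest = line[end + 1:]
        else:
            label, _, rest = line.partition(" ")
        labels.append(label)
        rows.append([float(v) for v in rest.split()])
    return labels, np.array(rows)


def write_distance_phylip(labels: Sequence[str], D: np.ndarray, path: str | Path) -> None:
    """Square PHYLIP distance matrix (alternate writer)."""
    D = _check_distance_matrix(labels, D)
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for i, lab in enumerate(labels):
            name = lab.replace(" ", "_")
            fh.write(name + "  " + " ".join(format(v, ".12g") for v in D[i]) + "\n")


# ---------------------------------------------------------------------------
# leaf annotations
# ---------------------------------------------------------------------------

def read_leaf_annotations_json(path: str | Path) -> list[LeafAnnotation]:
    """Read the JSON dialect: a list (or single object) with ``outline`` and
    ``midvein`` vertex lists plus optional ``specimen_id``/``image_size``."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    out = []
    for i, obj in enumerate(data):
        outline = np.array(obj["outline"], dtype=float)
        midvein = np.array(obj["midvein"], dtype=float)
        size = tuple(obj.get("image_size") or _size_from(outline))
        out.append(
            LeafAnnotation(
                specimen_id=str(obj.get("specimen_id", f"leaf_{i}")),
                outline=outline,
                midvein=midvein,
                image_size=(int(size[0]), int(size[1])),
            )
        )
    return out


def _size_from(outline: np.ndarray) -> tuple[int, int]:
    h = int(math.ceil(outline[:, 1].max())) + 1
    w = int(math.ceil(outline[:, 0].max())) + 1
    return h, w


def write_leaf_annotations_json(annots: Sequence[LeafAnnotation], path: str | Path) -> None:
    payload = [
        {
            "specimen_id": a.specimen_id,
            "outline": a.outline.tolist(),
            "midvein": a.midvein.tolist(),
            "image_size": list(a.image_size),
        }
        for a in annots
    ]
    Path(path).write_text(json.dumps(payload))


def read_leaf_annotations_cvat(path: str | Path) -> list[LeafAnnotation]:
    """Read CVAT-XML image annotations: one polygon (outline) and one
    polyline (main vein) per image."""
    tree = ET.parse(path)
    out: list[LeafAnnotation] = []
    for img in tree.getroot().iter("image"):
        name = img.get("name", img.get("id", "leaf"))
        h = int(float(img.get("height", "0")))
        w = int(float(img.get("width", "0")))
        poly = img.find("polygon")
        line = img.find("polyline")
        if poly is None or line is None:
            continue
        outline = _parse_cvat_points(poly.get("points", ""))
        midvein = _parse_cvat_points(line.get("points", ""))
        out.append(LeafAnnotation(str(name), outline, midvein, (h, w)))
    return out


def _parse_cvat_points(s: str) -> np.ndarray:
    pts = [tuple(float(v) for v in p.split(",")) for p in s.split(";") if p]
    return np.array(pts, dtype=float)
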