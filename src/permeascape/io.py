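"""Text-format readers and writers.

Rasters travel as single-band ESRI ASCII grids (integer class codes
1-9, legend in :data:`permeascape.types.LANDCOVER_CLASSES`); membership
surfaces as one ASCII grid per cluster plus a JSON sidecar, so
externally produced per-cluster probability rasters can be slotted in;
sites, genotypes and partitions as CSV (genotypes two columns per
locus, 0 = missing); segment rectangles as GeoJSON for inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    GenotypeMatrix,
    LandCoverRaster,
    MembershipSurface,
    PopulationPartition,
    SampleSite,
    Segment,
)

__all__ = [
    "write_ascii_grid", "read_ascii_grid", "write_raster", "read_raster",
    "write_sites_csv", "read_sites_csv",
    "write_genotypes_csv", "read_genotypes_csv", "read_genepop",
    "write_partition_csv", "read_partition_csv",
    "write_surface", "read_surface",
    "segments_geojson", "write_scenario_truth",
]


# ------------------------------------------------------------ ASCII grids

def write_ascii_grid(path: str | Path, data: np.ndarray, xllcorner: float,
                     yllcorner: float, cellsize: float, nodata: float = -9999) -> None:
    data = np.asarray(data)
    header = (
        f"ncols {data.shape[1]}\nnrows {data.shape[0]}\n"
        f"xllcorner {xllcorner:.6f}\nyllcorner {yllcorner:.6f}\n"
        f"cellsize {cellsize:.6f}\nNODATA_value {nodata}\n"
    )
    fmt = "%d" if np.issubdtype(data.dtype, np.integer) else "%.8g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    ):
        key, val = lines[i].split()[:2]
        meta[key.lower()] = float(val)
        i += 1
    data = np.loadtxt(lines[i:])
    data = np.atleast_2d(data)
    return data, meta


def write_raster(path: str | Path, raster: LandCoverRaster) -> None:
    _, ymin, _, _ = raster.extent
    write_ascii_grid(path, raster.classes.astype(int), raster.origin_x, ymin,
                     raster.resolution)


def read_raster(path: str | Path) -> LandCoverRaster:
    data, meta = read_ascii_grid(path)
    origin_y = meta["yllcorner"] + meta["nrows"] * meta["cellsize"]
    return LandCoverRaster(origin_x=meta["xllcorner"], origin_y=origin_y,
                           resolution=meta["cellsize"], classes=data.astype(np.int16))


# ------------------------------------------------------------------ sites

def write_sites_csv(path: str | Path, sites: list[SampleSite]) -> None:
    pd.DataFrame(
        [dict(site_id=s.id, x=s.x, y=s.y, cell_id=s.cell_id, habitat_class=s.habitat_class)
         for s in sites]
    ).to_csv(path, index=False)


def read_sites_csv(path: str | Path) -> list[SampleSite]:
    df = pd.read_csv(path)
    return [SampleSite(id=str(r.site_id), x=float(r.x), y=float(r.y),
                       cell_id=str(r.cell_id),
                       habitat_class=None if pd.isna(r.habitat_class) else str(r.habitat_class))
            for r in df.itertuples()]


# -------------------------------------------------------------- genotypes

def write_genotypes_csv(path: str | Path, G: GenotypeMatrix) -> None:
    cols: dict[str, object] = {"individual": G.individuals, "site_id": G.site_ids}
    for l, locus in enumerate(G.loci):
        cols[f"{locus}_1"] = G.calls[:, l, 0]
        cols[f"{locus}_2"] = G.calls[:, l, 1]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_genotypes_csv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path)
    loci = [c[:-2] for c in df.columns if c.endswith("_1") and f"{c[:-2]}_2" in df.columns]
    calls = np.stack(
        [np.column_stack([df[f"{l}_1"], df[f"{l}_2"]]) for l in loci], axis=1
    ).astype(np.int32)
    site_ids = df["site_id"].fillna("").astype(str).tolist() if "site_id" in df else [""] * len(df)
    return GenotypeMatrix(individuals=df["individual"].astype(str).tolist(),
                         site_ids=site_ids, loci=loci, calls=calls)


def read_genepop(path: str | Path) -> tuple[GenotypeMatrix, PopulationPartition]:
    """Minimal GENEPOP reader (2- or 3-digit alleles, comma-separated ids).

    Population blocks become clusters 1..k in file order; 00/000 codes
    map to missing (0).
    """
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    loci: list[str] = []
    i = 1  # skip title
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    inds, sites, rows, pops = [], [], [], []
    pop = 0
    for ln in lines[i:]:
        if ln.strip().lower() == "pop":
            pop += 1
            continue
        ident, geno = ln.split(",", 1)
        alleles = geno.split()
        if len(alleles) != len(loci):
            raise ValueError(f"{ident.strip()}: expected {len(loci)} loci, got {len(alleles)}")
        digits = len(alleles[0]) // 2
        row = [[int(a[:digits]), int(a[digits:])] for a in alleles]
        inds.append(ident.strip())
        sites.append("")
        rows.append(row)
        pops.append(pop)
    calls = np.asarray(rows, dtype=np.int32)
    G = GenotypeMatrix(individuals=inds, site_ids=sites, loci=loci, calls=calls)
    part = PopulationPartition(k=pop, site_to_pop={},
                               individual_to_pop=dict(zip(inds, pops)))
    return G, part


# -------------------------------------------------------------- partition

def write_partition_csv(path: str | Path, partition: PopulationPartition) -> None:
    rows = [dict(kind="site", id=s, population=p) for s, p in sorted(partition.site_to_pop.items())]
    rows += [dict(kind="individual", id=i, population=p)
             for i, p in sorted(partition.individual_to_pop.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_partition_csv(path: str | Path) -> PopulationPartition:
    df = pd.read_csv(path)
    site = {str(r.id): int(r.population) for r in df.itertuples() if r.kind == "site"}
    ind = {str(r.id): int(r.population) for r in df.itertuples() if r.kind == "individual"}
    k = int(df["population"].max())
    return PopulationPartition(k=k, site_to_pop=site, individual_to_pop=ind)


# ---------------------------------------------------------------- surface

def write_surface(base: str | Path, surf: MembershipSurface) -> None:
    """One ASCII grid per cluster band plus ``<base>.json`` sidecar."""
    base = Path(base)
    sidecar = dict(k=surf.k, xmin=surf.xmin, ymin=surf.ymin, xmax=surf.xmax,
                   ymax=surf.ymax, grid=surf.GRID,
                   bands=[f"{base.name}_band{c + 1}.asc" for c in range(surf.k)])
    base.parent.mkdir(parents=True, exist_ok=True)
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    for c in range(surf.k):
        write_ascii_grid(base.parent / sidecar["bands"][c], surf.probs[:, :, c],
                         surf.xmin, surf.ymin, (surf.xmax - surf.xmin) / surf.GRID or 1.0)


def read_surface(base: str | Path) -> MembershipSurface:
    base = Path(base)
    with open(base.with_suffix(".json")) as fh:
        meta = json.load(fh)
    bands = [read_ascii_grid(base.parent / b)[0] for b in meta["bands"]]
    probs = np.stack(bands, axis=2)
    return MembershipSurface(probs=probs, xmin=meta["xmin"], ymin=meta["ymin"],
                             xmax=meta["xmax"], ymax=meta["ymax"])


# --------------------------------------------------------------- segments

def segments_geojson(segments: list[Segment], width: float) -> dict:
    """GeoJSON FeatureCollection of segment rectangles at one width."""
    feats = []
    for seg in segments:
        ax, ay, bx, by = seg.site_a.x, seg.site_a.y, seg.site_b.x, seg.site_b.y
        L = seg.length
        ux, uy = (bx - ax) / L, (by - ay) / L
        nx, ny = -uy * width / 2, ux * width / 2
        ring = [[ax - nx, ay - ny], [ax + nx, ay + ny],
                [bx + nx, by + ny], [bx - nx, by - ny], [ax - nx, ay - ny]]
        feats.append(dict(type="Feature",
                          properties=dict(site_a=seg.site_a.id, site_b=seg.site_b.id,
                                          category=seg.category, length=seg.length,
                                          width=width),
                          geometry=dict(type="Polygon", coordinates=[ring])))
    return dict(type="FeatureCollection", features=feats)


def write_scenario_truth(path: str | Path, cfg) -> None:
    from dataclasses import asdict

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
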