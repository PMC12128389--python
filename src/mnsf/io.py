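"""Readers and writers for the formats the tool touches.

Visium-style directories (MatrixMarket counts + barcodes/features TSVs +
tissue positions CSV), plain TSV count/coordinate pairs, a JSON dataset
manifest, and the on-disk layout of fit results (per-sample factor CSVs,
loadings CSV, loss CSV, config JSON).
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.io import mmread

from .core_model import FactorMatrix, SampleData
from .inference import FitConfig, FitResult

__all__ = [
    "DatasetManifest",
    "ManifestEntry",
    "read_manifest",
    "read_visium",
    "read_tsv_pair",
    "write_sample_tsv",
    "write_results",
    "read_results",
    "ResultBundle",
]


@dataclass
class ManifestEntry:
    sample_id: str
    format: str  # "visium_dir" or "tsv"
    counts: str
    coords: Optional[str] = None
    labels: Optional[str] = None


@dataclass
class DatasetManifest:
    entries: List[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids in manifest must be unique")


def read_manifest(path: str | Path) -> DatasetManifest:
    """Load a JSON manifest: a list of sample records with file paths."""
    with open(path) as fh:
        raw = json.load(fh)
    entries = [ManifestEntry(**rec) for rec in raw]
    base = Path(path).parent
    for e in entries:
        for attr in ("counts", "coords", "labels"):
            p = getattr(e, attr)
            if p is not None:
                resolved = (base / p) if not Path(p).is_absolute() else Path(p)
                if not resolved.exists():
                    raise FileNotFoundError(f"{e.sample_id}: {attr} path {resolved}")
                setattr(e, attr, str(resolved))
    return DatasetManifest(entries=entries)


def load_manifest_samples(manifest: DatasetManifest) -> List[SampleData]:
    samples = []
    for e in manifest.entries:
        if e.format == "visium_dir":
            s = read_visium(e.counts, sample_id=e.sample_id)
        elif e.format == "tsv":
            s = read_tsv_pair(e.counts, e.coords, sample_id=e.sample_id)
        else:
            raise ValueError(f"unknown format tag {e.format!r}")
        if e.labels is not None:
            lab = pd.read_csv(e.labels, sep="\t", index_col=0)
            s.labels = lab.reindex(s.spot_ids).iloc[:, 0].to_numpy()
        samples.append(s)
    return samples


def _find(dirpath: Path, names: List[str]) -> Path:
    for name in names:
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"none of {names} found in {dirpath}")


def read_visium(dirpath: str | Path, sample_id: Optional[str] = None) -> SampleData:
    """Read a Visium-style directory into spots x genes counts with coordinates.

    Expects ``matrix.mtx[.gz]`` (genes x barcodes, 10x orientation),
    ``features.tsv[.gz]``, ``barcodes.tsv[.gz]`` and a tissue positions CSV.
    Pixel coordinates are used as the spot positions; spots flagged as out of
    tissue are dropped.
    """
    dirpath = Path(dirpath)
    mtx = _find(dirpath, ["matrix.mtx", "matrix.mtx.gz"])
    feat = _find(dirpath, ["features.tsv", "features.tsv.gz", "genes.tsv"])
    barc = _find(dirpath, ["barcodes.tsv", "barcodes.tsv.gz"])
    pos = _find(
        dirpath,
        ["tissue_positions.csv", "tissue_positions_list.csv", "positions.csv"],
    )
    counts = np.asarray(mmread(str(mtx)).todense()).T  # -> spots x genes
    features = pd.read_csv(feat, sep="\t", header=None)
    barcodes = pd.read_csv(barc, sep="\t", header=None)[0].astype(str).to_numpy()
    if counts.shape != (barcodes.size, features.shape[0]):
        raise ValueError(
            f"{dirpath}: matrix {counts.shape} does not match "
            f"{barcodes.size} barcodes x {features.shape[0]} features"
        )

    with open(pos) as fh:
        first = fh.readline()
    has_header = "barcode" in first.lower()
    cols = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"]
    positions = pd.read_csv(
        pos, header=0 if has_header else None,
        names=None if has_header else cols,
    )
    if has_header:
        positions.columns = cols[: len(positions.columns)]
    positions = positions.set_index(positions["barcode"].astype(str))
    missing = [b for b in barcodes if b not in positions.index]
    if missing:
        raise ValueError(f"{dirpath}: barcodes missing from positions: {missing[:5]}")
    positions = positions.loc[barcodes]

    keep = np.ones(barcodes.size, dtype=bool)
    if "in_tissue" in positions.columns:
        keep = positions["in_tissue"].to_numpy().astype(int) == 1
    coords = positions[["pxl_col", "pxl_row"]].to_numpy(dtype=float)
    gene_ids = features[0].astype(str).to_numpy()
    return SampleData(
        counts=counts[keep],
        coords=coords[keep],
        sample_id=sample_id or dirpath.name,
        spot_ids=barcodes[keep],
        gene_ids=gene_ids,
    )


def read_tsv_pair(
    counts_path: str | Path, coords_path: str | Path,
    sample_id: Optional[str] = None,
) -> SampleData:
    """Read a counts TSV (spot rows, gene columns) plus a 2-column coords TSV.

    Rows are aligned by spot id; the order of the counts file wins.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    coords = pd.read_csv(coords_path, sep="\t", index_col=0)
    if coords.shape[1] != 2:
        raise ValueError(f"{coords_path}: expected exactly 2 coordinate columns")
    missing = counts.index.difference(coords.index)
    if len(missing):
        raise ValueError(f"spot ids missing from coords: {list(missing[:5])}")
    coords = coords.reindex(counts.index)
    vals = counts.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        raise ValueError(f"{counts_path}: non-integer counts")
    return SampleData(
        counts=vals,
        coords=coords.to_numpy(dtype=float),
        sample_id=sample_id or Path(counts_path).stem,
        spot_ids=counts.index.astype(str).to_numpy(),
        gene_ids=counts.columns.astype(str).to_numpy(),
    )


def write_sample_tsv(
    sample: SampleData, counts_path: str | Path, coords_path: str | Path
) -> None:
    """Write one sample as the counts/coords TSV pair read_tsv_pair accepts."""
    pd.DataFrame(
        sample.counts,
        index=pd.Index(sample.spot_ids, name="spot_id"),
        columns=sample.gene_ids
        if sample.gene_ids is not None
        else [f"gene{g}" for g in range(sample.n_genes)],
    ).to_csv(counts_path, sep="\t")
    pd.DataFrame(
        sample.coords, index=pd.Index(sample.spot_ids, name="spot_id"),
        columns=["x", "y"],
    ).to_csv(coords_path, sep="\t")


@dataclass
class ResultBundle:
    """Re-loaded fit outputs (factors are on the log scale, as written)."""

    factors: List[pd.DataFrame]  # per sample: spot_id index, x, y, factor_1..L
    loadings: pd.DataFrame  # gene index, factor_1..L
    loss: np.ndarray
    config: dict
    sample_ids: List[str]


def write_results(
    fit: FitResult, out_dir: str | Path, dataset: Optional[List[SampleData]] = None
) -> None:
    """Write factors, loadings, loss and config to ``out_dir`` (created).

    Column order is deterministic; everything is re-loadable with
    :func:`read_results`.  ``dataset`` supplies spot ids and original
    coordinates for the factor CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    L = fit.config.L
    fcols = [f"factor_{l + 1}" for l in range(L)]
    for m, fm in enumerate(fit.factors):
        if dataset is not None:
            ids = dataset[m].spot_ids
            xy = dataset[m].coords
        else:
            ids = np.array([f"spot{i}" for i in range(fm.values.shape[0])])
            xy = np.zeros((fm.values.shape[0], 2))
        df = pd.DataFrame(
            np.column_stack([xy, fm.values]),
            index=pd.Index(ids, name="spot_id"),
            columns=["x", "y"] + fcols,
        )
        df.to_csv(out / f"factors_{fit.sample_ids[m]}.csv")
    gene_ids = (
        dataset[0].gene_ids
        if dataset is not None and dataset[0].gene_ids is not None
        else np.array([f"gene{g}" for g in range(fit.params.W.shape[0])])
    )
    pd.DataFrame(
        fit.params.W, index=pd.Index(gene_ids, name="gene"), columns=fcols
    ).to_csv(out / "loadings.csv")
    pd.DataFrame({"loss": fit.loss_trajectory}).to_csv(
        out / "loss.csv", index_label="iteration"
    )
    meta = dataclasses.asdict(fit.config)
    meta["sample_ids"] = list(fit.sample_ids)
    meta["converged"] = bool(fit.converged)
    with open(out / "config.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def read_results(out_dir: str | Path) -> ResultBundle:
    out = Path(out_dir)
    with open(out / "config.json") as fh:
        config = json.load(fh)
    sample_ids = config["sample_ids"]
    factors = [
        pd.read_csv(out / f"factors_{sid}.csv", index_col=0) for sid in sample_ids
    ]
    loadings = pd.read_csv(out / "loadings.csv", index_col=0)
    loss = pd.read_csv(out / "loss.csv", index_col=0)["loss"].to_numpy()
    return ResultBundle(
        factors=factors, loadings=loadings, loss=loss,
        config=config, sample_ids=sample_ids,
    )
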