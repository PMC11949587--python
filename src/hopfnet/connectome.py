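"""Region atlases, structural connectomes and tumor-region masks.

The structural substrate of the whole-brain model is a weighted, undirected
network whose nodes are cortical regions of a parcellation atlas and whose
edge weights quantify anatomical (streamline) connectivity. Tumor masks
select the subset of regions overlapping a patient's lesion; these are the
regions removed from the fitting objective during functional connectotomy.

File formats
------------
* Atlas: CSV with columns ``label[,x,y,z]`` (centroid coordinates in mm,
  optional but required for spatial clustering of tumor regions).
* Connectome / PLI matrices: delimited N x N numeric matrix whose header row
  holds the region labels in atlas order.
* Tumor masks: JSON object mapping ``subject_id`` to a list of region labels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import CapabilityError, FormatError, ValidationError

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered region labels, optionally with 3-D centroid coordinates (mm)."""

    labels: tuple[str, ...]
    centroids: np.ndarray | None = None

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValidationError("an atlas needs at least 2 regions")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("region labels must be unique")
        if self.centroids is not None:
            c = np.asarray(self.centroids, dtype=float)
            if c.shape != (len(self.labels), 3):
                raise ValidationError(
                    f"centroids must be {len(self.labels)}x3, got {c.shape}"
                )
            object.__setattr__(self, "centroids", c)

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region label {label!r}") from None


@dataclass(frozen=True)
class ConnectomeMatrix:
    """Nonnegative symmetric weighted adjacency matrix over an atlas."""

    W: np.ndarray
    atlas: RegionAtlas

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        n = self.atlas.n_regions
        if W.shape != (n, n):
            raise FormatError(f"connectome must be {n}x{n}, got {W.shape}")
        if not np.all(np.isfinite(W)):
            raise ValidationError("connectome contains non-finite weights")
        if np.any(W < 0):
            raise ValidationError("connectome weights must be nonnegative")
        if not np.allclose(W, W.T, atol=_SYMMETRY_TOL, rtol=0):
            raise ValidationError("connectome is not symmetric")
        if np.any(np.diag(W) != 0):
            raise ValidationError("connectome diagonal must be zero")
        if not np.any(W > 0):
            raise ValidationError("connectome has no positive weight")
        object.__setattr__(self, "W", W)

    @property
    def n_regions(self) -> int:
        return self.atlas.n_regions


@dataclass(frozen=True)
class TumorMask:
    """Set of region indices overlapping one subject's tumor."""

    subject_id: str
    regions: frozenset[int]
    n_regions: int  # atlas size the indices refer to

    def __post_init__(self):
        object.__setattr__(self, "regions", frozenset(int(i) for i in self.regions))
        bad = [i for i in self.regions if not 0 <= i < self.n_regions]
        if bad:
            raise ValidationError(f"mask indices out of range [0, {self.n_regions}): {bad}")


def read_atlas(path: str | Path) -> RegionAtlas:
    """Read a region atlas from CSV (columns: label[,x,y,z])."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "label" not in df.columns:
        raise FormatError(f"{path}: atlas CSV needs a 'label' column")
    labels = tuple(str(x) for x in df["label"])
    centroids = None
    if {"x", "y", "z"} <= set(df.columns):
        centroids = df[["x", "y", "z"]].to_numpy(dtype=float)
    return RegionAtlas(labels=labels, centroids=centroids)


def write_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    data: dict = {"label": list(atlas.labels)}
    if atlas.centroids is not None:
        data.update(
            x=atlas.centroids[:, 0], y=atlas.centroids[:, 1], z=atlas.centroids[:, 2]
        )
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def _sniff_delimiter(path: str | Path) -> str:
    """Detect the column delimiter from the header line (comma, tab, etc.)."""
    import csv

    with open(path, newline="") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",\t; ").delimiter
    except csv.Error:
        return ","


def _read_labeled_matrix(path: str | Path, atlas: RegionAtlas) -> np.ndarray:
    df = pd.read_csv(path, sep=_sniff_delimiter(path), float_precision="round_trip")
    if tuple(str(c) for c in df.columns) != atlas.labels:
        raise FormatError(
            f"{path}: header labels do not match atlas order "
            f"(got {list(df.columns)[:4]}..., expected {list(atlas.labels)[:4]}...)"
        )
    if len(df) != atlas.n_regions:
        raise FormatError(
            f"{path}: expected {atlas.n_regions} data rows, got {len(df)}"
        )
    return df.to_numpy(dtype=float)


def read_connectome(path: str | Path, atlas: RegionAtlas) -> ConnectomeMatrix:
    """Read and validate a structural connectome.

    Asymmetric input within reason (streamline-count matrices from external
    tools are near- but not exactly symmetric) is symmetrized by averaging;
    a nonzero diagonal is forced to zero. Both repairs are logged.
    """
    W = _read_labeled_matrix(path, atlas)
    if np.any(W < 0):
        raise ValidationError(f"{path}: negative connectome weight")
    if not np.allclose(W, W.T, atol=_SYMMETRY_TOL, rtol=0):
        logger.warning("%s: asymmetric connectome symmetrized by averaging", path)
        W = (W + W.T) / 2.0
    if np.any(np.diag(W) != 0):
        logger.warning("%s: nonzero diagonal forced to zero", path)
        np.fill_diagonal(W, 0.0)
    return ConnectomeMatrix(W=W, atlas=atlas)


def write_connectome(conn: ConnectomeMatrix, path: str | Path) -> None:
    pd.DataFrame(conn.W, columns=list(conn.atlas.labels)).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_tumor_masks(path: str | Path, atlas: RegionAtlas) -> dict[str, TumorMask]:
    """Read tumor masks from JSON mapping subject_id -> list of region labels."""
    with open(path) as fh:
        raw = json.load(fh)
    masks = {}
    for subject_id, labels in raw.items():
        idx = frozenset(atlas.index_of(lbl) for lbl in labels)
        masks[subject_id] = TumorMask(
            subject_id=subject_id, regions=idx, n_regions=atlas.n_regions
        )
    return masks


def write_tumor_masks(
    masks: dict[str, TumorMask], atlas: RegionAtlas, path: str | Path
) -> None:
    raw = {
        sid: sorted(atlas.labels[i] for i in m.regions) for sid, m in masks.items()
    }
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=1, sort_keys=True)


def union_tumor_regions(masks: list[TumorMask]) -> TumorMask:
    """Set-union of tumor regions across subjects (the pooled tumor mask)."""
    if not masks:
        raise ValidationError("union over an empty list of masks")
    n = masks[0].n_regions
    if any(m.n_regions != n for m in masks):
        raise ValidationError("masks refer to atlases of different sizes")
    regions: frozenset[int] = frozenset().union(*(m.regions for m in masks))
    return TumorMask(subject_id="union", regions=regions, n_regions=n)


def cluster_tumor_regions(
    masks: list[TumorMask],
    atlas: RegionAtlas,
    n_clusters: int = 3,
    seed: int = 0,
) -> dict[int, int]:
    """K-means clustering of tumor regions on their 3-D centroids.

    Groups the union of all subjects' tumor regions into ``n_clusters``
    spatial clusters (default 3). Uses 100 restarts at a fixed seed, keeping
    the lowest-inertia solution, so assignments are deterministic.

    Returns a mapping ``region index -> cluster id``.
    """
    if atlas.centroids is None:
        raise CapabilityError("clustering needs atlas centroids")
    union = union_tumor_regions(masks)
    regions = sorted(union.regions)
    if n_clusters < 1 or n_clusters > len(regions):
        raise ValidationError(
            f"n_clusters={n_clusters} not in [1, {len(regions)}] (tumor regions)"
        )
    pts = atlas.centroids[regions]
    km = KMeans(n_clusters=n_clusters, n_init=100, random_state=seed).fit(pts)
    return {r: int(c) for r, c in zip(regions, km.labels_)}
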