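"""Multiparametric tumor habitats by k-means clustering.

Co-registered parameter maps (T1w, T2w, T1 map, Ktrans, IVIM D0 and f, R2*)
are z-scored per channel within the tumor mask and clustered with k-means.
Habitat labels are renumbered by descending size so runs are deterministic
up to the clustering itself (fixed seed, k-means++ with restarts). Habitat
profiles (median and IQR per channel) are reported on the raw channel
units, since the channels are physically incommensurate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "ParameterStack",
    "FeatureTable",
    "HabitatMap",
    "build_feature_table",
    "cluster_habitats",
    "select_k",
    "habitat_profiles",
]


@dataclass
class ParameterStack:
    """Named channel volumes on one lattice plus the tumor mask."""

    channels: dict[str, np.ndarray]
    tumor_mask: np.ndarray
    affine: np.ndarray
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tumor_mask = np.asarray(self.tumor_mask).astype(bool)
        if not self.tumor_mask.any():
            raise ValueError("tumor mask is empty")
        for name, vol in self.channels.items():
            if np.asarray(vol).shape != self.tumor_mask.shape:
                raise ValueError(f"channel {name!r} is not on the tumor-mask lattice")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)


@dataclass
class FeatureTable:
    """Per-voxel feature rows (z-scored per channel within the tumor mask)."""

    features: np.ndarray           # (n_voxels, n_channels)
    voxel_indices: np.ndarray      # (n_voxels, 3) into the lattice
    channel_names: tuple[str, ...]
    shape: tuple[int, int, int]
    n_dropped: int = 0


def build_feature_table(stack: ParameterStack) -> FeatureTable:
    """Masked voxels x channels, each column zero-mean unit-variance.

    Non-finite voxels are dropped (and counted); a zero-variance channel is
    left as an all-zero column with a warning.
    """
    idx = np.argwhere(stack.tumor_mask)
    cols = [np.asarray(stack.channels[name], dtype=float)[stack.tumor_mask]
            for name in stack.channel_names]
    X = np.stack(cols, axis=1)
    finite = np.all(np.isfinite(X), axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} non-finite voxel(s) from the feature table",
                      stacklevel=2)
        X, idx = X[finite], idx[finite]
    if len(X) == 0:
        raise ValueError("no finite voxels inside the tumor mask")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD
    Z = np.zeros_like(X)
    for j, name in enumerate(stack.channel_names):
        if sd[j] == 0:
            warnings.warn(f"channel {name!r} has zero variance in the mask; "
                          "column left at zero", stacklevel=2)
        else:
            Z[:, j] = (X[:, j] - mean[j]) / sd[j]
    return FeatureTable(
        features=Z, voxel_indices=idx, channel_names=stack.channel_names,
        shape=stack.tumor_mask.shape, n_dropped=n_dropped,
    )


@dataclass
class HabitatMap:
    """Integer habitat labels over the tumor mask plus run metadata."""

    labels: np.ndarray             # lattice-shaped, 0 outside the tumor
    k: int
    seed: int
    inertia: float
    sizes: np.ndarray              # voxels per habitat, index h-1
    profiles: dict[int, dict[str, dict[str, float]]] = field(default_factory=dict)


def cluster_habitats(
    table: FeatureTable, k: int, seed: int = 0, n_init: int = 10
) -> HabitatMap:
    """k-means habitats (k-means++ init, best of ``n_init`` restarts).

    Labels are mapped back onto the lattice and renumbered by descending
    habitat size, so habitat 1 is always the largest.
    """
    n = len(table.features)
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available voxels")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw = km.fit_predict(table.features)
    sizes = np.bincount(raw, minlength=k)
    # size-descending order; centroid lexicographic tie-break keeps the
    # labeling invariant to voxel ordering even when sizes tie
    order = sorted(range(k),
                   key=lambda j: (-sizes[j], tuple(km.cluster_centers_[j])))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    lab = remap[raw]
    vol = np.zeros(table.shape, dtype=np.int16)
    vol[tuple(table.voxel_indices.T)] = lab
    return HabitatMap(
        labels=vol, k=k, seed=seed, inertia=float(km.inertia_),
        sizes=np.sort(sizes)[::-1],
    )


@dataclass
class KSelection:
    k: int
    silhouettes: dict[int, float]
    has_structure: bool


def select_k(
    table: FeatureTable,
    k_range=range(2, 7),
    seed: int = 0,
    n_init: int = 10,
    max_silhouette_n: int = 6000,
    structure_threshold: float = 0.2,
) -> KSelection:
    """Choose k by maximal mean silhouette over ``k_range`` (ties: smaller k).

    Silhouette is computed on the full table up to ``max_silhouette_n`` rows
    and on a seeded subsample beyond that. A best silhouette below
    ``structure_threshold`` flags the absence of habitat structure (the
    choice is still returned).
    """
    X = table.features
    n = len(X)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate features: all voxels identical")
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range contains no feasible k")
    sample = min(n, max_silhouette_n)
    sil: dict[int, float] = {}
    for k in ks:
        labels = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                        random_state=seed).fit_predict(X)
        if len(np.unique(labels)) < 2:
            sil[k] = -1.0
            continue
        kwargs = {} if sample == n else {"sample_size": sample, "random_state": seed}
        sil[k] = float(silhouette_score(X, labels, **kwargs))
    best = max(sil.values())
    chosen = min(k for k, s in sil.items() if s >= best - 1e-12)
    has_structure = best >= structure_threshold
    if not has_structure:
        warnings.warn(
            f"best silhouette {best:.3f} is below {structure_threshold}: "
            "no habitat structure detected", stacklevel=2,
        )
    return KSelection(k=chosen, silhouettes=sil, has_structure=has_structure)


def habitat_profiles(stack: ParameterStack, hmap: HabitatMap) -> dict:
    """Per-habitat, per-channel median and IQR on raw channel units."""
    out: dict[int, dict[str, dict[str, float]]] = {}
    for h in range(1, hmap.k + 1):
        sel = hmap.labels == h
        out[h] = {}
        for name in stack.channel_names:
            vals = np.asarray(stack.channels[name], dtype=float)[sel]
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            out[h][name] = {
                "median": float(med),
                "iqr": float(q3 - q1),
                "q1": float(q1),
                "q3": float(q3),
                "n": int(vals.size),
            }
    hmap.profiles = out
    return out
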