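"""Synthetic multi-view Gaussian-mixture data with shared cluster structure.

Each view draws its own cluster centers (random directions, rescaled so the
minimum pairwise center distance equals the requested separation) and adds
isotropic Gaussian noise; the cluster assignment is shared across views,
which is the structure a multi-view method is supposed to exploit.  Views
may differ in dimensionality and noise level, and a fraction of samples can
be flagged absent per view — never from all views at once — to emulate
incomplete multi-omics cohorts.

The defaults mirror a small multi-omics cohort: three views with a few
hundred selected features each, four clusters, and a separation-to-noise
ratio at which single-view clustering is reliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .data_model import MultiViewDataset

__all__ = ["ViewSpec", "SynthSpec", "generate", "degrade_view"]


@dataclass
class ViewSpec:
    """Geometry of one synthetic view."""

    d: int = 400
    center_separation: float = 6.0
    noise_sd: float = 1.0
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("view dimensionality must be >= 1")
        if self.center_separation <= 0:
            raise ValueError("center separation must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")


@dataclass
class SynthSpec:
    """Full specification of a synthetic multi-view dataset."""

    n_samples: int = 200
    n_clusters: int = 4
    views: list[ViewSpec] = field(default_factory=lambda: [
        ViewSpec(d=400), ViewSpec(d=170), ViewSpec(d=400)])
    proportions: np.ndarray | None = None
    heavy_tailed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.proportions is not None:
            p = np.asarray(self.proportions, dtype=float)
            if p.size != self.n_clusters or np.any(p < 0) or p.sum() <= 0:
                raise ValueError("invalid mixing proportions")
            self.proportions = p / p.sum()


def _cluster_centers(rng: np.random.Generator, k: int, d: int,
                     separation: float) -> np.ndarray:
    """Random-direction centers rescaled to minimum pairwise distance."""
    centers = rng.standard_normal((k, d))
    min_pair = pdist(centers).min()
    while min_pair <= 1e-9:  # essentially colinear draw; retry
        centers = rng.standard_normal((k, d))
        min_pair = pdist(centers).min()
    return centers * (separation / min_pair)


def generate(spec: SynthSpec) -> tuple[MultiViewDataset, np.ndarray]:
    """Draw a dataset; deterministic given ``spec.seed``.

    Returns ``(dataset, labels)``; labels are also stored on the dataset.
    A missingness draw that would leave a sample absent from every view is
    repaired by re-adding the sample to a random view (with a warning).
    """
    rng = np.random.default_rng(spec.seed)
    n, k, m = spec.n_samples, spec.n_clusters, len(spec.views)
    props = (np.full(k, 1.0 / k) if spec.proportions is None
             else spec.proportions)
    labels = rng.choice(k, size=n, p=props)

    views = []
    presence = np.ones((n, m), dtype=bool)
    for v, vs in enumerate(spec.views):
        centers = _cluster_centers(rng, k, vs.d, vs.center_separation)
        if spec.heavy_tailed:
            noise = rng.standard_t(3, size=(n, vs.d)) * vs.noise_sd
        else:
            noise = rng.standard_normal((n, vs.d)) * vs.noise_sd
        X = centers[labels] + noise
        if vs.missing_fraction > 0:
            n_missing = int(np.floor(vs.missing_fraction * n))
            absent = rng.choice(n, size=n_missing, replace=False)
            presence[absent, v] = False
        views.append(X)

    orphans = np.where(~presence.any(axis=1))[0]
    if orphans.size:
        warnings.warn(f"{orphans.size} samples were absent from every view; "
                      "re-added to one view each")
        for i in orphans:
            presence[i, rng.integers(m)] = True
    for v in range(m):
        views[v][~presence[:, v]] = 0.0

    ds = MultiViewDataset(views=views, sample_ids=[f"s{i}" for i in range(n)],
                          presence=presence, labels=labels)
    return ds, labels


def degrade_view(ds: MultiViewDataset, view: int, extra_noise_sd: float,
                 seed: int = 0) -> MultiViewDataset:
    """Add extra Gaussian noise to one view, leaving the others untouched.

    Useful for probing whether a combiner down-weights an inaccurate view.
    """
    if not 0 <= view < ds.n_views:
        raise ValueError(f"view index {view} out of range [0, {ds.n_views})")
    rng = np.random.default_rng(seed)
    views = [X.copy() for X in ds.views]
    if extra_noise_sd > 0:
        present = ds.presence[:, view]
        noise = rng.standard_normal(views[view].shape) * extra_noise_sd
        views[view][present] += noise[present]
    return MultiViewDataset(views=views, sample_ids=list(ds.sample_ids),
                            presence=ds.presence.copy(),
                            labels=None if ds.labels is None else ds.labels.copy())
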