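"""Multidimensional diet-similarity analysis.

PCA of the nine-item diet-score vectors (covariance decomposition: all items
share the 0-10 scale, so no standardization), pairwise Euclidean distances
in the first three components averaged within and between guilds, and
per-item score-frequency histograms for a guild subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.decomposition import PCA

from .guilds import FOOD_ITEMS

__all__ = [
    "DietSpaceResult",
    "GuildDistanceSummary",
    "pca_scores",
    "guild_distance_summary",
    "item_score_frequencies",
]


@dataclass
class DietSpaceResult:
    """Per-species principal-component coordinates, loadings and variance
    explained (percent, non-increasing).  ``coords`` is indexed by species
    with columns pc1, pc2, ..."""

    coords: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray

    def first_three(self) -> pd.DataFrame:
        return self.coords[["pc1", "pc2", "pc3"]]

    def coords_csv(self) -> str:
        out = self.first_three().copy()
        out.insert(0, "species", out.index)
        return out.to_csv(index=False)


def pca_scores(table: pd.DataFrame) -> DietSpaceResult:
    """Principal components of a species x food-item score table.

    Columns are mean-centered; components come from the covariance
    decomposition with a deterministic sign convention (the largest-magnitude
    loading of each component is positive).
    """
    X = table[list(FOOD_ITEMS)].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("PCA needs at least 4 species")
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("all diet-score vectors identical: zero variance")
    n_comp = min(n, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    load = pca.components_  # rows = components
    for c in range(n_comp):
        j = int(np.argmax(np.abs(load[c])))
        if load[c, j] < 0:
            load[c] *= -1
            scores[:, c] *= -1
    cols = [f"pc{i+1}" for i in range(n_comp)]
    coords = pd.DataFrame(scores, index=table.index, columns=cols)
    loadings = pd.DataFrame(load.T, index=list(FOOD_ITEMS), columns=cols)
    return DietSpaceResult(coords, loadings,
                           100.0 * pca.explained_variance_ratio_)


@dataclass
class GuildDistanceSummary:
    """Mean pairwise Euclidean distances (and standard errors over pairs)
    within guilds (diagonal) and between guilds (off-diagonal); symmetric.
    Within-guild entries are undefined (NaN) for guilds with < 2 members."""

    mean: pd.DataFrame
    sem: pd.DataFrame
    n_pairs: pd.DataFrame

    def to_csv(self) -> str:
        """Matrix of 'mean (sem)' strings, within-guild on the diagonal."""
        guilds = list(self.mean.index)
        rows = []
        for a in guilds:
            row = {}
            for b in guilds:
                m = self.mean.loc[a, b]
                s = self.sem.loc[a, b]
                row[b] = "" if np.isnan(m) else f"{m:.3f} ({s:.3f})"
            rows.append(row)
        df = pd.DataFrame(rows, index=guilds)
        df.insert(0, "guild", df.index)
        return df.to_csv(index=False)


def guild_distance_summary(coords: pd.DataFrame,
                           guilds: Mapping[str, str]) -> GuildDistanceSummary:
    """Average Euclidean distance in the first three components, within each
    guild (over n(n-1)/2 pairs) and between each guild pair (over na*nb
    pairs)."""
    missing = [sp for sp in coords.index if sp not in guilds]
    if missing:
        raise ValueError(f"species without guild assignment: {missing[:5]}")
    use = coords[["pc1", "pc2", "pc3"]]
    members: Dict[str, np.ndarray] = {}
    for sp in coords.index:
        members.setdefault(guilds[sp], []).append(sp)
    names = sorted(members)
    mean = pd.DataFrame(np.nan, index=names, columns=names)
    sem = pd.DataFrame(np.nan, index=names, columns=names)
    npairs = pd.DataFrame(0, index=names, columns=names)
    for i, a in enumerate(names):
        Xa = use.loc[members[a]].to_numpy()
        for b in names[i:]:
            if a == b:
                if len(members[a]) < 2:
                    continue
                d = pdist(Xa)
            else:
                Xb = use.loc[members[b]].to_numpy()
                d = cdist(Xa, Xb).ravel()
            m = float(d.mean())
            s = float(d.std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else 0.0
            mean.loc[a, b] = mean.loc[b, a] = m
            sem.loc[a, b] = sem.loc[b, a] = s
            npairs.loc[a, b] = npairs.loc[b, a] = len(d)
    return GuildDistanceSummary(mean, sem, npairs)


def item_score_frequencies(table: pd.DataFrame,
                           species: Sequence[str]) -> Dict[str, Dict[float, int]]:
    """Per-food-item histogram of scores over a species subset (e.g. all
    omnivores); each item's counts sum to the subset size."""
    species = list(species)
    if not species:
        raise ValueError("empty species subset")
    sub = table.loc[species, list(FOOD_ITEMS)]
    out: Dict[str, Dict[float, int]] = {}
    for item in FOOD_ITEMS:
        vals, counts = np.unique(sub[item].to_numpy(dtype=float), return_counts=True)
        out[item] = {float(v): int(c) for v, c in zip(vals, counts)}
    return out


def frequencies_to_json(freq: Mapping[str, Mapping[float, int]]) -> str:
    return json.dumps({item: {str(v): c for v, c in h.items()}
                       for item, h in freq.items()}, indent=2)
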