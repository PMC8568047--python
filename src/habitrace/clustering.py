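"""Functional clustering of responsive z traces and regional composition.

Deliberately over-clustered k-means (default k = 10, 20 replicate
initializations) partitions the responsive ROIs by response profile;
clusters are then validated for cross-animal consistency and merged when
their mean profiles are near-duplicates. Four validation criteria apply:

1. member coherence — each retained ROI must correlate > 0.5 with its
   cluster mean (low-correlation members are pruned first by default; a
   strict mode rejects the whole cluster instead);
2. size — at least 100 member ROIs;
3. breadth — represented (>= 1 member) in at least 75% of fish;
4. balance — no single fish contributes more than 33% of members.

Merging is the automated counterpart of combining clusters with near-
identical profiles: clusters whose mean traces correlate above a threshold
are joined by transitive closure, and merged means are member-weighted.
Every responsive class shares the loom lobes of the trace, which floors
cross-class mean correlations near 0.8; the default threshold of 0.9 sits
between that floor and the ≥0.95 correlations of same-class splinters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "ClusterResult",
    "ClusterValidity",
    "RegionComposition",
    "kmeans_traces",
    "validate_clusters",
    "merge_clusters",
    "region_composition",
]

MIN_CLUSTER_SIZE = 100
MIN_FISH_FRACTION = 0.75
MAX_SINGLE_FISH_SHARE = 1.0 / 3.0
MEMBER_CORR_MIN = 0.5


@dataclass
class ClusterValidity:
    """Per-cluster booleans for the four validation criteria."""

    coherent: bool  # members correlate with the cluster mean
    big_enough: bool  # >= 100 ROIs
    broad_enough: bool  # present in >= 75% of fish
    balanced: bool  # no fish contributes > 33%
    n_members: int
    n_fish_present: int
    max_fish_share: float

    @property
    def retained(self) -> bool:
        return self.coherent and self.big_enough and self.broad_enough and self.balanced


@dataclass
class ClusterResult:
    """k-means assignments, cluster mean traces, validity, and merge map."""

    assignments: pd.Series  # roi_id -> cluster id
    means: pd.DataFrame  # cluster id x sample
    inertia: float
    validity: dict[int, ClusterValidity] = field(default_factory=dict)
    merged_map: dict[int, int] = field(default_factory=dict)  # cluster -> merged id
    pruned: pd.Index | None = None  # roi_ids removed by the coherence criterion

    @property
    def retained_clusters(self) -> list[int]:
        return [c for c, v in self.validity.items() if v.retained]

    @property
    def merged_clusters(self) -> list[int]:
        return sorted(set(self.merged_map.values()))

    def merged_assignments(self) -> pd.Series:
        """roi_id -> merged cluster id, restricted to retained clusters."""
        keep = self.assignments[self.assignments.isin(self.merged_map.keys())]
        if self.pruned is not None:
            keep = keep.drop(index=self.pruned, errors="ignore")
        return keep.map(self.merged_map)


@dataclass(frozen=True)
class RegionComposition:
    """Per-region responsive proportions and normalized class shares."""

    proportion_responsive: pd.Series  # region -> mean over fish
    class_shares: pd.DataFrame  # region x class, rows sum to 1


def kmeans_traces(
    z_traces: pd.DataFrame, k: int = 10, replicates: int = 20, seed: int = 0
) -> ClusterResult:
    """Euclidean k-means over z traces, best of ``replicates`` seeded starts."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if len(z_traces) < k:
        raise ValueError(f"need at least k={k} ROIs, got {len(z_traces)}")
    km = KMeans(n_clusters=k, n_init=replicates, random_state=seed)
    labels = km.fit_predict(z_traces.to_numpy(dtype=float))
    assignments = pd.Series(labels, index=z_traces.index, name="cluster")
    means = pd.DataFrame(km.cluster_centers_, index=range(k), columns=z_traces.columns)
    return ClusterResult(assignments=assignments, means=means, inertia=float(km.inertia_))


def _member_correlations(block: np.ndarray, mean: np.ndarray) -> np.ndarray:
    mc = mean - mean.mean()
    denom_m = np.sqrt((mc**2).sum())
    bc = block - block.mean(axis=1, keepdims=True)
    denom_b = np.sqrt((bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (bc @ mc) / (denom_b * denom_m)
    return np.nan_to_num(r, nan=0.0)


def validate_clusters(
    result: ClusterResult,
    z_traces: pd.DataFrame,
    fish_ids: pd.Series,
    n_fish: int | None = None,
    *,
    strict_coherence: bool = False,
) -> ClusterResult:
    """Apply the four consistency criteria to each cluster.

    By default, members correlating <= 0.5 with the cluster mean are pruned
    and the remaining criteria evaluated on the survivors; with
    ``strict_coherence=True`` a cluster containing any such member is
    rejected outright. The fish-breadth denominator is ``n_fish`` (default:
    the number of distinct fish among the clustered ROIs).
    """
    fish = fish_ids.reindex(result.assignments.index)
    if n_fish is None:
        n_fish = int(fish.nunique())
    validity: dict[int, ClusterValidity] = {}
    pruned_ids: list = []
    for c in result.means.index:
        members = result.assignments.index[result.assignments == c]
        block = z_traces.loc[members].to_numpy(dtype=float)
        mean = result.means.loc[c].to_numpy(dtype=float)
        if len(members) == 0:
            validity[c] = ClusterValidity(False, False, False, False, 0, 0, 0.0)
            continue
        corr = _member_correlations(block, mean)
        low = corr <= MEMBER_CORR_MIN
        if strict_coherence:
            coherent = not bool(low.any())
            kept = members
        else:
            coherent = bool((~low).any())
            kept = members[~low]
            pruned_ids.extend(members[low])
        n_members = len(kept)
        fish_kept = fish.loc[kept]
        counts = fish_kept.value_counts()
        n_present = int(len(counts))
        max_share = float(counts.max() / n_members) if n_members else 0.0
        validity[c] = ClusterValidity(
            coherent=coherent,
            big_enough=n_members >= MIN_CLUSTER_SIZE,
            broad_enough=n_present >= MIN_FISH_FRACTION * n_fish,
            balanced=max_share <= MAX_SINGLE_FISH_SHARE,
            n_members=n_members,
            n_fish_present=n_present,
            max_fish_share=max_share,
        )
    result.validity = validity
    result.pruned = pd.Index(pruned_ids)
    return result


DEFAULT_MERGE_THRESHOLD = 0.9


def merge_clusters(
    result: ClusterResult, correlation_threshold: float = DEFAULT_MERGE_THRESHOLD
) -> ClusterResult:
    """Join retained clusters whose mean traces correlate above the threshold.

    Merging is the transitive closure of the pairwise relation, so the
    outcome is independent of cluster ordering. Merged cluster means are
    member-count-weighted averages, written back into ``result.means`` under
    the representative (smallest) cluster id.
    """
    retained = result.retained_clusters
    if not retained:
        result.merged_map = {}
        return result
    means = result.means.loc[retained].to_numpy(dtype=float)
    n = len(retained)
    corr = np.corrcoef(means) if n > 1 else np.ones((1, 1))
    # union-find over the threshold graph
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if corr[i, j] > correlation_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged_map: dict[int, int] = {}
    sizes = {c: result.validity[c].n_members for c in retained}
    for members in groups.values():
        ids = [retained[i] for i in members]
        rep = min(ids)
        for cid in ids:
            merged_map[cid] = rep
        w = np.array([sizes[cid] for cid in ids], dtype=float)
        merged_mean = (result.means.loc[ids].to_numpy(dtype=float).T @ (w / w.sum())).T
        result.means.loc[rep] = merged_mean
    result.merged_map = merged_map
    return result


def region_composition(
    responsive: pd.Series,
    class_labels: pd.Series,
    regions: pd.Series,
    fish_ids: pd.Series,
    class_names: tuple[str, ...] = ("dim", "checker", "both"),
) -> RegionComposition:
    """Per-region responsive proportions and normalized class composition.

    For each fish and region: responsive ROIs / total ROIs; these per-fish
    proportions are averaged across fish (fish lacking any ROI in a region
    are omitted from that region's average). Class shares are computed the
    same way over responsive ROIs only, then normalized to sum to 1 per
    region.
    """
    df = pd.DataFrame(
        {
            "responsive": responsive.astype(bool),
            "label": class_labels,
            "region": regions,
            "fish": fish_ids,
        }
    )
    prop = (
        df.groupby(["region", "fish"], observed=True)["responsive"]
        .mean()
        .groupby("region", observed=True)
        .mean()
    )
    shares = {}
    resp = df[df["responsive"]]
    for cls in class_names:
        frac = (
            resp.assign(hit=resp["label"] == cls)
            .groupby(["region", "fish"], observed=True)["hit"]
            .mean()
            .groupby("region", observed=True)
            .mean()
        )
        shares[cls] = frac
    share_df = pd.DataFrame(shares).fillna(0.0)
    row_sums = share_df.sum(axis=1)
    share_df = share_df.div(row_sums.where(row_sums > 0, 1.0), axis=0)
    return RegionComposition(proportion_responsive=prop, class_shares=share_df)
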