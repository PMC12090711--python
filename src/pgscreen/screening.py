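"""The candidate-gene screen built on the PG index.

Stages: filter gene families so both phenotype groups contribute enough
members; score every retained family; keep the top fraction (2% by default)
by PG index; re-cluster each candidate's members with k-means (K = 2) on the
same distance-row embedding and recompute the CH index with those labels;
rank candidates by recalculated CH; intersect top-k candidate lists across
cytokine comparisons; and, independently of sequence divergence, flag
presence/absence marker families enriched in the active group.

Rank statistics (Kruskal-Wallis across labeled PG-index collections, with
pairwise two-sided rank-sum tests under Bonferroni correction) summarize
whether PG-index distributions differ between runs or groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distances import build_distance_matrix
from .io import OgFamily, PresenceMatrix
from .pg_index import PgScore, bgss, ch_index, pg_score, row_embedding, wgss
from .phenotype import PhenotypeGroups


@dataclass
class ScreenConfig:
    """Tunable thresholds of the screen (defaults follow the published rules)."""

    top_fraction: float = 0.02
    k: int = 2
    top_k_overlap: int = 3
    kmeans_restarts: int = 10
    rng_seed: int = 0
    min_per_group: int = 2
    marker_active_threshold: float = 0.80
    marker_silent_threshold: float = 0.50
    filter_mode: str = "both"  # "both" | "any"
    embedding: str = "rows"

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.k != 2:
            raise ValueError("the screen is defined for K = 2")
        for t in (self.marker_active_threshold, self.marker_silent_threshold):
            if not (0 <= t <= 1):
                raise ValueError("marker thresholds must be in [0, 1]")
        if self.filter_mode not in ("both", "any"):
            raise ValueError("filter_mode must be 'both' or 'any'")


@dataclass
class ScreenResult:
    """Everything one (species, cytokine) screen produced."""

    species: str
    cytokine: str
    scores: list[PgScore]
    top2pct: list[str]
    kmeans_ranked: list[str]
    unplottable: set[str] = field(default_factory=set)  # recalculated CH == 0


@dataclass
class MarkerResult:
    """Presence/absence marker families for one comparison."""

    species: str
    cytokine: str
    markers: pd.DataFrame  # og_id, active_fraction, silent_fraction


def filter_ogs(
    presence: PresenceMatrix, groups: PhenotypeGroups, cfg: ScreenConfig
) -> list[str]:
    """Families represented by >= min_per_group strains in each group.

    Single-strain and absent families always fail; ``filter_mode='any'``
    relaxes the rule to either group (such families are still unscoreable
    if one group ends up empty, and are dropped at scoring).
    """
    if groups.degenerate:
        raise ValueError("refusing to screen degenerate phenotype groups")
    active_idx = [i for i, s in enumerate(presence.strain_ids) if s in groups.active]
    silent_idx = [i for i, s in enumerate(presence.strain_ids) if s in groups.silent]
    n_active = presence.present[:, active_idx].sum(axis=1)
    n_silent = presence.present[:, silent_idx].sum(axis=1)
    if cfg.filter_mode == "both":
        keep = (n_active >= cfg.min_per_group) & (n_silent >= cfg.min_per_group)
    else:
        keep = (n_active >= cfg.min_per_group) | (n_silent >= cfg.min_per_group)
        keep &= (n_active >= 1) & (n_silent >= 1)
    return [og for og, k in zip(presence.og_ids, keep) if k]


def score_all(
    families: Mapping[str, OgFamily],
    groups: PhenotypeGroups,
    cfg: ScreenConfig,
    og_ids: Sequence[str],
) -> list[PgScore]:
    """One PgScore per retained family, in the given order (deterministic)."""
    if not og_ids:
        raise ValueError("no families passed the filter")
    return [
        pg_score(families[og], groups, embedding=cfg.embedding) for og in og_ids
    ]


def _top_sort_key(s: PgScore):
    return (-s.pg_index, -s.ch_index, -s.bgss, -s.n_overall, s.og_id)


def select_top_fraction(
    scores: Sequence[PgScore], top_fraction: float
) -> list[str]:
    """The ceil(top_fraction * M) best families by PG index (at least one).

    Ties are broken by CH descending, then BGSS descending (separating
    coincident +inf scores), then family size descending, then og_id.
    """
    if not scores:
        raise ValueError("no scores to select from")
    k = max(1, math.ceil(top_fraction * len(scores)))
    return [s.og_id for s in sorted(scores, key=_top_sort_key)[:k]]


def _kmeans_once(x: np.ndarray, k: int, rng: np.random.Generator):
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = ((x - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        idx = rng.integers(n) if total == 0 else rng.choice(n, p=d2 / total)
        centers[c] = x[idx]
        d2 = np.minimum(d2, ((x - centers[c]) ** 2).sum(axis=1))
    labels = np.full(n, -1)
    for _ in range(300):
        dist = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new = dist.argmin(axis=1)
        for c in range(k):
            if not (new == c).any():
                # empty-cluster repair: move the point farthest from its centroid
                far = int(dist[np.arange(n), new].argmax())
                new[far] = c
        if (new == labels).all():
            break
        labels = new
        for c in range(k):
            centers[c] = x[labels == c].mean(axis=0)
    inertia = float(((x - centers[labels]) ** 2).sum())
    return labels, inertia


def kmeans2_recalc_ch(
    fam: OgFamily, cfg: ScreenConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, int] | None, float | None]:
    """K=2 k-means on the distance-row embedding plus CH recalculation.

    Returns (labels by strain, recalculated CH). The sequence-distribution
    factor is NOT applied to the recalculated index. Families with fewer
    than 3 members have an undefined CH and return (None, None); families
    whose members are all identical return CH = 0 (flagged unplottable by
    the caller).
    """
    if len(fam.members) < 3:
        return None, None
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    dm = build_distance_matrix(fam)
    emb = row_embedding(dm)
    x = emb.X
    if np.all(dm.d == 0.0):
        return {s: 0 for s in dm.strain_ids}, 0.0
    best_labels, best_inertia = None, math.inf
    for _ in range(cfg.kmeans_restarts):
        labels, inertia = _kmeans_once(x, 2, rng)
        if inertia < best_inertia:
            best_labels, best_inertia = labels, inertia
    cluster0 = frozenset(
        s for s, l in zip(dm.strain_ids, best_labels) if l == 0
    )
    cluster1 = frozenset(dm.strain_ids) - cluster0
    b = bgss(emb, cluster0, cluster1)
    w = wgss(emb, cluster0, cluster1)
    ch = ch_index(b, w, n=dm.n, k=2)
    return dict(zip(dm.strain_ids, (int(l) for l in best_labels))), ch


def overlap_top_k(
    result_a: ScreenResult, result_b: ScreenResult, top_k: int
) -> set[str]:
    """Families shared by both comparisons' top-k recalculated-CH lists."""
    return set(result_a.kmeans_ranked[:top_k]) & set(result_b.kmeans_ranked[:top_k])


def kruskal_wallis(score_groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p over labeled groups."""
    groups = [np.asarray(v, dtype=float) for v in score_groups.values()]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def pairwise_wilcoxon_bonferroni(
    score_groups: Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """Two-sided rank-sum p-values for every pair, Bonferroni-adjusted.

    Small tie-free pairs use the exact null distribution; larger or tied
    pairs the normal approximation with tie and continuity corrections.
    The adjusted value is min(1, p * number_of_pairs).
    """
    labels = list(score_groups)
    if len(labels) < 2:
        raise ValueError("need >=2 groups")
    n_pairs = len(labels) * (len(labels) - 1) // 2
    out = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for a, b in combinations(labels, 2):
        xa = np.asarray(score_groups[a], dtype=float)
        xb = np.asarray(score_groups[b], dtype=float)
        pooled = np.concatenate([xa, xb])
        if np.all(pooled == pooled[0]):
            p = 1.0
        else:
            p = float(
                stats.mannwhitneyu(xa, xb, alternative="two-sided", method="auto").pvalue
            )
        adj = min(1.0, p * n_pairs)
        out.loc[a, b] = out.loc[b, a] = adj
    return out


def marker_screen(
    presence: PresenceMatrix, groups: PhenotypeGroups, cfg: ScreenConfig
) -> MarkerResult:
    """Presence/absence markers: >=80% of active strains, <=50% of silent."""
    if groups.degenerate:
        raise ValueError("refusing to screen degenerate phenotype groups")
    active_idx = [i for i, s in enumerate(presence.strain_ids) if s in groups.active]
    silent_idx = [i for i, s in enumerate(presence.strain_ids) if s in groups.silent]
    af = presence.present[:, active_idx].sum(axis=1) / len(active_idx)
    sf = presence.present[:, silent_idx].sum(axis=1) / len(silent_idx)
    hit = (af >= cfg.marker_active_threshold) & (sf <= cfg.marker_silent_threshold)
    rows = [
        {"og_id": og, "active_fraction": float(a), "silent_fraction": float(s)}
        for og, a, s, h in zip(presence.og_ids, af, sf, hit)
        if h
    ]
    return MarkerResult(
        species=groups.species,
        cytokine=groups.cytokine,
        markers=pd.DataFrame(rows, columns=["og_id", "active_fraction", "silent_fraction"]),
    )


def run_screen(
    presence: PresenceMatrix,
    families: Mapping[str, OgFamily],
    groups: PhenotypeGroups,
    cfg: ScreenConfig,
) -> ScreenResult:
    """Full screen for one (species, cytokine) comparison.

    Deterministic given (inputs, cfg.rng_seed): each top-fraction candidate
    receives its own RNG stream derived from the seed and its rank-ordered
    position, so results do not depend on dict iteration order.
    """
    retained = [og for og in filter_ogs(presence, groups, cfg) if og in families]
    scores = score_all(families, groups, cfg, retained)
    top = select_top_fraction(scores, cfg.top_fraction)
    by_id = {s.og_id: s for s in scores}
    streams = np.random.SeedSequence(cfg.rng_seed).spawn(len(top))
    recalc: dict[str, float] = {}
    unplottable: set[str] = set()
    for og, ss in zip(top, streams):
        labels, ch = kmeans2_recalc_ch(
            families[og], cfg, rng=np.random.default_rng(ss)
        )
        by_id[og].in_top_fraction = True
        by_id[og].kmeans_labels = labels
        by_id[og].kmeans_ch = ch
        if ch is not None:
            recalc[og] = ch
            if ch == 0.0:
                unplottable.add(og)
    ranked = sorted(recalc, key=lambda og: (-recalc[og], og))
    return ScreenResult(
        species=groups.species,
        cytokine=groups.cytokine,
        scores=scores,
        top2pct=top,
        kmeans_ranked=ranked,
        unplottable=unplottable,
    )
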