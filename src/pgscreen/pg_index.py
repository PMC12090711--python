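"""The PG (potential-gene) index: a phenotype-group cluster-validity score.

For one orthologous gene group (OG), strains are embedded as the rows of the
OG's overall pairwise distance matrix, so the active-group, silent-group and
overall centroids all live in the same N-dimensional space and the variance
decomposition TSS = BGSS + WGSS holds exactly. The Calinski-Harabasz (CH)
index between the active and silent phenotype groups (K = 2),

    CH = (BGSS / (K - 1)) / (WGSS / (n - K)),

is then scaled by the sequence-distribution factor

    seq_dist_factor = N_overall / zero_value_count_overall,

the number of member strains divided by the count of zero entries in the
full N x N distance matrix (diagonal included, so the factor is exactly 1
when all members are distinct). The product CH x seq_dist_factor is the PG
index; it down-weights families whose members are largely identical, which
would otherwise separate trivially.

A family whose groups are internally identical but mutually distinct has
WGSS = 0 with BGSS > 0 — the strongest possible signal — and receives a +inf
CH sentinel rather than an arbitrary epsilon-regularized value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix, build_distance_matrix, classical_mds
from .phenotype import PhenotypeGroups


@dataclass(frozen=True)
class Embedding:
    """Strain coordinates for centroid arithmetic (default: distance rows)."""

    og_id: str
    strain_ids: tuple[str, ...]
    X: np.ndarray  # (N, p)

    def rows_for(self, members: set[str] | frozenset[str]) -> np.ndarray:
        idx = [i for i, s in enumerate(self.strain_ids) if s in members]
        if not idx:
            raise ValueError("no embedding rows for the requested strain set")
        return self.X[idx]


@dataclass
class PgScore:
    """All per-OG screening quantities."""

    og_id: str
    n_overall: int
    n_active: int
    n_silent: int
    zero_count: int
    bgss: float
    wgss: float
    ch_index: float
    seq_dist_factor: float
    pg_index: float
    kmeans_ch: float | None = None
    kmeans_labels: dict[str, int] | None = None
    in_top_fraction: bool = False


def row_embedding(dm: DistanceMatrix) -> Embedding:
    """Embed each strain as its row of the overall distance matrix."""
    return Embedding(og_id=dm.og_id, strain_ids=dm.strain_ids, X=dm.d.copy())


def mds_embedding(dm: DistanceMatrix, dims: int | None = None) -> Embedding:
    """Alternative embedding: classical MDS coordinates of the same matrix."""
    if dims is None:
        dims = dm.n - 1
    return Embedding(
        og_id=dm.og_id, strain_ids=dm.strain_ids, X=classical_mds(dm, dims)
    )


def group_centroid(emb: Embedding, members: set[str] | frozenset[str]) -> np.ndarray:
    """Arithmetic mean of the member strains' embedding rows."""
    return emb.rows_for(members).mean(axis=0)


def bgss(emb: Embedding, active: frozenset[str], silent: frozenset[str]) -> float:
    """Between-group sum of squares: sum_i n_i * ||C_i - C||^2."""
    xa = emb.rows_for(active)
    xs = emb.rows_for(silent)
    overall = np.vstack([xa, xs]).mean(axis=0)
    return float(
        len(xa) * np.sum((xa.mean(axis=0) - overall) ** 2)
        + len(xs) * np.sum((xs.mean(axis=0) - overall) ** 2)
    )


def wgss(emb: Embedding, active: frozenset[str], silent: frozenset[str]) -> float:
    """Within-group sum of squares: sum over groups of ||X - C_i||^2."""
    total = 0.0
    for members in (active, silent):
        x = emb.rows_for(members)
        total += float(np.sum((x - x.mean(axis=0)) ** 2))
    return total


def ch_index(bgss_value: float, wgss_value: float, n: int, k: int = 2) -> float:
    """Calinski-Harabasz index (BGSS/(K-1)) / (WGSS/(n-K)).

    WGSS = 0 with BGSS > 0 yields +inf (perfect separation sentinel);
    BGSS = 0 yields 0 regardless of WGSS.
    """
    if n <= k:
        raise ValueError(f"need n > K (got n={n}, K={k})")
    if bgss_value == 0.0:
        return 0.0
    if wgss_value == 0.0:
        return math.inf
    return (bgss_value / (k - 1)) / (wgss_value / (n - k))


def seq_dist_factor(dm: DistanceMatrix) -> float:
    """N_overall / (count of zero entries in the full overall matrix)."""
    if dm.n < 2:
        raise ValueError("need at least 2 members")
    zeros = int(np.count_nonzero(dm.d == 0.0))
    return dm.n / zeros


def pg_score(
    fam,
    groups: PhenotypeGroups,
    *,
    embedding: str = "rows",
    dm: DistanceMatrix | None = None,
) -> PgScore:
    """Assemble the full PG score of one family against one phenotype split.

    Only member strains with a phenotype are scored; both groups must be
    represented among the members (upstream filtering guarantees >=2 each).
    ``embedding`` selects the centroid space: ``"rows"`` (distance-matrix
    rows, default) or ``"mds"`` (classical MDS coordinates).
    """
    if groups.degenerate:
        raise ValueError(
            f"phenotype groups for ({groups.species}, {groups.cytokine}) "
            "are degenerate (one side empty)"
        )
    member_ids = set(fam.members) & set(groups.strains)
    active = frozenset(member_ids & groups.active)
    silent = frozenset(member_ids & groups.silent)
    if not active or not silent:
        raise ValueError(
            f"family {fam.og_id!r} lacks members in one phenotype group; "
            "it should have been filtered out"
        )
    if dm is None:
        sub = type(fam)(
            og_id=fam.og_id,
            members={s: fam.members[s] for s in member_ids},
        )
        dm = build_distance_matrix(sub)
    if embedding == "rows":
        emb = row_embedding(dm)
    elif embedding == "mds":
        emb = mds_embedding(dm)
    else:
        raise ValueError(f"unknown embedding {embedding!r}")
    b = bgss(emb, active, silent)
    w = wgss(emb, active, silent)
    ch = ch_index(b, w, n=dm.n, k=2)
    factor = seq_dist_factor(dm)
    zeros = int(np.count_nonzero(dm.d == 0.0))
    return PgScore(
        og_id=fam.og_id,
        n_overall=dm.n,
        n_active=len(active),
        n_silent=len(silent),
        zero_count=zeros,
        bgss=b,
        wgss=w,
        ch_index=ch,
        seq_dist_factor=factor,
        pg_index=ch * factor if math.isfinite(ch) else ch,
    )
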