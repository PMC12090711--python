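"""Per-family sequence distance matrices and classical MDS embedding.

Distances are p-distances (fraction of differing residues over gap-free
columns) between aligned amino-acid sequences. Unaligned pairs are first
globally aligned with a simple linear-gap Needleman-Wunsch. The distance
matrix rows double as the strain embedding used for centroid arithmetic, and
classical (Torgerson) MDS provides low-dimensional coordinates for
visual validation of candidate families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

GAP = "-"

_MATCH = 1
_MISMATCH = -1
_GAP = -2


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix for one gene family's members."""

    og_id: str
    strain_ids: tuple[str, ...]
    d: np.ndarray  # (N, N) float, zero diagonal

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.strain_ids), len(self.strain_ids)):
            raise ValueError("matrix shape does not match strain_ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return len(self.strain_ids)


def p_distance(a: str, b: str) -> float:
    """Fraction of differing residues among gap-free columns of an aligned pair.

    Columns where either sequence carries a gap are excluded (pairwise
    deletion). If no column survives, the pair is maximally distant (1.0)
    and a warning is issued.
    """
    if len(a) != len(b):
        raise ValueError(
            "sequences have unequal lengths; align them first (align_pair)"
        )
    xa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    xb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    gap = ord(GAP)
    valid = (xa != gap) & (xb != gap)
    n_valid = int(valid.sum())
    if n_valid == 0:
        warnings.warn(
            "no gap-free columns shared by the pair; distance set to 1.0",
            stacklevel=2,
        )
        return 1.0
    return float((xa[valid] != xb[valid]).sum()) / n_valid


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global alignment (match +1, mismatch -1, gap -2, linear).

    Traceback ties are broken deterministically: diagonal, then up (gap in
    the second sequence), then left.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    m, n = len(a), len(b)
    score = np.empty((m + 1, n + 1), dtype=np.int64)
    score[0, :] = _GAP * np.arange(n + 1)
    score[:, 0] = _GAP * np.arange(m + 1)
    for i in range(1, m + 1):
        row_prev = score[i - 1]
        row = score[i]
        ai = a[i - 1]
        for j in range(1, n + 1):
            sub = _MATCH if ai == b[j - 1] else _MISMATCH
            row[j] = max(row_prev[j - 1] + sub, row_prev[j] + _GAP, row[j - 1] + _GAP)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = _MATCH if a[i - 1] == b[j - 1] else _MISMATCH
            if score[i, j] == score[i - 1, j - 1] + sub:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + _GAP:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
            continue
        out_a.append(GAP)
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def alignment_score(a_aln: str, b_aln: str) -> int:
    """Score of an existing alignment under the align_pair parameters."""
    s = 0
    for x, y in zip(a_aln, b_aln):
        if x == GAP or y == GAP:
            s += _GAP
        elif x == y:
            s += _MATCH
        else:
            s += _MISMATCH
    return s


def _pairwise_p_distances_aligned(seqs: list[str]) -> np.ndarray:
    arr = np.vstack(
        [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in seqs]
    )
    gap = ord(GAP)
    nongap = arr != gap
    n = len(seqs)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        valid = nongap[i] & nongap[i + 1 :]
        diff = (arr[i] != arr[i + 1 :]) & valid
        n_valid = valid.sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = diff.sum(axis=1) / n_valid
        if (n_valid == 0).any():
            warnings.warn(
                "pair(s) with no gap-free shared columns; distance set to 1.0",
                stacklevel=3,
            )
            row = np.where(n_valid == 0, 1.0, row)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return d


def build_distance_matrix(fam) -> DistanceMatrix:
    """All pairwise p-distances for one family, strains in lexicographic order.

    Equal-length members are treated as aligned; ragged members are
    pairwise-aligned on the fly.
    """
    strain_ids = tuple(sorted(fam.members))
    if len(strain_ids) < 2:
        raise ValueError(f"family {fam.og_id!r} needs >=2 members for distances")
    seqs = [fam.members[s] for s in strain_ids]
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1:
        d = _pairwise_p_distances_aligned(seqs)
    else:
        n = len(seqs)
        d = np.zeros((n, n), dtype=float)
        for i in range(n):
            for j in range(i + 1, n):
                aa, bb = align_pair(seqs[i], seqs[j])
                d[i, j] = d[j, i] = p_distance(aa, bb)
    return DistanceMatrix(og_id=fam.og_id, strain_ids=strain_ids, d=d)


def classical_mds(dm: DistanceMatrix, dims: int) -> np.ndarray:
    """Torgerson classical MDS coordinates (N x dims).

    Squared distances are double-centered, eigendecomposed, and coordinates
    taken from the top ``dims`` eigenpairs; negative eigenvalues are
    truncated to zero. Each axis is oriented so its largest-magnitude
    loading is positive, making the output deterministic.
    """
    n = dm.n
    if dims >= n:
        raise ValueError(f"dims must be < number of points ({n}), got {dims}")
    d2 = dm.d**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[order], 0.0, None)
    coords = v[:, order] * np.sqrt(lam)
    for k in range(dims):
        col = coords[:, k]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords
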