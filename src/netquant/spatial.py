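"""Clustering vs dispersion of NETotic cell centres.

The statistic is the average nearest neighbor distance (ANND): the mean,
over all points in a tile, of the Euclidean distance to the closest other
point. Under complete spatial randomness at intensity lambda its
expectation is 1/(2 sqrt(lambda)) (Clark & Evans); smaller observed values
indicate clustering, larger ones dispersion. No edge correction is applied
— all tiles share one size, so the comparison between conditions is
unaffected.

Because ANND depends on how many cells a tile holds, two conditions are
compared only after their per-tile cell-count marginals are matched:
(1) the larger record set is culled uniformly at random with keep
probability equal to the size ratio; (2) both sets are truncated above the
smaller of the two cell-count maxima; (3) for every record of the
reference (un-culled) set, the closest-count record of the other set (ties
broken uniformly at random) is inserted into the resample. The two ANND
samples are then compared with a two-sample Kolmogorov-Smirnov test; the
whole match-and-test procedure is repeated with fresh randomness and the
replicate p-values are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import special
from sklearn.neighbors import NearestNeighbors

from .errors import DegenerateResampleError, ValidationError

__all__ = ["ANNDRecord", "KSComparison", "annd", "filter_tiles",
           "records_from_tiles", "match_marginals", "ks_two_sample",
           "compare_conditions", "clark_evans_expectation"]


@dataclass
class ANNDRecord:
    """One tile's (cell count, ANND) pair."""

    cell_count: int
    annd: float
    tile_id: str = ""

    def __post_init__(self):
        if self.cell_count < 2:
            raise ValidationError("ANND undefined for fewer than 2 cells")
        if not self.annd > 0:
            raise ValidationError("annd must be positive")


@dataclass
class KSComparison:
    """Repeated marginal-matched KS comparison of two ANND record sets.

    ``replicate_p`` / ``replicate_D`` hold one entry per repetition;
    ``p`` is their arithmetic-mean p-value (== ``mean_p``) and ``D`` the
    mean statistic.
    """

    D: float
    p: float
    n1: int
    n2: int
    replicate_p: list[float] = dc_field(default_factory=list)
    replicate_D: list[float] = dc_field(default_factory=list)

    @property
    def mean_p(self) -> float:
        return float(np.mean(self.replicate_p))


def annd(points) -> float:
    """Mean nearest-neighbor Euclidean distance of a point set (n >= 2).

    ``points`` is (n, 2); the coordinate convention does not matter as long
    as it is consistent.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValidationError("annd needs at least two 2-D points")
    nn = NearestNeighbors(n_neighbors=2).fit(pts)
    dist, _ = nn.kneighbors(pts)
    return float(dist[:, 1].mean())


def clark_evans_expectation(n_points: int, area: float) -> float:
    """CSR expectation 1 / (2 sqrt(lambda)) with lambda = points per unit
    area."""
    return 1.0 / (2.0 * np.sqrt(n_points / area))


def records_from_tiles(tiles, label: int = 2, min_points: int = 2
                       ) -> list[ANNDRecord]:
    """Build (cell count, ANND) records from annotated tiles, using the
    annotation points with the given label (default NETotic)."""
    records = []
    for tile in tiles:
        ann = tile.annotations
        pts = ann[ann.label == label][["x", "y"]].to_numpy(dtype=float)
        if len(pts) >= min_points:
            records.append(ANNDRecord(cell_count=len(pts), annd=annd(pts),
                                      tile_id=tile.field_id))
    return records


def filter_tiles(records: list[ANNDRecord], min_cells: int = 20
                 ) -> list[ANNDRecord]:
    """Keep records with cell_count >= min_cells (tiles with fewer are
    discarded as too noisy; a tile at exactly the minimum is retained)."""
    return [r for r in records if r.cell_count >= min_cells]


def match_marginals(set_a: list[ANNDRecord], set_b: list[ANNDRecord],
                    rng: np.random.Generator | int | None = 0
                    ) -> tuple[list[ANNDRecord], list[ANNDRecord]]:
    """Match the cell-count marginals of two record sets.

    Returns ``(reference, resampled)``: the reference is whichever input
    was *not* culled (the smaller one; ``set_a`` on equal sizes) after the
    truncation stage, and the resample draws, for each reference record,
    the closest-count record (ties uniform at random, with replacement)
    from the other set. ``len(resampled) == len(reference)`` always.
    """
    if not set_a or not set_b:
        raise DegenerateResampleError("both record sets must be non-empty")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    a, b = list(set_a), list(set_b)
    # stage 1: cull the larger set at keep probability = size ratio
    if len(a) > len(b):
        keep = rng.random(len(a)) < len(b) / len(a)
        a = [r for r, k in zip(a, keep) if k]
        ref, src = b, a
    elif len(b) > len(a):
        keep = rng.random(len(b)) < len(a) / len(b)
        b = [r for r, k in zip(b, keep) if k]
        ref, src = a, b
    else:
        ref, src = a, b
    if not src:
        raise DegenerateResampleError("culling stage emptied one set")
    # stage 2: truncate both above the smaller of the two count maxima
    cap = min(max(r.cell_count for r in ref),
              max(r.cell_count for r in src))
    ref = [r for r in ref if r.cell_count <= cap]
    src = [r for r in src if r.cell_count <= cap]
    if not ref or not src:
        raise DegenerateResampleError("truncation stage emptied one set")
    # stage 3: nearest-count resample with random tie-breaks
    src_counts = np.array([r.cell_count for r in src])
    resampled = []
    for r in ref:
        d = np.abs(src_counts - r.cell_count)
        ties = np.flatnonzero(d == d.min())
        resampled.append(src[int(rng.choice(ties))])
    return ref, resampled


def ks_two_sample(x, y, method: str = "asymptotic",
                  n_permutations: int = 10_000,
                  rng: np.random.Generator | int | None = 0
                  ) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs. The default
    p-value uses the asymptotic Kolmogorov distribution at effective size
    n1*n2/(n1+n2); ``method="permutation"`` gives an exact Monte-Carlo
    p-value (pooled relabelling, ``n_permutations`` resamples) for small
    samples.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValidationError("both samples need at least 2 values")
    d = _ks_statistic(x, y)
    if method == "asymptotic":
        ne = n1 * n2 / (n1 + n2)
        p = float(np.clip(special.kolmogorov(np.sqrt(ne) * d), 0.0, 1.0))
    elif method == "permutation":
        rng = np.random.default_rng(rng) if not isinstance(
            rng, np.random.Generator) else rng
        pooled = np.concatenate([x, y])
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if _ks_statistic(np.sort(perm[:n1]), np.sort(perm[n1:])) >= d - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return float(d), float(p)


def _ks_statistic(xs: np.ndarray, ys: np.ndarray) -> float:
    """Sup |F_x - F_y| for pre-sorted samples."""
    grid = np.concatenate([xs, ys])
    fx = np.searchsorted(xs, grid, side="right") / len(xs)
    fy = np.searchsorted(ys, grid, side="right") / len(ys)
    return float(np.abs(fx - fy).max())


def compare_conditions(set_a: list[ANNDRecord], set_b: list[ANNDRecord],
                       replicates: int = 10, seed: int = 0,
                       method: str = "asymptotic") -> KSComparison:
    """Repeated marginal-matched KS comparison of two conditions' ANNDs.

    Each replicate reruns :func:`match_marginals` with fresh randomness and
    KS-tests the reference ANNDs against the resampled ANNDs; the reported
    p-value is the arithmetic mean over replicates.
    """
    if replicates < 1:
        raise ValidationError("need at least 1 replicate")
    rng = np.random.default_rng(seed)
    ps, ds = [], []
    for _ in range(replicates):
        ref, res = match_marginals(set_a, set_b, rng)
        d, p = ks_two_sample([r.annd for r in ref], [r.annd for r in res],
                             method=method, rng=rng)
        ps.append(p)
        ds.append(d)
    return KSComparison(D=float(np.mean(ds)), p=float(np.mean(ps)),
                        n1=len(set_a), n2=len(set_b),
                        replicate_p=ps, replicate_D=ds)
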