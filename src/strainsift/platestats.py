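"""Plate geometry and the proximity (distance vs sharing) rank-sum test.

Well-to-well transfer predominantly hits neighbouring wells, so on a
contaminated plate the unrelated pairs that share strains should sit closer
together than the pairs that do not.  The test compares the within-plate
Euclidean distances of sharing pairs against non-sharing pairs with the
Wilcoxon rank-sum test (normal approximation without tie correction, the
convention of ``scipy.stats.ranksums``), with an exact/Monte-Carlo
permutation mode as reference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .model import SampleMeta, WellAddress
from .network import SharingEdge, is_unrelated

ALTERNATIVES = ("two_sided", "less", "greater")


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # standardized rank-sum z of the first group
    p_value: float
    method: str  # normal_approx | permutation_exact | permutation_mc


@dataclass(frozen=True)
class ProximityTestResult:
    plate_id: str
    n_sharing_pairs: int
    n_nonsharing_pairs: int
    statistic: float | None
    p_value: float | None
    method: str
    alternative: str
    testable: bool


def well_distance(a: WellAddress, b: WellAddress) -> float:
    """Euclidean distance between two wells of the same plate, in grid units."""
    if a.plate_id != b.plate_id:
        raise ValueError(f"wells on different plates: {a.plate_id} vs {b.plate_id}")
    return math.hypot(a.row - b.row, a.col - b.col)


def sample_pair_distance(a: SampleMeta, b: SampleMeta, plate_id: str) -> float | None:
    """Minimum distance over the two samples' contributing wells on a plate.

    Merged duplicate samples contribute several wells; contamination can act
    at any of them, so the closest pairing is used.  Returns ``None`` when
    either sample has no well on the plate.
    """
    wa = [w for w in a.wells if w.plate_id == plate_id]
    wb = [w for w in b.wells if w.plate_id == plate_id]
    if not wa or not wb:
        return None
    return min(well_distance(x, y) for x in wa for y in wb)


def _normal_p(z: float, alternative: str) -> float:
    if alternative == "two_sided":
        return float(2 * norm.sf(abs(z)))
    if alternative == "less":
        return float(norm.cdf(z))
    if alternative == "greater":
        return float(norm.sf(z))
    raise ValueError(f"unknown alternative {alternative!r}")


def rank_sum_test(
    x,
    y,
    alternative: str = "two_sided",
    method: str = "normal_approx",
    rng: np.random.Generator | None = None,
    max_exact: int = 100_000,
    n_resamples: int = 10_000,
    exact: bool | None = None,
    use_continuity: bool = True,
) -> RankSumResult:
    """Wilcoxon rank-sum test of ``x`` against ``y``.

    Midranks are assigned over the pooled values and the first group's rank
    sum ``W`` is standardized as ``z = (W - nx(N+1)/2) / sqrt(nx ny (N+1)/12)``
    with no tie correction.  ``method='normal_approx'`` takes p from the
    standard normal, by default with a 0.5 continuity correction (the
    convention of R's ``wilcox.test`` and ``scipy.stats.mannwhitneyu``; it
    keeps the approximation within ~0.01 of the exact permutation p at group
    sizes of ten).  ``use_continuity=False`` reproduces the uncorrected
    ``scipy.stats.ranksums`` p; the reported ``statistic`` is always the
    uncorrected z.  ``method='permutation'`` recomputes p by exhaustive
    enumeration of group assignments when ``C(N, nx) <= max_exact`` (or when
    ``exact=True`` forces it), otherwise by Monte-Carlo with ``rng``.

    With every pooled value tied, z = 0 and the two-sided p is 1 (degenerate
    but defined).
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    nx_, ny_ = int(x.size), int(y.size)
    n = nx_ + ny_
    ranks = rankdata(np.concatenate([x, y]))
    w = float(ranks[:nx_].sum())
    mu = nx_ * (n + 1) / 2.0
    sigma = math.sqrt(nx_ * ny_ * (n + 1) / 12.0)
    z = 0.0 if sigma == 0 else (w - mu) / sigma

    if method == "normal_approx":
        zp = z
        if use_continuity and sigma > 0:
            if alternative == "two_sided":
                zp = math.copysign(max(abs(w - mu) - 0.5, 0.0), w - mu) / sigma
            elif alternative == "less":
                zp = (w - mu + 0.5) / sigma
            else:
                zp = (w - mu - 0.5) / sigma
        return RankSumResult(z, min(1.0, _normal_p(zp, alternative)), "normal_approx")
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    n_comb = math.comb(n, nx_)
    tol = 1e-9
    if exact or (exact is None and n_comb <= max_exact):
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), nx_)),
            dtype=np.intp,
            count=n_comb * nx_,
        ).reshape(n_comb, nx_)
        sums = ranks[idx].sum(axis=1)
        label = "permutation_exact"
    else:
        rng = rng if rng is not None else np.random.default_rng(0)
        sums = np.empty(n_resamples)
        for i in range(n_resamples):
            sums[i] = ranks[rng.permutation(n)[:nx_]].sum()
        label = "permutation_mc"

    if alternative == "two_sided":
        p = float(np.mean(np.abs(sums - mu) >= abs(w - mu) - tol))
    elif alternative == "less":
        p = float(np.mean(sums <= w + tol))
    else:
        p = float(np.mean(sums >= w - tol))
    return RankSumResult(z, p, label)


def proximity_test(
    plate_id: str,
    edges: list[SharingEdge],
    samples: list[SampleMeta],
    alternative: str = "two_sided",
    method: str = "normal_approx",
    rng: np.random.Generator | None = None,
    treat_pc_as_subject: bool = False,
) -> ProximityTestResult:
    """Distance-vs-sharing rank-sum test for one plate.

    ``x`` holds the distances of unrelated within-plate pairs that share at
    least one strain, ``y`` the distances of unrelated within-plate pairs
    sharing none; pairs involving unplaced samples are excluded.  When either
    group is empty the plate is reported untestable with no p-value.
    """
    sharing_pairs = {e.pair for e in edges}
    placed = [
        s for s in samples if any(w.plate_id == plate_id for w in s.wells)
    ]
    x: list[float] = []
    y: list[float] = []
    for a, b in itertools.combinations(placed, 2):
        if not is_unrelated(a, b, treat_pc_as_subject):
            continue
        dist = sample_pair_distance(a, b, plate_id)
        if dist is None:
            continue
        if frozenset((a.sample_id, b.sample_id)) in sharing_pairs:
            x.append(dist)
        else:
            y.append(dist)
    if not x or not y:
        return ProximityTestResult(
            plate_id, len(x), len(y), None, None, method, alternative, False
        )
    res = rank_sum_test(x, y, alternative=alternative, method=method, rng=rng)
    return ProximityTestResult(
        plate_id, len(x), len(y), res.statistic, res.p_value, res.method,
        alternative, True,
    )


def write_proximity_tsv(results: list[ProximityTestResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "plate_id\tn_sharing_pairs\tn_nonsharing_pairs\tstatistic\t"
            "p_value\tmethod\talternative\ttestable\n"
        )
        for r in results:
            stat = "" if r.statistic is None else f"{r.statistic:.6g}"
            p = "" if r.p_value is None else f"{r.p_value:.6g}"
            fh.write(
                f"{r.plate_id}\t{r.n_sharing_pairs}\t{r.n_nonsharing_pairs}\t"
                f"{stat}\t{p}\t{r.method}\t{r.alternative}\t{r.testable}\n"
            )
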