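"""Replicate (mouse) batch-variation test on embedded pair distances.

For each (cell type, timepoint) stratum, 100 random cell pairs drawn
within one mouse and 100 drawn across two mice of the same timepoint
are compared: if the cross-mouse pair distances in the 2-D embedding
are stochastically longer (two-sample KS test, one-sided direction via
the medians), the stratum shows mouse-driven batch variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp


@dataclass
class PairDistanceResult:
    stratum: tuple  # (cell type, timepoint)
    same_mouse_distances: np.ndarray
    diff_mouse_distances: np.ndarray
    ks_statistic: float | None
    p_value: float | None
    verdict: str  # no_batch_effect | batch_effect | insufficient_cells


def sample_pair_distances(
    embedding: np.ndarray,
    cells: pd.DataFrame,
    labels: np.ndarray,
    stratum: tuple,
    n_pairs: int = 100,
    seed: int = 0,
):
    """Sample same-mouse and cross-mouse pair distances for one stratum.

    ``stratum = (cell_type_label, timepoint)``.  Pairs are distinct
    cells, sampled with replacement over pairs; cross-mouse pairs span
    two mice of the stratum's timepoint.  Returns ``(same, diff)``
    arrays or ``(None, None)`` when the stratum lacks two mice with
    two cells each.
    """
    rng = np.random.default_rng(seed)
    ctype, tp = stratum
    labels = np.asarray(labels)
    sel = (labels == ctype) & (cells["timepoint"].to_numpy() == tp)
    idx = np.flatnonzero(sel)
    mice = cells["mouse_id"].to_numpy()[idx]
    by_mouse = {m: idx[mice == m] for m in pd.unique(mice)}
    usable = [m for m, v in by_mouse.items() if len(v) >= 2]
    if len(usable) < 2:
        return None, None

    def dist(a, b):
        return np.linalg.norm(embedding[a] - embedding[b], axis=-1)

    same = np.empty(n_pairs)
    for t in range(n_pairs):
        m = usable[rng.integers(len(usable))]
        a, b = rng.choice(by_mouse[m], size=2, replace=False)
        same[t] = dist(a, b)
    diff = np.empty(n_pairs)
    for t in range(n_pairs):
        m1, m2 = rng.choice(len(usable), size=2, replace=False)
        a = rng.choice(by_mouse[usable[m1]])
        b = rng.choice(by_mouse[usable[m2]])
        diff[t] = dist(a, b)
    return same, diff


def compare_distance_cdfs(
    same, diff, stratum=("", ""), alpha: float = 0.05
) -> PairDistanceResult:
    """Two-sample KS comparison of same- vs cross-mouse distances.

    Verdict is ``batch_effect`` iff the KS p-value is below ``alpha``
    AND the cross-mouse median exceeds the same-mouse median (pairs
    from different animals must be *longer*, not merely different).
    """
    if same is None or diff is None:
        return PairDistanceResult(stratum, None, None, None, None, "insufficient_cells")
    same = np.asarray(same, float)
    diff = np.asarray(diff, float)
    if same.size == 0 or diff.size == 0:
        raise ValueError("empty distance list")
    if np.all(same == same[0]) and np.all(diff == same[0]):
        stat, p = 0.0, 1.0
    else:
        res = ks_2samp(same, diff, method="asymp")
        stat, p = float(res.statistic), float(res.pvalue)
    verdict = (
        "batch_effect"
        if (p < alpha and np.median(diff) > np.median(same))
        else "no_batch_effect"
    )
    return PairDistanceResult(stratum, same, diff, stat, p, verdict)


def batch_check(
    embedding: np.ndarray,
    cells: pd.DataFrame,
    labels: np.ndarray,
    n_pairs: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[PairDistanceResult]:
    """Run the pair-distance test over every (cell type, timepoint) stratum."""
    labels = np.asarray(labels)
    results = []
    rng = np.random.default_rng(seed)
    for tp in pd.unique(cells["timepoint"]):
        for ctype in pd.unique(labels):
            sub_seed = int(rng.integers(2**31))
            same, diff = sample_pair_distances(
                embedding, cells, labels, (ctype, tp), n_pairs=n_pairs, seed=sub_seed
            )
            results.append(compare_distance_cdfs(same, diff, (ctype, tp), alpha=alpha))
    return results
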