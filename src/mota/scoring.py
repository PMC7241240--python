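"""Activity scores: p-values -> z-scores -> Stouffer-combined neighborhood
scores -> ranked features.

Each centric-block node k gets

    M_k = z_k + sum_l z_lk,

where z_k = Phi^{-1}(1 - p_k / 2) is its own two-sided differential-
expression z-score and z_lk is the Stouffer combination (sum / sqrt(m)) of
the z-scores of its m network neighbors belonging to omic block l (the
centric block's intra-omic neighbors count as one such block).  Features are
ranked by M_k descending.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import GroupedStudy, OmicBlock
from .network import DifferentialNetwork

__all__ = [
    "NodeScore",
    "feature_pvalues",
    "p_to_z",
    "stouffer_combine",
    "mota_scores",
    "rank_features",
]

log = logging.getLogger("mota")


@dataclass
class NodeScore:
    """Scores attached to one centric-block feature."""

    feature_id: str
    p: float
    z: float
    z_blocks: dict[str, float] = field(default_factory=dict)
    direction: int = 0  # sign of group1 mean minus group2 mean

    @property
    def mota(self) -> float:
        return self.z + sum(self.z_blocks.values())


def feature_pvalues(block: OmicBlock, study: GroupedStudy) -> dict[str, float]:
    """Two-sided pooled-variance Student t-test per feature (group 1 vs 2).

    Features with zero pooled variance get p = 1 with a warning rather than
    an error: a flat feature is simply not differential.
    """
    labels = study.labels()
    x1 = block.values[labels == 1]
    x2 = block.values[labels == 2]
    if x1.shape[0] < 2 or x2.shape[0] < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(x1, x2, axis=0, equal_var=True)
    pvals = np.asarray(res.pvalue, dtype=float)
    flat = ~np.isfinite(pvals)
    if flat.any():
        names = [block.feature_ids[i] for i in np.flatnonzero(flat)]
        warnings.warn(
            f"block {block.name!r}: zero pooled variance for {names[:5]}; "
            "p set to 1",
            stacklevel=2,
        )
        pvals[flat] = 1.0
    pvals = np.clip(pvals, np.nextafter(0.0, 1.0), 1.0)
    return dict(zip(block.feature_ids, pvals.tolist()))


def p_to_z(p: float) -> float:
    """Two-sided p-value to nonnegative z-score: z = Phi^{-1}(1 - p/2).

    p = 1 maps to z = 0; p <= 0 is clamped to the smallest positive float
    (with a warning) so z stays finite; p > 1 is an error.
    """
    if p > 1:
        raise ValueError(f"p-value {p} exceeds 1")
    if p <= 0:
        warnings.warn(
            f"p-value {p} clamped to the smallest positive float", stacklevel=2
        )
        p = 2 * float(np.nextafter(0.0, 1.0))  # keeps p/2 positive below
    # isf(p/2) == ppf(1 - p/2) but stays accurate (and finite) for tiny p
    return float(stats.norm.isf(p / 2))


def stouffer_combine(zs, denominator: str = "sqrt_m") -> float:
    """Combine nonnegative z-scores: sum(z) / sqrt(m) (Stouffer's method).

    An empty input contributes 0 (no neighbors in that block).  The
    ``denominator="m"`` variant (arithmetic mean) is kept for sensitivity
    analysis of the combination rule.
    """
    zs = np.asarray(list(zs), dtype=float)
    if zs.size == 0:
        return 0.0
    if np.any(zs < 0):
        raise ValueError("z-scores must be nonnegative (two-sided construction)")
    if denominator == "sqrt_m":
        return float(zs.sum() / np.sqrt(zs.size))
    if denominator == "m":
        return float(zs.sum() / zs.size)
    raise ValueError(f"unknown denominator rule {denominator!r}")


def mota_scores(
    net: DifferentialNetwork,
    z_of: dict[tuple[str, str], float],
    p_of: dict[tuple[str, str], float],
    centric: str,
    directions: dict[str, int] | None = None,
    denominator: str = "sqrt_m",
) -> dict[str, NodeScore]:
    """Activity score for every centric-block node in the network.

    ``z_of`` / ``p_of`` map (omic, feature) to that node's z-score and
    p-value; every network node must be covered.
    """
    scores: dict[str, NodeScore] = {}
    for node in net.graph.nodes:
        if node not in z_of:
            raise KeyError(f"node {node} has no z-score")
    for omic, feature in sorted(net.graph.nodes):
        if omic != centric:
            continue
        z_blocks = {
            block: stouffer_combine(
                [z_of[(block, nb)] for nb in nbs], denominator=denominator
            )
            for block, nbs in net.neighbors_by_block(omic, feature).items()
        }
        scores[feature] = NodeScore(
            feature_id=feature,
            p=p_of[(omic, feature)],
            z=z_of[(omic, feature)],
            z_blocks=z_blocks,
            direction=(directions or {}).get(feature, 0),
        )
    return scores


def rank_features(scores: dict[str, NodeScore], centric: str = "omic1") -> pd.DataFrame:
    """Ranking table sorted by activity score.

    Ties in the score are broken by smaller p-value, then feature id.
    Columns mirror the usual presentation: the feature's p-value and its
    p-value rank alongside the activity score and its rank, plus the
    per-block combined neighbor z-scores and the direction of change.
    """
    if not scores:
        raise ValueError("no scores to rank")
    block_names = sorted({b for s in scores.values() for b in s.z_blocks})
    rows = []
    for s in scores.values():
        row = {
            "feature": s.feature_id,
            "p_value": s.p,
            "z": s.z,
            "z_intra": s.z_blocks.get(centric, 0.0),
        }
        for b in block_names:
            if b != centric:
                row[f"z_{b}"] = s.z_blocks.get(b, 0.0)
        row["mota_score"] = s.mota
        row["direction"] = s.direction
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["mota_score", "p_value", "feature"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["mota_rank"] = np.arange(1, len(df) + 1)
    p_order = df.sort_values(by=["p_value", "feature"], kind="mergesort").index
    p_rank = pd.Series(np.arange(1, len(df) + 1), index=p_order)
    df["p_rank"] = p_rank.sort_index().to_numpy()
    cols = (["feature", "p_value", "p_rank", "z", "z_intra"]
            + [f"z_{b}" for b in block_names if b != centric]
            + ["mota_score", "mota_rank", "direction"])
    return df[cols]
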