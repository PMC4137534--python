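"""Per-gene filter statistics and top-m selection.

Three ranking scores over a binary-class dataset:

* ``t_statistic`` — standardized class-mean difference,
  ``t = (m1 - m2) / sqrt(v1/n1 + v2/n2)``.
* ``snr`` — prediction strength ``(m1 - m2) / (s1 + s2)`` in the default
  ``sum`` mode; ``paper`` mode uses the literal ``s1 - s2`` denominator
  behind an epsilon guard (it divides by zero whenever the class SDs
  coincide, which is almost certainly a typo in the source formulation).
* ``f_test`` — plain variance ratio ``v1 / v2``, ranked ascending.

Variances use the unbiased n-1 denominator throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_data import ExpressionDataset

logger = logging.getLogger(__name__)

EPSILON = 1e-12

METHODS = ("t_statistic", "snr", "f_test")


@dataclass
class ClassStats:
    """Per-gene class means/variances/SDs plus the two class sizes."""

    mean1: np.ndarray
    mean2: np.ndarray
    var1: np.ndarray
    var2: np.ndarray
    sd1: np.ndarray
    sd2: np.ndarray
    n1: int
    n2: int


@dataclass
class GeneRanking:
    method: str
    scores: np.ndarray
    ranked_indices: np.ndarray  # permutation of gene indices, best first
    top_m: np.ndarray           # first m of ranked_indices
    m: int


def class_statistics(ds: ExpressionDataset) -> ClassStats:
    """Per-class, per-gene means, variances (ddof=1) and SDs."""
    idx1 = ds.class_indices(ds.class_names[0])
    idx2 = ds.class_indices(ds.class_names[1])
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError(
            f"each class needs >= 2 samples for a variance "
            f"(got {len(idx1)} and {len(idx2)})"
        )
    x1 = ds.matrix[:, idx1]
    x2 = ds.matrix[:, idx2]
    var1 = x1.var(axis=1, ddof=1)
    var2 = x2.var(axis=1, ddof=1)
    return ClassStats(
        mean1=x1.mean(axis=1),
        mean2=x2.mean(axis=1),
        var1=var1,
        var2=var2,
        sd1=np.sqrt(var1),
        sd2=np.sqrt(var2),
        n1=len(idx1),
        n2=len(idx2),
    )


def t_statistic(stats: ClassStats) -> np.ndarray:
    """t = (m1 - m2) / sqrt(v1/n1 + v2/n2) per gene.

    Degenerate genes (both class variances zero): equal means score 0,
    unequal means score +/-inf so they rank first under |t|.
    """
    diff = stats.mean1 - stats.mean2
    denom_sq = stats.var1 / stats.n1 + stats.var2 / stats.n2
    scores = np.empty_like(diff)
    degenerate = denom_sq <= 0.0
    ok = ~degenerate
    scores[ok] = diff[ok] / np.sqrt(denom_sq[ok])
    if degenerate.any():
        zero_diff = degenerate & (diff == 0.0)
        inf_diff = degenerate & (diff != 0.0)
        scores[zero_diff] = 0.0
        scores[inf_diff] = np.sign(diff[inf_diff]) * np.inf
        if zero_diff.any():
            logger.warning(
                "%d constant, identical-mean genes scored t=0", int(zero_diff.sum())
            )
        if inf_diff.any():
            logger.warning(
                "%d zero-variance genes with unequal means scored t=+/-inf",
                int(inf_diff.sum()),
            )
    return scores


def snr(stats: ClassStats, denominator_mode: str = "sum") -> np.ndarray:
    """Prediction strength PS = (m1 - m2) / denominator per gene.

    ``sum`` mode divides by s1 + s2; ``paper`` mode divides by s1 - s2,
    with |denominator| floored at EPSILON (guard activations are logged).
    Equal class means score exactly 0 in both modes.
    """
    if denominator_mode not in ("sum", "paper"):
        raise ValueError(
            f"denominator_mode must be 'sum' or 'paper', got {denominator_mode!r}"
        )
    diff = stats.mean1 - stats.mean2
    if denominator_mode == "sum":
        denom = stats.sd1 + stats.sd2
    else:
        denom = stats.sd1 - stats.sd2
    guarded = np.abs(denom) < EPSILON
    if guarded.any():
        logger.warning(
            "snr(%s): epsilon guard active for %d gene(s)",
            denominator_mode,
            int(guarded.sum()),
        )
    safe = np.where(guarded, np.sign(denom) * EPSILON, denom)
    safe = np.where(safe == 0.0, EPSILON, safe)  # sign(0) == 0
    scores = diff / safe
    scores[diff == 0.0] = 0.0
    return scores


def f_test(stats: ClassStats) -> np.ndarray:
    """F = v1 / v2 per gene, exactly as the ratio reads.

    v2 = 0 with v1 > 0 scores +inf (never selected under ascending rank);
    v1 = v2 = 0 scores 1 with a warning.
    """
    v1, v2 = stats.var1, stats.var2
    scores = np.empty_like(v1)
    ok = v2 > 0.0
    scores[ok] = v1[ok] / v2[ok]
    both_zero = (~ok) & (v1 == 0.0)
    only_v2_zero = (~ok) & (v1 > 0.0)
    scores[both_zero] = 1.0
    scores[only_v2_zero] = np.inf
    if both_zero.any():
        logger.warning("%d constant genes scored F=1", int(both_zero.sum()))
    return scores


def _selection_key(scores: np.ndarray, method: str, signed: bool, f_rank: str) -> np.ndarray:
    """Ascending-sort key implementing each method's selection direction."""
    if method in ("t_statistic", "snr"):
        return -scores if signed else -np.abs(scores)
    if method == "f_test":
        if f_rank == "ascending":
            return scores.copy()
        if f_rank == "two_tailed":
            # deviation from 1, symmetric in F <-> 1/F; F=0 and F=inf are worst
            with np.errstate(divide="ignore"):
                inv = np.where(scores > 0.0, 1.0 / scores, np.inf)
            return np.maximum(scores, inv)
        raise ValueError(f"f_rank must be 'ascending' or 'two_tailed', got {f_rank!r}")
    raise ValueError(f"unknown ranking method {method!r}")


def top_m(
    scores: np.ndarray,
    method: str,
    m: int,
    signed: bool = False,
    f_rank: str = "ascending",
) -> GeneRanking:
    """Rank genes by a method's selection direction and keep the first m.

    t_statistic and snr rank by descending |score| (descending signed score
    with ``signed=True``); f_test ranks ascending.  Ties break toward the
    lower gene index (stable sort).
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}], got {m}")
    key = _selection_key(scores, method, signed, f_rank)
    ranked = np.argsort(key, kind="stable")
    return GeneRanking(
        method=method,
        scores=scores,
        ranked_indices=ranked,
        top_m=ranked[:m].copy(),
        m=m,
    )


def rank_genes(
    ds: ExpressionDataset,
    method: str,
    m: int,
    snr_denominator: str = "sum",
    signed: bool = False,
    f_rank: str = "ascending",
) -> GeneRanking:
    """Convenience: class stats -> scores -> top-m in one call."""
    stats = class_statistics(ds)
    if method == "t_statistic":
        scores = t_statistic(stats)
    elif method == "snr":
        scores = snr(stats, denominator_mode=snr_denominator)
    elif method == "f_test":
        scores = f_test(stats)
    else:
        raise ValueError(f"unknown ranking method {method!r}; expected one of {METHODS}")
    return top_m(scores, method, m, signed=signed, f_rank=f_rank)


def write_ranking(ranking: GeneRanking, gene_ids, path) -> None:
    """Tab-delimited report: gene_id, method, score, rank (selection order)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tmethod\tscore\trank\n")
        for rank, gi in enumerate(ranking.ranked_indices, start=1):
            fh.write(
                f"{gene_ids[gi]}\t{ranking.method}\t"
                f"{format(ranking.scores[gi], '.12g')}\t{rank}\n"
            )
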