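"""Cell-line screen tests for synthetic-lethal partner discovery.

SPID (synthetic partner inactivation dependency) asks whether cell lines
carrying a LoF alteration in gene A are more sensitive to inactivation of
gene B than wild-type lines, via a one-sided Wilcoxon rank-sum test on
dependency scores.  SPEA (synthetic partner enrichment analysis) asks
whether LoF-A lines are enriched among the lines most sensitive to B, via
a weighted Kolmogorov-Smirnov-like running-sum enrichment score with a
label-permutation null.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    AlterationMatrix,
    CellLineTestResult,
    DependencyScreen,
    GenePair,
)
from .stats import rank_sum_p

log = logging.getLogger(__name__)

__all__ = [
    "spid",
    "positive_dependency_percentage",
    "spea_es",
    "spea_pvalue",
    "run_cellline_tests",
]

DEFAULT_N_PERM = 200
MIN_LOF_CELL_LINES = 20


def _clean(scores_b, lof_a) -> tuple[np.ndarray, np.ndarray]:
    """Align score/label vectors and drop cell lines with missing scores."""
    scores = np.asarray(scores_b, dtype=float)
    lof = np.asarray(lof_a)
    if scores.shape != lof.shape:
        raise ValueError("scores and LoF labels must be aligned and equal length")
    keep = ~np.isnan(scores)
    return scores[keep], lof[keep].astype(bool)


def spid(
    scores_b,
    lof_a,
    pair: GenePair | None = None,
    dataset: str = "",
) -> CellLineTestResult:
    """One-sided rank-sum test: LoF-A lines have lower B dependency scores.

    Cell lines with a missing score for gene B are excluded.  If either
    group is empty afterwards the result is marked inapplicable rather
    than assigned a p-value.
    """
    scores, lof = _clean(scores_b, lof_a)
    res = CellLineTestResult(pair=pair, dataset=dataset, test="SPID")
    res.n_lof, res.n_wt = int(lof.sum()), int((~lof).sum())
    if res.n_lof == 0 or res.n_wt == 0:
        res.applicable = False
        res.reason = "empty LoF or WT group after missing-score removal"
        return res
    stat, p = rank_sum_p(scores[lof], scores[~lof], alternative="less")
    res.statistic, res.p_value = stat, p
    res.direction_sl = bool(np.median(scores[lof]) < np.median(scores[~lof]))
    res.positive_dependency_pct = positive_dependency_percentage(scores_b, lof_a)
    return res


def positive_dependency_percentage(
    scores_b, lof_a, denominator: str = "lof"
) -> float:
    """Fraction of LoF-A cell lines whose B dependency score is positive.

    A positive score means the line grows *better* without gene B, so a
    high value argues against a synthetic-lethal interpretation.  With
    ``denominator="all"`` the fraction is taken over all scored lines
    instead of the LoF-A lines.
    """
    scores, lof = _clean(scores_b, lof_a)
    if lof.sum() == 0:
        raise ValueError("no LoF cell lines with non-missing scores")
    positive_lof = int((scores[lof] > 0).sum())
    if denominator == "lof":
        return positive_lof / int(lof.sum())
    if denominator == "all":
        return positive_lof / scores.size
    raise ValueError(f"unknown denominator {denominator!r}")


def _walk_steps(
    hits: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Running-sum increments for hit/miss indicator rows.

    ``hits`` is (n, N) boolean, ``weights`` (N,) non-negative; each row's
    hit increments are normalized to sum to 1 and each miss decrements by
    1/(N - n_hits).  Rows whose hit weights sum to zero fall back to
    unweighted increments.
    """
    hits = np.atleast_2d(hits)
    n, N = hits.shape
    n_hits = hits.sum(axis=1)
    if np.any(n_hits == 0) or np.any(n_hits == N):
        raise ValueError("need at least one hit and one miss")
    hit_w = hits * weights
    denom = hit_w.sum(axis=1)
    zero = denom == 0
    if np.any(zero):
        hit_w[zero] = hits[zero].astype(float)
        denom[zero] = n_hits[zero]
    steps = hit_w / denom[:, None] - (~hits) / (N - n_hits)[:, None]
    return steps


def spea_es(scores_b, lof_a, weight_exponent: float = 1.0) -> float:
    """Enrichment score of LoF-A lines among the most B-sensitive lines.

    Cell lines are ranked ascending by dependency score (most sensitive
    first); walking down the ranking, the running sum rises by
    ``|score|^w / sum_hits |score|^w`` at LoF-A lines and falls by
    ``1/(N - n_hits)`` at wild-type lines.  The ES is the signed value of
    maximal absolute deviation; positive ES means LoF-A lines concentrate
    among the most sensitive.  ES is always in [-1, 1].
    """
    scores, lof = _clean(scores_b, lof_a)
    if lof.sum() == 0 or (~lof).sum() == 0:
        raise ValueError("need at least one LoF and one WT cell line")
    order = np.argsort(scores, kind="stable")
    h = lof[order]
    w = np.abs(scores[order]) ** weight_exponent
    if weight_exponent > 0 and w[h].sum() == 0:
        log.warning("all LoF hit scores are zero; falling back to unweighted ES")
        w = np.ones_like(w)
    cs = np.cumsum(_walk_steps(h[None, :], w)[0])
    return float(cs[np.argmax(np.abs(cs))])


def spea_pvalue(
    scores_b,
    lof_a,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
    weight_exponent: float = 1.0,
    pair: GenePair | None = None,
    dataset: str = "",
) -> CellLineTestResult:
    """Empirical SPEA p-value from a label-permutation null.

    LoF labels are reassigned uniformly at random ``n_perm`` times; the
    p-value is ``(b + 1) / (n_perm + 1)`` where ``b`` counts permuted
    enrichment scores of the same sign as, and at least as extreme as, the
    observed one (sign-matched comparison, as in GSEA).  The attainable
    floor is therefore 1/(n_perm + 1), i.e. 0.005 (to 3 decimals) at the
    default 200 permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores, lof = _clean(scores_b, lof_a)
    res = CellLineTestResult(pair=pair, dataset=dataset, test="SPEA")
    res.n_lof, res.n_wt = int(lof.sum()), int((~lof).sum())
    if res.n_lof == 0 or res.n_wt == 0:
        res.applicable = False
        res.reason = "empty LoF or WT group after missing-score removal"
        return res

    order = np.argsort(scores, kind="stable")
    h_obs = lof[order]
    w = np.abs(scores[order]) ** weight_exponent
    if weight_exponent > 0 and w[h_obs].sum() == 0:
        log.warning("all LoF hit scores are zero; falling back to unweighted ES")
        w = np.ones_like(w)
    cs = np.cumsum(_walk_steps(h_obs[None, :], w)[0])
    es_obs = float(cs[np.argmax(np.abs(cs))])

    rng = np.random.default_rng(seed)
    base = np.broadcast_to(h_obs, (n_perm, h_obs.size))
    perms = rng.permuted(base, axis=1)
    cs_r = np.cumsum(_walk_steps(perms, w), axis=1)
    idx = np.argmax(np.abs(cs_r), axis=1)
    es_rand = cs_r[np.arange(n_perm), idx]

    same_sign = np.sign(es_rand) == np.sign(es_obs) if es_obs != 0 else np.ones(
        n_perm, dtype=bool
    )
    b = int((same_sign & (np.abs(es_rand) >= abs(es_obs))).sum())
    res.statistic = es_obs
    res.p_value = (b + 1) / (n_perm + 1)
    res.direction_sl = es_obs > 0
    return res


def run_cellline_tests(
    screen: DependencyScreen,
    alterations: AlterationMatrix,
    pairs: list[GenePair],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
    weight_exponent: float = 1.0,
    min_lof: int = MIN_LOF_CELL_LINES,
) -> list[CellLineTestResult]:
    """SPID and SPEA for every pair on one screen, with applicability gates.

    Gates: gene A must have LoF alterations in at least ``min_lof`` of the
    cell lines shared between the screen and the alteration matrix, and
    gene B must be a knockout/knockdown target in the screen.  Each pair's
    permutation stream is seeded from ``seed`` and the pair index so runs
    are reproducible regardless of pair order subsetting.
    """
    shared = [c for c in screen.cell_lines if c in set(alterations.samples)]
    dropped = len(screen.cell_lines) - len(shared)
    if dropped:
        log.info(
            "%s: %d cell lines without alteration data dropped",
            screen.dataset_name,
            dropped,
        )
    scores = screen.scores.loc[shared]
    alt = alterations.values.loc[shared]
    results: list[CellLineTestResult] = []
    for i, pair in enumerate(pairs):
        for test in ("SPID", "SPEA"):
            base = CellLineTestResult(pair=pair, dataset=screen.dataset_name, test=test)
            if pair.gene_b not in scores.columns:
                base.applicable = False
                base.reason = "gene B not a screen target"
                results.append(base)
                continue
            if pair.gene_a not in alt.columns:
                base.applicable = False
                base.reason = "gene A absent from alteration matrix"
                results.append(base)
                continue
            lof = alt[pair.gene_a].to_numpy()
            sc = scores[pair.gene_b].to_numpy()
            n_lof_scored = int(lof[~np.isnan(sc)].sum())
            if n_lof_scored < min_lof:
                base.applicable = False
                base.n_lof = n_lof_scored
                base.reason = f"gene A has {n_lof_scored} < {min_lof} LoF cell lines"
                results.append(base)
                continue
            if test == "SPID":
                results.append(spid(sc, lof, pair=pair, dataset=screen.dataset_name))
            else:
                pair_seed = None if seed is None else (seed + 1009 * i) % (2**31)
                results.append(
                    spea_pvalue(
                        sc,
                        lof,
                        n_perm=n_perm,
                        seed=pair_seed,
                        weight_exponent=weight_exponent,
                        pair=pair,
                        dataset=screen.dataset_name,
                    )
                )
    return results


def cellline_results_frame(results: list[CellLineTestResult]) -> pd.DataFrame:
    """Flatten test results into a tidy per-(pair, dataset, test) table."""
    rows = []
    for r in results:
        rows.append(
            {
                "gene_a": r.pair.gene_a if r.pair else "",
                "gene_b": r.pair.gene_b if r.pair else "",
                "series": r.pair.series if r.pair else "",
                "dataset": r.dataset,
                "test": r.test,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "n_lof": r.n_lof,
                "n_wt": r.n_wt,
                "positive_dependency_pct": r.positive_dependency_pct,
                "direction_sl": r.direction_sl,
                "applicable": r.applicable,
                "reason": r.reason or "",
            }
        )
    return pd.DataFrame(rows)
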