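"""Drug-sensitivity (SPDD) and shared-pathway (SPSP) evidence tests.

SPDD asks whether cell lines with LoF in gene A respond better (lower
ln(IC50) / log-fold-change) to drugs targeting candidate partner B; the
best (lowest-p) drug is reported, uncorrected for the number of drugs
tried, with the per-drug table retained for downstream correction.

SPSP asks whether A and B co-occur in more pathways than expected by
chance, via an upper-tail hypergeometric test over the pathway universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    AlterationMatrix,
    DrugScreen,
    GenePair,
    PathwayCollection,
    SimpleTestResult,
)
from .stats import rank_sum_p

__all__ = [
    "spdd",
    "spsp",
    "spsp_pair",
    "count_pathway_membership",
    "shared_pathways",
    "run_drug_tests",
    "run_pathway_tests",
]

MIN_LOF_CELL_LINES = 20


def spdd(
    drug_screen: DrugScreen,
    lof_a,
    gene_b: str,
    pair: GenePair | None = None,
    min_lof: int = MIN_LOF_CELL_LINES,
) -> SimpleTestResult:
    """Best-drug sensitivity test for LoF-A lines against drugs targeting B.

    ``lof_a`` must be aligned with the screen's cell lines.  For every
    drug annotated to target ``gene_b`` a one-sided rank-sum test is run
    for the alternative "response lower (more sensitive) in LoF-A lines";
    the minimum-p drug is reported and all per-drug results are kept in
    ``extra["per_drug"]``.
    """
    lof = np.asarray(lof_a).astype(bool)
    if lof.shape[0] != drug_screen.responses.shape[0]:
        raise ValueError("lof_a must align with the screen's cell lines")
    res = SimpleTestResult(pair=pair, test="SPDD")
    res.extra["dataset"] = drug_screen.dataset_name
    drugs = drug_screen.drugs_targeting(gene_b)
    if not drugs:
        res.applicable = False
        res.reason = f"no drug in {drug_screen.dataset_name} targets {gene_b}"
        return res
    if min_lof is not None and lof.sum() < min_lof:
        res.applicable = False
        res.reason = f"gene A has {int(lof.sum())} < {min_lof} LoF cell lines"
        return res
    per_drug = []
    for drug in drugs:
        values = drug_screen.responses[drug].to_numpy(dtype=float)
        keep = ~np.isnan(values)
        v, m = values[keep], lof[keep]
        if m.sum() == 0 or (~m).sum() == 0:
            per_drug.append((drug, np.nan, np.nan))
            continue
        stat, p = rank_sum_p(v[m], v[~m], alternative="less")
        per_drug.append((drug, stat, p))
    table = pd.DataFrame(per_drug, columns=["drug", "statistic", "p_value"])
    res.extra["per_drug"] = table
    valid = table.dropna(subset=["p_value"])
    if valid.empty:
        res.applicable = False
        res.reason = "no drug had both LoF and WT lines with responses"
        return res
    best = valid.loc[valid["p_value"].idxmin()]
    res.statistic = float(best["statistic"])
    res.p_value = float(best["p_value"])
    res.extra["best_drug"] = str(best["drug"])
    return res


def spsp(n_a: int, n_b: int, k: int, universe: int) -> float:
    """Upper-tail hypergeometric probability of >= k shared pathways.

    With ``universe`` pathways in total, gene B in ``n_b`` of them and
    gene A drawn into ``n_a``, returns P(X >= k); symmetric in A and B.
    """
    if not (0 <= k <= min(n_a, n_b) <= universe):
        raise ValueError(
            f"inconsistent pathway counts: n_a={n_a}, n_b={n_b}, k={k}, "
            f"universe={universe}"
        )
    return float(sps.hypergeom.sf(k - 1, universe, n_b, n_a))


def count_pathway_membership(collection: PathwayCollection, gene: str) -> int:
    """Number of pathways containing ``gene`` (0 if absent everywhere)."""
    return sum(1 for genes in collection.pathways.values() if gene in genes)


def shared_pathways(
    collection: PathwayCollection, gene_a: str, gene_b: str
) -> frozenset[str]:
    """Names of the pathways containing both genes."""
    return frozenset(
        name
        for name, genes in collection.pathways.items()
        if gene_a in genes and gene_b in genes
    )


def spsp_pair(
    collection: PathwayCollection,
    pair: GenePair,
    universe: int | None = None,
) -> SimpleTestResult:
    """SPSP for one gene pair against a loaded pathway collection."""
    res = SimpleTestResult(pair=pair, test="SPSP")
    n_a = count_pathway_membership(collection, pair.gene_a)
    n_b = count_pathway_membership(collection, pair.gene_b)
    shared = shared_pathways(collection, pair.gene_a, pair.gene_b)
    res.extra.update(n_pathways_a=n_a, n_pathways_b=n_b, n_shared=len(shared),
                     shared=sorted(shared))
    if n_a == 0 or n_b == 0:
        res.applicable = False
        res.reason = "both genes must belong to at least one pathway"
        return res
    res.statistic = float(len(shared))
    res.p_value = spsp(n_a, n_b, len(shared), universe or collection.universe_size)
    return res


def run_drug_tests(
    drug_screen: DrugScreen,
    alterations: AlterationMatrix,
    pairs: list[GenePair],
    min_lof: int = MIN_LOF_CELL_LINES,
) -> list[SimpleTestResult]:
    """SPDD for every pair on one drug screen (cell lines intersected with
    the alteration matrix by identifier)."""
    shared = [c for c in drug_screen.responses.index if c in set(alterations.samples)]
    screen = DrugScreen(
        drug_screen.dataset_name,
        drug_screen.responses.loc[shared],
        drug_screen.target_map,
    )
    alt = alterations.values.loc[shared]
    results = []
    for pair in pairs:
        if pair.gene_a not in alt.columns:
            r = SimpleTestResult(
                pair, "SPDD", applicable=False,
                reason="gene A absent from alteration matrix",
            )
            r.extra["dataset"] = screen.dataset_name
            results.append(r)
            continue
        results.append(
            spdd(screen, alt[pair.gene_a].to_numpy(), pair.gene_b, pair=pair,
                 min_lof=min_lof)
        )
    return results


def run_pathway_tests(
    collection: PathwayCollection,
    pairs: list[GenePair],
    universe: int | None = None,
) -> list[SimpleTestResult]:
    return [spsp_pair(collection, pair, universe=universe) for pair in pairs]
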