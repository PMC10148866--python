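"""Evidence engine: p-value combination, FDR correction, SL-evidence
criteria, ranking, and evidence-network export.

The workflow mirrors a two-stage screen: candidate pairs are first tested
in cell-line dependency screens (SPID + SPEA per screen), the per-pair
p-values are Fisher-combined and BH-corrected jointly across every tested
pair (both pair series together), and pairs passing adjusted p < alpha form
the *top cell-line* set.  Patient tests (SoF, ExprSL, SurvLRT, iSurvLRT)
are then run on all testable pairs with per-test BH correction; a top
cell-line pair confirmed by at least one patient test is *clinically
relevant*.  Drug (SPDD) and pathway (SPSP) tests annotate the output:
SPDD evidence deliberately uses the raw p-value (the test is validation,
not discovery), SPSP the adjusted one.  Clinically relevant pairs are
ranked by the adjusted combined cell-line p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cellline import run_cellline_tests
from .datatypes import (
    AlterationMatrix,
    DependencyScreen,
    DrugScreen,
    GenePair,
    PathwayCollection,
    ReferenceSurvival,
)
from .drug_pathway import run_drug_tests, run_pathway_tests
from .patient import (
    DEFAULT_QUANTILE_GRID,
    PatientCohort,
    run_patient_tests,
)

log = logging.getLogger(__name__)

__all__ = [
    "fisher_combine",
    "bh_adjust",
    "applicability",
    "evaluate_evidence",
    "run_pipeline",
    "export_network",
    "DataBundle",
    "PipelineConfig",
    "PipelineResult",
]

P_FLOOR = 1e-300


def fisher_combine(p_values) -> float:
    """Fisher's combined probability test.

    ``chi2 = -2 sum ln p_i`` referred to chi-square with 2k degrees of
    freedom.  Zero p-values are clamped to the smallest positive
    representable value with a warning; a single p-value is returned
    unchanged (the k=1 combination is the identity).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        log.warning("p-value of 0 clamped to %g before Fisher combination", P_FLOOR)
        p = np.clip(p, P_FLOOR, 1.0)
    stat = -2.0 * np.log(p).sum()
    return float(sps.chi2.sf(stat, df=2 * p.size))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    NaN entries (untested) are passed through as NaN and excluded from the
    correction.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def applicability(test: str, pair: GenePair, bundle: "DataBundle") -> tuple[bool, str]:
    """Whether ``test`` can be run for ``pair`` on this data bundle.

    Encodes every gate: SPID/SPEA need >= min_lof LoF cell lines for A and
    B as a screen target; SoF needs >= min_lof LoF patients and B's
    expression; ExprSL needs both expressions; SurvLRT/iSurvLRT need
    >= min_lof LoF patients (the per-genotype deceased gate is checked at
    run time on the realized genotypes); SPDD needs >= min_lof LoF cell
    lines and a drug targeting B; SPSP needs both genes in >= 1 pathway.
    Returns ``(ok, reason)`` with a reason code for unmet gates.
    """
    cfg = bundle.config or PipelineConfig()
    m = cfg.min_lof
    if test in ("SPID", "SPEA"):
        for screen in bundle.screens:
            if pair.gene_b not in screen.scores.columns:
                return False, "gene B not a screen target"
        n = bundle.cellline_alterations.n_lof(pair.gene_a)
        if n < m:
            return False, f"gene A has {n} < {m} LoF cell lines"
        return True, ""
    if test in ("SoF", "SurvLRT", "iSurvLRT", "SoF/ExprSL"):
        if bundle.cohort is None:
            return False, "no patient cohort"
        n = bundle.cohort.alterations.n_lof(pair.gene_a)
        if n < m:
            return False, f"gene A has {n} < {m} LoF patients"
        if test != "SurvLRT" and pair.gene_b not in bundle.cohort.expression.genes:
            return False, "gene B expression not measured"
        if test == "SurvLRT" and pair.gene_b not in bundle.cohort.alterations.genes:
            return False, "gene B alterations not recorded"
        return True, ""
    if test == "ExprSL":
        if bundle.cohort is None:
            return False, "no patient cohort"
        genes = set(bundle.cohort.expression.genes)
        if pair.gene_a not in genes or pair.gene_b not in genes:
            return False, "expression not measured for both genes"
        return True, ""
    if test == "SPDD":
        for screen in bundle.drug_screens:
            if screen.drugs_targeting(pair.gene_b):
                break
        else:
            return False, "no drug targets gene B"
        n = bundle.cellline_alterations.n_lof(pair.gene_a)
        if n < m:
            return False, f"gene A has {n} < {m} LoF cell lines"
        return True, ""
    if test == "SPSP":
        if bundle.pathways is None:
            return False, "no pathway collection"
        from .drug_pathway import count_pathway_membership

        if not count_pathway_membership(bundle.pathways, pair.gene_a):
            return False, "gene A in no pathway"
        if not count_pathway_membership(bundle.pathways, pair.gene_b):
            return False, "gene B in no pathway"
        return True, ""
    raise ValueError(f"unknown test {test!r}")


@dataclass
class PipelineConfig:
    """Thresholds and knobs of the evidence workflow (defaults follow the
    standard screening settings)."""

    alpha: float = 0.05
    rho_threshold: float = 0.4  # minimum |Spearman rho| for ExprSL evidence
    min_lof: int = 20
    min_deceased: int = 5
    n_perm: int = 200
    seed: int = 0
    weight_exponent: float = 1.0
    quantile_grid: tuple[float, ...] = DEFAULT_QUANTILE_GRID
    gate_wild_type_group: bool = True
    require_all_cellline_tests: bool = True
    spdd_use_adjusted: bool = False  # evidence from raw SPDD p by default
    spsp_universe: int | None = None
    patient_tests: tuple[str, ...] = ("SoF", "ExprSL", "SurvLRT", "iSurvLRT")


@dataclass
class DataBundle:
    """Everything one pipeline run consumes."""

    pairs: list[GenePair]
    screens: list[DependencyScreen] = field(default_factory=list)
    cellline_alterations: AlterationMatrix | None = None
    cohort: PatientCohort | None = None
    reference: ReferenceSurvival | None = None
    drug_screens: list[DrugScreen] = field(default_factory=list)
    pathways: PathwayCollection | None = None
    config: PipelineConfig | None = None


@dataclass
class PipelineResult:
    records: pd.DataFrame
    accounting: pd.DataFrame


def _series_counts(records: pd.DataFrame, mask) -> dict[str, int]:
    sel = records.loc[mask, "series"]
    counts = {s: int((sel == s).sum()) for s in sorted(records["series"].unique())}
    counts["total"] = int(mask.sum())
    return counts


def evaluate_evidence(record: dict, config: PipelineConfig) -> dict:
    """Fill the per-test evidence booleans and the clinical-relevance call.

    Evidence criteria: cell line = adjusted combined Fisher p < alpha;
    SoF adjusted p < alpha; ExprSL adjusted p < alpha AND |rho| above the
    correlation threshold; SurvLRT/iSurvLRT adjusted p < alpha AND both SL
    and CL flags equal 1; SPDD raw p < alpha (adjusted when configured);
    SPSP adjusted p < alpha.  A test that was not run leaves its evidence
    as None ("not assessed"), never False.  ``clinically_relevant`` =
    top cell-line candidate AND at least one patient-test evidence.
    """
    a = config.alpha

    def lt(value, thresh) -> bool | None:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        return bool(value < thresh)

    record["top_cellline"] = lt(record.get("combined_p_adj"), a)
    record["sof_evidence"] = lt(record.get("sof_p_adj"), a)
    ev = lt(record.get("exprsl_p_adj"), a)
    if ev:
        ev = abs(record.get("exprsl_rho", 0.0)) > config.rho_threshold
    record["exprsl_evidence"] = ev
    for t in ("survlrt", "isurvlrt"):
        ev = lt(record.get(f"{t}_p_adj"), a)
        if ev:
            ev = record.get(f"{t}_sl_flag") == 1 and record.get(f"{t}_cl_flag") == 1
        record[f"{t}_evidence"] = ev
    for key in [k for k in record if k.startswith("spdd_") and k.endswith("_p")]:
        ds = key[len("spdd_"):-len("_p")]
        src = record.get(f"spdd_{ds}_p_adj") if config.spdd_use_adjusted else record[key]
        record[f"spdd_{ds}_evidence"] = lt(src, a)
    if "spsp_p_adj" in record:
        record["spsp_evidence"] = lt(record.get("spsp_p_adj"), a)
    patient = [
        record.get(k)
        for k in ("sof_evidence", "exprsl_evidence", "survlrt_evidence",
                  "isurvlrt_evidence")
    ]
    record["n_patient_evidence"] = sum(1 for v in patient if v is True)
    if record["top_cellline"] is None:
        record["clinically_relevant"] = False
    else:
        record["clinically_relevant"] = bool(
            record["top_cellline"] and record["n_patient_evidence"] >= 1
        )
    return record


def run_pipeline(bundle: DataBundle) -> PipelineResult:
    """Execute the full two-stage evidence workflow on a data bundle.

    Stages: cell-line tests on all testable pairs -> Fisher combination of
    the per-screen SPID/SPEA p-values -> joint BH across all tested pairs
    (both series together) -> patient tests with per-test BH -> drug and
    pathway annotation -> evidence evaluation -> ranking of clinically
    relevant pairs by adjusted combined cell-line p (ties: raw combined p,
    then pair name).  Missing modalities degrade gracefully: their tests
    are marked not assessed and the pipeline continues.
    """
    cfg = bundle.config or PipelineConfig()
    pairs = bundle.pairs
    if not pairs:
        empty = pd.DataFrame(
            columns=[
                "gene_a", "gene_b", "series", "combined_p", "combined_p_adj",
                "top_cellline", "n_patient_evidence", "clinically_relevant", "rank",
            ]
        )
        accounting = pd.DataFrame([{"stage": "pairs_input", "total": 0}])
        return PipelineResult(records=empty, accounting=accounting)
    records: list[dict] = [
        {"gene_a": p.gene_a, "gene_b": p.gene_b, "series": p.series} for p in pairs
    ]
    index = {p: i for i, p in enumerate(pairs)}

    # --- stage 1: cell-line tests -------------------------------------
    n_cell_tests = 0
    if bundle.screens and bundle.cellline_alterations is not None:
        for screen in bundle.screens:
            results = run_cellline_tests(
                screen,
                bundle.cellline_alterations,
                pairs,
                n_perm=cfg.n_perm,
                seed=cfg.seed,
                weight_exponent=cfg.weight_exponent,
                min_lof=cfg.min_lof,
            )
            n_cell_tests += sum(r.applicable for r in results)
            for r in results:
                rec = records[index[r.pair]]
                key = f"{r.test.lower()}_{screen.dataset_name}"
                rec[f"{key}_p"] = r.p_value if r.applicable else np.nan
                rec[f"{key}_stat"] = r.statistic if r.applicable else np.nan
                if r.test == "SPID" and r.applicable:
                    rec[f"{key}_posdep"] = r.positive_dependency_pct
        expected = 2 * len(bundle.screens)
        for rec in records:
            ps = [
                rec[k]
                for k in rec
                if k.endswith("_p") and (k.startswith("spid_") or k.startswith("spea_"))
                and not np.isnan(rec[k])
            ]
            if not ps or (cfg.require_all_cellline_tests and len(ps) < expected):
                rec["combined_p"] = np.nan
            else:
                rec["combined_p"] = fisher_combine(ps)

    df = pd.DataFrame(records)
    if "combined_p" not in df.columns:
        df["combined_p"] = np.nan
    df["combined_p_adj"] = bh_adjust(df["combined_p"])

    # --- stage 2: patient tests ---------------------------------------
    if bundle.cohort is not None and bundle.reference is not None:
        by_test = run_patient_tests(
            bundle.cohort,
            bundle.reference,
            pairs,
            tests=cfg.patient_tests,
            min_lof=cfg.min_lof,
            min_deceased=cfg.min_deceased,
            quantile_grid=cfg.quantile_grid,
            gate_wild_type_group=cfg.gate_wild_type_group,
        )
        for test, results in by_test.items():
            col = test.lower()
            ps = [r.p_value if r.applicable else np.nan for r in results]
            df[f"{col}_p"] = ps
            if test == "ExprSL":
                df["exprsl_rho"] = [
                    r.extra.get("rho", np.nan) if r.applicable else np.nan
                    for r in results
                ]
            if test in ("SurvLRT", "iSurvLRT"):
                df[f"{col}_sl_flag"] = [r.sl_flag if r.applicable else 0 for r in results]
                df[f"{col}_cl_flag"] = [r.cl_flag if r.applicable else 0 for r in results]
                df[f"{col}_effect_size"] = [
                    r.effect_size if r.applicable else np.nan for r in results
                ]
                df[f"{col}_delta11_expected"] = [
                    r.delta11_expected if r.applicable else np.nan for r in results
                ]
            if test == "iSurvLRT":
                df["isurvlrt_threshold"] = [
                    r.threshold if r.applicable else np.nan for r in results
                ]
                df["isurvlrt_threshold_quantile"] = [
                    r.threshold_quantile if r.applicable else np.nan for r in results
                ]
            df[f"{col}_p_adj"] = bh_adjust(df[f"{col}_p"])

    # --- stage 3: drug and pathway annotation -------------------------
    if bundle.drug_screens and bundle.cellline_alterations is not None:
        for screen in bundle.drug_screens:
            results = run_drug_tests(
                screen, bundle.cellline_alterations, pairs, min_lof=cfg.min_lof
            )
            ds = screen.dataset_name
            df[f"spdd_{ds}_p"] = [
                r.p_value if r.applicable else np.nan for r in results
            ]
            df[f"spdd_{ds}_drug"] = [
                r.extra.get("best_drug", "") if r.applicable else "" for r in results
            ]
            df[f"spdd_{ds}_p_adj"] = bh_adjust(df[f"spdd_{ds}_p"])
    if bundle.pathways is not None:
        results = run_pathway_tests(bundle.pathways, pairs, universe=cfg.spsp_universe)
        df["spsp_p"] = [r.p_value if r.applicable else np.nan for r in results]
        df["spsp_shared"] = [r.extra.get("n_shared", 0) for r in results]
        df["spsp_p_adj"] = bh_adjust(df["spsp_p"])

    # --- stage 4: evidence + ranking ----------------------------------
    evaluated = [evaluate_evidence(dict(row), cfg) for row in df.to_dict("records")]
    df = pd.DataFrame(evaluated)
    ranked = df[df["clinically_relevant"]].sort_values(
        ["combined_p_adj", "combined_p", "gene_a", "gene_b"],
        kind="stable",
    )
    df["rank"] = np.nan
    df.loc[ranked.index, "rank"] = np.arange(1, len(ranked) + 1)

    # stable column + row order for diffable output
    df = df.sort_values(["series", "gene_a", "gene_b"], kind="stable")
    df = df.sort_values("rank", na_position="last", kind="stable").reset_index(
        drop=True
    )

    # --- accounting (per-series counts mirroring a screening summary) --
    stages = {
        "pairs_input": df["gene_a"].notna(),
        "cellline_tested": df["combined_p"].notna(),
        "combined_p_lt_alpha": df["combined_p"] < cfg.alpha,
        "top_cellline": df["top_cellline"].apply(lambda v: v is True),
        "clinically_relevant": df["clinically_relevant"],
    }
    for t in ("sof", "exprsl", "survlrt", "isurvlrt", "spsp"):
        if f"{t}_p" in df.columns:
            stages[f"{t}_tested"] = df[f"{t}_p"].notna()
            stages[f"{t}_evidence"] = df[f"{t}_evidence"].apply(lambda v: v is True)
    acc_rows = []
    for stage, mask in stages.items():
        acc_rows.append({"stage": stage, **_series_counts(df, mask)})
    accounting = pd.DataFrame(acc_rows)
    for _, row in accounting.iterrows():
        log.info("pipeline stage %s: %s", row["stage"], row.drop("stage").to_dict())
    return PipelineResult(records=df, accounting=accounting)


def export_network(
    records: pd.DataFrame,
    top_n: int = 50,
    alpha: float = 0.05,
) -> nx.Graph:
    """Evidence network of the top-ranked clinically relevant pairs.

    Nodes are genes with a ``partner_count`` attribute; each edge carries
    the shared-pathway count (``weight``), the best drug name when any
    SPDD p-value is below ``alpha``, and ``style`` solid/dashed encoding
    confirmation by at least two patient tests.
    """
    ranked = records[records.get("rank").notna()].sort_values("rank")
    top = ranked.head(min(top_n, len(ranked)))
    g = nx.Graph()
    for _, row in top.iterrows():
        drug = ""
        for col in [c for c in records.columns if c.endswith("_drug")]:
            pcol = col[:-5] + "_p"
            if pcol in row and pd.notna(row[pcol]) and row[pcol] < alpha:
                drug = row[col]
                break
        g.add_edge(
            row["gene_a"],
            row["gene_b"],
            weight=int(row.get("spsp_shared", 0) or 0),
            best_drug=drug,
            style="solid" if row.get("n_patient_evidence", 0) >= 2 else "dashed",
            rank=int(row["rank"]),
        )
    for node in g.nodes:
        g.nodes[node]["partner_count"] = g.degree[node]
    return g


def write_network(g: nx.Graph, edge_tsv_path, graphml_path=None) -> None:
    """Write the evidence network as an edge-list TSV (and GraphML)."""
    rows = [
        {
            "gene_a": u,
            "gene_b": v,
            "shared_pathways": d.get("weight", 0),
            "best_drug": d.get("best_drug", ""),
            "style": d.get("style", "dashed"),
            "rank": d.get("rank", ""),
        }
        for u, v, d in sorted(g.edges(data=True), key=lambda e: e[2].get("rank", 0))
    ]
    pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "shared_pathways", "best_drug", "style", "rank"],
    ).to_csv(edge_tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
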