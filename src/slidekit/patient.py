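"""Patient-data tests for synthetic lethality.

Four tests run on tumor genomics, expression and survival:

* **SoF** (survival of the fittest): tumors with LoF in gene A compensate
  by raising expression of partner B — one-sided rank-sum test.
* **ExprSL**: co-expression of A and B (Spearman correlation with a
  two-sided t test).
* **SurvLRT**: a likelihood-ratio test of fitness epistasis under the
  Lehmann (proportional survival) model ``S_g(t) = S(t)^{Delta_g}``, where
  ``S`` is a reference survival curve and ``Delta_g`` the fitness of a
  tumor with genotype ``g = (g_A, g_B)``.  No epistasis means
  ``delta00 + delta11 = delta01 + delta10`` on the log-fitness scale; the
  synthetic-lethal direction is ``<`` (double-LoF tumors are unexpectedly
  unfit, so their patients survive longer than expected).
* **iSurvLRT**: SurvLRT with gene B's LoF status replaced by low
  expression, scanning a grid of expression-quantile thresholds and
  keeping the most significant iteration.

Under the Lehmann model, ``-ln S(T)`` for a patient with fitness ``Delta``
is Exponential(Delta), which yields the closed-form group estimate
``Delta_hat = d / sum_i(-ln S(t_i))`` (events ``d`` over all patients in
the group, censored included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import optimize
from scipy import stats as sps

from .datatypes import (
    AlterationMatrix,
    ExpressionMatrix,
    FitnessResult,
    GenePair,
    ReferenceSurvival,
    SimpleTestResult,
    SurvivalRecord,
    survival_frame,
)
from .stats import rank_sum_p

log = logging.getLogger(__name__)

__all__ = [
    "sof",
    "exprsl",
    "estimate_reference_survival",
    "fit_group_fitness",
    "survlrt",
    "isurvlrt",
    "PatientCohort",
    "run_patient_tests",
    "DEFAULT_QUANTILE_GRID",
]

MIN_LOF_PATIENTS = 20
MIN_DECEASED_PER_GENOTYPE = 5
GENOTYPES = ((0, 0), (0, 1), (1, 0), (1, 1))
DEFAULT_QUANTILE_GRID = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


def sof(expr_b, lof_a, pair: GenePair | None = None) -> SimpleTestResult:
    """One-sided rank-sum test: B expression higher in LoF-A tumors."""
    expr = np.asarray(expr_b, dtype=float)
    lof = np.asarray(lof_a).astype(bool)
    keep = ~np.isnan(expr)
    expr, lof = expr[keep], lof[keep]
    res = SimpleTestResult(pair=pair, test="SoF")
    n_lof = int(lof.sum())
    res.extra["n_lof"] = n_lof
    res.extra["n_wt"] = int((~lof).sum())
    if n_lof == 0 or (~lof).sum() == 0:
        res.applicable = False
        res.reason = "empty LoF or WT patient group"
        return res
    res.statistic, res.p_value = rank_sum_p(
        expr[lof], expr[~lof], alternative="greater"
    )
    return res


def exprsl(expr_a, expr_b, pair: GenePair | None = None) -> SimpleTestResult:
    """Spearman co-expression of A and B with a two-sided t test.

    p comes from ``t = rho * sqrt((n-2) / (1-rho^2))`` on ``n-2`` degrees
    of freedom; perfectly monotone data (|rho| = 1) is reported as p = 0
    with a degeneracy flag.
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    res = SimpleTestResult(pair=pair, test="ExprSL")
    n = a.size
    res.extra["n"] = n
    if n < 4:
        res.applicable = False
        res.reason = f"only {n} paired observations (need >= 4)"
        return res
    if np.unique(a).size == 1 or np.unique(b).size == 1:
        res.applicable = False
        res.reason = "constant expression vector; correlation undefined"
        return res
    rho = float(sps.spearmanr(a, b).statistic)
    res.statistic = rho
    res.extra["rho"] = rho
    if abs(rho) >= 1.0:
        res.p_value = 0.0
        res.extra["degenerate"] = True
        return res
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    res.p_value = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return res


def estimate_reference_survival(
    reference: list[SurvivalRecord] | pd.DataFrame,
    floor: float = 1e-12,
) -> ReferenceSurvival:
    """Kaplan-Meier estimate of the reference survival function S(t).

    The reference cohort stands for patients who did not die of the
    disease under study; its curve anchors the tumor-fitness model.
    """
    if isinstance(reference, list):
        reference = survival_frame(reference)
    times = reference["time"].to_numpy(dtype=float)
    events = reference["event"].to_numpy(dtype=int)
    if times.size == 0:
        raise ValueError("empty reference cohort")
    if events.sum() == 0:
        raise ValueError("reference cohort contains no events")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return ReferenceSurvival(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        floor=floor,
    )


def fit_group_fitness(times, events, reference: ReferenceSurvival) -> float:
    """Closed-form MLE of a group's tumor fitness ``Delta``.

    ``Delta_hat = d / sum_i(-ln S(t_i))`` with the sum over all patients
    in the group (events and censored) and ``d`` the number of events.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    d = int(events.sum())
    if d == 0:
        raise ValueError("group has no events; fitness not estimable")
    x = reference.neg_log(times)
    total = float(x.sum())
    if total <= 0:
        raise ValueError("sum of -ln S(t) is zero; all times at S=1")
    return d / total


def _group_stats(times, events, reference, genotypes):
    """Per-genotype (d, sum -ln S, n) sufficient statistics."""
    x = reference.neg_log(np.asarray(times, dtype=float))
    events = np.asarray(events, dtype=int)
    out = {}
    for g in GENOTYPES:
        mask = np.all(genotypes == np.asarray(g), axis=1)
        out[g] = (int(events[mask].sum()), float(x[mask].sum()), int(mask.sum()))
    return out


def _loglik(delta: np.ndarray, d: np.ndarray, x: np.ndarray) -> float:
    """Lehmann-model log likelihood (up to delta-free terms)."""
    return float(np.sum(d * delta - np.exp(delta) * x))


def survlrt(
    lof_a,
    lof_b,
    times,
    events,
    reference: ReferenceSurvival,
    pair: GenePair | None = None,
    min_lof: int = MIN_LOF_PATIENTS,
    min_deceased: int = MIN_DECEASED_PER_GENOTYPE,
    gate_wild_type_group: bool = True,
    test_name: str = "SurvLRT",
) -> FitnessResult:
    """Likelihood-ratio test of fitness epistasis between genes A and B.

    The unconstrained likelihood uses the four closed-form genotype MLEs;
    the null (``delta00 + delta11 = delta01 + delta10``) is maximized
    numerically over three free log-fitness parameters.  The statistic
    ``2(l_alt - l_null)`` is referred to chi-square with 1 df (two-sided
    alternative); the SL flag records whether the estimated epistasis
    ``delta = delta00 + delta11 - delta01 - delta10`` is negative and the
    CL (clinically relevant) flag whether ``delta00 > delta11``.

    Gates: gene A must be LoF-altered in at least ``min_lof`` patients and
    every genotype group must contain at least ``min_deceased`` deceased
    patients (``gate_wild_type_group=False`` exempts genotype (0, 0)).
    Gate failures yield an inapplicable result, not an exception.
    """
    lof_a = np.asarray(lof_a).astype(int)
    lof_b = np.asarray(lof_b).astype(int)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    res = FitnessResult(pair=pair, test=test_name)
    if min_lof is not None and lof_a.sum() < min_lof:
        res.applicable = False
        res.reason = f"gene A has {int(lof_a.sum())} < {min_lof} LoF patients"
        return res
    genotypes = np.column_stack([lof_a, lof_b])
    stats = _group_stats(times, events, reference, genotypes)
    res.group_sizes = {g: (n, d) for g, (d, _, n) in stats.items()}
    gated = [g for g in GENOTYPES if gate_wild_type_group or g != (0, 0)]
    for g in gated:
        d, x, _ = stats[g]
        if d < min_deceased:
            res.applicable = False
            res.reason = f"genotype {g} has {d} < {min_deceased} deceased patients"
            return res
        if x <= 0:
            res.applicable = False
            res.reason = f"genotype {g} has zero cumulative reference hazard"
            return res
    # genotype (0,0) still needs an estimable fitness even when ungated
    if not gate_wild_type_group and (stats[(0, 0)][0] == 0 or stats[(0, 0)][1] <= 0):
        res.applicable = False
        res.reason = "genotype (0, 0) fitness not estimable"
        return res

    d = np.array([stats[g][0] for g in GENOTYPES], dtype=float)
    x = np.array([stats[g][1] for g in GENOTYPES], dtype=float)
    delta_free = np.log(d / x)
    ll_alt = _loglik(delta_free, d, x)

    def negll_null(theta: np.ndarray) -> float:
        d00, d01, d10 = theta
        delta = np.array([d00, d01, d10, d01 + d10 - d00])
        return -_loglik(delta, d, x)

    start = delta_free[:3]
    opt = optimize.minimize(
        negll_null,
        start,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000},
    )
    ll_null = -float(opt.fun)
    res.lrt_statistic = max(0.0, 2.0 * (ll_alt - ll_null))
    res.p_value = float(sps.chi2.sf(res.lrt_statistic, df=1))
    res.delta_hat = dict(zip(GENOTYPES, delta_free))
    d00, d01, d10, d11 = delta_free
    res.effect_size = float(d00 + d11 - d01 - d10)
    res.delta11_expected = float(d01 + d10 - d00)
    res.sl_flag = 1 if res.effect_size < 0 else -1
    res.cl_flag = 1 if d00 > d11 else -1
    return res


def isurvlrt(
    lof_a,
    expr_b,
    times,
    events,
    reference: ReferenceSurvival,
    pair: GenePair | None = None,
    quantile_grid: tuple[float, ...] = DEFAULT_QUANTILE_GRID,
    min_lof: int = MIN_LOF_PATIENTS,
    min_deceased: int = MIN_DECEASED_PER_GENOTYPE,
    gate_wild_type_group: bool = True,
) -> FitnessResult:
    """SurvLRT with gene B's genotype defined by low expression.

    For each threshold ``t`` on the grid of empirical quantiles of B's
    expression, ``g_B(t) = 1`` iff ``e_B < t``; the SurvLRT iteration with
    the smallest p-value is returned together with its threshold.  No
    multiplicity correction is applied across the grid (the raw minimum is
    anti-conservative by construction; see package docs).  Iterations
    failing the deceased-per-genotype gate are skipped; if all fail the
    result is inapplicable.
    """
    lof_a = np.asarray(lof_a).astype(int)
    expr = np.asarray(expr_b, dtype=float)
    res = FitnessResult(pair=pair, test="iSurvLRT")
    if min_lof is not None and lof_a.sum() < min_lof:
        res.applicable = False
        res.reason = f"gene A has {int(lof_a.sum())} < {min_lof} LoF patients"
        return res
    if np.isnan(expr).all():
        res.applicable = False
        res.reason = "expression of gene B not measured"
        return res
    thresholds = np.quantile(expr[~np.isnan(expr)], quantile_grid)
    best: FitnessResult | None = None
    seen: set[float] = set()
    for q, t in zip(quantile_grid, thresholds):
        if t in seen:  # duplicate thresholds collapse to one iteration
            continue
        seen.add(float(t))
        g_b = (expr < t).astype(int)
        it = survlrt(
            lof_a,
            g_b,
            times,
            events,
            reference,
            pair=pair,
            min_lof=None,  # the >=20 LoF-A gate is checked once, above
            min_deceased=min_deceased,
            gate_wild_type_group=gate_wild_type_group,
            test_name="iSurvLRT",
        )
        if not it.applicable:
            continue
        it.threshold = float(t)
        it.threshold_quantile = float(q)
        if best is None or it.p_value < best.p_value:
            best = it
    if best is None:
        res.applicable = False
        res.reason = "no expression threshold satisfied the genotype gates"
        return res
    return best


@dataclass
class PatientCohort:
    """Expression + alteration + survival for one patient set, aligned on
    the intersection of sample identifiers (unmatched ids dropped with a
    logged count)."""

    expression: ExpressionMatrix
    alterations: AlterationMatrix
    survival: pd.DataFrame  # indexed by sample_id, columns time/event

    def __post_init__(self) -> None:
        if isinstance(self.survival, list):
            self.survival = survival_frame(self.survival)
        shared = [
            s
            for s in self.expression.samples
            if s in set(self.alterations.samples) and s in set(self.survival.index)
        ]
        dropped = (
            len(
                set(self.expression.samples)
                | set(self.alterations.samples)
                | set(self.survival.index)
            )
            - len(shared)
        )
        if dropped:
            log.info("patient cohort: %d unmatched sample ids dropped", dropped)
        self.expression = ExpressionMatrix(
            self.expression.values.loc[shared], normalized=self.expression.normalized
        )
        self.alterations = AlterationMatrix(self.alterations.values.loc[shared])
        self.survival = self.survival.loc[shared]

    @property
    def samples(self) -> list[str]:
        return list(self.survival.index)


def run_patient_tests(
    cohort: PatientCohort,
    reference: ReferenceSurvival,
    pairs: list[GenePair],
    tests: tuple[str, ...] = ("SoF", "ExprSL", "SurvLRT", "iSurvLRT"),
    min_lof: int = MIN_LOF_PATIENTS,
    min_deceased: int = MIN_DECEASED_PER_GENOTYPE,
    quantile_grid: tuple[float, ...] = DEFAULT_QUANTILE_GRID,
    gate_wild_type_group: bool = True,
) -> dict[str, list]:
    """All requested patient tests for every pair, with applicability gates."""
    expr = cohort.expression.values
    alt = cohort.alterations.values
    times = cohort.survival["time"].to_numpy(dtype=float)
    events = cohort.survival["event"].to_numpy(dtype=int)
    out: dict[str, list] = {t: [] for t in tests}
    for pair in pairs:
        a_altered = pair.gene_a in alt.columns
        a_expr = pair.gene_a in expr.columns
        b_expr = pair.gene_b in expr.columns
        b_altered = pair.gene_b in alt.columns
        lof_a = alt[pair.gene_a].to_numpy() if a_altered else None
        n_lof = int(lof_a.sum()) if lof_a is not None else 0

        if "SoF" in tests:
            if not (a_altered and b_expr):
                out["SoF"].append(
                    SimpleTestResult(
                        pair, "SoF", applicable=False,
                        reason="gene A alterations or gene B expression missing",
                    )
                )
            elif n_lof < min_lof:
                out["SoF"].append(
                    SimpleTestResult(
                        pair, "SoF", applicable=False,
                        reason=f"gene A has {n_lof} < {min_lof} LoF patients",
                    )
                )
            else:
                out["SoF"].append(sof(expr[pair.gene_b].to_numpy(), lof_a, pair=pair))
        if "ExprSL" in tests:
            if not (a_expr and b_expr):
                out["ExprSL"].append(
                    SimpleTestResult(
                        pair, "ExprSL", applicable=False,
                        reason="expression not measured for both genes",
                    )
                )
            else:
                out["ExprSL"].append(
                    exprsl(
                        expr[pair.gene_a].to_numpy(),
                        expr[pair.gene_b].to_numpy(),
                        pair=pair,
                    )
                )
        if "SurvLRT" in tests:
            if not (a_altered and b_altered):
                out["SurvLRT"].append(
                    FitnessResult(
                        pair, "SurvLRT", applicable=False,
                        reason="LoF alteration status missing for gene A or B",
                    )
                )
            else:
                out["SurvLRT"].append(
                    survlrt(
                        lof_a,
                        alt[pair.gene_b].to_numpy(),
                        times,
                        events,
                        reference,
                        pair=pair,
                        min_lof=min_lof,
                        min_deceased=min_deceased,
                        gate_wild_type_group=gate_wild_type_group,
                    )
                )
        if "iSurvLRT" in tests:
            if not (a_altered and b_expr):
                out["iSurvLRT"].append(
                    FitnessResult(
                        pair, "iSurvLRT", applicable=False,
                        reason="gene A alterations or gene B expression missing",
                    )
                )
            else:
                out["iSurvLRT"].append(
                    isurvlrt(
                        lof_a,
                        expr[pair.gene_b].to_numpy(),
                        times,
                        events,
                        reference,
                        pair=pair,
                        quantile_grid=quantile_grid,
                        min_lof=min_lof,
                        min_deceased=min_deceased,
                        gate_wild_type_group=gate_wild_type_group,
                    )
                )
    return out
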