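"""Coherent multi-omics synthetic data with planted synthetic-lethal pairs.

The generator emulates the statistical structure each test assumes — not
biological realism: LoF matrices are independent Bernoulli draws, dependency
scores and expression are Gaussian, survival follows the Lehmann model
``S_g(t) = exp(-lambda t)^{Delta_g}`` (so death times are Exponential with
rate ``lambda * Delta_g``), drug responses are Gaussian, and pathways are
random gene sets.  Planted pairs receive the per-modality shifts a true SL
pair would show: lower dependency of B in LoF-A cell lines, compensatory
upregulation of B in LoF-A tumors, unexpectedly long survival of double-LoF
patients, stronger drug response of LoF-A lines to drugs targeting B, and
co-membership in shared pathways.

A planted pair cannot carry the compensatory-upregulation (SoF) and the
low-expression-survival (iSurvLRT) signal at once — upregulating B in LoF-A
tumors depletes the low-expression double genotype — so the default profile
plants SoF plus the LoF-based survival signal, and the expression-based
survival profile is available separately for threshold-recovery studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import (
    AlterationMatrix,
    DependencyScreen,
    DrugScreen,
    ExpressionMatrix,
    GenePair,
    PathwayCollection,
    ReferenceSurvival,
    SurvivalRecord,
)
from .evidence import DataBundle, PipelineConfig
from .patient import PatientCohort, estimate_reference_survival

log = logging.getLogger(__name__)

__all__ = [
    "EffectProfile",
    "PlantedPair",
    "GeneratorConfig",
    "generate",
    "truth_table",
    "write_bundle",
    "draw_survival",
    "exponential_reference",
]

MIN_CARRIERS = 20  # planted focus genes must clear the >=20 LoF gate


@dataclass(frozen=True)
class EffectProfile:
    """Which modalities carry the planted signal for one pair."""

    dependency: bool = True
    sof: bool = True
    survival_lof: bool = True  # survival genotype from B's LoF alterations
    survival_expr: bool = False  # survival genotype from low B expression
    drug: bool = True
    pathway: bool = True
    expr_quantile: float = 0.25  # dichotomization point for survival_expr


#: profile for threshold-recovery studies: survival signal rides on low
#: expression of B instead of B's LoF status (and SoF is off, see module doc)
EXPRESSION_SURVIVAL_PROFILE = EffectProfile(
    sof=False, survival_lof=False, survival_expr=True
)


@dataclass(frozen=True)
class PlantedPair:
    gene_a: str
    gene_b: str
    profile: EffectProfile = EffectProfile()


def _default_planted() -> list[PlantedPair]:
    return [
        PlantedPair("FA01", "FB01"),
        PlantedPair("FA02", "FB02"),
        PlantedPair("FA03", "FB03"),
        PlantedPair("FA04", "DB01"),
        PlantedPair("FA05", "DB02"),
    ]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic bundle.

    Genes split into focus genes (``FAxx``, the LoF-tested A genes), focus
    partners (``FBxx``), druggable partners (``DBxx``) and background genes
    (``BGxx``); candidate pairs are every focus gene against every partner,
    with the series determined by the partner class.
    """

    seed: int = 0
    n_focus_genes: int = 8
    n_focus_partners: int = 13
    n_druggable_partners: int = 13
    n_background_genes: int = 26
    n_cell_lines: int = 300
    n_patients: int = 800
    n_reference_patients: int = 400
    n_drugs: int = 40
    n_pathways: int = 50
    lof_prevalence: float = 0.10
    planted_lof_prevalence: float = 0.25
    planted_pairs: list[PlantedPair] = field(default_factory=_default_planted)
    dependency_shift: float = -2.0  # mean dependency drop of B in LoF-A lines
    sof_shift: float = 2.0  # expression increase of B in LoF-A tumors
    survival_deltas: dict = field(
        default_factory=lambda: {
            (0, 0): 0.0,
            (0, 1): -0.2,
            (1, 0): -0.2,
            (1, 1): -1.5,  # well below the no-epistasis expectation of -0.4
        }
    )
    baseline_hazard: float = 0.02  # per month
    censoring_rate: float = 0.30
    drug_shift: float = -2.0  # ln(IC50) drop in LoF-A lines for planted drugs
    pathway_overlap: int = 5
    pathway_size_range: tuple[int, int] = (5, 20)

    @property
    def focus_genes(self) -> list[str]:
        return [f"FA{i:02d}" for i in range(1, self.n_focus_genes + 1)]

    @property
    def focus_partners(self) -> list[str]:
        return [f"FB{i:02d}" for i in range(1, self.n_focus_partners + 1)]

    @property
    def druggable_partners(self) -> list[str]:
        return [f"DB{i:02d}" for i in range(1, self.n_druggable_partners + 1)]

    @property
    def genes(self) -> list[str]:
        background = [f"BG{i:02d}" for i in range(1, self.n_background_genes + 1)]
        return (
            self.focus_genes
            + self.focus_partners
            + self.druggable_partners
            + background
        )

    @property
    def pairs(self) -> list[GenePair]:
        out = [
            GenePair(a, b, "focus")
            for a in self.focus_genes
            for b in self.focus_partners
        ]
        out += [
            GenePair(a, b, "focus_vs_druggable")
            for a in self.focus_genes
            for b in self.druggable_partners
        ]
        return out

    def validate(self) -> None:
        genes = set(self.genes)
        for p in self.planted_pairs:
            if p.gene_a not in genes or p.gene_b not in genes:
                raise ValueError(f"planted pair {p.gene_a}~{p.gene_b} outside gene set")
        if not 0 < self.lof_prevalence < 1 or not 0 < self.planted_lof_prevalence < 1:
            raise ValueError("LoF prevalences must lie in (0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.n_cell_lines < MIN_CARRIERS or self.n_patients < MIN_CARRIERS:
            raise ValueError(
                f"need at least {MIN_CARRIERS} cell lines and patients to satisfy "
                "the LoF-carrier gates"
            )


def _lof_matrix(
    rng: np.random.Generator,
    samples: list[str],
    genes: list[str],
    prevalence: float,
    boosted: set[str],
    boosted_prevalence: float,
) -> AlterationMatrix:
    """Bernoulli LoF matrix; boosted genes get a deterministic carrier count
    (first k samples of a seeded shuffle) to guarantee gate satisfaction."""
    n = len(samples)
    values = (rng.random((n, len(genes))) < prevalence).astype(np.int8)
    k = max(int(round(boosted_prevalence * n)), MIN_CARRIERS)
    for j, gene in enumerate(genes):
        if gene in boosted:
            col = np.zeros(n, dtype=np.int8)
            col[rng.permutation(n)[:k]] = 1
            values[:, j] = col
    return AlterationMatrix(
        pd.DataFrame(values, index=pd.Index(samples, name="sample_id"), columns=genes)
    )


def _censoring_rate_solve(rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with E[fraction censored] = target,
    given per-patient death rates; P(censored) = c / (c + rate)."""
    if target <= 0:
        return 0.0

    def f(c: float) -> float:
        return float(np.mean(c / (c + rates))) - target

    hi = rates.max() * target / (1 - target) * 100 + 1.0
    return float(optimize.brentq(f, 1e-12, hi))


def draw_survival(
    rng: np.random.Generator,
    log_fitness: np.ndarray,
    baseline_hazard: float,
    censoring_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Death/censoring draws under the Lehmann model.

    Each patient's death time is Exponential with rate
    ``baseline_hazard * exp(log_fitness)``; censoring is independent
    Exponential with its rate solved so the expected censored fraction
    equals ``censoring_rate``.  Returns (observed time, event indicator).
    """
    rates = baseline_hazard * np.exp(np.asarray(log_fitness, dtype=float))
    death = rng.exponential(1.0 / rates)
    if censoring_rate <= 0:
        return death, np.ones(death.size, dtype=int)
    c = _censoring_rate_solve(rates, censoring_rate)
    censor = rng.exponential(1.0 / c, size=death.size)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    return time, event


def exponential_reference(
    baseline_hazard: float, t_max: float = 600.0, n_steps: int = 12000
) -> ReferenceSurvival:
    """Dense step-function rendering of S(t) = exp(-lambda t), handy when a
    closed-form reference is wanted instead of a KM estimate."""
    t = np.linspace(0.0, t_max, n_steps)
    return ReferenceSurvival(times=t, survival=np.exp(-baseline_hazard * t))


@dataclass
class SyntheticBundle:
    """Generator output: a ready-to-run data bundle plus the truth table
    and reference cohort records."""

    bundle: DataBundle
    truth: pd.DataFrame
    reference_records: list[SurvivalRecord]


def generate(config: GeneratorConfig) -> SyntheticBundle:
    """Draw a complete multi-omics bundle under the configured conditions.

    The same seed and config always produce the identical bundle.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.genes
    planted = {(p.gene_a, p.gene_b): p for p in config.planted_pairs}
    planted_a = {p.gene_a for p in config.planted_pairs}
    planted_b = {p.gene_b for p in config.planted_pairs}

    cell_lines = [f"CL{i:04d}" for i in range(1, config.n_cell_lines + 1)]
    patients = [f"PT{i:04d}" for i in range(1, config.n_patients + 1)]

    # (i) LoF alteration matrices
    cl_alt = _lof_matrix(
        rng, cell_lines, genes, config.lof_prevalence, planted_a,
        config.planted_lof_prevalence,
    )
    pt_alt = _lof_matrix(
        rng, patients, genes, config.lof_prevalence, planted_a | planted_b,
        config.planted_lof_prevalence,
    )

    # (ii) dependency screens (an independent noise draw per screen)
    screens = []
    for name in ("screen-crispr", "screen-rnai"):
        scores = rng.normal(0.0, 1.0, size=(config.n_cell_lines, len(genes)))
        for (a, b), pp in planted.items():
            if not pp.profile.dependency:
                continue
            mask = cl_alt.values[a].to_numpy().astype(bool)
            j = genes.index(b)
            scores[mask, j] = rng.normal(config.dependency_shift, 1.0, mask.sum())
        screens.append(
            DependencyScreen(
                name,
                pd.DataFrame(
                    scores, index=pd.Index(cell_lines, name="sample_id"), columns=genes
                ),
            )
        )

    # (iii) patient expression (log scale, treated as already normalized)
    expr = rng.normal(0.0, 1.0, size=(config.n_patients, len(genes)))
    for (a, b), pp in planted.items():
        if pp.profile.sof:
            mask = pt_alt.values[a].to_numpy().astype(bool)
            expr[mask, genes.index(b)] += config.sof_shift
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=pd.Index(patients, name="sample_id"), columns=genes),
        normalized=True,
    )

    # (iv) survival under the Lehmann model; planted pairs contribute their
    # genotype's log fitness additively (independent pairs multiply fitness)
    log_fitness = np.zeros(config.n_patients)
    for (a, b), pp in planted.items():
        g_a = pt_alt.values[a].to_numpy()
        if pp.profile.survival_lof:
            g_b = pt_alt.values[b].to_numpy()
        elif pp.profile.survival_expr:
            e_b = expr[:, genes.index(b)]
            g_b = (e_b < np.quantile(e_b, pp.profile.expr_quantile)).astype(int)
        else:
            continue
        deltas = np.array(
            [[config.survival_deltas[(i, j)] for j in (0, 1)] for i in (0, 1)]
        )
        log_fitness += deltas[g_a, g_b]
    times, events = draw_survival(
        rng, log_fitness, config.baseline_hazard, config.censoring_rate
    )
    survival = pd.DataFrame(
        {"time": times, "event": events},
        index=pd.Index(patients, name="sample_id"),
    )
    ref_times, ref_events = draw_survival(
        rng,
        np.zeros(config.n_reference_patients),
        config.baseline_hazard,
        config.censoring_rate,
    )
    reference_records = [
        SurvivalRecord(f"RF{i:04d}", float(t), int(e))
        for i, (t, e) in enumerate(zip(ref_times, ref_events), start=1)
    ]

    # (v) drug screens: background noise + planted sensitivity shifts; every
    # planted partner gets a dedicated targeting drug, the rest draw 1-3
    # targets at random
    drug_screens = []
    for name in ("drugs-ic50", "drugs-lfc"):
        drug_ids = [f"{name}-D{i:03d}" for i in range(1, config.n_drugs + 1)]
        responses = rng.normal(0.0, 1.0, size=(config.n_cell_lines, config.n_drugs))
        target_map: dict[str, set[str]] = {}
        planted_bs = [p.gene_b for p in config.planted_pairs if p.profile.drug]
        for j, drug in enumerate(drug_ids):
            if j < len(planted_bs):
                target_map[drug] = {planted_bs[j]}
            else:
                n_targets = int(rng.integers(1, 4))
                target_map[drug] = set(
                    rng.choice(genes, size=n_targets, replace=False)
                )
        for (a, b), pp in planted.items():
            if not pp.profile.drug:
                continue
            mask = cl_alt.values[a].to_numpy().astype(bool)
            for j, drug in enumerate(drug_ids):
                if b in target_map[drug]:
                    responses[mask, j] += config.drug_shift
        drug_screens.append(
            DrugScreen(
                name,
                pd.DataFrame(
                    responses,
                    index=pd.Index(cell_lines, name="sample_id"),
                    columns=drug_ids,
                ),
                {d: frozenset(t) for d, t in target_map.items()},
            )
        )

    # (vi) pathways: random gene sets + guaranteed shared membership for
    # planted pairs
    lo, hi = config.pathway_size_range
    lo, hi = min(lo, len(genes)), min(hi, len(genes))
    pathway_names = [f"PW{i:03d}" for i in range(1, config.n_pathways + 1)]
    pathways: dict[str, set[str]] = {
        name: set(rng.choice(genes, size=int(rng.integers(lo, hi + 1)), replace=False))
        for name in pathway_names
    }
    for (a, b), pp in planted.items():
        if not pp.profile.pathway:
            continue
        shared = rng.choice(
            pathway_names, size=min(config.pathway_overlap, len(pathway_names)),
            replace=False,
        )
        for name in shared:
            pathways[name].update((a, b))
    collection = PathwayCollection({n: frozenset(g) for n, g in pathways.items()})

    cohort = PatientCohort(expression, pt_alt, survival)
    reference = estimate_reference_survival(reference_records)
    bundle = DataBundle(
        pairs=config.pairs,
        screens=screens,
        cellline_alterations=cl_alt,
        cohort=cohort,
        reference=reference,
        drug_screens=drug_screens,
        pathways=collection,
        config=PipelineConfig(seed=config.seed),
    )
    return SyntheticBundle(
        bundle=bundle, truth=truth_table(config), reference_records=reference_records
    )


def truth_table(config: GeneratorConfig) -> pd.DataFrame:
    """Every candidate pair labeled planted/not with per-modality expected
    signal flags; derivable from the config alone."""
    planted = {(p.gene_a, p.gene_b): p for p in config.planted_pairs}
    rows = []
    for pair in config.pairs:
        pp = planted.get((pair.gene_a, pair.gene_b))
        prof = pp.profile if pp else None
        rows.append(
            {
                "gene_a": pair.gene_a,
                "gene_b": pair.gene_b,
                "series": pair.series,
                "planted": pp is not None,
                "signal_dependency": bool(prof and prof.dependency),
                "signal_sof": bool(prof and prof.sof),
                "signal_survival_lof": bool(prof and prof.survival_lof),
                "signal_survival_expr": bool(prof and prof.survival_expr),
                "signal_drug": bool(prof and prof.drug),
                "signal_pathway": bool(prof and prof.pathway),
            }
        )
    return pd.DataFrame(rows)


def null_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A configuration with no planted pairs (for calibration studies)."""
    return replace(GeneratorConfig(seed=seed, planted_pairs=[]), **overrides)


def write_bundle(synth: SyntheticBundle, out_dir) -> None:
    """Write every input file in the formats the readers consume."""
    from . import io as skio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    b = synth.bundle
    skio.write_matrix(b.cellline_alterations.values, out / "cellline_alterations.tsv")
    for screen in b.screens:
        skio.write_matrix(screen.scores, out / f"dependency_{screen.dataset_name}.tsv")
    skio.write_matrix(b.cohort.alterations.values, out / "patient_alterations.tsv")
    skio.write_matrix(b.cohort.expression.values, out / "patient_expression.tsv")
    surv = b.cohort.survival.reset_index()
    surv.to_csv(out / "patient_survival.tsv", sep="\t", index=False,
                float_format="%.6g")
    skio.write_survival(synth.reference_records, out / "reference_survival.tsv")
    for screen in b.drug_screens:
        skio.write_matrix(screen.responses, out / f"drug_{screen.dataset_name}.tsv")
        skio.write_target_map(
            screen.target_map, out / f"targets_{screen.dataset_name}.tsv"
        )
    skio.write_gmt(b.pathways, out / "pathways.gmt")
    skio.write_pairs(b.pairs, out / "pairs.tsv")
    synth.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
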