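"""Core data containers for multi-evidence synthetic-lethality screening.

All tabular containers wrap :class:`pandas.DataFrame` with samples on rows
and genes (or drugs) on columns.  Identifiers are plain strings and must be
unique on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "AlterationMatrix",
    "DependencyScreen",
    "ExpressionMatrix",
    "SurvivalRecord",
    "DrugScreen",
    "PathwayCollection",
    "GenePair",
    "CellLineTestResult",
    "SimpleTestResult",
    "FitnessResult",
    "ReferenceSurvival",
]


@dataclass(frozen=True)
class VariantRecord:
    """A single somatic variant call at gene resolution.

    ``predictor_flags`` are the damaging verdicts of five variant-effect
    predictors and are required for (and only meaningful for) missense
    variants; pass ``None`` otherwise.
    """

    sample_id: str
    gene: str
    consequence: str
    predictor_flags: tuple[bool, ...] | None = None


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class AlterationMatrix:
    """Binary samples x genes loss-of-function indicator matrix."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample identifiers")
        _check_unique(self.values.columns, "gene symbols")
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("alteration matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def lof_vector(self, gene: str) -> pd.Series:
        """Binary LoF status of ``gene`` across all samples."""
        return self.values[gene]

    def n_lof(self, gene: str) -> int:
        return int(self.values[gene].sum()) if gene in self.values.columns else 0


@dataclass
class DependencyScreen:
    """Gene-dependency scores from a knockout/knockdown screen.

    Rows are cell lines, columns genes; missing scores allowed (NaN).
    Negative score = the line proliferates worse after inactivating the gene.
    """

    dataset_name: str
    scores: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.scores.index, "cell line identifiers")
        _check_unique(self.scores.columns, "gene symbols")

    @property
    def cell_lines(self) -> list[str]:
        return list(self.scores.index)

    @property
    def genes(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class ExpressionMatrix:
    """Samples x genes expression, log2 scale once ``normalized``."""

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample identifiers")
        _check_unique(self.values.columns, "gene symbols")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in months, event 1 = deceased."""

    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.sample_id}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0/1, got {self.event}")


def survival_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Records -> DataFrame indexed by sample_id with time/event columns."""
    df = pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [r.event for r in records],
        },
        index=pd.Index([r.sample_id for r in records], name="sample_id"),
    )
    _check_unique(df.index, "survival sample identifiers")
    return df


@dataclass
class DrugScreen:
    """Cell-line drug responses plus the drug -> target-gene mapping.

    Responses follow the lower-is-more-sensitive convention (e.g. ln(IC50)
    or median-collapsed log-fold-change); this is dataset metadata and is
    never inferred from the values.
    """

    dataset_name: str
    responses: pd.DataFrame  # cell lines x drugs
    target_map: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        _check_unique(self.responses.index, "cell line identifiers")
        _check_unique(self.responses.columns, "drug identifiers")
        missing = set(self.responses.columns) - set(self.target_map)
        if missing:
            raise ValueError(f"drugs without target annotation: {sorted(missing)[:5]}")
        self.target_map = {d: frozenset(t) for d, t in self.target_map.items()}

    def drugs_targeting(self, gene: str) -> list[str]:
        return [d for d in self.responses.columns if gene in self.target_map[d]]


@dataclass
class PathwayCollection:
    """Named gene sets plus the size of the pathway universe tested."""

    pathways: dict[str, frozenset[str]]
    universe_size: int | None = None

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"empty pathway {name!r}")
        if self.universe_size is None:
            self.universe_size = len(self.pathways)
        if self.universe_size < len(self.pathways):
            raise ValueError("universe_size smaller than number of stored pathways")


@dataclass(frozen=True, order=True)
class GenePair:
    """Ordered candidate pair: A carries the endogenous LoF, B is the
    candidate synthetic-lethal partner."""

    gene_a: str
    gene_b: str
    series: str = "focus"

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"gene pair must be two distinct genes: {self.gene_a}")

    @property
    def label(self) -> str:
        return f"{self.gene_a}~{self.gene_b}"


@dataclass
class SimpleTestResult:
    """Outcome of one scalar statistical test on one pair."""

    pair: GenePair
    test: str
    statistic: float = float("nan")
    p_value: float = float("nan")
    applicable: bool = True
    reason: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class CellLineTestResult:
    """SPID or SPEA outcome on one dependency screen."""

    pair: GenePair
    dataset: str
    test: str  # "SPID" | "SPEA"
    statistic: float = float("nan")
    p_value: float = float("nan")
    n_lof: int = 0
    n_wt: int = 0
    positive_dependency_pct: float = float("nan")
    direction_sl: bool = False
    applicable: bool = True
    reason: str | None = None


@dataclass
class FitnessResult:
    """Per-genotype tumor-fitness estimates and the epistasis LRT outcome.

    ``delta_hat`` maps genotype (g_A, g_B) to the estimated log fitness
    delta_g = ln(Delta_g); ``effect_size`` is
    delta00 + delta11 - delta01 - delta10 (negative in the SL direction);
    ``delta11_expected`` = delta01 + delta10 - delta00 is the double-LoF log
    fitness expected without epistasis.
    """

    pair: GenePair
    test: str = "SurvLRT"
    delta_hat: dict[tuple[int, int], float] = field(default_factory=dict)
    effect_size: float = float("nan")
    delta11_expected: float = float("nan")
    lrt_statistic: float = float("nan")
    p_value: float = float("nan")
    sl_flag: int = 0  # 1 = epistasis in SL direction, -1 otherwise
    cl_flag: int = 0  # 1 = clinically relevant (delta00 > delta11)
    threshold: float | None = None  # expression threshold (iSurvLRT only)
    threshold_quantile: float | None = None
    group_sizes: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)
    applicable: bool = True
    reason: str | None = None


@dataclass
class ReferenceSurvival:
    """Right-continuous step estimate of a reference survival function S(t).

    Values are floored at ``floor`` so that -ln S stays finite; times past
    the last observed time carry the last step value.
    """

    times: np.ndarray
    survival: np.ndarray
    floor: float = 1e-12

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.survival.shape:
            raise ValueError("times and survival must be 1-D and equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        self.survival = np.clip(self.survival, self.floor, 1.0)

    def evaluate(self, t) -> np.ndarray:
        """S(t) for scalar or array t (right-continuous step lookup)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out

    def neg_log(self, t) -> np.ndarray:
        """-ln S(t), the cumulative hazard of the reference population."""
        return -np.log(self.evaluate(t))
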