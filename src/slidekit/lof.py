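"""Loss-of-function (LoF) variant classification and alteration matrices.

A variant counts as LoF when its consequence is high impact (splice site,
nonsense, frameshift indel, start-codon disruption, stop-codon indel) or
when it is a missense call that at least 3 of 5 effect predictors flag as
damaging.  The per-variant predictor verdicts are inputs; no predictor is
run here.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import AlterationMatrix, VariantRecord

log = logging.getLogger(__name__)

__all__ = [
    "HIGH_IMPACT_CONSEQUENCES",
    "BENIGN_CONSEQUENCES",
    "CONSEQUENCE_VOCABULARY",
    "classify_lof",
    "build_alteration_matrix",
]

#: Consequence terms that are LoF irrespective of predictor verdicts.
HIGH_IMPACT_CONSEQUENCES = frozenset(
    {
        "splice_site",
        "splice_donor",
        "splice_acceptor",
        "stop_gained",
        "nonsense",
        "frameshift",
        "frameshift_insertion",
        "frameshift_deletion",
        "start_lost",
        "start_codon_insertion",
        "start_codon_deletion",
        "start_codon_snp",
        "stop_lost",
        "stop_codon_insertion",
        "stop_codon_deletion",
    }
)

#: Consequence terms that never count as LoF.
BENIGN_CONSEQUENCES = frozenset(
    {
        "synonymous",
        "silent",
        "inframe_insertion",
        "inframe_deletion",
        "intron",
        "utr",
        "upstream",
        "downstream",
    }
)

CONSEQUENCE_VOCABULARY = HIGH_IMPACT_CONSEQUENCES | BENIGN_CONSEQUENCES | {"missense"}

#: Minimum number of damaging predictor verdicts for a damaging-missense call.
MISSENSE_CONSENSUS = 3


def classify_lof(variant: VariantRecord) -> int:
    """Return 1 if ``variant`` is a loss-of-function alteration, else 0.

    Missense variants need predictor verdicts: >=3 of the 5 damaging flags
    make the call.  If fewer than five verdicts are available the consensus
    is taken over the available ones only when at least three exist;
    otherwise the variant is conservatively non-LoF (logged).

    Raises
    ------
    ValueError
        If the consequence term is outside the controlled vocabulary, or a
        missense variant carries no predictor verdicts.
    """
    term = variant.consequence.strip().lower()
    if term not in CONSEQUENCE_VOCABULARY:
        raise ValueError(f"unknown consequence term: {variant.consequence!r}")
    if term in HIGH_IMPACT_CONSEQUENCES:
        return 1
    if term != "missense":
        return 0
    flags = variant.predictor_flags
    if flags is None:
        raise ValueError(
            f"missense variant in {variant.gene} ({variant.sample_id}) "
            "has no predictor verdicts"
        )
    if len(flags) < 5:
        if len(flags) < MISSENSE_CONSENSUS:
            log.warning(
                "missense variant in %s has only %d predictor verdicts; "
                "classified non-LoF",
                variant.gene,
                len(flags),
            )
            return 0
        log.warning(
            "missense variant in %s has %d/5 predictor verdicts; "
            "consensus taken over available ones",
            variant.gene,
            len(flags),
        )
    return 1 if sum(bool(f) for f in flags) >= MISSENSE_CONSENSUS else 0


def build_alteration_matrix(
    variants: list[VariantRecord],
    samples: list[str],
    genes: list[str],
    strict: bool = False,
) -> AlterationMatrix:
    """Binary samples x genes matrix: 1 iff the sample carries >=1 LoF
    variant in the gene.

    Samples/genes without any variant stay as all-zero rows/columns.  A
    variant naming an unknown sample or gene is skipped with a warning, or
    raises when ``strict``.
    """
    if not samples or not genes:
        raise ValueError("samples and genes must be non-empty")
    values = pd.DataFrame(
        np.zeros((len(samples), len(genes)), dtype=np.int8),
        index=pd.Index(samples, name="sample_id"),
        columns=pd.Index(genes, name="gene"),
    )
    sample_set, gene_set = set(samples), set(genes)
    skipped = 0
    for v in variants:
        if v.sample_id not in sample_set or v.gene not in gene_set:
            if strict:
                raise KeyError(
                    f"variant references unknown sample/gene: "
                    f"{v.sample_id}/{v.gene}"
                )
            skipped += 1
            continue
        if classify_lof(v):
            values.at[v.sample_id, v.gene] = 1
    if skipped:
        log.warning("skipped %d variants with unknown sample/gene", skipped)
    return AlterationMatrix(values)
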