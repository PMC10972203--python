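"""Reaction states, taxonomy-level frequencies, scores and thresholds.

For each metagenome species pangenome (MSP) the binary reaction state
says whether the species' gene complement switches a reference-GEM
reaction on. States are pooled over MSPs sharing a taxon at each of the
five levels (genus, family, order, class, phylum) into reaction
frequencies in [0, 1]; the reaction score is state + frequency, in
[0, 2], and drives the pruning order for species-GEM generation. Each
level's lowest non-zero frequency is that level's gap-filling threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import GEM, eval_gpr
from .tables import TAXONOMY_LEVELS, UNCLASSIFIED

MEAN_OVER_LEVELS = "mean_over_levels"


def msp_reaction_states(
    ref: GEM,
    msps: dict[str, set[str]],
    mode: str = "boolean",
    catalog_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Binary reaction x MSP presence matrix from GPR rules.

    ``boolean`` mode evaluates each reaction's GPR with the MSP's genes
    present (AND complexes require all subunits); ``any_gene`` mode calls
    a reaction present as soon as any GPR gene is in the MSP. Reactions
    with an empty GPR are absent (0) for every MSP.
    """
    if mode not in ("boolean", "any_gene"):
        raise ValueError(f"unknown state mode {mode!r}")
    if catalog_genes is not None:
        for msp, genes in msps.items():
            stray = genes - catalog_genes
            if stray:
                raise ValueError(
                    f"MSP {msp} has genes outside the catalogue: {sorted(stray)[:5]}"
                )
    rxn_ids = ref.reaction_ids
    msp_ids = list(msps)
    data = np.zeros((len(rxn_ids), len(msp_ids)), dtype=np.int8)
    for i, rxn in enumerate(ref.reactions):
        genes = rxn.genes
        if not genes:
            continue
        for j, msp in enumerate(msp_ids):
            hit = genes & msps[msp]
            if mode == "any_gene":
                data[i, j] = 1 if hit else 0
            else:
                data[i, j] = 1 if hit and eval_gpr(rxn.gpr_rule, hit) else 0
    return pd.DataFrame(data, index=rxn_ids, columns=msp_ids)


def _group_labels(tax: pd.DataFrame, msp_ids: list[str], level: str) -> pd.Series:
    """Per-MSP group key at one level; unclassified MSPs stay singletons."""
    labels = tax.loc[msp_ids, level].astype(str)
    mask = labels.str.lower() == UNCLASSIFIED
    labels = labels.where(~mask, other=[f"{UNCLASSIFIED}::{m}" for m in labels.index])
    return labels


def taxon_reaction_frequencies(
    states: pd.DataFrame, tax: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Per-level reaction frequencies: mean state over each MSP's taxon peers.

    Returns one reactions x MSPs matrix per taxonomy level; the entry for
    (reaction r, MSP i) is the mean of r's states over all MSPs whose
    level-L taxon equals MSP i's. ``unclassified`` lineage entries never
    pool: each such MSP is its own singleton group (frequency = own state).
    """
    missing = [m for m in states.columns if m not in tax.index]
    if missing:
        raise ValueError(f"MSPs without taxonomy records: {missing}")
    msp_ids = list(states.columns)
    freqs: dict[str, pd.DataFrame] = {}
    for level in TAXONOMY_LEVELS:
        labels = _group_labels(tax, msp_ids, level)
        group_mean = states.T.groupby(labels.values).mean().T  # reactions x taxa
        freqs[level] = group_mean.loc[:, labels.values].set_axis(msp_ids, axis=1)
    return freqs


def combined_frequency(
    freqs: dict[str, pd.DataFrame], freq_mode: str = MEAN_OVER_LEVELS
) -> pd.DataFrame:
    """The frequency term used in scores: across-level mean or one level."""
    if freq_mode == MEAN_OVER_LEVELS:
        stacked = np.stack([freqs[level].values for level in TAXONOMY_LEVELS])
        first = freqs[TAXONOMY_LEVELS[0]]
        return pd.DataFrame(stacked.mean(axis=0), index=first.index, columns=first.columns)
    if freq_mode in freqs:
        return freqs[freq_mode].copy()
    raise ValueError(f"freq_mode must be {MEAN_OVER_LEVELS!r} or a taxonomy level, got {freq_mode!r}")


def reaction_scores(
    states: pd.DataFrame,
    freqs: dict[str, pd.DataFrame],
    freq_mode: str = MEAN_OVER_LEVELS,
) -> pd.DataFrame:
    """Reaction scores in [0, 2]: state + taxonomy frequency.

    The frequency term defaults to the mean over the five levels;
    ``freq_mode`` may instead name a single level.
    """
    f = combined_frequency(freqs, freq_mode)
    if not f.index.equals(states.index) or not f.columns.equals(states.columns):
        raise ValueError("state and frequency matrices are not aligned")
    return states.astype(float) + f


def taxonomy_thresholds(freqs: dict[str, pd.DataFrame]) -> dict[str, float]:
    """Per-level threshold: the lowest non-zero frequency at that level."""
    thresholds: dict[str, float] = {}
    for level, mat in freqs.items():
        positive = mat.values[mat.values > 0]
        if positive.size == 0:
            raise ValueError(f"all frequencies are zero at level {level!r}; threshold undefined")
        thresholds[level] = float(positive.min())
    return thresholds
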