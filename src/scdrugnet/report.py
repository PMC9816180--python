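"""Tissue-specificity exclusion filter and the final candidate table.

A repurposing candidate whose target is specific to a tissue irrelevant to the
disease is excluded: for candidates significant only in non-microglia cell
networks, any of the four HPA specificity categories (Tissue enriched, Tissue
enhanced, Group enriched, Group enhanced) pointing at a non-brain tissue is
disqualifying.  Microglia candidates keep targets specific to immune-related
tissues (lymphoid tissue, blood, bone marrow, gallbladder), since microglia
are the brain's resident immune cells; a candidate significant in both
microglia and other networks is evaluated under the more permissive microglia
rule.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

SPECIFIC_CATEGORIES = frozenset(
    {"Tissue enriched", "Tissue enhanced", "Group enriched", "Group enhanced"}
)
CATEGORY_VOCABULARY = SPECIFIC_CATEGORIES | {"Low specificity", "Not detected"}

DEFAULT_BRAIN_TISSUES = ("brain", "cerebral cortex", "cerebellum")
DEFAULT_IMMUNE_TISSUES = ("lymphoid tissue", "blood", "bone marrow", "gallbladder")


def build_candidate_table(screen_results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate significant screen rows into one row per (drug, target).

    Keeps the cells and modules where the pair is significant, the best
    (lowest) combined z and the smallest empirical p."""
    sig = screen_results[screen_results["significant"]]
    rows = []
    for (drug, target), grp in sig.groupby(["drug", "target"], sort=True):
        modules = sorted(f"{c}:{m}" for c, m in zip(grp["cell"], grp["module"]))
        rows.append(
            {
                "drug": drug,
                "target": target,
                "cells": ",".join(sorted(set(grp["cell"]))),
                "modules": ",".join(modules),
                "combined_z": float(grp["combined_z"].min()),
                "p": float(grp["p"].min()),
            }
        )
    return pd.DataFrame(
        rows, columns=["drug", "target", "cells", "modules", "combined_z", "p"]
    )


def tissue_filter(
    candidates: pd.DataFrame,
    tissue_table: pd.DataFrame,
    brain_tissues=DEFAULT_BRAIN_TISSUES,
    immune_tissues=DEFAULT_IMMUNE_TISSUES,
) -> pd.DataFrame:
    """Flag candidates excluded by target tissue specificity.

    Pure function: the returned table contains every input row plus
    ``excluded_by_tissue_filter`` and ``exclusion_reason`` columns.  Targets
    absent from the tissue table are retained with a note; an unknown
    specificity category is rejected."""
    unknown = set(tissue_table["category"]) - CATEGORY_VOCABULARY
    if unknown:
        raise ValueError(f"unknown tissue specificity categories: {sorted(unknown)}")
    brain = {t.lower() for t in brain_tissues}
    immune = {t.lower() for t in immune_tissues}
    spec = tissue_table.set_index("gene")

    out = candidates.copy()
    excluded, reasons = [], []
    for row in out.itertuples(index=False):
        if row.target not in spec.index:
            logger.info("target %s absent from tissue table; retained", row.target)
            excluded.append(False)
            reasons.append("target not in tissue table")
            continue
        rec = spec.loc[row.target]
        if isinstance(rec, pd.DataFrame):  # several tissues listed for one gene
            cats = list(rec["category"])
            tissues = [str(t).lower() for t in rec["tissue"]]
        else:
            cats = [rec["category"]]
            tissues = [str(rec["tissue"]).lower()]
        is_mic = "MIC" in str(row.cells).split(",")
        allowed = brain | immune if is_mic else brain
        bad = [
            t
            for c, t in zip(cats, tissues)
            if c in SPECIFIC_CATEGORIES and t not in allowed
        ]
        if bad:
            excluded.append(True)
            reasons.append(f"target specific for non-disease tissue: {','.join(sorted(bad))}")
        else:
            excluded.append(False)
            reasons.append("")
    out["excluded_by_tissue_filter"] = excluded
    out["exclusion_reason"] = reasons
    return out
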