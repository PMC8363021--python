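"""End-to-end drivers: scan -> classify -> complement -> gain/loss.

These functions chain the package's stages the way the analysis scripts
and the acceptance checks run them, so every result reported anywhere is
recomputed from sequences at call time.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from nrminer.classify import (
    NRClassification,
    PBoxCatalog,
    ReferencePanel,
    call_complement,
    classify_record,
)
from nrminer.config import DEFAULT_CONFIG, RunConfig
from nrminer.datasets import (
    build_reference_panel,
    build_survey,
    load_ancestral_root_set,
    load_class_tree,
    load_curated_events,
    load_outgroup_presence,
    load_pbox_catalog,
    load_species_table,
)
from nrminer.evolution import (
    ComplementMatrix,
    ancestral_complement,
    build_matrix,
    dollo_gain_loss,
    propagate_events,
)
from nrminer.motifs import ProteinRecord


def classify_records(
    records: Iterable[ProteinRecord],
    catalog: PBoxCatalog,
    panel: ReferencePanel,
    config: RunConfig = DEFAULT_CONFIG,
) -> list[NRClassification]:
    """Classify every record that carries at least one full DBD."""
    out = []
    for rec in records:
        cls = classify_record(rec, catalog, panel, config)
        if cls is not None:
            out.append(cls)
    return out


def classifications_frame(classifications: Sequence[NRClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "record_id": [c.record_id for c in classifications],
            "species": [c.species for c in classifications],
            "architecture": [c.architecture for c in classifications],
            "subfamily": [c.subfamily for c in classifications],
            "group": [c.group for c in classifications],
            "divergent": [c.divergent for c in classifications],
            "chc2": [c.chc2 for c in classifications],
            "typical_pbox": [c.typical_pbox for c in classifications],
            "pbox10": [c.pbox10 for c in classifications],
        }
    )


def complement_matrix(
    classifications: Sequence[NRClassification],
) -> ComplementMatrix:
    """Species x group complement counts from gene classifications."""
    by_species: dict[str, list[NRClassification]] = {}
    for cls in classifications:
        by_species.setdefault(cls.species, []).append(cls)
    rows = {
        sp: call_complement(members, sp) for sp, members in sorted(by_species.items())
    }
    return build_matrix(rows)


def class_level_presence(
    matrix: ComplementMatrix,
    include_outgroup: bool = True,
) -> pd.DataFrame:
    """Collapse species rows to the five flatworm lineages (plus outgroup).

    Presence per lineage is the union over its species; the divergent and
    unassigned bins are lineage-specific inventions, not ortholog groups,
    and are excluded from gain/loss analysis.
    """
    table = load_species_table().set_index("code")
    pres = matrix.presence
    drop = [c for c in ("divergent", "unassigned") if c in pres.columns]
    pres = pres.drop(columns=drop)
    lineages = {}
    for sp in pres.index:
        lin = table.loc[sp, "lineage"]
        if lin in lineages:
            lineages[lin] = lineages[lin] | pres.loc[sp]
        else:
            lineages[lin] = pres.loc[sp].copy()
    frame = pd.DataFrame(lineages).T
    if include_outgroup:
        out_row = load_outgroup_presence()
        frame.loc["Outgroup"] = [
            bool(out_row.get(g, False)) for g in frame.columns
        ]
    return frame.astype(bool)


def run_survey(seed: int = 0, config: RunConfig = DEFAULT_CONFIG):
    """Full synthetic-survey pipeline.

    Returns a dict with the classifications, the complement matrix, the
    class-level presence frame, the Dollo reconstruction, the reconstructed
    flatworm-ancestor complement, and the diff against the curated
    24-member fixture list.
    """
    survey = build_survey(seed=seed)
    catalog = load_pbox_catalog()
    panel = build_reference_panel()
    classifications = classify_records(survey.records, catalog, panel, config)
    matrix = complement_matrix(classifications)
    presence = class_level_presence(matrix, include_outgroup=True)
    tree = load_class_tree(include_outgroup=True)
    recon = dollo_gain_loss(presence, tree)
    mrca_set = ancestral_complement(recon, "Platy")
    fixture = set(load_ancestral_root_set())
    diff = {
        "fixture_only": sorted(fixture - mrca_set),
        "reconstruction_only": sorted(mrca_set - fixture),
    }
    return {
        "survey": survey,
        "classifications": classifications,
        "matrix": matrix,
        "presence": presence,
        "reconstruction": recon,
        "mrca_set": mrca_set,
        "fixture_root_set": fixture,
        "root_set_diff": diff,
    }


def curated_propagation(presence: pd.DataFrame):
    """Replay the curated per-branch events from the 24-member root set and
    diff the propagated per-lineage complements against observation."""
    tree = load_class_tree(include_outgroup=False)
    observed = presence.drop(index=["Outgroup"], errors="ignore")
    return propagate_events(
        load_ancestral_root_set(),
        load_curated_events(),
        tree,
        observed=observed,
    )
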