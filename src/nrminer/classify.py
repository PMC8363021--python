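"""P-box and reference-panel classification of NR DBDs.

The P-box — the recognition element anchored at the third CI chelating
cysteine — is diagnostic for NR subfamilies and for some ortholog groups
(ESCKG marks subfamily 5, CDGCRG marks NHR236, EACKA marks ERR).  Fine
group assignment additionally uses the nearest labelled reference DBD under
the anchor-alignment p-distance; on conflict between the two lines of
evidence the P-box wins, mirroring how a diagnostic P-box overrides a
weakly supported tree placement.

A *divergent* NR is one whose P-box is atypical, or whose P-box is typical
but resolves to no group and to no unique subfamily.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from nrminer.config import DEFAULT_CONFIG, RunConfig
from nrminer.motifs import DBDHit, PBox, ProteinRecord, scan_record
from nrminer.phylo import AnchoredDBD, anchor_align, from_hit, pairwise_p_distance

SUBFAMILIES = ("NR1", "NR2", "NR3", "NR4", "NR5", "NR6", "2DBD")

#: Subfamily membership of every ortholog-group label the package knows.
GROUP_SUBFAMILY: dict[str, str] = {
    "TR": "NR1", "TRb": "NR1", "E78": "NR1",
    "HR96a": "NR1", "HR96b": "NR1", "HR96c": "NR1", "HR96d": "NR1",
    "NR1a": "NR1", "NR1b": "NR1",
    "HNF4": "NR2", "RXR1": "NR2", "RXR2": "NR2", "TR4": "NR2",
    "TLX": "NR2", "PNR": "NR2", "DSF": "NR2", "fax1": "NR2",
    "NHR236": "NR2", "CoupTFI": "NR2", "CoupTFII": "NR2",
    "ERR": "NR3",
    "NR4A": "NR4",
    "FTZF1": "NR5", "HR39": "NR5",
    "GCNF": "NR6",
    "2DBDa": "2DBD", "2DBDb": "2DBD", "2DBDg": "2DBD",
}

#: Family base of a fine group, used when a catalogue candidate names the
#: family rather than the paralog (RXR covers RXR1/RXR2, etc.).
_BASE = re.compile(r"(I+|[0-9]+|[a-d])$")


def group_base(group: str) -> str:
    if group in ("NR1a", "NR1b", "NR4A", "TR4", "E78", "HR39"):
        return group
    return _BASE.sub("", group)


def subfamily_of(label: str) -> str | None:
    if label in SUBFAMILIES:
        return label
    return GROUP_SUBFAMILY.get(label)


@dataclass(frozen=True)
class CatalogEntry:
    pattern: str
    labels: tuple[str, ...]
    level: str  # "subfamily" | "group" | "divergent"
    canonical: bool


@dataclass(frozen=True)
class PBoxCatalog:
    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        patterns = [e.pattern for e in self.entries]
        if len(patterns) != len(set(patterns)):
            raise ValueError("catalogue patterns must be unique")
        for e in self.entries:
            if not 5 <= len(e.pattern) <= 10:
                raise ValueError(f"pattern {e.pattern!r} outside length 5-10")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PBoxCatalog":
        entries = []
        for _, row in frame.iterrows():
            entries.append(
                CatalogEntry(
                    pattern=row["pattern"],
                    labels=tuple(str(row["label"]).split("|")),
                    level=row["level"],
                    canonical=bool(row["canonical"]),
                )
            )
        return cls(entries=tuple(entries))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pattern": [e.pattern for e in self.entries],
                "label": ["|".join(e.labels) for e in self.entries],
                "level": [e.level for e in self.entries],
                "canonical": [e.canonical for e in self.entries],
            }
        )


def classify_by_pbox(
    pbox: PBox, catalog: PBoxCatalog
) -> tuple[tuple[str, ...], bool]:
    """Match the P-box window against the diagnostic catalogue.

    Patterns match as substrings of the 10-mer window (an exact 10-mer is
    the longest possible match).  The longest matched pattern wins; ties at
    the same length contribute all their candidate labels.  ``typical`` is
    true iff a canonical entry is among the winners.
    """
    window = pbox.sequence
    matched = [e for e in catalog.entries if e.pattern in window]
    if not matched:
        return (), False
    best_len = max(len(e.pattern) for e in matched)
    winners = [e for e in matched if len(e.pattern) == best_len]
    candidates: list[str] = []
    for e in winners:
        for lab in e.labels:
            if lab not in candidates:
                candidates.append(lab)
    typical = any(e.canonical for e in winners)
    return tuple(candidates), typical


@dataclass(frozen=True)
class ReferencePanel:
    """Labelled reference DBDs used for nearest-reference group calls."""

    dbds: tuple[AnchoredDBD, ...]
    labels: Mapping[str, str]  # reference id -> group label

    def __post_init__(self) -> None:
        for d in self.dbds:
            if d.id not in self.labels:
                raise ValueError(f"reference {d.id} has no label")


@dataclass(frozen=True)
class NRClassification:
    record_id: str
    species: str
    architecture: str
    subfamily: str | None
    group: str | None
    divergent: bool
    chc2: bool
    typical_pbox: bool
    pbox10: str
    evidence: tuple[str, ...] = ()
    nearest_reference: str | None = None
    nearest_distance: float | None = None


def nearest_reference(
    query: AnchoredDBD,
    panel: ReferencePanel,
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[str | None, float | None]:
    """Nearest panel reference by anchor-alignment p-distance.

    Deterministic: ties go to the first reference in panel order.
    """
    if not panel.dbds:
        return None, None
    best_id, best_d = None, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ref in panel.dbds:
            aln = anchor_align([query, ref])
            d = float(pairwise_p_distance(aln, config).values[0, 1])
            if best_d is None or d < best_d:
                best_id, best_d = ref.id, d
    return best_id, best_d


def _consistent(group: str, candidates: Sequence[str]) -> bool:
    if not candidates:
        return True
    if group in candidates or group_base(group) in candidates:
        return True
    sub = subfamily_of(group)
    return sub is not None and sub in candidates


def _subfamily_from_candidates(candidates: Sequence[str]) -> str | None:
    subs = {subfamily_of(c) for c in candidates}
    subs.discard(None)
    if len(subs) == 1:
        return subs.pop()
    return None


def assign_group(
    hit: DBDHit,
    sequence: str,
    catalog: PBoxCatalog,
    panel: ReferencePanel,
    config: RunConfig = DEFAULT_CONFIG,
    architecture: str = "single",
    species: str = "",
) -> NRClassification:
    """Classify one DBD hit into subfamily/group with divergence flags."""
    candidates, typical = classify_by_pbox(hit.pbox, catalog)
    evidence: list[str] = []
    if candidates:
        evidence.append("pbox_exact" if len(hit.pbox.sequence) == 10 else "pbox_core")
    if not panel.dbds:
        warnings.warn("empty reference panel: classification by P-box only")
    ref_id, ref_d = nearest_reference(from_hit(hit, sequence), panel, config)
    group: str | None = None
    if ref_id is not None and ref_d is not None and ref_d <= config.distance_threshold:
        ref_group = panel.labels[ref_id]
        if architecture == "2DBD":
            # tandem DBDs are themselves the subfamily diagnostic; the
            # second DBD's P-box (typically an NR1-style box) does not
            # constrain the group here
            if subfamily_of(ref_group) == "2DBD":
                group = ref_group
                evidence.append("nearest_reference")
        elif _consistent(ref_group, candidates):
            group = ref_group
            evidence.append("nearest_reference")
    if group is None and candidates:
        # a group-level catalogue diagnostic alone can pin the group
        group_level = [c for c in candidates if c in GROUP_SUBFAMILY]
        if len(group_level) == 1 and typical:
            group = group_level[0]
            evidence.append("pbox_group")
    subfamily = subfamily_of(group) if group else _subfamily_from_candidates(candidates)
    if architecture == "2DBD":
        subfamily = "2DBD"
    divergent = (not typical) or (group is None and subfamily is None)
    return NRClassification(
        record_id=hit.record_id,
        species=species,
        architecture=architecture,
        subfamily=subfamily,
        group=group,
        divergent=divergent,
        chc2=hit.cii.kind.value == "CII_CHC2",
        typical_pbox=typical,
        pbox10=hit.pbox.sequence,
        evidence=tuple(evidence),
        nearest_reference=ref_id,
        nearest_distance=ref_d,
    )


def classify_record(
    record: ProteinRecord,
    catalog: PBoxCatalog,
    panel: ReferencePanel,
    config: RunConfig = DEFAULT_CONFIG,
) -> NRClassification | None:
    """Gene-level classification: scan, then classify.

    Returns ``None`` when the protein has no full DBD.  For 2DBD genes the
    second (more conserved) DBD carries the group call; the CHC2 flag is
    true if any DBD's CII is the CHC2 variant.
    """
    hits, partial, arch = scan_record(record, config)
    if not hits:
        return None
    chosen = hits[1] if arch.n_dbds == 2 else hits[0]
    cls = assign_group(
        chosen,
        record.sequence,
        catalog,
        panel,
        config,
        architecture=arch.label,
        species=record.species,
    )
    if any(h.cii.kind.value == "CII_CHC2" for h in hits) and not cls.chc2:
        import dataclasses

        cls = dataclasses.replace(cls, chc2=True)
    return cls


def call_complement(
    classifications: Iterable[NRClassification],
    species: str,
) -> dict[str, int]:
    """Per-species ortholog-group counts (Table-style complement row).

    Genes with an assigned group count under it; divergent genes count
    under ``divergent``; typical-but-groupless genes under ``unassigned``.
    2DBD genes count once.  The ``total`` key is the number of distinct
    genes with at least one full DBD.
    """
    counts: dict[str, int] = {}
    seen: set[str] = set()
    for cls in classifications:
        if cls.species and species and cls.species != species:
            raise ValueError(f"{cls.record_id}: species mismatch")
        if cls.record_id in seen:
            raise ValueError(f"duplicate record id {cls.record_id}")
        seen.add(cls.record_id)
        if cls.divergent:
            key = "divergent"
        elif cls.group is not None:
            key = cls.group
        else:
            key = "unassigned"
        counts[key] = counts.get(key, 0) + 1
    counts["total"] = len(seen)
    return counts
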