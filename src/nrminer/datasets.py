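"""Curated fixtures and the synthetic flatworm NR survey.

The genuine survey data (per-species DBD sequences of 33 flatworm species)
live in an external supplementary file; this module ships a *synthetic*
stand-in: per-species ortholog-group rosters transcribed from the survey's
running text and complement table, realised as protein sequences by the
package's own generator.  Group identity is carried by a synthetic
reference panel (one deterministic DBD per ortholog group); every survey
gene is its group's reference plus a few point mutations, parasitic HR96b
genes carry the CHC2 substitution, divergent genes get independent random
DBDs with their documented (a)typical P-boxes, and 2DBD-NR genes carry two
tandem DBDs.  The rosters reproduce the published per-species totals
(15-61 NRs) and group counts; the sequences themselves are synthetic.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from nrminer.classify import GROUP_SUBFAMILY, PBoxCatalog, ReferencePanel
from nrminer.motifs import ProteinRecord
from nrminer.phylo import AnchoredDBD
from nrminer.simulate import SAFE_ALPHABET, build_dbd, mutate
from nrminer.splicing import JunctionCatalog

#: Chelator offsets within the canonical 50-residue generator DBD.
DBD_ANCHORS = (0, 3, 17, 20, 30, 36, 46, 49)
#: Offset of the second CII chelator — the CHC2 substitution site.
CHC2_SITE = 36

#: Canonical P-box (10-mer window) per ortholog group.  NR1-subfamily
#: groups share the typical NR1 box; group identity there is carried by
#: the reference panel, exactly as the classifier is designed to work.
PBOX_OF_GROUP = {
    "TR": "CEGCKGFFRR", "TRb": "CEGCKGFFRR", "E78": "CEGCKGFFRR",
    "HR96a": "CEGCKGFFRR", "HR96b": "CEGCKGFFRR", "HR96c": "CEGCKGFFRR",
    "HR96d": "CEGCKGFFRR", "NR1a": "CEGCKGFFRR", "NR1b": "CEGCKGFFRR",
    "HNF4": "CDGCKVFFKR",
    "RXR1": "CEGCKGFFKR", "RXR2": "CEGCKGFFKR",
    "TR4": "CEGCKGFFKR", "NR4A": "CEGCKGFFKR",
    "TLX": "CEGCKSFFRR", "PNR": "CEGCKTFFKR", "DSF": "CEGCKDFFKR",
    "fax1": "CEGCKEFFRR", "NHR236": "CDGCRGFFKR",
    "CoupTFI": "CEGCKAFFKR", "CoupTFII": "CEGCKAFFKR",
    "ERR": "CEACKAFFRR",
    "FTZF1": "CESCKGFFKR", "HR39": "CESCKGFFKR",
    "GCNF": "CEACKNFFRR",
    "2DBDa": "CEGCKGFFRR", "2DBDb": "CEGCKGFFRR", "2DBDg": "CEGCKGFFRR",
}

#: First-DBD P-box of 2DBD-NRs (their second DBD carries the typical box).
PBOX_2DBD_FIRST = "CEACKKFFRR"

# ---------------------------------------------------------------------------
# Per-lineage gene rosters (counts per fine ortholog group) transcribed
# from the survey's complement statements.  Divergent genes are listed
# separately with their P-boxes.

_ML_ATYPICAL = (
    "CDACKTFFRR", "CEDCRTFFKK", "CGSCKDFFQR", "CNACRVFFTM", "CQGCRDFFSS",
    "CTPCNAFFRL", "CVSCGGFFDE", "CWDCTKFFNI", "CYACQPFFGT", "CIKCNNFFWD",
    "CLTCEDFFMV", "CMNCSRFFAQ", "CFQCDLFFEG", "CRVCAWFFTK", "CSECGIFFPD",
    "CKWCVMFFLN", "CGDCTQFFYS",
)
_MC_ATYPICAL = ("CEACRRFFVS", "CDTCKLFFRG", "CQPCSVFFKD")
#: Typical P-box shared with RXR/TR4/NR4A but fitting no group.
_TYPICAL_DIVERGENT = "CEGCKGFFKR"

_ROSTERS: dict[str, dict[str, int]] = {
    "Ml": {
        "TR": 2, "E78": 2, "HR96a": 4, "HR96b": 4, "HR96c": 4, "HR96d": 4,
        "NR1a": 1, "HNF4": 1, "RXR2": 2, "TR4": 2, "TLX": 1, "PNR": 1,
        "DSF": 1, "fax1": 1, "NHR236": 2, "CoupTFI": 2, "ERR": 4,
        "NR4A": 2, "HR39": 1, "GCNF": 1, "2DBDg": 2,
    },
    "Sme": {
        "TR": 3, "HR96a": 1, "HR96b": 1, "HR96c": 1, "NR1a": 1, "NR1b": 1,
        "HNF4": 1, "RXR2": 2, "TR4": 1, "TLX": 1, "PNR": 1, "DSF": 1,
        "NHR236": 1, "CoupTFI": 2, "NR4A": 2, "FTZF1": 1, "HR39": 1,
        "2DBDa": 2, "2DBDb": 1, "2DBDg": 1,
    },
    "Px": {
        "TR": 1, "E78": 1, "HR96a": 1, "HR96b": 1, "HR96c": 1, "NR1a": 1,
        "NR1b": 1, "HNF4": 1, "RXR1": 1, "RXR2": 1, "TR4": 1, "TLX": 1,
        "PNR": 1, "DSF": 1, "NHR236": 1, "CoupTFI": 1, "CoupTFII": 1,
        "NR4A": 1, "FTZF1": 1, "HR39": 1, "2DBDa": 1, "2DBDb": 1, "2DBDg": 1,
    },
    "Gs": {
        "TR": 1, "E78": 1, "HR96b": 1, "HR96c": 1, "HNF4": 1, "RXR2": 1,
        "TR4": 1, "TLX": 1, "PNR": 1, "DSF": 1, "CoupTFI": 1, "CoupTFII": 1,
        "NR4A": 1, "HR39": 1, "2DBDa": 1, "2DBDb": 1, "2DBDg": 1,
    },
    "Hymenolepididae": {
        "TR": 1, "E78": 1, "HR96a": 1, "HR96b": 1, "HR96c": 1, "NR1b": 1,
        "HNF4": 1, "TR4": 1, "TLX": 1, "NR4A": 1, "HR39": 1,
        "2DBDa": 1, "2DBDb": 1, "2DBDg": 1,
    },
    "Taeniidae": {
        "TR": 1, "E78": 1, "HR96a": 1, "HR96b": 1, "HR96c": 1, "NR1b": 1,
        "HNF4": 1, "TR4": 1, "TLX": 1, "CoupTFI": 1, "NR4A": 1, "FTZF1": 1,
        "HR39": 1, "2DBDa": 1, "2DBDb": 1, "2DBDg": 1,
    },
    "Mesocestoididae": {
        "TR": 2, "E78": 1, "HR96a": 1, "HR96b": 1, "HR96c": 1, "NR1a": 1,
        "NR1b": 1, "HNF4": 1, "TR4": 1, "TLX": 1, "NR4A": 1, "HR39": 1,
        "2DBDa": 1, "2DBDb": 1, "2DBDg": 1,
    },
    "Dl": {
        "TR": 1, "E78": 1, "HR96a": 1, "HR96b": 1, "HR96c": 1, "NR1b": 1,
        "HNF4": 1, "RXR2": 1, "TR4": 1, "TLX": 1, "PNR": 1, "CoupTFI": 1,
        "NR4A": 1, "FTZF1": 1, "HR39": 1, "2DBDa": 1, "2DBDb": 1, "2DBDg": 1,
    },
    "Ss": {
        "TR": 1, "E78": 1, "HR96a": 1, "HR96b": 1, "HR96c": 1, "NR1b": 1,
        "HNF4": 1, "RXR1": 1, "RXR2": 1, "TR4": 1, "TLX": 1, "PNR": 1,
        "CoupTFI": 1, "NR4A": 1, "FTZF1": 1, "HR39": 1,
        "2DBDa": 1, "2DBDb": 1, "2DBDg": 1,
    },
    "Se": {
        "TR": 1, "E78": 1, "HR96a": 1, "HR96b": 1, "HR96c": 1, "NR1a": 1,
        "NR1b": 1, "HNF4": 1, "RXR1": 1, "TR4": 1, "TLX": 1, "PNR": 1,
        "CoupTFI": 1, "NR4A": 1, "FTZF1": 1, "HR39": 1,
        "2DBDa": 1, "2DBDb": 1, "2DBDg": 1,
    },
    "TremNonStrig": {
        "TR": 1, "TRb": 1, "E78": 1, "HR96a": 1, "HR96b": 1, "HR96c": 1,
        "NR1a": 1, "HNF4": 1, "RXR1": 1, "RXR2": 1, "TR4": 1, "TLX": 1,
        "PNR": 1, "DSF": 1, "CoupTFI": 1, "CoupTFII": 1, "NR4A": 1,
        "FTZF1": 1, "HR39": 1, "2DBDa": 1, "2DBDb": 1, "2DBDg": 1,
    },
    "Strigeidida": {
        "TR": 1, "TRb": 1, "E78": 1, "HR96a": 1, "HR96b": 1, "NR1a": 1,
        "HNF4": 1, "RXR1": 1, "RXR2": 1, "TR4": 1, "TLX": 1, "PNR": 1,
        "DSF": 1, "CoupTFI": 1, "CoupTFII": 1, "NR4A": 1, "FTZF1": 1,
        "HR39": 1, "2DBDa": 1, "2DBDb": 1, "2DBDg": 1,
    },
}

#: Divergent genes per lineage key: P-box windows of the atypical (or
#: typical-but-groupless) boxes.
_DIVERGENT: dict[str, tuple[str, ...]] = {
    "Ml": _ML_ATYPICAL,
    "Sme": (_TYPICAL_DIVERGENT,),
    "Gs": ("CEPCKVFFKR",),
    "Hymenolepididae": ("CEACKAFFQQ",),
    "Taeniidae": ("CDSCRAFFEM",),
    "Mesocestoididae": (_TYPICAL_DIVERGENT,) + _MC_ATYPICAL,
    "Dl": ("CEACKSFFKR",),
    "Ss": ("CEACKSFFKR",),
    "Se": ("CEACKSFFKR",),
}

#: Species code -> roster key.
_ROSTER_KEY = {
    "Ml": "Ml", "Sme": "Sme", "Px": "Px", "Gs": "Gs",
    "Hd": "Hymenolepididae", "Hm": "Hymenolepididae", "Hn": "Hymenolepididae",
    "Ec": "Taeniidae", "Eg": "Taeniidae", "Em": "Taeniidae",
    "Ta": "Taeniidae", "Tm": "Taeniidae", "Ts": "Taeniidae",
    "Tso": "Taeniidae", "Ht": "Taeniidae",
    "Mc": "Mesocestoididae",
    "Dl": "Dl", "Ss": "Ss", "Se": "Se",
    "Cs": "TremNonStrig", "Of": "TremNonStrig", "Ov": "TremNonStrig",
    "Eca": "TremNonStrig", "Fh": "TremNonStrig",
    "Sb": "Strigeidida", "Sc": "Strigeidida", "Sh": "Strigeidida",
    "Sj": "Strigeidida", "Sm": "Strigeidida", "Sma": "Strigeidida",
    "Smt": "Strigeidida", "Sr": "Strigeidida", "Tr": "Strigeidida",
}

FREE_LIVING = {"Ml", "Sme"}


def _data_path(name: str) -> Path:
    return Path(resources.files("nrminer") / "data" / name)


def load_species_table() -> pd.DataFrame:
    return pd.read_csv(_data_path("species.tsv"), sep="\t", comment="#")


def load_pbox_catalog(include_extension: bool = True) -> PBoxCatalog:
    frames = [pd.read_csv(_data_path("pbox_catalog.tsv"), sep="\t", comment="#")]
    if include_extension:
        frames.append(
            pd.read_csv(_data_path("pbox_catalog_extension.tsv"), sep="\t", comment="#")
        )
    return PBoxCatalog.from_frame(pd.concat(frames, ignore_index=True))


def load_junction_catalog() -> JunctionCatalog:
    frame = pd.read_csv(_data_path("junction_catalog.tsv"), sep="\t", comment="#")
    return JunctionCatalog(
        entries=tuple(
            (row["group"], int(row["position"]), int(row["phase"]))
            for _, row in frame.iterrows()
        )
    )


def load_class_tree(include_outgroup: bool = True) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(_data_path("class_tree.nwk")),
        schema="newick",
        preserve_underscores=True,
    )
    if not include_outgroup:
        taxa = [t for t in tree.taxon_namespace if t.label == "Outgroup"]
        tree.prune_taxa(taxa)
        # re-root at the flatworm ancestor node
        tree.seed_node.label = "Platy"
    return tree


def load_outgroup_presence() -> pd.Series:
    frame = pd.read_csv(_data_path("outgroup_presence.tsv"), sep="\t", comment="#")
    return pd.Series(
        frame["present"].astype(bool).values, index=frame["group"], name="Outgroup"
    )


def load_ancestral_root_set() -> tuple[str, ...]:
    frame = pd.read_csv(_data_path("ancestral_root_set.tsv"), sep="\t", comment="#")
    return tuple(frame["group"])


def load_curated_events() -> list[dict[str, str]]:
    frame = pd.read_csv(_data_path("fig_events.tsv"), sep="\t", comment="#")
    return frame.to_dict("records")


# ---------------------------------------------------------------------------
# Reference panel and survey construction


def _gene_rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng((seed * 1_000_003 + zlib.crc32(tag.encode())) % 2**31)


@dataclass(frozen=True)
class SurveyTruth:
    records: tuple[ProteinRecord, ...]
    truth: pd.DataFrame  # record_id, species, group, subfamily, chc2, n_dbds


def reference_dbd(group: str, seed: int = 7) -> str:
    """Deterministic synthetic reference DBD for an ortholog group."""
    rng = _gene_rng(seed, f"ref:{group}")
    dbox = "".join(rng.choice(list(SAFE_ALPHABET), size=5))
    return build_dbd(PBOX_OF_GROUP[group], dbox, chc2=False, rng=rng)


def first_dbd_reference(seed: int = 7) -> str:
    rng = _gene_rng(seed, "ref:2DBD-first")
    dbox = "".join(rng.choice(list(SAFE_ALPHABET), size=5))
    return build_dbd(PBOX_2DBD_FIRST, dbox, chc2=False, rng=rng)


def build_reference_panel(seed: int = 7) -> ReferencePanel:
    """Synthetic labelled reference panel: one DBD per ortholog group."""
    dbds = []
    labels = {}
    for group in sorted(GROUP_SUBFAMILY):
        rid = f"ref_{group}"
        dbds.append(
            AnchoredDBD(id=rid, sequence=reference_dbd(group, seed), anchors=DBD_ANCHORS)
        )
        labels[rid] = group
    return ReferencePanel(dbds=tuple(dbds), labels=labels)


def _guard_positions(offset: int) -> set[int]:
    chel = [offset + i for i in DBD_ANCHORS]
    pbox = [offset + i for i in range(17, 27)]
    dbox = [offset + i for i in range(31, 36)]
    return set(chel + pbox + dbox)


def _survey_gene(
    species: str,
    group: str,
    index: int,
    seed: int,
    panel_seed: int = 7,
) -> tuple[ProteinRecord, dict]:
    gene_id = f"{species}_{group}{index + 1}"
    rng = _gene_rng(seed, gene_id)
    flank5 = "".join(rng.choice(list(SAFE_ALPHABET), size=15))
    flank3 = "".join(rng.choice(list(SAFE_ALPHABET), size=20))
    n_mut = 2 + index  # paralogs of one species differ from each other
    is_2dbd = GROUP_SUBFAMILY[group] == "2DBD"
    chc2 = group == "HR96b" and species not in FREE_LIVING
    if is_2dbd:
        first = mutate(
            first_dbd_reference(panel_seed), n_mut, rng, preserve=_guard_positions(0)
        )
        second = mutate(
            reference_dbd(group, panel_seed), n_mut, rng, preserve=_guard_positions(0)
        )
        spacer = "".join(rng.choice(list(SAFE_ALPHABET), size=25))
        seq = flank5 + first + spacer + second + flank3
        n_dbds = 2
    else:
        dbd = mutate(
            reference_dbd(group, panel_seed), n_mut, rng, preserve=_guard_positions(0)
        )
        if chc2:
            dbd = dbd[:CHC2_SITE] + "H" + dbd[CHC2_SITE + 1 :]
        seq = flank5 + dbd + flank3
        n_dbds = 1
    record = ProteinRecord(id=gene_id, species=species, sequence=seq)
    truth = {
        "record_id": gene_id,
        "species": species,
        "group": group,
        "subfamily": GROUP_SUBFAMILY[group],
        "divergent": False,
        "chc2": chc2,
        "n_dbds": n_dbds,
        "pbox10": PBOX_OF_GROUP[group],
    }
    return record, truth


def _divergent_gene(
    species: str, pbox: str, index: int, seed: int
) -> tuple[ProteinRecord, dict]:
    gene_id = f"{species}_div{index + 1}"
    rng = _gene_rng(seed, gene_id)
    dbox = "".join(rng.choice(list(SAFE_ALPHABET), size=5))
    dbd = build_dbd(pbox, dbox, chc2=False, rng=rng)
    flank5 = "".join(rng.choice(list(SAFE_ALPHABET), size=15))
    flank3 = "".join(rng.choice(list(SAFE_ALPHABET), size=20))
    record = ProteinRecord(id=gene_id, species=species, sequence=flank5 + dbd + flank3)
    truth = {
        "record_id": gene_id,
        "species": species,
        "group": "divergent",
        "subfamily": None,
        "divergent": True,
        "chc2": False,
        "n_dbds": 1,
        "pbox10": pbox,
    }
    return record, truth


def build_survey(seed: int = 0) -> SurveyTruth:
    """Realise the full 33-species synthetic survey with ground truth."""
    records: list[ProteinRecord] = []
    rows: list[dict] = []
    species_table = load_species_table()
    for code in species_table["code"]:
        key = _ROSTER_KEY[code]
        roster = _ROSTERS[key]
        for group in sorted(roster):
            for i in range(roster[group]):
                rec, truth = _survey_gene(code, group, i, seed)
                records.append(rec)
                rows.append(truth)
        for i, pbox in enumerate(_DIVERGENT.get(key, ())):
            rec, truth = _divergent_gene(code, pbox, i, seed)
            records.append(rec)
            rows.append(truth)
    return SurveyTruth(records=tuple(records), truth=pd.DataFrame(rows))


def expected_totals() -> dict[str, int]:
    """Published per-species NR totals implied by the rosters."""
    out = {}
    for code, key in _ROSTER_KEY.items():
        out[code] = sum(_ROSTERS[key].values()) + len(_DIVERGENT.get(key, ()))
    return out


def lineage_of(species: str) -> str:
    table = load_species_table()
    return table.set_index("code").loc[species, "lineage"]
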