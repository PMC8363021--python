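"""Zinc-finger scanning and DBD assembly for nuclear receptors.

The NR DNA-binding domain is built from two zinc-finger modules, each
chelating one Zn2+ ion through four residues:

* CI  : ``C-X2-C-X13-C-X2-C`` (21 residues) — carries the P-box, the
  recognition helix element anchored at the third chelating cysteine.
* CII : ``C-X5-C-X9-C-X2-C`` (20 residues) — carries the D-box, the five
  residues between its first two chelators, involved in dimerisation.

A CHC2 variant of CII, in which a histidine replaces the second chelating
cysteine, marks HR96b orthologs of parasitic flatworms and is scanned for
when ``allow_chc2`` is enabled.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from nrminer.config import DEFAULT_CONFIG, RunConfig

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: X is tolerated at spacer positions but never matches a chelator.
ALPHABET = AMINO_ACIDS | {"X"}

CI_LENGTH = 21
CII_LENGTH = 20
#: Offsets of the four chelating residues within each module.
CI_CHELATOR_OFFSETS = (0, 3, 17, 20)
CII_CHELATOR_OFFSETS = (0, 6, 16, 19)


class FingerKind(str, Enum):
    CI = "CI"
    CII_C4 = "CII_C4"
    CII_CHC2 = "CII_CHC2"


class ValidationError(ValueError):
    """Raised for malformed sequence input."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a verbatim accession and a species code."""

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"{self.id}: empty sequence")
        for i, ch in enumerate(self.sequence):
            if ch not in ALPHABET:
                raise ValidationError(
                    f"{self.id}: invalid residue {ch!r} at position {i}"
                )


@dataclass(frozen=True)
class ZincFinger:
    kind: FingerKind
    start: int
    end: int
    chelator_positions: tuple[int, int, int, int]

    def validate(self, sequence: str) -> None:
        """Re-check this finger against its declared pattern by direct
        character and spacing checks."""
        c1, c2, c3, c4 = self.chelator_positions
        if not (c1 < c2 < c3 < c4):
            raise ValidationError("chelators not strictly increasing")
        if self.kind is FingerKind.CI:
            # X-spacings 2, >=2 (13 canonically), 2
            if c2 - c1 != 3 or c4 - c3 != 3 or c3 - c2 < 3:
                raise ValidationError("CI chelator spacing violated")
        else:
            if (c2 - c1, c3 - c2, c4 - c3) != (6, 10, 3):
                raise ValidationError("CII chelator spacing violated")
        if (c1, c4) != (self.start, self.end - 1):
            raise ValidationError("chelators must bound the finger span")
        for i, pos in enumerate(self.chelator_positions):
            if not self.start <= pos < self.end:
                raise ValidationError("chelator outside finger span")
            want = "H" if (self.kind is FingerKind.CII_CHC2 and i == 1) else "C"
            if sequence[pos] != want:
                raise ValidationError(
                    f"position {pos} is {sequence[pos]!r}, expected {want!r}"
                )


@dataclass(frozen=True)
class PBox:
    """P-box window anchored at the third CI chelator (default 10-mer)."""

    sequence: str
    core6: str
    partial: bool = False

    def __post_init__(self) -> None:
        if not self.sequence.startswith(self.core6):
            raise ValidationError("core6 must be a prefix of the P-box window")


@dataclass(frozen=True)
class DBox:
    """The five residues between the first two CII chelators."""

    sequence: str
    chc2: bool

    def __post_init__(self) -> None:
        if len(self.sequence) != 5:
            raise ValidationError("D-box must be 5 residues")


@dataclass(frozen=True)
class DBDHit:
    """One assembled DBD: a CI finger paired with a downstream CII."""

    record_id: str
    ci: ZincFinger
    cii: ZincFinger
    pbox: PBox
    dbox: DBox
    index_in_protein: int = 0

    @property
    def start(self) -> int:
        return self.ci.start

    @property
    def end(self) -> int:
        return self.cii.end

    @property
    def chc2(self) -> bool:
        return self.cii.kind is FingerKind.CII_CHC2

    @property
    def chelator_positions(self) -> tuple[int, ...]:
        return self.ci.chelator_positions + self.cii.chelator_positions


@dataclass(frozen=True)
class Architecture:
    record_id: str
    n_dbds: int

    @property
    def label(self) -> str:
        return {0: "none", 1: "single", 2: "2DBD"}.get(self.n_dbds, "multi")


def _match_ci(seq: str, start: int, inner_min: int, inner_max: int) -> ZincFinger | None:
    n = len(seq)
    if seq[start] != "C":
        return None
    for inner in range(inner_min, inner_max + 1):
        end = start + 8 + inner  # 4 chelators + 2 + inner + 2 spacers
        if end > n:
            continue
        c2 = start + 3
        c3 = c2 + 1 + inner
        c4 = c3 + 3
        if seq[c2] == "C" and seq[c3] == "C" and seq[c4] == "C":
            if "*" not in seq[start:end]:
                return ZincFinger(FingerKind.CI, start, end, (start, c2, c3, c4))
    return None


def _match_cii(seq: str, start: int, allow_chc2: bool) -> list[ZincFinger]:
    out: list[ZincFinger] = []
    end = start + CII_LENGTH
    if end > len(seq) or seq[start] != "C":
        return out
    c2, c3, c4 = start + 6, start + 16, start + 19
    if seq[c3] != "C" or seq[c4] != "C":
        return out
    if "*" in seq[start:end]:
        return out
    chel = (start, c2, c3, c4)
    if seq[c2] == "C":
        out.append(ZincFinger(FingerKind.CII_C4, start, end, chel))
    elif allow_chc2 and seq[c2] == "H":
        out.append(ZincFinger(FingerKind.CII_CHC2, start, end, chel))
    return out


def find_fingers_in(
    seq: str,
    allow_chc2: bool = True,
    config: RunConfig = DEFAULT_CONFIG,
) -> list[ZincFinger]:
    """Scan a raw amino-acid string (stop codons ``*`` simply never match)."""
    fingers: list[ZincFinger] = []
    for start in range(len(seq)):
        ci = _match_ci(seq, start, config.ci_inner_min, config.ci_inner_max)
        if ci is not None:
            fingers.append(ci)
        fingers.extend(_match_cii(seq, start, allow_chc2))
    fingers.sort(key=lambda f: (f.start, f.kind.value))
    return fingers


def find_zinc_fingers(
    record: ProteinRecord,
    allow_chc2: bool = True,
    config: RunConfig = DEFAULT_CONFIG,
) -> list[ZincFinger]:
    """Report every CI / CII zinc-finger module match in the protein.

    All matches at all start positions are reported, including overlapping
    ones; downstream pairing decides usage.  CHC2-variant CII modules are
    reported only when ``allow_chc2`` is true.  Sequence validation happens
    at :class:`ProteinRecord` construction.
    """
    return find_fingers_in(record.sequence, allow_chc2, config)


def extract_pbox(sequence: str, ci: ZincFinger, pbox_len: int = 10) -> PBox:
    """P-box window starting at the third CI chelating cysteine.

    The window is shorter (flagged ``partial``) only when the protein ends
    inside it.
    """
    anchor = ci.chelator_positions[2]
    window = sequence[anchor : anchor + pbox_len]
    return PBox(sequence=window, core6=window[:6], partial=len(window) < pbox_len)


def extract_dbox(sequence: str, cii: ZincFinger) -> DBox:
    """The five residues between the first and second CII chelators."""
    first, second = cii.chelator_positions[0], cii.chelator_positions[1]
    return DBox(
        sequence=sequence[first + 1 : second],
        chc2=cii.kind is FingerKind.CII_CHC2,
    )


def detect_chc2(hit: DBDHit) -> bool:
    """True iff the hit's CII is the CHC2 variant (His at the second chelator)."""
    return hit.cii.kind is FingerKind.CII_CHC2


def assemble_dbds(
    record: ProteinRecord,
    fingers: Sequence[ZincFinger],
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[list[DBDHit], list[ZincFinger], Architecture]:
    """Pair CI fingers with downstream CII fingers into DBDs.

    Greedy left-to-right: each CI takes the nearest downstream CII whose
    linker gap (``cii.start - ci.end``) lies in ``[gap_min, gap_max]``;
    paired fingers are consumed and DBD spans never overlap.  Under the
    window structure induced by the gap bounds this greedy matching attains
    the maximum number of disjoint pairs.  Unpaired fingers are returned
    separately as partial hits.

    Returns ``(hits, partial_fingers, architecture)``.
    """
    cis = [f for f in fingers if f.kind is FingerKind.CI]
    ciis = [f for f in fingers if f.kind is not FingerKind.CI]
    used_cii: set[int] = set()
    hits: list[DBDHit] = []
    cursor = 0  # end of the last assembled DBD span
    used_ci: set[int] = set()
    for i, ci in enumerate(cis):
        if ci.start < cursor:
            continue
        best: tuple[int, int] | None = None  # (cii.start, index)
        for j, cii in enumerate(ciis):
            if j in used_cii or cii.start < ci.end:
                continue
            gap = cii.start - ci.end
            if config.gap_min <= gap <= config.gap_max:
                if best is None or cii.start < best[0]:
                    best = (cii.start, j)
        if best is None:
            continue
        j = best[1]
        cii = ciis[j]
        used_cii.add(j)
        used_ci.add(i)
        hits.append(
            DBDHit(
                record_id=record.id,
                ci=ci,
                cii=cii,
                pbox=extract_pbox(record.sequence, ci, config.pbox_len),
                dbox=extract_dbox(record.sequence, cii),
                index_in_protein=len(hits),
            )
        )
        cursor = cii.end
    partial = [f for i, f in enumerate(cis) if i not in used_ci]
    partial += [f for j, f in enumerate(ciis) if j not in used_cii]
    partial.sort(key=lambda f: (f.start, f.kind.value))
    architecture = Architecture(record_id=record.id, n_dbds=len(hits))
    return hits, partial, architecture


def scan_record(
    record: ProteinRecord,
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[list[DBDHit], list[ZincFinger], Architecture]:
    """Convenience: finger scan followed by DBD assembly."""
    fingers = find_zinc_fingers(record, allow_chc2=config.allow_chc2, config=config)
    return assemble_dbds(record, fingers, config)


def hits_table(
    records: Iterable[ProteinRecord],
    config: RunConfig = DEFAULT_CONFIG,
):
    """Scan many records into a tidy table (one row per DBD hit).

    Returns a pandas DataFrame with record ids preserved verbatim.
    """
    import pandas as pd

    rows = []
    for rec in records:
        hits, partial, arch = scan_record(rec, config)
        for h in hits:
            rows.append(
                {
                    "record_id": rec.id,
                    "species": rec.species,
                    "start": h.start,
                    "end": h.end,
                    "ci_start": h.ci.start,
                    "ci_end": h.ci.end,
                    "cii_start": h.cii.start,
                    "cii_end": h.cii.end,
                    "pbox10": h.pbox.sequence,
                    "core6": h.pbox.core6,
                    "dbox": h.dbox.sequence,
                    "chc2": h.chc2,
                    "index_in_protein": h.index_in_protein,
                    "architecture": arch.label,
                    "n_dbds": arch.n_dbds,
                    "partial_fingers": len(partial),
                }
            )
        if not hits:
            rows.append(
                {
                    "record_id": rec.id,
                    "species": rec.species,
                    "start": -1,
                    "end": -1,
                    "ci_start": -1,
                    "ci_end": -1,
                    "cii_start": -1,
                    "cii_end": -1,
                    "pbox10": "",
                    "core6": "",
                    "dbox": "",
                    "chc2": False,
                    "index_in_protein": -1,
                    "architecture": arch.label,
                    "n_dbds": 0,
                    "partial_fingers": len(partial),
                }
            )
    return pd.DataFrame(rows)
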