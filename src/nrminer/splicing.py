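"""GT-AG splice-aware reconstruction of DBD coding regions.

Spliceosomal introns begin with ``GT`` and end with ``AG``.  Within NR
ortholog groups the intron position inside the DBD (its amino-acid column
and codon phase) is conserved, so a catalogue of known junction positions
plus the GT-AG rule suffices to deduce the DBD peptide from genomic
sequence without a gene model.

The search is anchored: a complete CI finger must be encoded by the first
exon, which holds for the shipped junction catalogue (all catalogued
junctions lie downstream of CI — NR DBD introns interrupt the region
between the P-box and the second finger or CII itself).  From each CI
anchor, donor positions are predicted from the catalogued junctions and
paired with every in-bounds ``AG`` acceptor; surviving candidates must
translate into a full DBD with each intron landing on a catalogued
junction (within tolerance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

from nrminer.config import DEFAULT_CONFIG, RunConfig
from nrminer.motifs import (
    CI_LENGTH,
    DBDHit,
    FingerKind,
    ProteinRecord,
    ValidationError,
    assemble_dbds,
    find_fingers_in,
)

logger = logging.getLogger(__name__)

_CODON = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(nt: str) -> str:
    """Simple standard-code translation; stops appear as ``*``, codons with
    N as ``X``."""
    out = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        out.append(_CODON.get(codon, "X"))
    return "".join(out)


@dataclass(frozen=True)
class JunctionCatalog:
    """Conserved DBD intron junctions: (group, amino-acid column, phase)."""

    entries: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for group, pos, phase in self.entries:
            if phase not in (0, 1, 2):
                raise ValueError(f"{group}: phase must be 0/1/2")
            if pos < 0:
                raise ValueError(f"{group}: negative junction position")

    @property
    def positions(self) -> list[tuple[int, int]]:
        """Distinct (column, phase) pairs across all groups."""
        seen = []
        for _, pos, phase in self.entries:
            if (pos, phase) not in seen:
                seen.append((pos, phase))
        return seen

    def for_group(self, group: str) -> list[tuple[int, int]]:
        return [(p, ph) for g, p, ph in self.entries if g == group]


@dataclass(frozen=True)
class SplicedDBD:
    source_id: str
    frame: int
    exon_spans: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int, int, int], ...]
    # (donor_start, acceptor_end, dbd_relative_position, phase)
    translation: str
    dbd_start_aa: int
    dbd_end_aa: int
    dbd_hit: DBDHit
    junction_deviation: int = 0

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    @property
    def dbd_sequence(self) -> str:
        return self.translation[self.dbd_start_aa : self.dbd_end_aa]


def _revcomp(nt: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(nt))


def _scan_translation(source_id: str, protein: str, config: RunConfig):
    """Find DBD hits in a raw translation (may contain stops)."""
    fingers = find_fingers_in(protein, allow_chc2=config.allow_chc2, config=config)
    rec = _RawRecord(source_id, protein)
    hits, _, _ = assemble_dbds(rec, fingers, config)
    return hits


class _RawRecord:
    """Duck-typed stand-in for ProteinRecord during frame scanning (skips
    alphabet validation so stop codons are tolerated)."""

    def __init__(self, rid: str, sequence: str):
        self.id = rid
        self.species = ""
        self.sequence = sequence


def reconstruct_dbd(
    genomic: str,
    catalog: JunctionCatalog,
    max_introns: int = 2,
    config: RunConfig = DEFAULT_CONFIG,
    source_id: str = "genomic",
) -> list[SplicedDBD]:
    """Enumerate candidate DBD splicings of a genomic sequence.

    Candidates carry 0..``max_introns`` introns, every intron starts GT and
    ends AG with a length inside the configured bounds, and every intron
    lands on a catalogued junction position within ``junction_tolerance``
    columns; candidate DBDs containing stop codons are rejected outright.
    Results are sorted by (smallest total deviation from catalogued
    junctions, fewest introns, longest DBD, coordinates) so the consistent
    parsimonious splicing ranks first.
    """
    genomic = genomic.upper()
    if any(b not in "ACGTN" for b in genomic):
        raise ValidationError("genomic sequence must be A/C/G/T/N")
    if max_introns > 2:
        raise ValueError("at most two introns are supported")
    if len(genomic) < (CI_LENGTH + 29) * 3:
        logger.warning("%s: sequence shorter than a DBD coding region", source_id)
        return []
    strands = [("+", genomic)]
    if config.six_frame:
        strands.append(("-", _revcomp(genomic)))
    results: list[SplicedDBD] = []
    for strand, seq in strands:
        window = seq[: config.splice_window]
        results.extend(_reconstruct_strand(window, catalog, max_introns, config, source_id))
    results.sort(
        key=lambda r: (
            r.junction_deviation,
            r.n_introns,
            -(r.dbd_end_aa - r.dbd_start_aa),
            r.frame,
            r.exon_spans,
        )
    )
    return results


def _reconstruct_strand(
    seq: str,
    catalog: JunctionCatalog,
    max_introns: int,
    config: RunConfig,
    source_id: str,
) -> list[SplicedDBD]:
    out: list[SplicedDBD] = []
    acceptors = [i for i in range(2, len(seq)) if seq[i - 2 : i] == "AG"]

    # 0 introns: plain frame translation scanning
    for frame in range(3):
        protein = translate(seq[frame:])
        for hit in _scan_translation(source_id, protein, config):
            if "*" in protein[hit.start : hit.end]:
                continue
            out.append(
                SplicedDBD(
                    source_id=source_id,
                    frame=frame,
                    exon_spans=((0, len(seq)),),
                    introns=(),
                    translation=protein,
                    dbd_start_aa=hit.start,
                    dbd_end_aa=hit.end,
                    dbd_hit=hit,
                )
            )
    if max_introns == 0:
        return out

    tol = config.junction_tolerance
    junctions = catalog.positions
    for frame in range(3):
        protein = translate(seq[frame:])
        cis = [
            f for f in find_fingers_in(protein, config.allow_chc2, config)
            if f.kind is FingerKind.CI
        ]
        for ci in cis:
            dbd_nt = frame + 3 * ci.start
            out.extend(
                _splice_from_anchor(
                    seq, frame, dbd_nt, ci.start, junctions, acceptors,
                    max_introns, tol, config, source_id,
                )
            )
    # dedupe identical candidate splicings found from different anchors
    seen = set()
    unique = []
    for r in out:
        key = (r.frame, r.exon_spans, r.introns, r.dbd_start_aa)
        if key not in seen:
            seen.add(key)
            unique.append(r)
    return unique


def _splice_from_anchor(
    seq: str,
    frame: int,
    dbd_nt: int,
    dbd_aa: int,
    junctions: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    max_introns: int,
    tol: int,
    config: RunConfig,
    source_id: str,
) -> list[SplicedDBD]:
    """Try splicings whose first exon starts with the CI anchored at
    ``dbd_nt`` (genomic coordinates) / ``dbd_aa`` (frame translation)."""
    import bisect

    results: list[SplicedDBD] = []
    lo, hi = config.intron_min_len, config.intron_max_len
    cap = config.max_acceptors_per_donor

    def acceptor_range(donor: int) -> Sequence[int]:
        """Nearest in-bounds acceptors for a donor, capped deterministically."""
        left = bisect.bisect_left(acceptors, donor + lo)
        right = bisect.bisect_right(acceptors, donor + hi)
        return acceptors[left : min(right, left + cap)]

    def donor_sites(rel_base: int) -> list[tuple[int, int, int]]:
        """Candidate (donor_pos, column, phase) near catalogued junctions.

        ``rel_base`` is the genomic position of DBD column 0 for the
        current (possibly already once-spliced) coordinate system.
        """
        sites = []
        for pos, phase in junctions:
            for dpos in range(pos - tol, pos + tol + 1):
                if dpos <= 0:
                    continue
                donor = rel_base + 3 * dpos + phase
                sites.append((donor, dpos, phase))
        return sites

    for donor1, col1, phase1 in donor_sites(dbd_nt):
        if donor1 + 2 > len(seq) or seq[donor1 : donor1 + 2] != "GT":
            continue
        for acc1 in acceptor_range(donor1):
            spliced1 = seq[:donor1] + seq[acc1:]
            cand = _finish_candidate(
                seq, spliced1, frame, dbd_nt, dbd_aa,
                [(donor1, acc1, col1, phase1)], junctions, config, source_id,
            )
            if cand is not None:
                results.append(cand)
            if max_introns >= 2:
                shift1 = acc1 - donor1
                for donor2s, col2, phase2 in donor_sites(dbd_nt):
                    if col2 <= col1:
                        continue
                    donor2 = donor2s + shift1  # back to genomic coordinates
                    if donor2 <= acc1 or donor2 + 2 > len(seq):
                        continue
                    if seq[donor2 : donor2 + 2] != "GT":
                        continue
                    for acc2 in acceptor_range(donor2):
                        spliced2 = seq[:donor1] + seq[acc1:donor2] + seq[acc2:]
                        cand = _finish_candidate(
                            seq, spliced2, frame, dbd_nt, dbd_aa,
                            [
                                (donor1, acc1, col1, phase1),
                                (donor2, acc2, col2, phase2),
                            ],
                            junctions, config, source_id,
                        )
                        if cand is not None:
                            results.append(cand)
    return results


def _finish_candidate(
    seq: str,
    spliced: str,
    frame: int,
    dbd_nt: int,
    dbd_aa: int,
    introns: list[tuple[int, int, int, int]],
    junctions: Sequence[tuple[int, int]],
    config: RunConfig,
    source_id: str,
) -> SplicedDBD | None:
    # fast local check first: translate only the region around the anchored
    # DBD; the vast majority of donor/acceptor combinations die here
    local_off = max(0, dbd_aa - 1)
    local_nt = spliced[frame + 3 * local_off : frame + 3 * (dbd_aa + 90)]
    local_hits = _scan_translation(source_id, translate(local_nt), config)
    if not any(h.start == dbd_aa - local_off for h in local_hits):
        return None
    protein = translate(spliced[frame:])
    hits = _scan_translation(source_id, protein, config)
    target = None
    for hit in hits:
        if hit.start == dbd_aa:
            target = hit
            break
    if target is None:
        return None
    if "*" in protein[target.start : target.end]:
        return None
    # every intron must fall strictly inside the DBD span
    deviation = 0
    for _, _, col, phase in introns:
        if not 0 < col < (target.end - target.start):
            return None
        deviation += min(
            abs(col - p) for p, ph in junctions if ph == phase
        )
    exons = []
    prev = 0
    for donor, acc, _, _ in introns:
        exons.append((prev, donor))
        prev = acc
    exons.append((prev, len(seq)))
    return SplicedDBD(
        source_id=source_id,
        frame=frame,
        exon_spans=tuple(exons),
        introns=tuple(introns),
        translation=protein,
        dbd_start_aa=target.start,
        dbd_end_aa=target.end,
        dbd_hit=target,
        junction_deviation=deviation,
    )


# ---------------------------------------------------------------------------
# Intron-position consistency across groups


@dataclass(frozen=True)
class IntronAnnotation:
    gene_id: str
    positions: tuple[tuple[int, int], ...]  # (dbd column, phase)


@dataclass(frozen=True)
class ConsistencyReport:
    consensus: dict[str, tuple[tuple[int, int], ...]]
    deviants: dict[str, tuple[str, ...]]
    shared_between_groups: tuple[tuple[str, str], ...]

    @property
    def consistent(self) -> bool:
        return not any(self.deviants.values()) and not self.shared_between_groups


def check_intron_consistency(
    annotations: Sequence[IntronAnnotation],
    grouping: dict[str, str],
) -> ConsistencyReport:
    """Within each group the DBD intron positions should agree; between
    groups they should differ.

    The consensus per group is the most common position multiset (ties:
    lexicographically smallest); members deviating from it are listed, and
    any two groups sharing an identical consensus are reported.
    """
    from collections import Counter, defaultdict

    by_group: dict[str, list[IntronAnnotation]] = defaultdict(list)
    for ann in annotations:
        if ann.gene_id not in grouping:
            raise ValueError(f"{ann.gene_id} missing from grouping")
        by_group[grouping[ann.gene_id]].append(ann)
    consensus: dict[str, tuple[tuple[int, int], ...]] = {}
    deviants: dict[str, tuple[str, ...]] = {}
    for group in sorted(by_group):
        members = by_group[group]
        counts = Counter(tuple(sorted(m.positions)) for m in members)
        top = max(counts.values())
        cons = sorted(k for k, v in counts.items() if v == top)[0]
        consensus[group] = cons
        deviants[group] = tuple(
            m.gene_id for m in members if tuple(sorted(m.positions)) != cons
        )
    shared = []
    groups = sorted(consensus)
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            if consensus[g1] == consensus[g2]:
                shared.append((g1, g2))
    return ConsistencyReport(
        consensus=consensus,
        deviants=deviants,
        shared_between_groups=tuple(shared),
    )
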