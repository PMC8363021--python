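"""Synthetic data with ground truth for every pipeline stage.

Three generators:

* proteins carrying 0, 1 or 2 DBDs with chosen P-box / D-box content and an
  optional CHC2 substitution, embedded in decoy flanks that are verified
  pattern-free by an independent regex matcher;
* genomic loci: back-translated DBD coding sequence with up to two GT..AG
  introns inserted at chosen junction positions (or deliberately violating
  dinucleotides);
* presence/absence histories: single-gain / multiple-loss evolution of
  ortholog groups on a known species tree, with a replayable event log.

All generators are deterministic under a fixed seed.  Spacer and flank
residues are drawn from an alphabet without C or H so that no spurious
chelator can arise outside the designed fingers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from nrminer.config import DEFAULT_CONFIG, RunConfig
from nrminer.evolution import label_nodes, node_label
from nrminer.motifs import ProteinRecord

#: Residues safe for spacers/flanks: cannot complete a chelator set.
SAFE_ALPHABET = "ADEFGIKLMNPQRSTVWY"

#: Independent decoy verifier — regex-based, deliberately separate from the
#: production scanner to avoid circularity in sensitivity/specificity tests.
_PATTERNS = (
    re.compile(r"(?=C.{2}C.{13}C.{2}C)"),
    re.compile(r"(?=C.{5}C.{9}C.{2}C)"),
    re.compile(r"(?=C.{5}H.{9}C.{2}C)"),
)


def contains_finger_pattern(seq: str) -> bool:
    """Minimal independent matcher for any of the three finger patterns."""
    return any(p.search(seq) for p in _PATTERNS)


class UnrealizableSpec(ValueError):
    """The requested protein/locus cannot satisfy the motif patterns."""


@dataclass(frozen=True)
class ProteinSpec:
    """Blueprint for one synthetic NR-like protein.

    ``pbox`` is the 10-mer window anchored at the third CI chelator; its
    first and fourth residues are themselves the last two CI chelating
    cysteines, so both must be ``C``.
    """

    n_dbds: int = 1
    pbox: str = "CEGCKGFFRR"
    dbox: str = "PATNQ"
    chc2: bool = False
    n_flank: int = 20
    c_flank: int = 25
    dbd_spacer: int = 30
    mutations: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_dbds <= 2:
            raise UnrealizableSpec("n_dbds must be 0..2")
        if self.n_dbds:
            if len(self.pbox) != 10 or self.pbox[0] != "C" or self.pbox[3] != "C":
                raise UnrealizableSpec(
                    "pbox must be a 10-mer with C at positions 0 and 3 "
                    "(they are CI chelators)"
                )
            if "C" in self.pbox[1:3] + self.pbox[4:] or "H" in self.pbox[1:3]:
                raise UnrealizableSpec("stray chelator residue inside the P-box")
            if len(self.dbox) != 5 or "C" in self.dbox:
                raise UnrealizableSpec("dbox must be 5 residues without C")


def _draw(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(SAFE_ALPHABET), size=n))


def build_dbd(
    pbox: str,
    dbox: str,
    chc2: bool,
    rng: np.random.Generator,
) -> str:
    """One 50-residue DBD: CI (21) + 9-residue linker + CII (20).

    The P-box occupies positions 17-26 (third CI chelator onward), so its
    tail supplies the first six linker residues.
    """
    x13 = _draw(rng, 13)
    ci_and_pbox = "C" + _draw(rng, 2) + "C" + x13 + pbox  # 4 + 13 + 10 = 27
    linker_tail = _draw(rng, 3)
    second = "H" if chc2 else "C"
    cii = "C" + dbox + second + _draw(rng, 9) + "C" + _draw(rng, 2) + "C"
    return ci_and_pbox + linker_tail + cii


def mutate(
    sequence: str,
    n_mutations: int,
    rng: np.random.Generator,
    preserve: frozenset[int] | set[int] = frozenset(),
) -> str:
    """Apply point substitutions, avoiding ``preserve`` positions.

    Substitutions are drawn from the safe alphabet, so chelators are never
    created; they are never destroyed either unless their positions are
    left out of ``preserve``.
    """
    free = [i for i in range(len(sequence)) if i not in preserve]
    if n_mutations > len(free):
        raise UnrealizableSpec("more mutations requested than mutable positions")
    seq = list(sequence)
    sites = rng.choice(free, size=n_mutations, replace=False) if n_mutations else []
    for i in sites:
        choices = [a for a in SAFE_ALPHABET if a != seq[i]]
        seq[i] = choices[int(rng.integers(len(choices)))]
    return "".join(seq)


def dbd_guard_positions(offset: int = 0) -> set[int]:
    """Positions inside one 50-mer DBD that carry motif identity: the eight
    chelators, the P-box window and the D-box."""
    chel = [0, 3, 17, 20, 30, 36, 46, 49]
    pbox = list(range(17, 27))
    dbox = list(range(31, 36))
    return {offset + i for i in chel + pbox + dbox}


def generate_protein(
    spec: ProteinSpec,
    seed: int,
    record_id: str = "synthetic",
    species: str = "Syn",
) -> tuple[ProteinRecord, dict]:
    """Realise a spec into a protein record plus a ground-truth row."""
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    truth_dbds: list[dict] = []
    flank = _draw(rng, spec.n_flank)
    parts.append(flank)
    pos = len(flank)
    guard: set[int] = set()
    for k in range(spec.n_dbds):
        dbd = build_dbd(spec.pbox, spec.dbox, spec.chc2, rng)
        truth_dbds.append(
            {
                "start": pos,
                "end": pos + len(dbd),
                "pbox10": spec.pbox,
                "core6": spec.pbox[:6],
                "dbox": spec.dbox,
                "chc2": spec.chc2,
                "chelators": [pos + i for i in (0, 3, 17, 20, 30, 36, 46, 49)],
            }
        )
        guard |= dbd_guard_positions(pos)
        parts.append(dbd)
        pos += len(dbd)
        if k + 1 < spec.n_dbds:
            spacer = _draw(rng, spec.dbd_spacer)
            parts.append(spacer)
            pos += len(spacer)
    cflank = _draw(rng, spec.c_flank)
    parts.append(cflank)
    sequence = "".join(parts)
    if spec.n_dbds == 0 and contains_finger_pattern(sequence):
        raise UnrealizableSpec("decoy sequence accidentally matches a finger pattern")
    if spec.mutations:
        # guard also the remaining chelators (already in guard) — mutations
        # land in spacers/flanks only.
        sequence = mutate(sequence, spec.mutations, rng, preserve=guard)
    record = ProteinRecord(id=record_id, species=species, sequence=sequence)
    truth = {
        "record_id": record_id,
        "species": species,
        "n_dbds": spec.n_dbds,
        "architecture": {0: "none", 1: "single", 2: "2DBD"}[spec.n_dbds],
        "dbds": truth_dbds,
    }
    return record, truth


# ---------------------------------------------------------------------------
# Genomic loci

#: Fixed back-translation table: one codon per amino acid, chosen once for
#: reproducibility (alphabetically first codon of each residue).
BACK_TABLE = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC", "G": "GGA",
    "H": "CAC", "I": "ATA", "K": "AAA", "L": "CTA", "M": "ATG", "N": "AAC",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "AGC", "T": "ACA", "V": "GTA",
    "W": "TGG", "Y": "TAC",
}


def back_translate(protein: str) -> str:
    try:
        return "".join(BACK_TABLE[a] for a in protein)
    except KeyError as exc:  # pragma: no cover - guarded by specs
        raise UnrealizableSpec(f"cannot back-translate residue {exc}") from exc


@dataclass(frozen=True)
class IntronSpec:
    """One intron to insert: junction at amino-acid column ``position``
    (0-based, relative to the DBD start) with the given codon phase."""

    position: int
    phase: int = 0
    length: int = 60
    donor: str = "GT"
    acceptor: str = "AG"

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise UnrealizableSpec("phase must be 0, 1 or 2")
        if self.length < 8:
            raise UnrealizableSpec("intron too short to carry its dinucleotides")


def _intron_body(n: int, rng: np.random.Generator) -> str:
    """Synthetic intron interior: G-free with a stop codon every five bases.

    No G means no internal GT/AG dinucleotide, so the designed donor and
    acceptor are the only splice sites the reconstructor can use; TAA at a
    period coprime to 3 disrupts every reading frame within 15 nt.  Real
    introns are messier — this keeps the designed splicing uniquely
    identifiable, which is what generator round-trip tests require.
    """
    body = list("".join(rng.choice(list("ACT"), size=n)))
    for off in range(0, n, 5):
        body[off : off + 3] = list("TAA"[: min(3, n - off)])
    return "".join(body)


@dataclass(frozen=True)
class LocusSpec:
    protein: ProteinSpec = field(default_factory=ProteinSpec)
    introns: tuple[IntronSpec, ...] = ()

    def __post_init__(self) -> None:
        if len(self.introns) > 2:
            raise UnrealizableSpec("at most two introns are supported")
        positions = [i.position for i in self.introns]
        if positions != sorted(positions):
            raise UnrealizableSpec("introns must be ordered by position")


def generate_locus(
    spec: LocusSpec,
    seed: int,
    locus_id: str = "locus",
) -> tuple[tuple[str, str], dict]:
    """Build a genomic locus carrying the spec'd DBD coding region.

    Returns ``((locus_id, nucleotide_sequence), truth)`` where the truth
    carries the uninterrupted translation, the DBD coordinates within it,
    and exact exon/intron coordinates on the genomic sequence.
    """
    rng = np.random.default_rng(seed)
    protein_rec, ptruth = generate_protein(
        spec.protein, seed=int(rng.integers(2**31 - 1)), record_id=locus_id
    )
    if spec.protein.n_dbds != 1:
        raise UnrealizableSpec("locus generation models single-DBD coding regions")
    protein = protein_rec.sequence
    dbd_start_aa = ptruth["dbds"][0]["start"]
    coding = back_translate(protein)
    # insertion points in coding coordinates, right-to-left so earlier
    # coordinates stay valid
    introns_nt: list[tuple[int, IntronSpec, str]] = []
    for ispec in spec.introns:
        point = (dbd_start_aa + ispec.position) * 3 + ispec.phase
        if not 0 < point < len(coding):
            raise UnrealizableSpec("intron insertion point outside coding region")
        intron = ispec.donor + _intron_body(ispec.length - 4, rng) + ispec.acceptor
        introns_nt.append((point, ispec, intron))
    genomic = coding
    truth_introns = []
    offset = 0
    exon_bounds = [0]
    for point, ispec, intron in introns_nt:
        gpoint = point + offset
        genomic = genomic[:gpoint] + intron + genomic[gpoint:]
        truth_introns.append(
            {
                "donor_start": gpoint,
                "acceptor_end": gpoint + len(intron),
                "dbd_relative_position": ispec.position,
                "phase": ispec.phase,
            }
        )
        exon_bounds.append(gpoint)
        offset += len(intron)
    exons = []
    prev = 0
    for t in truth_introns:
        exons.append((prev, t["donor_start"]))
        prev = t["acceptor_end"]
    exons.append((prev, len(genomic)))
    truth = {
        "locus_id": locus_id,
        "translation": protein,
        "dbd_start_aa": dbd_start_aa,
        "dbd_end_aa": ptruth["dbds"][0]["end"],
        "exons": exons,
        "introns": truth_introns,
        "protein_truth": ptruth,
    }
    return (locus_id, genomic), truth


# ---------------------------------------------------------------------------
# Gain/loss histories


@dataclass(frozen=True)
class HistorySpec:
    """Single-gain / multiple-loss evolution on a known rooted tree."""

    tree_newick: str
    root_groups: tuple[str, ...]
    loss_probability: float = 0.1
    gains: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    # gains: child-node label -> groups gained on the edge above it

    def __post_init__(self) -> None:
        if not 0.0 <= self.loss_probability <= 1.0:
            raise UnrealizableSpec("loss probability must lie in [0, 1]")


def simulate_history(spec: HistorySpec, seed: int) -> tuple[dict[str, set[str]], list[dict]]:
    """Evolve group presence down the tree.

    Each group is gained once (at the root, or on the edge named in
    ``spec.gains``) and is then lost independently on every descendant edge
    with ``loss_probability``.  Returns per-leaf presence sets and an event
    log with rows ``{"edge": child_label, "event": "gain"|"loss",
    "group": g}`` sufficient to replay the history.
    """
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree.get(data=spec.tree_newick, schema="newick",
                             preserve_underscores=True)
    label_nodes(tree)
    events: list[dict] = []
    presence: dict[str, set[str]] = {}

    def descend(node, state: set[str]) -> None:
        state = set(state)
        label = node_label(node)
        for g in spec.gains.get(label, ()):  # gains apply on the edge above node
            if g not in state:
                state.add(g)
                events.append({"edge": label, "event": "gain", "group": g})
        if node.parent_node is not None:
            for g in sorted(state):
                if rng.random() < spec.loss_probability:
                    state.discard(g)
                    events.append({"edge": label, "event": "loss", "group": g})
        if node.is_leaf():
            presence[label] = state
        for child in node.child_nodes():
            descend(child, state)

    root_state = set(spec.root_groups)
    descend(tree.seed_node, root_state)
    return presence, events
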