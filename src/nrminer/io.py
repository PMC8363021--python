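"""Readers and writers: FASTA (Biopython), TSV (pandas), Newick (dendropy).

FASTA identifiers are preserved verbatim; TSV outputs carry a commented
provenance header with the configuration digest.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from nrminer import __version__
from nrminer.config import RunConfig
from nrminer.motifs import ProteinRecord, ValidationError


def read_fasta(path: str | Path, species_from_id: bool = True) -> list[ProteinRecord]:
    """Read protein FASTA into :class:`ProteinRecord` objects.

    The species code is taken as the prefix of the identifier up to the
    first underscore (e.g. ``Sm_TRa`` -> ``Sm``) when ``species_from_id``
    is set, else left empty.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        species = rec.id.split("_", 1)[0] if species_from_id else ""
        records.append(
            ProteinRecord(id=rec.id, species=species, sequence=str(rec.seq).upper())
        )
    return records


def read_nucleotide_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read nucleotide FASTA as ``(id, sequence)`` pairs (uppercased)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper()))
    return out


def write_fasta(records: Iterable[ProteinRecord | tuple[str, str]], path: str | Path) -> None:
    seqrecords = []
    for rec in records:
        if isinstance(rec, ProteinRecord):
            rid, seq = rec.id, rec.sequence
        else:
            rid, seq = rec
        seqrecords.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seqrecords, str(path), "fasta")


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def write_tsv(
    frame: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    inputs: Sequence[str | Path] = (),
) -> None:
    """Write a TSV with a single commented provenance header block."""
    lines = [f"# nrminer {__version__}"]
    if config is not None:
        lines.append(f"# config_digest={config.digest()}")
    for inp in inputs:
        lines.append(f"# input {Path(inp).name} sha256:{file_digest(inp)}")
    header = "\n".join(lines) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_newick(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True)
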