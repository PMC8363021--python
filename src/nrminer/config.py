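"""Run configuration shared across the pipeline stages."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the pipeline, serialisable for provenance headers.

    Attributes
    ----------
    gap_min, gap_max
        Allowed residue gap between the end of the first zinc finger (CI)
        and the start of the second (CII) when pairing fingers into a DBD.
        The canonical NR DBD linker is ~10-15 residues; the wide default
        also covers HR96b-style DBDs with extra sequence between the P-box
        and D-box regions.
    allow_chc2
        Report the CHC2 variant of CII (second chelating Cys replaced by
        His) in addition to the canonical C4 fingers.
    ci_inner_min, ci_inner_max
        Spacing range for CI's inner X-run. The canonical pattern is
        exactly 13 (C-X2-C-X13-C-X2-C); widening is off by default.
    intron_min_len, intron_max_len
        Accepted spliceosomal intron lengths (nt) during DBD reconstruction.
    junction_tolerance
        Amino-acid slack (columns) when matching an intron to a catalogued
        conserved junction position.
    splice_window
        Maximum nucleotide span scanned for donor/acceptor candidates.
    max_acceptors_per_donor
        Deterministic candidate cap: for each predicted donor only the
        nearest in-bounds acceptors (smallest intron first) are tried.
    six_frame
        Also search the reverse complement during reconstruction.
    pbox_len
        P-box window length anchored at the third CI chelator.
    distance_threshold
        Maximum anchor-alignment p-distance for nearest-reference group
        assignment.
    min_comparable_columns
        Pairs sharing fewer gap-free columns than this get p-distance 1.0.
    count_partial_hits
        Include unpaired single fingers in complement totals (off: a gene
        needs at least one full CI+CII DBD to be counted).
    """

    gap_min: int = 6
    gap_max: int = 40
    allow_chc2: bool = True
    ci_inner_min: int = 13
    ci_inner_max: int = 13
    intron_min_len: int = 30
    intron_max_len: int = 20000
    junction_tolerance: int = 1
    splice_window: int = 25000
    max_acceptors_per_donor: int = 40
    six_frame: bool = False
    pbox_len: int = 10
    distance_threshold: float = 0.35
    min_comparable_columns: int = 20
    count_partial_hits: bool = False

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, embedded in output headers."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


DEFAULT_CONFIG = RunConfig()
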