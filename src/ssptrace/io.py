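"""Sequence I/O, run configuration and logging.

All coordinates in this package are 1-based inclusive, the way motif
positions are written in the plant-peptide literature; converters to
0-based Python slices are internal to each function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("ssptrace")

#: the 20 standard residues plus X (unknown), the only letters accepted in
#: unaligned input.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")
GAP = "-"

GROUPS = ("land_plant", "protist", "unassigned")

#: id-prefix convention used to tag group membership inside aligned FASTA
#: ("LP|at_CLE1" is a land-plant reference row, "PR|tsar_17" a protistan
#: candidate row).
DEFAULT_GROUP_PREFIXES: Mapping[str, str] = {"LP|": "land_plant", "PR|": "protist"}


class SeqIOError(ValueError):
    """Raised for malformed sequence input (bad residue, duplicate id, ...)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: id, amino-acid sequence and lineage/group metadata.

    The universal currency of the pipeline.  ``lineage`` is a free-form
    supergroup label (e.g. "TSAR", "Amoebozoa"); ``group`` says which side
    of the land-plant / protist divide the record sits on and is carried as
    metadata from the input, never inferred from taxonomy.
    """

    id: str
    seq: str
    lineage: str = ""
    group: str = "unassigned"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SeqIOError(f"unknown group {self.group!r} for {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignedBlock:
    """A gapped multiple alignment: equal-width rows of ProteinRecord."""

    records: tuple[ProteinRecord, ...]
    width: int

    def __post_init__(self) -> None:
        for r in self.records:
            if len(r.seq) != self.width:
                raise SeqIOError(
                    f"aligned row {r.id!r} has length {len(r.seq)}, "
                    f"expected {self.width}"
                )

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col`` (gaps included)."""
        return "".join(r.seq[col - 1] for r in self.records)


@dataclass
class RunConfig:
    """Thresholds, paths and the root RNG seed for a pipeline run.

    Defaults mirror the screening protocol: motif hits are kept at coverage
    and similarity >= 0.5 (both inclusive); the profile-rescoring stage is
    deliberately permissive (empirical p <= 0.5, the shuffle-null analogue
    of an HMMER e-value <= 10); receptor domain searches use an approximate
    e-value cutoff of 1e-5.
    """

    coverage_min: float = 0.5
    similarity_min: float = 0.5
    profile_p_max: float = 0.5
    profile_evalue_max: float = 10.0
    profile_null_draws: int = 1000
    rlk_evalue_max: float = 1e-5
    cterm_min: float = 0.6
    sp_region: int = 30  # residues at the N-terminus where TM/SP overlap is forgiven
    rng_seed: int = 0
    vascular_labels: tuple[str, ...] = ()
    blacklist: tuple[str, ...] = (
        "ribosomal protein",
        "histone",
        "tubulin",
        "actin",
        "heat shock protein",
        "ubiquitin",
    )
    out_dir: str = "ssptrace_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("coverage_min", "similarity_min", "profile_p_max", "cterm_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.rlk_evalue_max <= 0:
            raise ValueError("rlk_evalue_max must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("vascular_labels", "blacklist"):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        return cls(**known)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def log_stage(stage: str, n_in: int, n_out: int, **thresholds) -> None:
    """Every filtering stage logs its survival counts and active thresholds."""
    th = " ".join(f"{k}={v}" for k, v in thresholds.items())
    log.info("stage=%s in=%d out=%d %s", stage, n_in, n_out, th)


# ---------------------------------------------------------------------------
# FASTA

def _validate_seq(rec_id: str, seq: str, allow_gaps: bool) -> str:
    seq = seq.upper()
    ok = ALPHABET | {GAP} if allow_gaps else ALPHABET
    for pos, ch in enumerate(seq, start=1):
        if ch not in ok:
            raise SeqIOError(
                f"illegal residue {ch!r} at position {pos} of record {rec_id!r}"
            )
    if not seq:
        raise SeqIOError(f"record {rec_id!r} has an empty sequence")
    return seq


def read_fasta(
    path: str | Path,
    lineage_label: str = "",
    group_label: str = "unassigned",
) -> list[ProteinRecord]:
    """Read unaligned protein FASTA into ProteinRecord objects.

    Sequences are upper-cased and validated against the 20-letter alphabet
    (plus X).  Gaps are rejected here; use :func:`read_alignment` for
    aligned input.  Duplicate ids raise.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise SeqIOError(f"duplicate id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = _validate_seq(entry.id, str(entry.seq), allow_gaps=False)
        records.append(
            ProteinRecord(id=entry.id, seq=seq, lineage=lineage_label, group=group_label)
        )
    if not records:
        raise SeqIOError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, wrap: int = 60) -> None:
    entries = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(entries)


def _group_from_id(rec_id: str, prefixes: Mapping[str, str]) -> str:
    for pref, group in prefixes.items():
        if rec_id.startswith(pref):
            return group
    return "unassigned"


def read_alignment(
    path: str | Path,
    group_prefixes: Mapping[str, str] = DEFAULT_GROUP_PREFIXES,
) -> AlignedBlock:
    """Read aligned FASTA into an AlignedBlock.

    All rows must share one length; ragged input raises an error listing the
    offending ids, and an all-gap column raises naming the (1-based) column.
    Group labels are parsed from the id-prefix convention (``LP|``/``PR|``
    by default).
    """
    path = Path(path)
    rows: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise SeqIOError(f"duplicate id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = _validate_seq(entry.id, str(entry.seq), allow_gaps=True)
        rows.append(
            ProteinRecord(id=entry.id, seq=seq, group=_group_from_id(entry.id, group_prefixes))
        )
    if not rows:
        raise SeqIOError(f"no FASTA records in {path}")
    width = len(rows[0].seq)
    ragged = [r.id for r in rows if len(r.seq) != width]
    if ragged:
        raise SeqIOError(f"ragged alignment in {path}: offending ids {ragged}")
    for col in range(1, width + 1):
        if all(r.seq[col - 1] == GAP for r in rows):
            raise SeqIOError(f"all-gap column {col} in {path}")
    return AlignedBlock(records=tuple(rows), width=width)


def write_alignment(block: AlignedBlock, path: str | Path) -> None:
    write_fasta(block.records, path)


def write_tsv(df, path: str | Path) -> None:
    """All tabular outputs are TSV with a header row."""
    df.to_csv(path, sep="\t", index=False)
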