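"""Synthetic multi-lineage protein collections with known ground truth.

The generator emulates transcriptome-derived proteomes from deeply
branching eukaryotic supergroups: per lineage it emits background decoys
plus planted SSP precursors (signal peptide + prodomain + C-terminal motif)
wherever the presence plan says a family occurs, and can emit tripartite
LRR-TM-kinase receptor proteins with controlled architecture defects.
Because every planted id is recorded, each pipeline stage is testable for
recall and false-discovery behaviour without any download.

The default conditions mirror the screening study the pipeline models:
7 protistan supergroups, 200 decoys per lineage, 20 planted positives per
occupied presence cell, land-plant references diverged at a low rate (0.05
substitutions/site) and protistan homologs at a higher one (0.2).  Decoys
model *real* unrelated proteins of a curated database, so by default every
decoy carries a confident mock annotation (the InterPro/Pfam stand-in that
the blacklist stage consumes), while planted SSPs — novel, unannotated
genes — carry none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import AMINO_ACIDS, AlignedBlock, ProteinRecord, write_fasta
from .screen import FAMILIES, MotifQuery
from .traceability import GroupedAlignment

# --- reference motifs --------------------------------------------------------

#: Synthetic reference motifs, one per family, modeled on the published
#: consensus of each SSP family's conserved C-terminal region (mature
#: peptide plus flanking conserved residues, so that every query is long
#: enough for coverage-based filtering).  They are stand-ins, not curated
#: sequences.
DEFAULT_MOTIFS: Mapping[str, str] = {
    "CLE-CLV3": "RTVPSGPDPLHH",
    "CLE-TDIF": "HEVPSGPNPISN",
    "PIP/PIPL": "RLASGPSRRGAGH",
    "CEP": "DFRPTTPGHSPGVGH",
    "IDA/IDL": "PIPPSAPSKRHN",
    "CLEL": "DYSNPGHHPPRHN",
    "PSY": "DYGDPSANPKHDPGVG",
    "CIF": "DYGNSSPKPKLVRPPFKL",
    "PEP": "ATKVKAKQRGKEKVSSGRPGQHN",
    "PSK": "AHTDVRKTDYIYTQ",
}

#: Default lineage panel: the seven supergroups in which the screening
#: study retained strong candidates.
DEFAULT_LINEAGES = (
    "TSAR", "Haptista", "Archaeoplastida", "Excavates", "CRuMs", "Amoebozoa", "Obazoa",
)

#: Default presence plan — a reconstruction of the reported SSP
#: distribution across protistan supergroups.  Constraints honored exactly:
#: family breadths (PSY/CEP/PEP/CLE-CLV3 in 4 lineages, CIF/CLE-TDIF/
#: IDA-IDL in 3, CLEL in TSAR+Obazoa only, PIP/PIPL and PSK vascular-plant
#: specific hence absent), Archaeoplastida and Amoebozoa sharing PSY and
#: CEP, PSY-CIF the single strongest family-profile correlation,
#: Archaeoplastida-Amoebozoa the single strongest lineage correlation, a
#: positive PSY-CEP association, every lineage occupied, and no pairwise
#: correlation significant at p < 0.05 on either axis.  The individual
#: cells beyond those constraints are free choices of the reconstruction.
_PLAN_ROWS = {
    "CLE-CLV3": ("TSAR", "Archaeoplastida", "Excavates", "CRuMs"),
    "CLE-TDIF": ("Archaeoplastida", "Excavates", "Obazoa"),
    "PIP/PIPL": (),
    "CEP": ("TSAR", "Archaeoplastida", "Amoebozoa", "Obazoa"),
    "IDA/IDL": ("TSAR", "Haptista", "CRuMs"),
    "CLEL": ("TSAR", "Obazoa"),
    "PSY": ("TSAR", "Haptista", "Archaeoplastida", "Amoebozoa"),
    "CIF": ("TSAR", "Haptista", "Archaeoplastida"),
    "PEP": ("TSAR", "Archaeoplastida", "CRuMs", "Amoebozoa"),
    "PSK": (),
}


def default_presence_plan() -> pd.DataFrame:
    plan = pd.DataFrame(0, index=list(DEFAULT_LINEAGES), columns=list(FAMILIES), dtype=int)
    for fam, lineages in _PLAN_ROWS.items():
        for lin in lineages:
            plan.loc[lin, fam] = 1
    return plan


#: Approximate gene copy numbers of each family in the Arabidopsis thaliana
#: genome, compiled from the primary family descriptions (CLV3-type CLEs
#: ~28 members, CIF 4, etc.); used by the breadth-vs-copy-number analysis.
ARABIDOPSIS_COPY_NUMBER: Mapping[str, int] = {
    "CLE-CLV3": 28,
    "CLE-TDIF": 4,
    "PIP/PIPL": 11,
    "CEP": 15,
    "IDA/IDL": 9,
    "CLEL": 11,
    "PSY": 9,
    "CIF": 4,
    "PEP": 8,
    "PSK": 5,
}

_HYDROPHOBIC = "LIVFA"
_BASIC = "KR"
#: residue pools for receptor scaffolds, chosen so one region cannot mimic
#: another region's detector (no LIVF in kinase spacers, no G/K/H in LRR
#: spacers, etc.)
_LRR_SPACER = "TSNQDEP"
_KINASE_SPACER = "ATSNQDEKRHGPY"
_POLAR = "TSNQDEKRHG"

ANNOTATION_LABELS = (
    "ribosomal protein", "histone", "tubulin", "actin", "heat shock protein", "ubiquitin",
)


@dataclass
class SyntheticSpec:
    """Study-condition parameters for one synthetic collection."""

    lineages: tuple[str, ...] = DEFAULT_LINEAGES
    families: tuple[str, ...] = tuple(FAMILIES)
    motifs: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    decoys_per_lineage: int = 200
    positives_per_cell: int = 20
    refs_per_family: int = 4
    sub_rate_plants: float = 0.05
    sub_rate_protists: float = 0.2
    no_sp_fraction: float = 0.1
    prodomain_range: tuple[int, int] = (40, 120)
    decoy_len_range: tuple[int, int] = (60, 250)
    annotated_decoy_fraction: float = 1.0
    background: str = "uniform"
    presence_plan: pd.DataFrame = field(default_factory=default_presence_plan)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate_plants", "sub_rate_protists", "no_sp_fraction",
                     "annotated_decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("decoys_per_lineage", "positives_per_cell", "refs_per_family"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        plan = self.presence_plan
        if list(plan.index) != list(self.lineages) or list(plan.columns) != list(self.families):
            raise ValueError("presence_plan dimensions must match lineages x families")
        for fam in self.families:
            if plan[fam].any() and fam not in self.motifs:
                raise ValueError(f"family {fam!r} occupied in plan but has no motif")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class GroundTruth:
    """What was planted where, for recall/FDP scoring."""

    planted_ssp: dict[tuple[str, str], list[str]]  # (lineage, family) -> ids
    planted_rlk_ids: list[str]
    presence: pd.DataFrame
    annotations: dict[str, str]  # decoy id -> confident annotation label

    def all_planted_ids(self) -> set[str]:
        return {i for ids in self.planted_ssp.values() for i in ids}


# --- elementary generators ---------------------------------------------------

def mutate_motif(motif: str, sub_rate: float, rng: np.random.Generator) -> str:
    """Independently substitute each site with probability ``sub_rate`` to a
    uniformly chosen *different* residue; length is preserved."""
    if not motif:
        raise ValueError("motif must be non-empty")
    if not 0.0 <= sub_rate <= 1.0:
        raise ValueError(f"sub_rate must be in [0,1], got {sub_rate}")
    out = []
    for ch in motif:
        if rng.random() < sub_rate:
            choices = [a for a in AMINO_ACIDS if a != ch]
            out.append(choices[rng.integers(0, len(choices))])
        else:
            out.append(ch)
    return "".join(out)


def _random_seq(length: int, rng: np.random.Generator, alphabet: str = AMINO_ACIDS) -> str:
    idx = rng.integers(0, len(alphabet), size=length)
    return "".join(alphabet[i] for i in idx)


def signal_peptide_block(rng: np.random.Generator) -> str:
    """Met + two basic residues + 10-12 hydrophobic stretch + A-X-A cleavage
    triplet; satisfies the built-in signal-peptide heuristic by construction."""
    h_len = int(rng.integers(10, 13))
    return (
        "M"
        + _random_seq(2, rng, _BASIC)
        + _random_seq(h_len, rng, _HYDROPHOBIC)
        + "A" + _random_seq(1, rng, _POLAR) + "A"
    )


def generate_precursor(
    family: str,
    lineage: str,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    with_sp: bool = True,
    sub_rate: float | None = None,
    rec_id: str = "",
) -> ProteinRecord:
    """One SSP precursor: [signal peptide] + prodomain + mutated motif near
    the C-terminus (motif end within the final 10 residues; total <= 250 aa).

    ``with_sp=False`` emulates 5'-truncated transcripts whose precursor
    lacks the signal peptide (the heuristic must treat that as supporting
    evidence lost, not grounds for removal).
    """
    if family not in spec.motifs:
        raise ValueError(f"family {family!r} has no reference motif in the spec")
    if sub_rate is None:
        sub_rate = spec.sub_rate_protists
    motif = mutate_motif(spec.motifs[family], sub_rate, rng)
    lo, hi = spec.prodomain_range
    prodomain = _random_seq(int(rng.integers(lo, hi + 1)), rng, _POLAR)
    if with_sp:
        head = signal_peptide_block(rng) + prodomain
    else:
        # truncated transcript: polar start, no n-region charge pattern
        head = "M" + _random_seq(4, rng, "TSNQDE") + prodomain
    tail = _random_seq(int(rng.integers(0, 10)), rng, _POLAR)
    seq = head + motif + tail
    if len(seq) > 250:
        seq = seq[-(250):]
    return ProteinRecord(id=rec_id or f"{lineage}_{family}_pos", seq=seq,
                         lineage=lineage, group="protist")


def make_reference_queries(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> list[MotifQuery]:
    """Land-plant reference motif sets: the canonical motif plus
    ``refs_per_family - 1`` low-divergence paralogs per family."""
    if rng is None:
        rng = np.random.default_rng([spec.rng_seed, 1])
    queries = []
    for fam in spec.families:
        motif = spec.motifs.get(fam)
        if motif is None:
            continue
        refs = [motif]
        for _ in range(spec.refs_per_family - 1):
            refs.append(mutate_motif(motif, spec.sub_rate_plants, rng))
        queries.append(MotifQuery(family=fam, motif_seqs=tuple(refs)))
    return queries


# --- full collection ---------------------------------------------------------

def generate_lineage_collection(
    spec: SyntheticSpec,
) -> tuple[dict[str, list[ProteinRecord]], GroundTruth]:
    """Emit per-lineage protein collections plus ground truth.

    Decoys are drawn from the background composition (uniform over the 20
    residues by default); positives are planted only where the presence
    plan has a 1; a configurable fraction of decoys carries a confident
    mock annotation (the InterPro/Pfam stand-in table).  Fixed seed implies
    byte-identical output.
    """
    root = np.random.SeedSequence(spec.rng_seed)
    lineage_seeds = root.spawn(len(spec.lineages))
    collections: dict[str, list[ProteinRecord]] = {}
    planted: dict[tuple[str, str], list[str]] = {}
    annotations: dict[str, str] = {}
    for lin, seed in zip(spec.lineages, lineage_seeds):
        rng = np.random.default_rng(seed)
        records: list[ProteinRecord] = []
        for d in range(spec.decoys_per_lineage):
            length = int(rng.integers(spec.decoy_len_range[0], spec.decoy_len_range[1] + 1))
            rid = f"{lin}|decoy{d:04d}"
            records.append(
                ProteinRecord(id=rid, seq=_random_seq(length, rng), lineage=lin, group="protist")
            )
            if rng.random() < spec.annotated_decoy_fraction:
                annotations[rid] = ANNOTATION_LABELS[int(rng.integers(0, len(ANNOTATION_LABELS)))]
        for fam in spec.families:
            if not spec.presence_plan.loc[lin, fam]:
                continue
            ids = []
            for k in range(spec.positives_per_cell):
                with_sp = rng.random() >= spec.no_sp_fraction
                rid = f"{lin}|{_safe(fam)}|pos{k:03d}"
                rec = generate_precursor(
                    fam, lin, spec, rng, with_sp=with_sp, rec_id=rid
                )
                records.append(rec)
                ids.append(rid)
            planted[(lin, fam)] = ids
        collections[lin] = records
    truth = GroundTruth(
        planted_ssp=planted,
        planted_rlk_ids=[],
        presence=spec.presence_plan.copy(),
        annotations=annotations,
    )
    return collections, truth


def _safe(name: str) -> str:
    return name.replace("/", "-")


def write_collection(
    collections: Mapping[str, Sequence[ProteinRecord]],
    truth: GroundTruth,
    spec: SyntheticSpec,
    out_dir: str | Path,
) -> None:
    """Write per-lineage FASTA, the ground-truth/annotation TSVs and the
    generating parameters as YAML alongside the outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for lin, records in collections.items():
        write_fasta(records, out / f"{_safe(lin)}.fasta")
    rows = [
        {"lineage": lin, "family": fam, "id": rid}
        for (lin, fam), ids in truth.planted_ssp.items()
        for rid in ids
    ]
    pd.DataFrame(rows).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    ann = pd.DataFrame(
        [{"id": k, "annotation": v} for k, v in sorted(truth.annotations.items())]
    )
    ann.to_csv(out / "annotations.tsv", sep="\t", index=False)
    truth.presence.to_csv(out / "presence_plan.tsv", sep="\t")
    params = {
        k: v for k, v in spec.__dict__.items() if k not in ("presence_plan", "motifs")
    }
    params["motifs"] = dict(spec.motifs)
    params["lineages"] = list(spec.lineages)
    params["families"] = list(spec.families)
    for key in ("prodomain_range", "decoy_len_range"):
        params[key] = list(params[key])
    (out / "spec.yaml").write_text(yaml.safe_dump(params, sort_keys=False))


# --- receptor scaffolds ------------------------------------------------------

@dataclass(frozen=True)
class RlkPrototype:
    """A receptor family scaffold: region sequences plus which positions may
    mutate (spacer positions) without breaking the detectors."""

    sp: str
    lrr: str
    lrr_mutable: tuple[int, ...]
    tm: str
    kinase: str
    kinase_mutable: tuple[int, ...]
    linker1: str
    linker2: str

    @property
    def kinase_domain_seq(self) -> str:
        return self.kinase

    @property
    def lrr_domain_seq(self) -> str:
        return self.lrr


_LRR_UNIT = "LTSLDLSN"  # LxxLxLxx consensus on a polar backbone


def build_rlk_prototype(rng: np.random.Generator, n_lrr_units: int = 6) -> RlkPrototype:
    """Construct the family scaffold a synthetic receptor radiation descends
    from.  LRR: tandem LxxLxLxx units on a polar backbone; TM: 21-residue
    hydrophobic stretch; kinase: ~220 aa containing the Gly-rich loop,
    VAIK, HRD and DFG motifs in order with polar spacers."""
    lrr_units = []
    lrr_mut = []
    pos = 0
    for _ in range(n_lrr_units):
        unit = list(_LRR_UNIT)
        for i in (1, 2, 4, 6, 7):  # x positions of LxxLxLxx
            unit[i] = _LRR_SPACER[rng.integers(0, len(_LRR_SPACER))]
            lrr_mut.append(pos + i)
        lrr_units.append("".join(unit))
        pos += 8
    lrr = "".join(lrr_units)
    tm = _random_seq(21, rng, "LIVF")
    motifs = ["GEGSFG", "VAVK", "HRD", "DFG"]
    spacers = [int(rng.integers(25, 60)) for _ in range(5)]
    kin_parts = []
    kin_mut = []
    kpos = 0
    for i, sp_len in enumerate(spacers):
        spacer = _random_seq(sp_len, rng, _KINASE_SPACER)
        kin_parts.append(spacer)
        kin_mut.extend(range(kpos, kpos + sp_len))
        kpos += sp_len
        if i < len(motifs):
            kin_parts.append(motifs[i])
            kpos += len(motifs[i])
    kinase = "".join(kin_parts)
    return RlkPrototype(
        sp=signal_peptide_block(rng),
        lrr=lrr,
        lrr_mutable=tuple(lrr_mut),
        tm=tm,
        kinase=kinase,
        kinase_mutable=tuple(kin_mut),
        linker1=_random_seq(10, rng, _LRR_SPACER),
        linker2=_random_seq(8, rng, _KINASE_SPACER),
    )


def _mutate_positions(seq: str, mutable: Sequence[int], rate: float,
                      alphabet: str, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in mutable:
        if rng.random() < rate:
            choices = [a for a in alphabet if a != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


INVALID_MODES = ("kinase_only", "lrr_only", "reversed")


def generate_rlk_protein(
    valid: bool,
    rng: np.random.Generator,
    prototype: RlkPrototype | None = None,
    invalid_mode: str = "kinase_only",
    sub_rate: float = 0.05,
    rec_id: str = "rlk",
    lineage: str = "",
) -> ProteinRecord:
    """One receptor homolog descended from the prototype scaffold.

    valid=True gives signal block + >=4 tandem LRR units + 21-residue TM +
    kinase region with its subdomain motifs in order.  Invalid classes drop
    or reorder regions: kinase_only, lrr_only, or reversed (kinase before
    LRR).  Only spacer positions mutate, so class membership survives
    divergence."""
    if prototype is None:
        prototype = build_rlk_prototype(rng)
    lrr = _mutate_positions(prototype.lrr, prototype.lrr_mutable, sub_rate, _LRR_SPACER, rng)
    kin = _mutate_positions(prototype.kinase, prototype.kinase_mutable, sub_rate,
                            _KINASE_SPACER, rng)
    if valid:
        seq = prototype.sp + lrr + prototype.linker1 + prototype.tm + prototype.linker2 + kin
    elif invalid_mode == "kinase_only":
        seq = prototype.sp + prototype.linker2 + kin
    elif invalid_mode == "lrr_only":
        seq = prototype.sp + lrr + prototype.linker1 + prototype.tm + prototype.linker2
    elif invalid_mode == "reversed":
        seq = prototype.sp + kin + prototype.linker2 + prototype.tm + prototype.linker1 + lrr
    else:
        raise ValueError(f"unknown invalid_mode {invalid_mode!r}")
    return ProteinRecord(id=rec_id, seq=seq, lineage=lineage, group="protist")


def generate_rlk_mix(
    rng: np.random.Generator,
    n_per_class: int = 10,
    sub_rate: float = 0.05,
) -> tuple[list[ProteinRecord], RlkPrototype, list[str]]:
    """The standard validation mix: ``n_per_class`` valid receptors plus the
    same number of each invalid class, all descended from one prototype.
    Returns (proteins, prototype, valid_ids)."""
    prototype = build_rlk_prototype(rng)
    proteins: list[ProteinRecord] = []
    valid_ids: list[str] = []
    for k in range(n_per_class):
        rid = f"rlk|valid{k:02d}"
        proteins.append(generate_rlk_protein(True, rng, prototype, sub_rate=sub_rate, rec_id=rid))
        valid_ids.append(rid)
    for mode in INVALID_MODES:
        for k in range(n_per_class):
            rid = f"rlk|{mode}{k:02d}"
            proteins.append(
                generate_rlk_protein(False, rng, prototype, invalid_mode=mode,
                                     sub_rate=sub_rate, rec_id=rid)
            )
    return proteins, prototype, valid_ids


# --- divergence simulators for alignments and trees --------------------------

def grouped_motif_alignment(
    motif: str,
    n_plants: int,
    n_protists: int,
    plant_rate: float,
    protist_rate: float,
    rng: np.random.Generator,
) -> GroupedAlignment:
    """Gap-free grouped alignment: plant rows and protist rows are
    independent mutants of the same ancestral motif at their group's rate."""
    records = []
    for i in range(n_plants):
        records.append(ProteinRecord(id=f"LP|plant{i:03d}",
                                     seq=mutate_motif(motif, plant_rate, rng),
                                     group="land_plant"))
    for i in range(n_protists):
        records.append(ProteinRecord(id=f"PR|protist{i:03d}",
                                     seq=mutate_motif(motif, protist_rate, rng),
                                     group="protist"))
    block = AlignedBlock(records=tuple(records), width=len(motif))
    return GroupedAlignment.from_block(block)


def diverge_from_ancestor(
    rng: np.random.Generator,
    length: int = 100,
    n_plants: int = 8,
    n_protists: int = 4,
    plant_stem_rate: float = 0.3,
    plant_rate: float = 0.05,
    protist_rate: float = 0.3,
) -> AlignedBlock:
    """Minimal clade simulator for tree tests: protists diverge early and
    independently from the ancestor (high rate); land plants radiate late
    from a common plant ancestor (stem divergence then low within-clade
    rate).  Returns an ungapped AlignedBlock with LP|/PR| ids."""
    ancestor = _random_seq(length, rng)
    plant_anc = mutate_motif(ancestor, plant_stem_rate, rng)
    records = []
    for i in range(n_plants):
        records.append(ProteinRecord(id=f"LP|plant{i:03d}",
                                     seq=mutate_motif(plant_anc, plant_rate, rng),
                                     group="land_plant"))
    for i in range(n_protists):
        records.append(ProteinRecord(id=f"PR|protist{i:03d}",
                                     seq=mutate_motif(ancestor, protist_rate, rng),
                                     group="protist"))
    return AlignedBlock(records=tuple(records), width=length)
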