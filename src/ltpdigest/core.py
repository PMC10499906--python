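"""Domain types and fixtures for the Pru p 3 digestion pipeline.

Pru p 3 is the major peach allergen, a 9 kDa non-specific lipid transfer
protein (nsLTP1) whose mature chain of 91 residues carries four conserved
intramolecular disulphide bonds.  Every downstream stage — in silico
proteolysis, peptide mapping, epitope-survival classification — works in the
coordinate frame of this mature chain (1-based, inclusive intervals), so the
types here pin down that frame and its self-consistency rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinIsoform:
    """A protein isoform sequence with its own numbering frame.

    ``numbering_origin`` is the coordinate assigned to the first residue;
    mature chains use 1, while N-terminally extended splice variants may keep
    their own frame.
    """

    accession: str
    sequence: str
    label: str = ""
    numbering_origin: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = [
            (i + 1, ch)
            for i, ch in enumerate(self.sequence)
            if ch not in CANONICAL_RESIDUES
        ]
        if bad:
            pos, ch = bad[0]
            raise ValueError(
                f"{self.accession}: non-canonical residue {ch!r} at position {pos}"
            )
        if self.numbering_origin < 1:
            raise ValueError("numbering_origin must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based position in this isoform's frame."""
        idx = position - self.numbering_origin
        if not 0 <= idx < len(self.sequence):
            raise IndexError(f"position {position} outside {self.accession}")
        return self.sequence[idx]

    def slice(self, start: int, end: int) -> str:
        """Subsequence for the inclusive interval [start, end]."""
        if start > end:
            raise ValueError(f"bad interval ({start}, {end})")
        return "".join(self.residue(p) for p in range(start, end + 1))


@dataclass(frozen=True)
class Epitope:
    """A linear IgE epitope, labelled with its boundary residues (e.g. A11-G20)."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"epitope {self.label}: start > end")

    def check_against(self, isoform: ProteinIsoform) -> None:
        """Verify the label's boundary letters against the parent sequence."""
        first, last = self.label.split("-")
        if isoform.residue(self.start) != first[0]:
            raise ValueError(
                f"epitope {self.label}: residue {self.start} is "
                f"{isoform.residue(self.start)}, label says {first[0]}"
            )
        if isoform.residue(self.end) != last[0]:
            raise ValueError(
                f"epitope {self.label}: residue {self.end} is "
                f"{isoform.residue(self.end)}, label says {last[0]}"
            )


@dataclass(frozen=True)
class DisulphideTopology:
    """Unordered cysteine-position pairs forming intramolecular disulphide bonds."""

    pairs: tuple[tuple[int, int], ...]

    @classmethod
    def from_pairs(cls, pairs: Iterable[Iterable[int]]) -> "DisulphideTopology":
        return cls(tuple(tuple(sorted(int(x) for x in p)) for p in pairs))

    @property
    def paired_cysteines(self) -> frozenset[int]:
        return frozenset(p for pair in self.pairs for p in pair)

    def __len__(self) -> int:
        return len(self.pairs)


EMPTY_TOPOLOGY = DisulphideTopology(())

# Enzyme activities of the intestinal digestion tests, U per mg substrate.
# "High" models adult duodenal/ileal protease levels, "low" infant levels.
_ENZYME_LEVELS = {
    "high": {"trypsin_U_per_mg": 34.5, "chymotrypsin_U_per_mg": 0.4},
    "low": {"trypsin_U_per_mg": 3.5, "chymotrypsin_U_per_mg": 0.04},
}


@dataclass(frozen=True)
class DigestionCondition:
    """Metadata describing one in vitro gastrointestinal digestion condition."""

    phase: str  # gastric | intestinal
    pH: float
    bile_mM: float = 0.0  # per bile salt (taurocholate / glycodeoxycholate)
    enzyme_level: str = "high"
    trypsin_U_per_mg: float | None = None
    chymotrypsin_U_per_mg: float | None = None
    pepsin_U_per_mg: float = 0.0
    time_min: float = 120.0

    def __post_init__(self) -> None:
        if self.phase not in ("gastric", "intestinal"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.enzyme_level not in _ENZYME_LEVELS:
            raise ValueError(f"unknown enzyme level {self.enzyme_level!r}")
        defaults = _ENZYME_LEVELS[self.enzyme_level]
        if self.trypsin_U_per_mg is None:
            object.__setattr__(
                self, "trypsin_U_per_mg", defaults["trypsin_U_per_mg"]
            )
        if self.chymotrypsin_U_per_mg is None:
            object.__setattr__(
                self, "chymotrypsin_U_per_mg", defaults["chymotrypsin_U_per_mg"]
            )
        for name in ("bile_mM", "trypsin_U_per_mg", "chymotrypsin_U_per_mg",
                     "pepsin_U_per_mg", "time_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def condition_id(self) -> str:
        return f"{self.enzyme_level}_pH{self.pH:g}_bile{self.bile_mM:g}mM"


@dataclass(frozen=True)
class ModificationSpec:
    """A post-translational or chemical modification with its mass deltas."""

    name: str
    targets: frozenset[str]
    delta_mono: float
    delta_avg: float


# Monoisotopic deltas are exact; average deltas from standard elemental
# composition (HPO3, deamidation O/NH, O, C2H3NO).
PHOSPHO_S = ModificationSpec("phospho-S", frozenset("STY"), 79.96633, 79.9799)
DEAMIDATION_NQ = ModificationSpec("deamidation-NQ", frozenset("NQ"), 0.98402, 0.9848)
OXIDATION_M = ModificationSpec("oxidation-M", frozenset("MW"), 15.99491, 15.9994)
CARBAMIDOMETHYL_C = ModificationSpec(
    "carbamidomethyl-C", frozenset("C"), 57.02146, 57.0513
)

MODIFICATIONS = {
    m.name: m for m in (PHOSPHO_S, DEAMIDATION_NQ, OXIDATION_M, CARBAMIDOMETHYL_C)
}


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinIsoform]:
    """Read a multi-record FASTA file into isoforms.

    The header token before the first whitespace becomes the accession and the
    remainder the label; sequences are upper-cased and validated against the
    canonical 20-residue alphabet.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    isoforms = []
    for rec in records:
        seq = str(rec.seq).upper()
        if any(ch in "-." for ch in seq):
            raise ValueError(f"{rec.id}: gap characters are not allowed")
        label = rec.description[len(rec.id):].strip()
        isoforms.append(ProteinIsoform(accession=rec.id, sequence=seq, label=label))
    return isoforms


def write_fasta(isoforms: Iterable[ProteinIsoform], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(iso.sequence), id=iso.accession, description=iso.label)
        for iso in isoforms
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Vendored Pru p 3 fixture
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("ltpdigest").joinpath("data", name)))


def load_prup3_fixtures() -> tuple[ProteinIsoform, list[Epitope], DisulphideTopology]:
    """Load the vendored mature Pru p 3 chain with its epitopes and topology.

    Returns the 91-residue mature sequence (UniProt Q9LED1, Pru p 3.0102
    numbering, first residue I1), the three linear IgE epitopes (A11-G20,
    I31-T40, G71-K80) and the canonical nsLTP1 disulphide pairing
    C1-C6, C2-C3, C4-C7, C5-C8, i.e. (3,50), (13,27), (28,73), (48,87).
    All annotations are checked against the sequence before returning.
    """
    isoform = read_fasta(_data_path("prup3.fasta"))[0]
    ann = json.loads(_data_path("prup3_annotations.json").read_text())
    if isoform.accession != ann["accession"]:
        raise ValueError("fixture FASTA/annotation accession mismatch")
    epitopes = [Epitope(e["label"], e["start"], e["end"]) for e in ann["epitopes"]]
    for epi in epitopes:
        epi.check_against(isoform)
    topology = DisulphideTopology.from_pairs(ann["disulphide_pairs"])
    violations = validate_topology(isoform, topology)
    if violations:
        raise ValueError(f"fixture topology invalid: {violations}")
    return isoform, epitopes, topology


def validate_topology(
    isoform: ProteinIsoform, topology: DisulphideTopology
) -> list[str]:
    """Return human-readable violations; empty list means the topology is valid."""
    violations = []
    seen: set[int] = set()
    for a, b in topology.pairs:
        for pos in (a, b):
            try:
                res = isoform.residue(pos)
            except IndexError:
                violations.append(f"position {pos} outside sequence")
                continue
            if res != "C":
                violations.append(f"position {pos} is {res}, not Cys")
            if pos in seen:
                violations.append(f"Cys {pos} used in more than one pair")
            seen.add(pos)
    return violations
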