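"""Mapping identified peptides onto isoforms: coverage, abundance, cleavage
usage and epitope survival.

The identification tables come from an upstream search engine; this module
takes them at face value after the score filter and asks where each peptide
sits on each isoform, which peptide bonds must have been hydrolysed to
produce it, and whether the linear IgE epitopes survived digestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Epitope, ProteinIsoform
from .digest import CleavageSite

IDENTIFICATION_COLUMNS = [
    "sample_id",
    "reduced",
    "sequence",
    "mods",
    "score",
    "spectral_count",
]


@dataclass(frozen=True)
class IdentifiedPeptide:
    """One observed peptide from an identification table."""

    sequence: str
    spectral_count: int = 1
    score: float = 0.0
    sample_id: str = ""
    reduced: bool = True
    mods: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.spectral_count < 0:
            raise ValueError("spectral_count must be >= 0")
        for pos, _name in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"mod position {pos} outside peptide")


@dataclass(frozen=True)
class PeptideLocation:
    """A placement of an identified peptide on one isoform."""

    accession: str
    start: int
    end: int
    unique_to_isoform: bool = True
    il_ambiguous: bool = False
    peptide: IdentifiedPeptide | None = None


@dataclass
class CoverageMap:
    accession: str
    counts: np.ndarray  # per-residue identification counts
    numbering_origin: int = 1

    @property
    def coverage_fraction(self) -> float:
        return float(np.count_nonzero(self.counts)) / len(self.counts)

    def covered_intervals(self) -> list[tuple[int, int]]:
        """Maximal runs of covered residues in isoform coordinates."""
        covered = self.counts > 0
        out = []
        start = None
        for i, c in enumerate(covered):
            if c and start is None:
                start = i
            elif not c and start is not None:
                out.append((start + self.numbering_origin, i - 1 + self.numbering_origin))
                start = None
        if start is not None:
            out.append(
                (start + self.numbering_origin, len(covered) - 1 + self.numbering_origin)
            )
        return out


def filter_identifications(
    table: pd.DataFrame, min_score: float = 5.0
) -> pd.DataFrame:
    """Retain rows with score strictly greater than ``min_score``."""
    if "score" not in table.columns:
        raise ValueError("identification table lacks a 'score' column")
    return table[table["score"] > min_score].reset_index(drop=True)


def _il_collapse(seq: str) -> str:
    return seq.replace("L", "I")


def map_peptides(
    peptides: Sequence[IdentifiedPeptide],
    isoforms: Sequence[ProteinIsoform],
    equivalence: str = "exact",
) -> tuple[list[PeptideLocation], list[IdentifiedPeptide]]:
    """Locate every peptide on every isoform.

    Returns (locations, unmapped).  Under ``IL`` equivalence isoleucine and
    leucine are interchangeable (indistinguishable by MS); matches that relied
    on the equivalence carry ``il_ambiguous=True``.  ``unique_to_isoform`` is
    true when the peptide matches exactly one accession.
    """
    if equivalence not in ("exact", "IL"):
        raise ValueError(f"unknown equivalence {equivalence!r}")
    if not isoforms:
        raise ValueError("isoform list is empty")

    locations: list[PeptideLocation] = []
    unmapped: list[IdentifiedPeptide] = []
    for pep in peptides:
        query = pep.sequence
        hits: list[tuple[ProteinIsoform, int, bool]] = []
        for iso in isoforms:
            hay = iso.sequence
            needle = query
            if equivalence == "IL":
                hay, needle = _il_collapse(hay), _il_collapse(needle)
            idx = hay.find(needle)
            while idx != -1:
                exact = iso.sequence[idx : idx + len(query)] == query
                hits.append((iso, idx, not exact))
                idx = hay.find(needle, idx + 1)
        if not hits:
            unmapped.append(pep)
            continue
        accessions = {iso.accession for iso, _, _ in hits}
        for iso, idx, ambiguous in hits:
            start = iso.numbering_origin + idx
            locations.append(
                PeptideLocation(
                    accession=iso.accession,
                    start=start,
                    end=start + len(query) - 1,
                    unique_to_isoform=len(accessions) == 1,
                    il_ambiguous=ambiguous,
                    peptide=pep,
                )
            )
    return locations, unmapped


def coverage(
    locations: Iterable[PeptideLocation], isoform: ProteinIsoform
) -> CoverageMap:
    """Per-residue identification counts over the isoform's own length."""
    counts = np.zeros(len(isoform), dtype=int)
    origin = isoform.numbering_origin
    for loc in locations:
        if loc.accession != isoform.accession:
            continue
        counts[loc.start - origin : loc.end - origin + 1] += 1
    return CoverageMap(isoform.accession, counts, origin)


def cleavage_site_usage(
    locations: Iterable[PeptideLocation],
    predicted: Iterable[CleavageSite],
    isoform: ProteinIsoform,
) -> pd.DataFrame:
    """Observed cut events implied by peptide termini, against predictions.

    Each located peptide contributes events at positions start-1 and end,
    excluding the chain termini (which are not proteolytic evidence).  Events
    at predicted positions inherit the protease name, others are labelled
    non-typical.  Counts are weighted by spectral count.
    """
    origin = isoform.numbering_origin
    chain_end = origin + len(isoform) - 1
    label_by_pos: dict[int, str] = {}
    for site in predicted:
        if site.position in label_by_pos:
            label_by_pos[site.position] += "+" + site.protease
        else:
            label_by_pos[site.position] = site.protease

    counts: dict[int, float] = {}
    for loc in locations:
        if loc.accession != isoform.accession:
            continue
        weight = loc.peptide.spectral_count if loc.peptide is not None else 1
        for pos in (loc.start - 1, loc.end):
            if origin - 1 < pos < chain_end:
                counts[pos] = counts.get(pos, 0) + weight
    rows = [
        {
            "position": pos,
            "label": label_by_pos.get(pos, "non-typical"),
            "count": counts[pos],
        }
        for pos in sorted(counts)
    ]
    return pd.DataFrame(rows, columns=["position", "label", "count"])


def abundance_matrix(identifications: pd.DataFrame) -> pd.DataFrame:
    """Spectral-count matrix: rows located peptides, columns samples.

    Expects columns start, end, sequence, sample_id, spectral_count.  Returns
    a frame indexed by (start, end, sequence) with raw-count columns per
    sample and matching ``frac_<sample>`` columns holding per-sample fractions
    (each non-empty sample's fractions sum to 1).
    """
    required = {"start", "end", "sequence", "sample_id", "spectral_count"}
    missing = required - set(identifications.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (identifications["spectral_count"] < 0).any():
        raise ValueError("negative spectral counts")
    raw = identifications.pivot_table(
        index=["start", "end", "sequence"],
        columns="sample_id",
        values="spectral_count",
        aggfunc="sum",
        fill_value=0,
    ).sort_index()
    out = raw.copy()
    for col in raw.columns:
        total = raw[col].sum()
        out[f"frac_{col}"] = raw[col] / total if total > 0 else 0.0
    out.columns.name = None
    return out


def epitope_status(
    epitope: Epitope,
    locations: Iterable[PeptideLocation],
    cut_events: Iterable[int],
) -> str:
    """Classify an epitope as digested, partially_degraded or intact.

    An epitope survives in some peptide when a located peptide spans its full
    interval.  digested: no peptide spans it.  partially_degraded: spanned,
    but some observed cut falls strictly inside the interval (a bond between
    start and end), so cleaved copies coexist.  intact: spanned and uncut.
    """
    spanned = any(
        loc.start <= epitope.start and loc.end >= epitope.end for loc in locations
    )
    if not spanned:
        return "digested"
    cut = any(epitope.start <= pos <= epitope.end - 1 for pos in cut_events)
    return "partially_degraded" if cut else "intact"
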