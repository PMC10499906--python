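"""Rule-based in silico proteolysis and disulphide-linked fragment analysis.

Cleavage prediction follows classic P1/P1' specificity rules (cleave after a
P1 residue unless the next residue blocks, e.g. proline).  Because the four
disulphide bonds of an nsLTP tether most proteolytic fragments together,
fragments are additionally grouped into disulphide-connected components: the
species actually observed on a non-reducing gel or in a non-reduced LC-MS/MS
run.  A peptide is observable without reduction only when none of its
cysteines participates in a bridge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pyteomics import mass as _pmass

from .core import (
    CANONICAL_RESIDUES,
    DisulphideTopology,
    ModificationSpec,
    ProteinIsoform,
)

# Mass of one hydrogen atom; a disulphide bond removes two relative to the
# free-thiol chains.
H_MASS_MONO = 1.0078250319
H_MASS_AVG = 1.00794

_AVG_AA_MASS = dict(_pmass.std_aa_mass)  # pyteomics ships mono; build avg below
_AVG_AA_MASS = {
    aa: _pmass.calculate_mass(sequence=aa, average=True)
    - _pmass.calculate_mass(formula="H2O", average=True)
    for aa in CANONICAL_RESIDUES
}
_WATER_MONO = _pmass.calculate_mass(formula="H2O")
_WATER_AVG = _pmass.calculate_mass(formula="H2O", average=True)


@dataclass(frozen=True)
class CleavageRule:
    """Protease specificity: cleave after any P1 residue unless blocked at P1'."""

    protease: str
    p1_residues: frozenset[str]
    blocked_p1prime: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.p1_residues:
            raise ValueError("p1_residues must be non-empty")
        for s in (self.p1_residues, self.blocked_p1prime):
            if not s <= CANONICAL_RESIDUES:
                raise ValueError(f"non-canonical residues in rule {self.protease}")

    @classmethod
    def make(cls, protease: str, p1: str, blocked: str = "") -> "CleavageRule":
        return cls(protease, frozenset(p1), frozenset(blocked))


TRYPSIN = CleavageRule.make("trypsin", "KR", "P")
# Chymotrypsin here includes Leu as P1 (F/Y/W/L, blocked before P) — the
# broad-specificity variant appropriate for extended bovine alpha-chymotrypsin
# digestion of an nsLTP.
CHYMOTRYPSIN = CleavageRule.make("chymotrypsin", "FYWL", "P")
# Pepsin (pH 2) is supplied for gastric-phase modelling but is not part of the
# default intestinal rule set: Pru p 3 survives the gastric phase essentially
# intact, so observed peptides arise from trypsin/chymotrypsin.
PEPSIN = CleavageRule.make("pepsin", "FLWY", "P")

DEFAULT_RULES = (TRYPSIN, CHYMOTRYPSIN)
RULES_BY_NAME = {r.protease: r for r in (TRYPSIN, CHYMOTRYPSIN, PEPSIN)}


@dataclass(frozen=True)
class CleavageSite:
    """The peptide bond between residues ``position`` and ``position``+1."""

    position: int
    protease: str
    specific: bool = True


@dataclass(frozen=True)
class TheoreticalPeptide:
    """An in silico digestion product in parent coordinates (1-based, inclusive)."""

    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0
    termini_specific: int = 2

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match interval")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentComponent:
    """Proteolytic fragments held together by disulphide bridges.

    ``members`` are non-overlapping backbone fragments; ``bridges`` the
    disulphide pairs whose cysteines both fall inside the component.  Masses
    subtract two hydrogens per bridge relative to the free-thiol chains.
    """

    members: tuple[TheoreticalPeptide, ...]
    bridges: tuple[tuple[int, int], ...]
    mass_mono: float
    mass_avg: float

    @property
    def intervals(self) -> tuple[tuple[int, int], ...]:
        return tuple((m.start, m.end) for m in self.members)


def predict_cleavage_sites(
    isoform: ProteinIsoform, rule: CleavageRule
) -> list[CleavageSite]:
    """Positions i where the rule predicts cleavage of the i/(i+1) bond.

    The chain's final residue never yields a site (there is no bond after it).
    """
    seq = isoform.sequence
    origin = isoform.numbering_origin
    sites = []
    for i in range(len(seq) - 1):
        if seq[i] in rule.p1_residues and seq[i + 1] not in rule.blocked_p1prime:
            sites.append(CleavageSite(origin + i, rule.protease, specific=True))
    return sites


def _site_positions(
    isoform: ProteinIsoform, rules: Iterable[CleavageRule]
) -> list[int]:
    positions: set[int] = set()
    for rule in rules:
        positions.update(s.position for s in predict_cleavage_sites(isoform, rule))
    return sorted(positions)


def digest(
    isoform: ProteinIsoform,
    rules: Sequence[CleavageRule] = DEFAULT_RULES,
    max_missed: int = 2,
    specificity: str = "full",
    length_range: tuple[int, int] = (1, 10**9),
    mass_range_Da: tuple[float, float] | None = None,
) -> list[TheoreticalPeptide]:
    """Enumerate theoretical digestion products.

    ``full`` specificity yields products of consecutive predicted sites with
    at most ``max_missed`` internal sites; ``semi`` requires only one
    enzymatic terminus; ``none`` enumerates all substrings.  Chain termini
    count as specific termini.  Results are filtered by length and, when a
    mass window is given, by monoisotopic mass, and ordered by (start, end).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    min_len, max_len = length_range
    if min_len > max_len:
        raise ValueError("length_range must be ordered (min, max)")
    if mass_range_Da is not None and mass_range_Da[0] > mass_range_Da[1]:
        raise ValueError("mass_range_Da must be ordered (min, max)")
    if specificity not in ("full", "semi", "none"):
        raise ValueError(f"unknown specificity {specificity!r}")

    seq = isoform.sequence
    n = len(seq)
    origin = isoform.numbering_origin
    if specificity == "none" and max_len >= n and n > 60:
        raise ValueError(
            "non-specific digestion of a long sequence requires a length bound"
        )

    sites = _site_positions(isoform, rules)
    site_set = set(sites)
    # boundary coordinates: a peptide [s, e] has specific N-terminus when s-1
    # is a predicted site or the chain start, specific C-terminus when e is a
    # predicted site or the chain end.
    chain_start = origin - 1
    chain_end = origin + n - 1
    n_boundaries = {chain_start, *site_set}
    c_boundaries = {chain_end, *site_set}
    required = {"full": 2, "semi": 1, "none": 0}[specificity]

    # prefix count of sites for O(1) missed-cleavage queries
    import bisect

    def missed(s: int, e: int) -> int:
        # internal sites are positions p with s <= p <= e-1
        lo = bisect.bisect_left(sites, s)
        hi = bisect.bisect_right(sites, e - 1)
        return hi - lo

    out = []
    if specificity == "full":
        bounds = [chain_start] + sites + [chain_end]
        for i in range(len(bounds) - 1):
            for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
                s, e = bounds[i] + 1, bounds[j]
                out.append((s, e, j - i - 1, 2))
    else:
        for s in range(origin, chain_end + 1):
            max_e = min(chain_end, s + max_len - 1)
            for e in range(s + min_len - 1, max_e + 1):
                spec_termini = (s - 1 in n_boundaries) + (e in c_boundaries)
                if spec_termini < required:
                    continue
                m = missed(s, e)
                if m > max_missed:
                    continue
                out.append((s, e, m, spec_termini))

    peptides = []
    for s, e, m, t in sorted(out):
        length = e - s + 1
        if not min_len <= length <= max_len:
            continue
        subseq = seq[s - origin : e - origin + 1]
        if mass_range_Da is not None:
            mz = peptide_mass(subseq)
            if not mass_range_Da[0] <= mz <= mass_range_Da[1]:
                continue
        peptides.append(TheoreticalPeptide(s, e, subseq, m, t))
    return peptides


def peptide_mass(
    sequence: str,
    mods: Sequence[tuple[int, ModificationSpec]] = (),
    kind: str = "mono",
) -> float:
    """Neutral peptide mass in Da: residue masses + water + modification deltas."""
    if not sequence:
        raise ValueError("empty peptide")
    if kind not in ("mono", "avg"):
        raise ValueError(f"unknown mass kind {kind!r}")
    for pos, spec in mods:
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"modification position {pos} outside peptide")
        if sequence[pos - 1] not in spec.targets:
            raise ValueError(
                f"{spec.name} not allowed on residue {sequence[pos - 1]} at {pos}"
            )
    if kind == "mono":
        base = _pmass.fast_mass(sequence)
        return base + sum(spec.delta_mono for _, spec in mods)
    base = sum(_AVG_AA_MASS[aa] for aa in sequence) + _WATER_AVG
    return base + sum(spec.delta_avg for _, spec in mods)


def _fragments_from_cuts(
    isoform: ProteinIsoform, cut_positions: Iterable[int]
) -> list[TheoreticalPeptide]:
    origin = isoform.numbering_origin
    chain_end = origin + len(isoform.sequence) - 1
    cuts = sorted(set(cut_positions))
    for c in cuts:
        if not origin <= c < chain_end:
            raise ValueError(f"cut position {c} is not an internal bond")
    bounds = [origin - 1] + cuts + [chain_end]
    return [
        TheoreticalPeptide(
            bounds[i] + 1,
            bounds[i + 1],
            isoform.slice(bounds[i] + 1, bounds[i + 1]),
        )
        for i in range(len(bounds) - 1)
    ]


def build_fragment_components(
    isoform: ProteinIsoform,
    cut_positions: Iterable[int],
    topology: DisulphideTopology,
) -> list[FragmentComponent]:
    """Split the chain at the cuts and merge fragments joined by disulphides.

    Components partition the fragments; each component's mass is the sum of
    its member masses minus 2 H per disulphide bond internal to the component
    (whether the bond links two members or closes a loop within one).
    """
    fragments = _fragments_from_cuts(isoform, cut_positions)

    def frag_index(pos: int) -> int:
        for i, f in enumerate(fragments):
            if f.start <= pos <= f.end:
                return i
        raise ValueError(f"cysteine position {pos} outside chain")

    # union-find over fragment indices
    parent = list(range(len(fragments)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    bridge_frags = []
    for a, b in topology.pairs:
        ia, ib = frag_index(a), frag_index(b)
        bridge_frags.append(((a, b), ia, ib))
        ra, rb = find(ia), find(ib)
        if ra != rb:
            parent[ra] = rb

    groups: dict[int, list[int]] = {}
    for i in range(len(fragments)):
        groups.setdefault(find(i), []).append(i)

    components = []
    for members_idx in groups.values():
        members = tuple(fragments[i] for i in sorted(members_idx))
        member_set = set(members_idx)
        bridges = tuple(
            pair for pair, ia, ib in bridge_frags
            if ia in member_set and ib in member_set
        )
        m_mono = sum(peptide_mass(m.sequence) for m in members)
        m_avg = sum(peptide_mass(m.sequence, kind="avg") for m in members)
        components.append(
            FragmentComponent(
                members,
                bridges,
                m_mono - 2 * H_MASS_MONO * len(bridges),
                m_avg - 2 * H_MASS_AVG * len(bridges),
            )
        )
    components.sort(key=lambda c: c.members[0].start)
    return components


def nonreduced_observable(
    peptide: TheoreticalPeptide, topology: DisulphideTopology
) -> bool:
    """True iff the peptide is untethered: no disulphide-paired Cys inside it."""
    return not any(
        peptide.start <= pos <= peptide.end for pos in topology.paired_cysteines
    )


def interbridge_free_intervals(
    isoform: ProteinIsoform, topology: DisulphideTopology
) -> list[tuple[int, int]]:
    """Maximal intervals containing no disulphide-paired cysteine."""
    origin = isoform.numbering_origin
    chain_end = origin + len(isoform.sequence) - 1
    blocked = sorted(topology.paired_cysteines)
    intervals = []
    lo = origin
    for pos in blocked + [chain_end + 1]:
        if pos > lo:
            intervals.append((lo, pos - 1))
        lo = pos + 1
    return [iv for iv in intervals if iv[0] <= chain_end]
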