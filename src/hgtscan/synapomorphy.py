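"""Residue-level synapomorphy typing of PADI-like sequences.

Animal and late-diverging cyanobacterial PADIs (the three-domain "Ai" type)
share derived residue states that the two-domain actinobacterial/fungal "Bi"
type lacks, and vice versa.  The most telling single site is the calcium
switch (human PADI2 position 389): aspartate there is competent for the
ordered calcium binding that activates catalysis, while the Bi type carries
glycine.  The Bi type also carries a distinctive triple-histidine motif at
positions 300-302 of the beta-sheet connecting the PAD_M and PAD_C domains.
Catalytic and substrate-binding residues are conserved in all PADIs and act
as sanity checks rather than type markers.

All rule positions are 1-based ungapped coordinates of a designated reference
row (human PADI2 numbering); a ``ColumnMap`` translates them to alignment
columns so sequences can be compared at the homologous sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

__all__ = [
    "AlignmentRow",
    "Alignment",
    "ColumnMap",
    "ResidueRule",
    "ResidueRuleSet",
    "Call",
    "RuleObservation",
    "TypeCall",
    "read_alignment_fasta",
    "build_column_map",
    "classify_sequence",
    "conservation_report",
    "default_rules",
    "read_rules_tsv",
]

GAP = "-"


@dataclass(frozen=True)
class AlignmentRow:
    id: str
    group: str
    seq: str


@dataclass
class Alignment:
    rows: list[AlignmentRow]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(r.seq) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0].seq)

    def row(self, id: str) -> AlignmentRow:
        for r in self.rows:
            if r.id == id:
                return r
        raise KeyError(f"row {id!r} not in alignment")

    def ids(self) -> list[str]:
        return [r.id for r in self.rows]


def read_alignment_fasta(path: str | Path) -> Alignment:
    """Aligned FASTA; a ``group=`` token in the description sets the group."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        group = "other"
        for token in rec.description.split()[1:]:
            if token.startswith("group="):
                group = token[6:]
        rows.append(AlignmentRow(rec.id, group, str(rec.seq).upper()))
    return Alignment(rows)


@dataclass(frozen=True)
class ColumnMap:
    """1-based ungapped reference position -> 0-based alignment column."""

    reference_id: str
    mapping: dict[int, int]

    def column(self, position: int) -> int:
        return self.mapping[position]

    def __len__(self) -> int:
        return len(self.mapping)


def build_column_map(alignment: Alignment, reference_id: str) -> ColumnMap:
    """Bijection between the reference row's non-gap positions and columns."""
    row = alignment.row(reference_id)
    mapping: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(row.seq):
        if ch != GAP:
            pos += 1
            mapping[pos] = col
    if not mapping:
        raise ValueError(f"reference row {reference_id!r} is all gaps")
    return ColumnMap(reference_id, mapping)


# ---------------------------------------------------------------------------
# Rules


@dataclass(frozen=True)
class ResidueRule:
    name: str
    kind: str               # 'conserved' | 'diagnostic'
    severity: str           # 'critical' | 'advisory'
    positions: tuple[int, ...]
    ai_states: tuple[frozenset[str], ...]   # per position; empty tuple = none
    bi_states: tuple[frozenset[str], ...]
    note: str = ""

    def __post_init__(self) -> None:
        for ai, bi in zip(self.ai_states, self.bi_states):
            if ai & bi:
                raise ValueError(f"rule {self.name!r}: ai and bi states overlap")

    @property
    def has_ai(self) -> bool:
        return bool(self.ai_states)

    @property
    def has_bi(self) -> bool:
        return bool(self.bi_states)


@dataclass(frozen=True)
class ResidueRuleSet:
    rules: tuple[ResidueRule, ...]

    def critical(self) -> list[ResidueRule]:
        return [r for r in self.rules if r.severity == "critical"]


def _parse_positions(text: str) -> tuple[int, ...]:
    out: list[int] = []
    for part in text.split(","):
        part = part.strip()
        if "-" in part:
            lo, hi = part.split("-")
            out.extend(range(int(lo), int(hi) + 1))
        else:
            out.append(int(part))
    return tuple(out)


def _parse_states(text: str, n_pos: int) -> tuple[frozenset[str], ...]:
    text = text.strip()
    if text in ("", "-"):
        return ()
    states = tuple(frozenset(tok.split("/")) for tok in text.split(","))
    if len(states) != n_pos:
        raise ValueError(f"expected {n_pos} state groups, got {len(states)}")
    return states


def read_rules_tsv(source: str) -> ResidueRuleSet:
    rules = []
    for line in source.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("name\t"):
            continue
        name, kind, severity, positions, ai, bi, *rest = line.split("\t")
        pos = _parse_positions(positions)
        rules.append(ResidueRule(
            name=name, kind=kind, severity=severity, positions=pos,
            ai_states=_parse_states(ai, len(pos)),
            bi_states=_parse_states(bi, len(pos)),
            note=rest[0] if rest else "",
        ))
    if not rules:
        raise ValueError("no rules parsed")
    return ResidueRuleSet(tuple(rules))


def default_rules() -> ResidueRuleSet:
    """The shipped rule set (editable TSV in the package data directory)."""
    text = resources.files("hgtscan.data").joinpath("synapomorphy_rules.tsv").read_text()
    return read_rules_tsv(text)


# ---------------------------------------------------------------------------
# Classification


class Call(str, Enum):
    Ai_like = "Ai_like"
    Bi_like = "Bi_like"
    ambiguous = "ambiguous"


@dataclass(frozen=True)
class RuleObservation:
    rule: str
    severity: str
    observed: tuple[str, ...]     # per rule position; '-' for gap, '?' unmapped
    evaluable: bool
    matches_ai: bool | None       # None when the rule defines no Ai states
    matches_bi: bool | None


@dataclass(frozen=True)
class TypeCall:
    id: str
    call: Call
    per_rule: tuple[RuleObservation, ...]


def _observe(rule: ResidueRule, seq: str, cmap: ColumnMap) -> RuleObservation:
    observed = []
    evaluable = True
    for p in rule.positions:
        col = cmap.mapping.get(p)
        if col is None:
            observed.append("?")
            evaluable = False
        else:
            ch = seq[col]
            observed.append(ch)
            if ch == GAP:
                evaluable = False
    m_ai = m_bi = None
    if rule.has_ai:
        m_ai = evaluable and all(ch in st for ch, st in zip(observed, rule.ai_states))
    if rule.has_bi:
        m_bi = evaluable and all(ch in st for ch, st in zip(observed, rule.bi_states))
    return RuleObservation(rule.name, rule.severity, tuple(observed), evaluable, m_ai, m_bi)


def classify_sequence(
    alignment: Alignment,
    cmap: ColumnMap,
    rules: ResidueRuleSet,
    id: str,
) -> TypeCall:
    """Type a sequence from its states at the rule positions.

    Ai_like requires every critical rule that defines Ai states to match them
    and no critical Bi marker to match; Bi_like is the mirror image (critical
    conserved rules, which define no Bi states, must still match their Ai
    states — they are conserved in all PADIs).  Anything else, including
    unevaluable critical rules (gaps), is ambiguous.
    """
    seq = alignment.row(id).seq
    obs = tuple(_observe(r, seq, cmap) for r in rules.rules)
    crit = [(r, o) for r, o in zip(rules.rules, obs) if r.severity == "critical"]

    conserved_ok = all(o.matches_ai for r, o in crit if r.kind == "conserved")
    diag = [(r, o) for r, o in crit if r.kind == "diagnostic"]
    any_bi = any(o.matches_bi for _, o in diag)
    any_ai = any(o.matches_ai for _, o in diag)
    ai_ok = all(o.matches_ai for r, o in diag if r.has_ai)
    bi_ok = all(o.matches_bi for r, o in diag if r.has_bi)

    if conserved_ok and ai_ok and not any_bi:
        call = Call.Ai_like
    elif conserved_ok and bi_ok and not any_ai:
        call = Call.Bi_like
    else:
        call = Call.ambiguous
    return TypeCall(id, call, obs)


def conservation_report(
    alignment: Alignment,
    cmap: ColumnMap,
    positions: Sequence[int],
    groups: Sequence[str],
) -> dict[int, dict[str, str]]:
    """Per-group consensus at reference positions.

    A group's entry is the single shared residue when all evaluable members
    agree, ``"X/Y"`` (alphabetical) when exactly two residues occur, and
    ``"nc"`` (not conserved) otherwise.  Members with a gap at the position
    are unevaluable and excluded; a group with no evaluable member reports
    ``"-"``.
    """
    by_group: dict[str, list[AlignmentRow]] = {}
    for row in alignment.rows:
        by_group.setdefault(row.group, []).append(row)
    for g in groups:
        if g not in by_group or not by_group[g]:
            raise ValueError(f"group {g!r} has no sequences in the alignment")

    report: dict[int, dict[str, str]] = {}
    for p in positions:
        col = cmap.mapping.get(p)
        entry: dict[str, str] = {}
        for g in groups:
            if col is None:
                entry[g] = "-"
                continue
            residues = sorted({r.seq[col] for r in by_group[g]} - {GAP})
            if not residues:
                entry[g] = "-"
            elif len(residues) == 1:
                entry[g] = residues[0]
            elif len(residues) == 2:
                entry[g] = f"{residues[0]}/{residues[1]}"
            else:
                entry[g] = "nc"
        report[p] = entry
    return report


def report_to_tsv(report: dict[int, dict[str, str]], groups: Sequence[str]):
    yield "position\t" + "\t".join(groups)
    for p in sorted(report):
        yield f"{p}\t" + "\t".join(report[p][g] for g in groups)
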