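"""Homolog-screen filters and taxonomic survey tables.

A domain-similarity screen across proteome databases yields one hit record
per (species, group) with an E-value and a protein length.  The survey keeps
significant hits (E-value strictly below 1e-3), drops fragments (shorter
than 450 aa), counts unique species per taxonomic group, and reports the
percentage of each group's species carrying a homolog, rounded half-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "HitRecord",
    "SurveyRow",
    "filter_hits",
    "drop_fragments",
    "survey_table",
    "round_half_up",
    "published_survey_counts",
    "read_hits_tsv",
    "read_totals_tsv",
    "rows_to_tsv",
]

EVALUE_MAX = 1e-3
MIN_LENGTH_AA = 450


@dataclass(frozen=True)
class HitRecord:
    species: str
    group: str
    evalue: float
    length_aa: int

    def __post_init__(self) -> None:
        if not (self.evalue >= 0 and self.evalue == self.evalue):
            raise ValueError(f"bad E-value for {self.species!r}")
        if self.length_aa < 1:
            raise ValueError(f"bad length for {self.species!r}")


@dataclass(frozen=True)
class SurveyRow:
    group: str
    taxid: str
    n_hit_species: int
    n_total_species: int
    pct: float


def round_half_up(x: float, dp: int = 2) -> float:
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def filter_hits(records: Iterable[HitRecord],
                evalue_max: float = EVALUE_MAX) -> list[HitRecord]:
    """Keep hits with E-value strictly below the cutoff."""
    return [r for r in records if r.evalue < evalue_max]


def drop_fragments(records: Iterable[HitRecord],
                   min_len: int = MIN_LENGTH_AA) -> list[HitRecord]:
    """Remove fragment sequences shorter than ``min_len`` amino acids."""
    return [r for r in records if r.length_aa >= min_len]


def survey_table(
    records: Iterable[HitRecord],
    totals: Mapping[str, int],
    taxids: Mapping[str, str] | None = None,
    dp: int | Mapping[str, int] = 2,
) -> list[SurveyRow]:
    """Unique hit species per group against group totals.

    Every record's group must appear in ``totals``; groups with no hits are
    reported with 0.  ``dp`` sets the output precision (half-up), either
    globally or per group.
    """
    species: dict[str, set[str]] = {g: set() for g in totals}
    for r in records:
        if r.group not in totals:
            raise KeyError(f"group {r.group!r} missing from the totals table")
        species[r.group].add(r.species)

    taxids = taxids or {}
    rows = []
    for group, total in totals.items():
        n_hit = len(species[group])
        if not (0 <= n_hit <= total):
            raise ValueError(f"group {group!r}: {n_hit} hits exceed total {total}")
        d = dp[group] if isinstance(dp, Mapping) else dp
        pct = round_half_up(100.0 * n_hit / total, d) if total else 0.0
        rows.append(SurveyRow(group, taxids.get(group, ""), n_hit, total, pct))
    return rows


def published_survey_counts() -> list[dict]:
    """The shipped published survey count pairs (group, taxid, counts, dp)."""
    text = resources.files("hgtscan.data").joinpath("table1_counts.tsv").read_text()
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("group\t"):
            continue
        group, taxid, n_hit, n_total, dp = line.split("\t")
        rows.append({"group": group, "taxid": taxid, "n_hit": int(n_hit),
                     "n_total": int(n_total), "dp": int(dp)})
    return rows


def read_hits_tsv(path: str | Path) -> list[HitRecord]:
    """TSV columns: species, group, evalue, length_aa."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("species\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed hit line: {line!r}")
            records.append(HitRecord(parts[0], parts[1],
                                     float(parts[2]), int(parts[3])))
    return records


def read_totals_tsv(path: str | Path) -> dict[str, int]:
    """TSV columns: group, n_total_species."""
    totals: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("group\t"):
                continue
            group, total = line.split("\t")[:2]
            totals[group] = int(total)
    if not totals:
        raise ValueError(f"no totals found in {path}")
    return totals


def rows_to_tsv(rows: Sequence[SurveyRow]) -> Iterator[str]:
    yield "group\ttaxid\tn_hit_species\tn_total_species\tpct"
    for r in rows:
        yield f"{r.group}\t{r.taxid}\t{r.n_hit_species}\t{r.n_total_species}\t{r.pct:g}"
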