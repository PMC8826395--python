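"""Pairwise sequence scoring: local-alignment bit scores, bit-score density,
and global percent identity.

The bit-score density of a query ``q`` against a target ``t`` is the bit score
of their optimal local alignment divided by the query's self-alignment bit
score.  Self-similarity is exactly 1, and under a diagonally dominant
substitution matrix (BLOSUM62) the density lies in [0, 1], making it a
length-normalized similarity that can be compared across proteins of very
different sizes.  Raw Smith--Waterman scores are converted to bits with the
Karlin--Altschul transform ``bits = (lambda * S - ln K) / ln 2`` so that the
scale does not depend on the substitution matrix used.

Scores here are produced by deterministic pairwise local alignment
(Smith--Waterman with affine gaps).  This is a self-contained, reproducible
stand-in for scores produced by profile-based database search tools; the
divergence layer also accepts externally computed bit scores from TSV for
users who have them.

Gap convention: opening a gap of length L costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "TaxonGroup",
    "ProteinSequence",
    "ScoringScheme",
    "BitscoreDensity",
    "local_align_score",
    "to_bits",
    "bitscore_density",
    "global_identity",
    "read_protein_fasta",
    "write_protein_fasta",
    "densities_to_tsv",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
_NUCLEOTIDES = frozenset("ACGTUN")


class TaxonGroup(str, Enum):
    metazoa = "metazoa"
    cyanobacteria = "cyanobacteria"
    actinobacteria = "actinobacteria"
    proteobacteria = "proteobacteria"
    fungi = "fungi"
    other = "other"


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20-letter alphabet (X permitted)."""

    id: str
    residues: str
    taxon: str = ""
    group: TaxonGroup = TaxonGroup.other

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)!r}; "
                "only the 20 amino acids plus X are accepted (uppercase)"
            )

    def __len__(self) -> int:
        return len(self.residues)


def _default_matrix():
    """BLOSUM62 with X scoring 0 against everything (ambiguity is neutral)."""
    m = substitution_matrices.load("BLOSUM62").copy()
    for a in m.alphabet:
        m["X", a] = 0.0
        m[a, "X"] = 0.0
    return m


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin--Altschul parameters.

    Defaults are BLOSUM62 with gap open 11 / extend 1 and the standard gapped
    Karlin--Altschul parameters for that combination (lambda=0.267, K=0.041).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    matrix: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if self.matrix is None:
            if self.matrix_name == "BLOSUM62":
                self.matrix = _default_matrix()
            else:
                self.matrix = substitution_matrices.load(self.matrix_name)

    def aligner(self, mode: str = "local") -> PairwiseAligner:
        al = PairwiseAligner()
        al.mode = mode
        al.substitution_matrix = self.matrix
        # first gap position is charged open + extend, later ones extend
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -float(self.gap_extend)
        return al


@dataclass(frozen=True)
class BitscoreDensity:
    """Normalized similarity of a query to a target on a 0-1 scale."""

    query_id: str
    target_id: str
    raw_score: int
    bits: float
    self_bits: float
    density: float


def _residues(seq) -> str:
    return seq.residues if isinstance(seq, ProteinSequence) else str(seq)


def local_align_score(a, b, scheme: ScoringScheme | None = None) -> int:
    """Optimal Smith--Waterman local alignment score with affine gaps.

    Symmetric in its arguments; the empty local alignment is allowed, so the
    score is never negative.
    """
    scheme = scheme or ScoringScheme()
    ra, rb = _residues(a), _residues(b)
    if not ra or not rb:
        raise ValueError("cannot align empty sequences")
    score = scheme.aligner("local").score(ra, rb)
    return int(round(max(0.0, score)))


def to_bits(raw: float, scheme: ScoringScheme | None = None) -> float:
    """Karlin--Altschul normalized bit score: (lambda*S - ln K) / ln 2."""
    if raw < 0:
        raise ValueError("raw score must be non-negative")
    scheme = scheme or ScoringScheme()
    return (scheme.lam * raw - math.log(scheme.K)) / math.log(2)


def bitscore_density(q, t, scheme: ScoringScheme | None = None) -> BitscoreDensity:
    """Bit score of q against t divided by the self bit score of q."""
    scheme = scheme or ScoringScheme()
    raw = local_align_score(q, t, scheme)
    bits = to_bits(raw, scheme)
    self_raw = local_align_score(q, q, scheme)
    self_bits = to_bits(self_raw, scheme)
    if self_bits <= 0:
        raise ArithmeticError(
            f"degenerate query {getattr(q, 'id', '?')!r}: self bit score <= 0"
        )
    qid = getattr(q, "id", "query")
    tid = getattr(t, "id", "target")
    return BitscoreDensity(qid, tid, raw, bits, self_bits, bits / self_bits)


def _is_nucleotide(s: str) -> bool:
    return bool(s) and set(s) <= _NUCLEOTIDES


def global_identity(a, b, gap_open: float = 10.0, gap_extend: float = 0.5) -> float:
    """Global (Needleman--Wunsch) percent identity with affine gaps.

    Returns 100 * identical aligned positions / alignment length.  Nucleotide
    inputs are aligned with an identity matrix (match 1 / mismatch 0); protein
    inputs with BLOSUM62.  Defaults match the EMBOSS Needle gap penalties.
    """
    ra, rb = _residues(a), _residues(b)
    if not ra or not rb:
        raise ValueError("cannot align empty sequences")
    al = PairwiseAligner()
    al.mode = "global"
    if _is_nucleotide(ra) and _is_nucleotide(rb):
        al.match_score = 1.0
        al.mismatch_score = 0.0
    else:
        al.substitution_matrix = _default_matrix()
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    aln = al.align(ra, rb)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


# ---------------------------------------------------------------------------
# FASTA / TSV plumbing


def read_protein_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read proteins from FASTA; ``taxon=`` and ``group=`` tokens in the
    description are honoured if present."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon, group = "", TaxonGroup.other
        for token in rec.description.split()[1:]:
            if token.startswith("taxon="):
                taxon = token[6:]
            elif token.startswith("group="):
                try:
                    group = TaxonGroup(token[6:])
                except ValueError:
                    group = TaxonGroup.other
        out.append(ProteinSequence(rec.id, str(rec.seq).upper(), taxon, group))
    if not out:
        raise ValueError(f"no sequences found in {path}")
    return out


def write_protein_fasta(seqs: Iterable[ProteinSequence], path: str | Path,
                        width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            desc = ""
            if s.taxon:
                desc += f" taxon={s.taxon}"
            if s.group is not TaxonGroup.other:
                desc += f" group={s.group.value}"
            fh.write(f">{s.id}{desc}\n")
            if width:
                for i in range(0, len(s.residues), width):
                    fh.write(s.residues[i:i + width] + "\n")
            else:
                fh.write(s.residues + "\n")


def densities_to_tsv(densities: Iterable[BitscoreDensity]) -> Iterator[str]:
    yield "query_id\ttarget_id\traw\tbits\tdensity"
    for d in densities:
        yield f"{d.query_id}\t{d.target_id}\t{d.raw_score}\t{d.bits:.6g}\t{d.density:.6g}"
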