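"""Synthetic reference fixtures.

``synthetic_padi_alignment`` builds a small SYNTHETIC alignment shaped like a
PADI family: a reference row that plays the role of human PADI2 (so that the
shipped 1-based residue numbering of the rule file applies), an Ai-type
cyanobacterial-like row, two Bi-type rows (fungal- and actinobacterial-like)
carrying the calcium-switch D389G substitution and the 300-302 triple
histidine, and a fragment row that is gapped across every rule position.
The sequences are random apart from the controlled sites — they are NOT real
PADI sequences; they exist so the synapomorphy machinery can be exercised
and round-tripped deterministically.
"""

from __future__ import annotations

import numpy as np

from .scoring import AMINO_ACIDS
from .synapomorphy import Alignment, AlignmentRow, default_rules

__all__ = ["synthetic_padi_alignment", "REFERENCE_ID", "REF_LENGTH"]

REFERENCE_ID = "PADI2_ref_synthetic"
REF_LENGTH = 660

# states the synthetic Ai reference carries at the critical rule sites
_AI_SITES = {125: "D", 131: "E", 351: "D", 389: "D", 471: "H", 473: "D",
             647: "C", 300: "T", 301: "V", 302: "S"}
_BI_SITES = {125: "N", 131: "D", 351: "D", 389: "G", 471: "H", 473: "D",
             647: "C", 300: "H", 301: "H", 302: "H"}


def _rule_positions() -> set[int]:
    pos: set[int] = set()
    for rule in default_rules().rules:
        pos.update(rule.positions)
    return pos


def synthetic_padi_alignment(seed: int = 7, divergence: float = 0.15) -> Alignment:
    """Deterministic synthetic PADI-like alignment (see module docstring).

    ``divergence`` is the per-site substitution probability applied outside
    the controlled rule positions.
    """
    rng = np.random.default_rng(seed)
    protected = _rule_positions()

    ref = rng.choice(list(AMINO_ACIDS), size=REF_LENGTH)
    for p, aa in _AI_SITES.items():
        ref[p - 1] = aa

    def mutate(base: np.ndarray, sites: dict[int, str]) -> np.ndarray:
        out = base.copy()
        mask = rng.random(out.size) < divergence
        repl = rng.choice(list(AMINO_ACIDS), size=int(mask.sum()))
        out[mask] = repl
        for p in protected:
            out[p - 1] = base[p - 1]
        for p, aa in sites.items():
            out[p - 1] = aa
        return out

    rows = {
        REFERENCE_ID: ("metazoa", ref),
        "cyano_Ai_synthetic": ("cyanobacteria", mutate(ref, _AI_SITES)),
        "fungal_Bi_synthetic": ("fungi", mutate(ref, _BI_SITES)),
        "actino_Bi_synthetic": ("actinobacteria", mutate(ref, _BI_SITES)),
    }

    # a 6-column insertion carried only by the cyanobacterial row, placed
    # between reference positions 200 and 201, exercises the column map
    insert_at = 200
    insert = rng.choice(list(AMINO_ACIDS), size=6)
    aligned: list[AlignmentRow] = []
    for rid, (group, arr) in rows.items():
        left, right = "".join(arr[:insert_at]), "".join(arr[insert_at:])
        middle = "".join(insert) if rid.startswith("cyano") else "-" * 6
        aligned.append(AlignmentRow(rid, group, left + middle + right))

    # fragment row: gaps across all rule positions (columns shifted by the
    # insert for reference positions > 200)
    frag = list(aligned[0].seq)
    for p in protected:
        col = p - 1 if p <= insert_at else p - 1 + 6
        frag[col] = "-"
    aligned.append(AlignmentRow("fragment_synthetic", "other", "".join(frag)))

    return Alignment(aligned)
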