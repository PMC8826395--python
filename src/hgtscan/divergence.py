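"""Accumulated genetic divergence (AGD) over homolog triples, control-panel
summaries, and z-score outlier testing.

The AGD of a protein is defined over a triple of homologs: a *reference*
(e.g. the human protein), a *bridge* homolog from an intermediate lineage
(e.g. amphioxus), and a *distal* homolog from the deep lineage under test
(e.g. a cyanobacterium).  Both bit-score densities are measured with the
reference as the query, so they share the self-normalizing denominator:

    AGD = density(reference, bridge) - density(reference, distal)

For a vertically inherited, conserved protein the bridge homolog is far more
similar to the reference than the distal one, so AGD is large.  A gene that
entered the reference's lineage horizontally from near the distal lineage has
accumulated much less extra divergence on the deep comparison, giving a small
AGD.  Panels of control proteins (vertically inherited ribosomal proteins,
endosymbiotic-transfer candidates, mitochondrially encoded proteins) supply a
null distribution; after a Shapiro--Wilk normality check, a candidate's AGD is
tested as a one-tailed z-score outlier against the panel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .scoring import ProteinSequence, ScoringScheme, bitscore_density

__all__ = [
    "HomologTriple",
    "AGDRecord",
    "PanelCategory",
    "Panel",
    "OutlierTest",
    "compute_agd",
    "agd_from_bits",
    "panel_summary",
    "z_outlier_test",
    "normal_cdf",
    "panel_membership",
    "read_triples_tsv",
    "records_to_tsv",
    "report_json",
]


@dataclass(frozen=True)
class HomologTriple:
    """Reference / bridge / distal homolog ids for one protein family."""

    label: str
    reference_id: str
    bridge_id: str
    distal_id: str

    def __post_init__(self) -> None:
        ids = {self.reference_id, self.bridge_id, self.distal_id}
        if len(ids) != 3:
            raise ValueError(f"triple {self.label!r}: the three ids must be distinct")


@dataclass(frozen=True)
class AGDRecord:
    label: str
    d_distal_ref: float
    d_bridge_ref: float

    @property
    def agd(self) -> float:
        return self.d_bridge_ref - self.d_distal_ref


class PanelCategory(str, Enum):
    vertical_ribosomal = "vertical_ribosomal"
    egt_candidate = "egt_candidate"
    mito_encoded = "mito_encoded"
    custom = "custom"


@dataclass
class Panel:
    """Summary of a control panel of AGD records."""

    category: PanelCategory
    records: list[AGDRecord]
    mean: float
    sd: float
    shapiro_W: float
    shapiro_p: float

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def normality_retained(self) -> bool:
        return bool(self.shapiro_p > 0.05)

    @property
    def usable_for_z(self) -> bool:
        return self.sd > 0


@dataclass(frozen=True)
class OutlierTest:
    test_value: float
    z: float
    p_one_tailed: float
    alpha: float
    reject: bool
    tail: str


def compute_agd(
    triple: HomologTriple,
    sequences: Mapping[str, ProteinSequence],
    scheme: ScoringScheme | None = None,
) -> AGDRecord:
    """AGD for one homolog triple from pairwise bit-score densities.

    The reference homolog is the query (and the self-normalizer) in both
    density computations.
    """
    scheme = scheme or ScoringScheme()
    try:
        ref = sequences[triple.reference_id]
        bridge = sequences[triple.bridge_id]
        distal = sequences[triple.distal_id]
    except KeyError as e:
        raise KeyError(f"triple {triple.label!r}: sequence {e.args[0]!r} not loaded") from e
    d_bridge = bitscore_density(ref, bridge, scheme).density
    d_distal = bitscore_density(ref, distal, scheme).density
    return AGDRecord(triple.label, d_distal_ref=d_distal, d_bridge_ref=d_bridge)


def agd_from_bits(label: str, bits_ref_self: float, bits_ref_bridge: float,
                  bits_ref_distal: float) -> AGDRecord:
    """AGD from externally supplied bit scores (bypasses the internal aligner)."""
    if bits_ref_self <= 0:
        raise ArithmeticError(f"{label!r}: self bit score must be positive")
    return AGDRecord(
        label,
        d_distal_ref=bits_ref_distal / bits_ref_self,
        d_bridge_ref=bits_ref_bridge / bits_ref_self,
    )


def panel_summary(
    records: Sequence[AGDRecord],
    category: PanelCategory = PanelCategory.custom,
) -> Panel:
    """Mean, sample SD and Shapiro--Wilk normality of a panel's AGD values.

    Normality is retained when the Shapiro--Wilk p exceeds 0.05.  A panel of
    constant values has sd = 0 and is flagged unusable for z-testing
    (shapiro statistics are NaN in that case).
    """
    if len(records) < 3:
        raise ValueError("a panel needs at least 3 records")
    values = np.array([r.agd for r in records], dtype=float)
    mean = float(values.mean())
    if values.max() == values.min():
        sd = 0.0   # constant panel: no spread, z-testing undefined
        W, p = float("nan"), float("nan")
    else:
        sd = float(values.std(ddof=1))
        W, p = (float(x) for x in stats.shapiro(values))
    return Panel(category, list(records), mean, sd, W, p)


def normal_cdf(z: float) -> float:
    """Standard normal CDF via the complementary error function."""
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def z_outlier_test(
    value: float,
    panel: Panel,
    tail: str = "lower",
    alpha: float = 0.05,
) -> OutlierTest:
    """One-tailed z test of a value against a panel's normal null.

    ``tail='lower'`` asks whether the value is anomalously small (p = Phi(z));
    ``'upper'`` whether it is anomalously large (p = 1 - Phi(z)).
    """
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    if not panel.usable_for_z:
        raise ArithmeticError("panel sd is zero; z test undefined")
    z = (value - panel.mean) / panel.sd
    p = normal_cdf(z) if tail == "lower" else 1.0 - normal_cdf(z)
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return OutlierTest(value, z, p, alpha, reject=bool(p < alpha), tail=tail)


# ---------------------------------------------------------------------------
# Fixtures and I/O


def panel_membership() -> dict[str, list[str]]:
    """Protein names of the shipped control panels.

    26 universally conserved ribosomal proteins (vertical descent), 19
    mitochondrially located endosymbiotic-transfer candidates, and the 10
    proteins still encoded in animal mitochondrial genomes.
    """
    text = resources.files("hgtscan.data").joinpath("panels.tsv").read_text()
    out: dict[str, list[str]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("category\t"):
            continue
        cat, name = line.split("\t")[:2]
        out.setdefault(cat, []).append(name)
    return out


def read_triples_tsv(path: str | Path) -> list[HomologTriple]:
    """TSV columns: label, reference_id, bridge_id, distal_id [, category]."""
    triples = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("label\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed triple line: {line!r}")
            triples.append(HomologTriple(*parts[:4]))
    if not triples:
        raise ValueError(f"no triples found in {path}")
    return triples


def records_to_tsv(records: Sequence[AGDRecord]):
    yield "label\td_bridge_ref\td_distal_ref\tagd"
    for r in records:
        yield f"{r.label}\t{r.d_bridge_ref:.6g}\t{r.d_distal_ref:.6g}\t{r.agd:.6g}"


def report_json(panel: Panel, test: OutlierTest | None = None) -> str:
    out = {
        "category": panel.category.value,
        "n": panel.n,
        "mean": panel.mean,
        "sd": panel.sd,
        "shapiro_W": panel.shapiro_W,
        "shapiro_p": panel.shapiro_p,
        "normality_retained": panel.normality_retained,
    }
    if test is not None:
        out["outlier_test"] = {
            "value": test.test_value,
            "z": test.z,
            "p_one_tailed": test.p_one_tailed,
            "tail": test.tail,
            "alpha": test.alpha,
            "reject": test.reject,
        }
    return json.dumps(out, indent=2, allow_nan=True)
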