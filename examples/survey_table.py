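"""Homolog-survey percentages from screened hit tables.

Applies the screen filters (E-value strictly below 1e-3; fragments under
450 aa dropped) to a toy hit table, then recomputes the shipped published
survey percentages from their count pairs.
"""

from hgtscan import (
    HitRecord, drop_fragments, filter_hits, published_survey_counts,
    round_half_up, survey_table,
)

hits = [
    HitRecord("Nostoc punctiforme", "cyanobacteria", 2e-8, 620),
    HitRecord("Nostoc punctiforme", "cyanobacteria", 5e-6, 615),   # duplicate
    HitRecord("Anabaena cylindrica", "cyanobacteria", 1e-3, 600),  # at cutoff
    HitRecord("Aspergillus oryzae", "fungi", 3e-12, 449),          # fragment
    HitRecord("Neurospora crassa", "fungi", 8e-20, 700),
]
kept = drop_fragments(filter_hits(hits))
rows = survey_table(kept, {"cyanobacteria": 10, "fungi": 8})
print("toy screen after filters:")
for r in rows:
    print(f"  {r.group:<14} {r.n_hit_species}/{r.n_total_species} species "
          f"= {r.pct:.2f}%")

print("\npublished survey rows, recomputed from their count pairs:")
for row in published_survey_counts()[:6]:
    pct = round_half_up(100.0 * row["n_hit"] / row["n_total"], row["dp"])
    print(f"  {row['group']:<16} {row['n_hit']:>4}/{row['n_total']:<6} "
          f"= {pct}%")
print()
print("Duplicate species count once; the E-value cutoff is strict, so a hit")
print("at exactly 1e-3 is excluded, as is the 449-aa fragment.")
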