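# Packaged survey fixture

Reconstruction of the published regional survey (15 Cantabrian-coast
beaches, Feb-Mar 2016) from its printed summary tables:

- `beaches.csv` — beach ids, names, coordinates.
- `source_map.csv` — object-type -> source-category vocabulary.
- `litter_summary.csv` — the printed per-beach analysis table: litter
  density (items/m^2), material percentages (HPl/OPl/Foam/NPl and the
  printed sum-of-plastics column, which differs from the category sum by
  rounding), source percentages (S/F/HH/NA), separately for general
  litter (standardized quadrats, 12 beaches) and fouled rafting items
  (whole-beach inventory, 15 beaches).  This table is the authoritative
  input for the distance-based inference.
- `quadrat_counts.csv` — item-level reconstruction of the standardized
  counts.  Per-beach totals are round(density x 72 m^2); per-category
  integer counts are the vectors whose half-up-rounded percentages match
  the printed integers; the joint material x source assignment uses a
  northwest-corner fill (no analysis depends on the joint); the spread
  over the 8 quadrats is synthetic (fixed-seed multinomial) — only the
  per-beach margins are data.
- `fouled_items.csv` — item-level reconstruction of the 94 fouled items.
  Per-beach material/source counts reconstructed as above.  Exception:
  Bayas source percentages (33/67 over 7 items) have no exact integer
  encoding; the closest vector (2/7, 5/7) is used.  Attachment counts
  are synthetic: regional per-material taxon totals equal 8x the printed
  profile percentages, spread evenly over that material's items — the
  per-material pooled profile is data, the per-item and per-beach split
  is not.
- `taxon_profiles.csv` — the regional attached-biota profile per
  material (row-normalized printed percentages; the NPl row is the
  published verbal description: goose 97, acorn 2, molluscs 1).
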