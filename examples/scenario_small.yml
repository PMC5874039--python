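# Two-species virtual scenario: a 40x40 grid, 11 one-kyr slices with
# glacial-style cooling/drying drift, and one fossil planted for sp_a at
# 10 kyr BP outside the species' present-day range.
nrows: 40
ncols: 40
west: -70.0
north: 0.0
cell_size: 0.25
n_slices: 11
drift: [-0.45, -0.5, -20.0, -4.5]
inter_variable_correlation: 0.3
n_occurrences: 100
seed: 0
species:
  - species_id: sp_a
    niche_center: [22.5, 16.0, 425.0, 120.0]
    niche_width: [1.5, 8.0, 100.0, 160.0]
  - species_id: sp_b
    niche_center: [22.5, 16.0, 875.0, 120.0]
    niche_width: [1.5, 8.0, 100.0, 160.0]
fossils:
  - species: sp_a
    target_slice: 10
    require_outside_current: true
    candidates: [sp_a, sp_b]
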