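# Default desk-scale impact: type II bone sandwich plate, 20 km/h cylinder.
# Any omitted block falls back to the calibrated package defaults.
fixture: plate
speed_kmh: 20
duration_s: 0.005
plate:
  span_mm: 40
  width_mm: 40
  cortical_mm: 1.5
  core_mm: 7.0
  element_mm: 1.5
contact:
  c0_mm: 1.5
  p0_MPa: 100.0
  mu: 0.2
impactor:
  length_mm: 200
  diameter_mm: 40
  mass_kg: 2
damage:
  G_mJ_per_mm2: 1.54
  trabecular_cap: 0.06
  deletion_threshold: 0.99
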