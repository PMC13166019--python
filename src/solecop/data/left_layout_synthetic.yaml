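# Synthetic default left-insole layout (EU size 42-43).
#
# The vendor does not publish per-cell centroid coordinates or areas, so this
# file is an anatomically plausible FIXTURE, not manufacturer ground truth:
# 16 cells in the standard rearfoot/midfoot/forefoot/toes partition, covering
# roughly two thirds of the insole surface.
#
# Coordinates: origin at the posterior-medial corner of the bounding box,
# x_mm antero-posterior (heel -> toe), y_mm medio-lateral (medial -> lateral).
side: left
size_variant: "42-43"
length_mm: 270.0
width_mm: 90.0
sensors:
  - {id: 1,  label: "Posterior Medial Heel",            zone: rearfoot, x_mm: 25.0,  y_mm: 30.0, area_cm2: 9.0}
  - {id: 2,  label: "Posterior Lateral Heel",           zone: rearfoot, x_mm: 25.0,  y_mm: 60.0, area_cm2: 9.0}
  - {id: 3,  label: "Anterior Medial Heel",             zone: rearfoot, x_mm: 60.0,  y_mm: 32.0, area_cm2: 8.0}
  - {id: 4,  label: "Anterior Lateral Heel/Lateral Arch", zone: rearfoot, x_mm: 62.0, y_mm: 62.0, area_cm2: 8.0}
  - {id: 5,  label: "Central/Medial Midfoot",           zone: midfoot,  x_mm: 105.0, y_mm: 30.0, area_cm2: 8.0}
  - {id: 6,  label: "Central/Lateral Midfoot",          zone: midfoot,  x_mm: 105.0, y_mm: 58.0, area_cm2: 8.0}
  - {id: 7,  label: "Medial Arch",                      zone: midfoot,  x_mm: 140.0, y_mm: 25.0, area_cm2: 7.5}
  - {id: 8,  label: "Lateral Midfoot Border",           zone: midfoot,  x_mm: 140.0, y_mm: 65.0, area_cm2: 7.5}
  - {id: 9,  label: "1st Metatarsal Head (MTH1)",       zone: forefoot, x_mm: 185.0, y_mm: 22.0, area_cm2: 8.5}
  - {id: 10, label: "2nd Metatarsal Head (MTH2)",       zone: forefoot, x_mm: 192.0, y_mm: 38.0, area_cm2: 7.0}
  - {id: 11, label: "3rd Metatarsal Head (MTH3)",       zone: forefoot, x_mm: 196.0, y_mm: 52.0, area_cm2: 7.0}
  - {id: 12, label: "4th Metatarsal Head (MTH4)",       zone: forefoot, x_mm: 198.0, y_mm: 65.0, area_cm2: 6.5}
  - {id: 13, label: "5th Metatarsal Head (MTH5)",       zone: forefoot, x_mm: 196.0, y_mm: 78.0, area_cm2: 6.5}
  - {id: 14, label: "Hallux (Great Toe)",               zone: toes,     x_mm: 240.0, y_mm: 20.0, area_cm2: 9.0}
  - {id: 15, label: "Central Toes",                     zone: toes,     x_mm: 245.0, y_mm: 45.0, area_cm2: 6.0}
  - {id: 16, label: "Lateral Toes",                     zone: toes,     x_mm: 240.0, y_mm: 68.0, area_cm2: 5.0}
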