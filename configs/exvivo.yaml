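# Ex vivo accuracy experiment: ten spindle phantoms of exactly known volume
# measured at the clinical slice geometry.
experiment: exvivo
seed: 1
spacing_mm: [1.0, 3.3, 1.0]
thickness_mm: 3.0
gap_mm: 0.3
exvivo_volumes_cm3: [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
aspect_ratio: 2.5
shape_exponent: 1.0
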