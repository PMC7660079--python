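# Vibration timing / response experiment: three stimulated conditions from
# day 9 (1 s, 5 s, and 1/3/5 s changing every ~5 days), nine plates each,
# with three daily inspections for the triple manual reference count.
name: experiment1
seed: 0
acquisition_days: [1, 2, 5, 6, 7, 8, 9, 12, 13, 14, 15, 16, 17, 19, 20, 21]
conditions:
  - schedule:
      label: V_d9-t1
      durations: {9: 1, 12: 1, 13: 1, 14: 1, 15: 1, 16: 1, 17: 1, 19: 1, 20: 1, 21: 1}
    n_plates: 9
    inspections: 3
    plate: {image_size: [256, 256]}
  - schedule:
      label: V_d9-t5
      durations: {9: 5, 12: 5, 13: 5, 14: 5, 15: 5, 16: 5, 17: 5, 19: 5, 20: 5, 21: 5}
    n_plates: 9
    inspections: 3
    plate: {image_size: [256, 256]}
  - schedule:
      label: V_d9-t1,3,5
      durations: {9: 1, 12: 1, 13: 1, 14: 1, 15: 3, 16: 3, 17: 3, 19: 3, 20: 5, 21: 5}
    n_plates: 9
    inspections: 3
    plate: {image_size: [256, 256]}
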