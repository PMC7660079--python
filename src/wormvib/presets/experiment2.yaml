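# Habituation experiment: a 3 s vibration applied daily from a start day that
# varies per condition, against a never-stimulated control. The two large
# cohorts (NV and V_d2-t3) are the ones compared for habituation and for the
# lifespan-effect survival analysis.
name: experiment2
seed: 0
acquisition_days: [2, 5, 6, 7, 8, 9, 12, 13, 14, 15, 16, 19, 20, 21]
conditions:
  - schedule:
      label: NV
      durations: {}
    n_plates: 11
    plate: {image_size: [256, 256]}
  - schedule:
      label: V_d2-t3
      durations: {2: 3, 5: 3, 6: 3, 7: 3, 8: 3, 9: 3, 12: 3, 13: 3, 14: 3,
                  15: 3, 16: 3, 19: 3, 20: 3, 21: 3}
    n_plates: 11
    plate: {image_size: [256, 256]}
  - schedule:
      label: V_d9-t3
      durations: {9: 3, 12: 3, 13: 3, 14: 3, 15: 3, 16: 3, 19: 3, 20: 3, 21: 3}
    n_plates: 2
    plate: {image_size: [256, 256]}
  - schedule:
      label: V_d19-t3
      durations: {19: 3, 20: 3, 21: 3}
    n_plates: 2
    plate: {image_size: [256, 256]}
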