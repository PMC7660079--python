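# Lifespan-error experiment: two non-stimulated replications against V_d5-t3
# (3 s vibration immediately before the 30 s capture from day 5 on). Weekday
# acquisition; ~120 worms (8 plates x 15) per cohort.
name: experiment3
seed: 0
acquisition_days: [1, 2, 5, 6, 7, 8, 9, 12, 13, 14, 15, 16, 19, 20, 21]
conditions:
  - schedule:
      label: NV_rep1
      durations: {}
    n_plates: 8
    plate: {image_size: [256, 256]}
  - schedule:
      label: NV_rep2
      durations: {}
    n_plates: 8
    plate: {image_size: [256, 256]}
  - schedule:
      label: V_d5-t3
      durations: {5: 3, 6: 3, 7: 3, 8: 3, 9: 3, 12: 3, 13: 3, 14: 3, 15: 3,
                  16: 3, 19: 3, 20: 3, 21: 3}
    n_plates: 8
    plate: {image_size: [256, 256]}
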