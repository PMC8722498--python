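# Five-segment preference fixture, version 1.
#
# Shares, opt-out ("none") constants and every utility listed under `printed`
# are the published class-level zero-centered part-worth utilities of the
# SARS-CoV-2 testing preference study this package emulates.  Levels absent
# from `printed` were not published; the loader reconstructs them by splitting
# each attribute's zero-sum residual equally among the missing levels and
# flags them as reconstructed (see ClassSpec.reconstructed).
version: 1
classes:
  - label: noninvasive home testers
    share: 0.192
    none_utility: -299.6
    printed:
      test_type:
        PCR and serology: 39.5
      specimen_type:
        Saliva: 48.6
        NP swab: -92.1
        Blood draw: -41.3
      venue:
        Home collection, return by mail: 55.3
        Home collection, return to collection site: 42.7
        Doctor's office or urgent care: -41.6
        Walk-in community testing site: -44.5
      turnaround:
        Immediate: 42.0
        Same day: 30.4
  - label: fast-track testers
    share: 0.258
    none_utility: -238.0
    printed:
      test_type:
        PCR and serology: 53.0
      specimen_type:
        Cheek swab: 25.4
        NP swab: -51.1
        Blood draw: -20.7
      venue:
        Drive-through community testing site: 10.8
      turnaround:
        Immediate: 98.6
        Same day: 63.8
  - label: dual testers
    share: 0.185
    none_utility: -217.4
    printed:
      test_type:
        PCR and serology: 93.3
      specimen_type:
        Saliva: 14.2
        Cheek swab: 16.4
        NP swab: -30.5
      venue:
        Drive-through community testing site: 12.2
      turnaround:
        Immediate: 64.9
        Same day: 40.5
  - label: noninvasive dual testers
    share: 0.329
    none_utility: -226.6
    printed:
      test_type:
        PCR and serology: 73.3
      specimen_type:
        Saliva: 28.1
        Cheek swab: 37.8
        NP swab: -100.9
      venue:
        Home collection, return to collection site: 16.8
      turnaround:
        Immediate: 54.7
        Same day: 25.1
  - label: hesitant home testers
    share: 0.036
    none_utility: 32.5
    printed:
      test_type:
        PCR and serology: 36.1
      specimen_type:
        Urine: 33.5
        Finger prick: 24.5
        Cheek swab: 25.6
        Saliva: 18.7
        NP swab: -77.7
        Blood draw: -21.1
      venue:
        Home collection, return by mail: 93.2
        Home collection, return to collection site: 60.2
        Walk-in community testing site: -75.9
        Doctor's office or urgent care: -44.6
      turnaround:
        Immediate: 32.5
        Same day: 21.2
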