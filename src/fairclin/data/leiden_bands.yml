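# Daily severity-score band table.
#
# Retained daily components keep the published 4C mortality score bands
# (respiratory rate, SpO2 on room air, Glasgow Coma Scale, urea, CRP); the
# fixed admission parameters (age, sex at birth, comorbidity count) are not
# part of the engine. The three added daily oxygen parameters have no
# published point assignment; their bands below are placeholders flagged
# `provisional: true` and are expected to be replaced by a clinically
# validated table before any real-world use.
#
# Every band is a half-open interval [lo, hi) worth an integer number of
# points; per parameter the bands are disjoint and cover the declared range.
score_type: Leiden
parameters:
  respiratory_rate:
    applicability: both
    unit: breaths/min
    bands:
      - {lo: 0, hi: 20, points: 0}
      - {lo: 20, hi: 30, points: 1}
      - {lo: 30, hi: 80, points: 2}
  spo2:
    applicability: both
    unit: "%"
    bands:
      - {lo: 0, hi: 92, points: 2}
      - {lo: 92, hi: 101, points: 0}
  gcs:
    applicability: both
    unit: score
    bands:
      - {lo: 3, hi: 15, points: 2}
      - {lo: 15, hi: 16, points: 0}
  urea:
    applicability: both
    unit: mmol/L
    bands:
      - {lo: 0, hi: 7, points: 0}
      - {lo: 7, hi: 14, points: 1}
      - {lo: 14, hi: 200, points: 3}
  crp:
    applicability: both
    unit: mg/L
    bands:
      - {lo: 0, hi: 50, points: 0}
      - {lo: 50, hi: 100, points: 1}
      - {lo: 100, hi: 1000, points: 2}
  oxygen_flow:
    applicability: ward
    unit: L/min
    provisional: true
    bands:
      - {lo: 0, hi: 1, points: 0}
      - {lo: 1, hi: 5, points: 1}
      - {lo: 5, hi: 15, points: 2}
      - {lo: 15, hi: 80, points: 3}
  pf_ratio:
    applicability: ICU
    unit: kPa
    provisional: true
    bands:
      - {lo: 0, hi: 13.3, points: 3}
      - {lo: 13.3, hi: 26.6, points: 2}
      - {lo: 26.6, hi: 40, points: 1}
      - {lo: 40, hi: 150, points: 0}
  fio2:
    applicability: ICU
    unit: "%"
    provisional: true
    bands:
      - {lo: 21, hi: 40, points: 0}
      - {lo: 40, hi: 60, points: 1}
      - {lo: 60, hi: 80, points: 2}
      - {lo: 80, hi: 101, points: 3}
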