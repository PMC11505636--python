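# Default ICR scoring scheme.
#
# Eight four-level ordinal items; every item awards 0,1,2,3 points to its
# ordered levels (lowest risk first), so the theoretical maximum is 24.
# Category bins follow the published convention Low 0-5, Moderate 6-10,
# High 11-15, Very High 16-max. Both the points map and the bins are
# overridable by supplying a custom scheme file.
items:
  diet_content:
    level_labels:
      - low consumption of sugars
      - moderate consumption of sugars
      - high consumption of sugars
      - severe consumption of sugars
    level_points: [0, 1, 2, 3]
  diet_frequency:
    level_labels:
      - 0-3 meals
      - 4-5 meals
      - 6-7 meals
      - more than 7 meals
    level_points: [0, 1, 2, 3]
  hygiene_habits:
    level_labels:
      - brushing 3 times a day performed by a parent
      - brushing 2 times a day performed by a parent
      - brushing 2 times a day with supervision
      - brushing 1-2 times a day without supervision/no brushing
    level_points: [0, 1, 2, 3]
  fluoride_program:
    level_labels:
      - fluoride toothpaste + fluoride mouthwash + fluoride os (in the past)
      - fluoride toothpaste + fluoride os (in the past)
      - fluoride toothpaste
      - absence of fluoride program
    level_points: [0, 1, 2, 3]
  family_susceptibility:
    level_labels:
      - mother - father -
      - mother + father -
      - mother ++ father +/-
      - mother ++ father ++
    level_points: [0, 1, 2, 3]
  caries_experience:
    level_labels:
      - absence of caries + no old restorations + absence of teeth missing due to caries
      - 1 or 2 caries (or restorations or teeth missing due to caries)
      - 2 to 4 caries (or restorations or teeth missing due to caries)
      - 4 or more caries (or restorations or teeth missing due to caries)
    level_points: [0, 1, 2, 3]
  oral_hygiene_status:
    level_labels:
      - no plaque
      - plaque without bleeding
      - plaque with bleeding, calculus, marginal gingivitis
      - plaque with bleeding, calculus, gingivitis in multiple sites
    level_points: [0, 1, 2, 3]
  ph_test:
    level_labels:
      - alkaline pH (>7)
      - neutral pH (7)
      - acidic pH (6.5-5.5)
      - critical pH (<5.5)
    level_points: [0, 1, 2, 3]
category_thresholds:
  - [Low, 0, 5]
  - [Moderate, 6, 10]
  - [High, 11, 15]
  - [Very High, 16, 24]
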