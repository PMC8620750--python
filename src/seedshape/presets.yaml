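# Named geometric seed-shape models.
#
# `models` are the canonical presets exposed by the CLI; `extra` holds
# additional published parameter sets and approximate profiles kept as
# configuration data.  Superellipse/spiral parameters are the published
# values; `target_ar` stretches the pose-normalized contour to a stated
# aspect ratio (used to distinguish the short/long Echinocactus models,
# which share the same generating arc).

models:
  REBUTIA_HELIOSA:
    family: superellipse
    params: {p: 2.3, a: 1.5, b: 2.0}
  HYLO1:
    family: spiral_arc
    params: {t_min: 0.3, t_max: 5.0}
    closure: chord
  PACHY1:
    family: spiral_arc
    params: {t_min: 0.5, t_max: 5.0}
    closure: chord
  FERO1:
    family: spiral_arc
    params: {t_min: 1.0, t_max: 5.0}
    closure: chord
  ECHI1:
    family: spiral_arc
    params: {t_min: 1.0, t_max: 5.0}
    closure: chord
    target_ar: 1.24
  ECHI2:
    family: spiral_arc
    params: {t_min: 1.0, t_max: 5.0}
    closure: chord
    target_ar: 1.46
  OPUNTIA1:
    family: opuntia
    params: {t_min: 2.0, t_max: 6.0}
    closure: chord
  PERESKIA1:
    family: spiral_arc
    params: {t_min: 1.0, t_max: 6.0}
    closure: chord

extra:
  REBUTIA_PSEUDODEMINUTA:
    family: superellipse
    params: {p: 2.6, a: 1.0, b: 2.1}
  REBUTIA_FIEBRIGII:
    family: superellipse
    params: {p: 2.2, a: 1.5, b: 3.0}
  # Alternative Pereskia interval also in circulation for the same curve.
  PERESKIA1_T2:
    family: spiral_arc
    params: {t_min: 2.0, t_max: 6.0}
    closure: chord
  # Approximate Echinopsis profiles: paired semi-ellipses with a flattened
  # hilum-side lobe, ordered from least to most flattened.
  ECHINOPSIS_CALOCHLORA:
    family: bi_semi_ellipse
    params: {a: 1.0, b_up: 1.05, b_lo: 0.85, flat_depth: 0.25}
  ECHINOPSIS_LEUCANTHA:
    family: bi_semi_ellipse
    params: {a: 1.0, b_up: 1.05, b_lo: 0.85, flat_depth: 0.45}
  ECHINOPSIS_KLINGERIANA:
    family: bi_semi_ellipse
    params: {a: 1.0, b_up: 1.05, b_lo: 0.85, flat_depth: 0.65}
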