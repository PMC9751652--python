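# Fracture-site vocabulary and outcome classification.
#
# Each site is tagged with the MOST SPECIFIC outcome class it belongs to.
# Outcome classes are strictly nested:
#
#     hip  ⊂  MOF  ⊂  osteoporotic  ⊂  any
#
# so a site tagged "MOF" also counts as osteoporotic and any, a site tagged
# "hip" counts for every outcome, and a site tagged "any" counts only for
# the all-fracture outcome.
#
# Classes:
#   hip           — hip fracture
#   MOF           — major osteoporotic fracture: hip, clinical vertebral,
#                   proximal humerus, distal forearm/wrist
#   osteoporotic  — the broader Kanis-type osteoporotic-site set (adds ribs,
#                   pelvis, humerus, clavicle, scapula, sternum, other femoral,
#                   tibia, fibula)
#   any           — every recorded fracture site
#
# Mapping choices for cohort-recorded labels (editable; this file is the
# single point of truth):
#   wrist    -> distal forearm/wrist   (MOF)
#   vertebra -> clinical vertebral     (MOF)
#   shoulder -> proximal humerus       (MOF)
#   humerus  -> humeral shaft/distal; osteoporotic but not MOF
#   arm      -> unspecific upper limb; counted for "any" only
sites:
  hip: hip
  vertebra: MOF
  wrist: MOF
  shoulder: MOF
  humerus: osteoporotic
  ribs: osteoporotic
  pelvis: osteoporotic
  clavicle: osteoporotic
  scapula: osteoporotic
  sternum: osteoporotic
  femur_other: osteoporotic
  tibia: osteoporotic
  fibula: osteoporotic
  arm: any
  skull_face: any
  foot: any
  metatarsal: any
  hand: any
  fingers: any
  toes: any
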