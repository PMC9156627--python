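# Default semiology taxonomy: pattern rules mapping free-text seizure
# descriptions to category labels.  The shipped inventory covers the twelve
# most common ictal categories plus the postictal and asymptomatic buckets;
# further ictal categories can be added by loading an extended file.
#
# Each rule: kind (ictal/postictal/asymptomatic), include (word-boundary
# regular expressions), exclude (longer terms that must NOT trigger the
# category even though they contain an include pattern), negation_window
# (number of preceding tokens scanned for negation cues).
version: "1.0"
categories:
  Tonic:
    kind: ictal
    include: ["tonic", "stiff posturing", "stiffening", "tonic posturing"]
    exclude: ["dystonic", "myoclonic", "atonic", "clonic"]
    negation_window: 3
  Oral and manual automatisms:
    kind: ictal
    include:
      - "lip smacking"
      - "chewing"
      - "oro-?alimentary"
      - "orofacial automatisms?"
      - "manual automatisms?"
      - "upper limb automatisms?"
      - "pedal automatisms?"
      - "automotor"
      - "fiddling"
      - "ictal drinking"
      - "ictal swallowing"
    exclude: []
    negation_window: 3
  Dialeptic-LOA-LOC:
    kind: ictal
    include:
      - "blank stare"
      - "loss of awareness"
      - "unaware"
      - "loss of contact"
      - "loss of consciousness"
      - "psychomotor arrest"
      - "distant gaze"
      - "dreamy state"
      - "dyscognitive"
      - "dialeptic"
    exclude: []
    negation_window: 3
  Epigastric:
    kind: ictal
    include:
      - "epigastric"
      - "abdominal rising"
      - "rising sensation"
      - "butterfly sensation"
      - "abdominal aura"
    exclude: []
    negation_window: 3
  Vocalization:
    kind: ictal
    include: ["vocali[sz]ations?", "grunting", "mumbling", "humming", "unintelligible noises?"]
    exclude: ["ictal speech", "dysphasia"]
    negation_window: 3
  Autonomic:
    kind: ictal
    include:
      - "autonomic"
      - "hypopnoea"
      - "urinary urge"
      - "pilomotor"
      - "piloerection"
      - "laryngeal constriction"
      - "tachycardia"
      - "flushing"
    exclude: []
    negation_window: 3
  Olfactory:
    kind: ictal
    include: ["olfactory", "ictal smell", "smell of burning", "odou?r"]
    exclude: []
    negation_window: 3
  Head version:
    kind: ictal
    include: ["head version", "versive", "forced head deviation", "head deviation", "extreme head turn"]
    exclude: []
    negation_window: 3
  Dystonic:
    kind: ictal
    include: ["dystonic", "dystonia", "twisted posture"]
    exclude: []
    negation_window: 3
  Other automatisms:
    kind: ictal
    include:
      - "blinking"
      - "ictal cough"
      - "gelastic"
      - "dacrystic"
      - "nose wiping"
      - "face rubbing"
      - "ictal laughter"
      - "ictal crying"
    exclude: []
    negation_window: 3
  Mimetic automatisms:
    kind: ictal
    include:
      - "mimetic"
      - "grimacing"
      - "raising of eyebrows"
      - "fearful expression"
      - "facial expressions?"
      - "chapeau de gendarme"
    exclude: []
    negation_window: 3
  Somatosensory:
    kind: ictal
    include: ["somatosensory", "tingling", "touch sensation", "paraesthesia", "paresthesia", "numbness"]
    exclude: []
    negation_window: 3
  Postictal:
    kind: postictal
    include: ["post-?ictal"]
    exclude: []
    negation_window: 3
  Asymptomatic:
    kind: asymptomatic
    include: ["asymptomatic", "no clinical response", "silent stimulation"]
    exclude: []
    negation_window: 0
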