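# Default hierarchical brain-region inventory for semiology localization.
# Top-level lobes/structures are fixed; descendant nodes may be extended freely.
top_level:
  - Temporal
  - Frontal
  - Parietal
  - Occipital
  - Cingulate
  - Insula
  - Hypothalamus
  - Cerebellum

children:
  Temporal:
    - Mesial Temporal
    - Anterior Temporal
    - Lateral Temporal
    - Posterior Temporal
    - Basal Temporal

# Interlobar junctions are data-entry conveniences; analysis redistributes their
# weight equally over the constituent top-level regions.
junctions:
  Frontotemporal: [Frontal, Temporal]
  Temporo-occipital: [Temporal, Occipital]
  Temporo-parietal: [Temporal, Parietal]
  Fronto-temporo-parietal: [Frontal, Temporal, Parietal]
  Temporo-parieto-occipital: [Temporal, Parietal, Occipital]
  Parieto-occipital: [Parietal, Occipital]
  Fronto-parietal: [Frontal, Parietal]
  Perisylvian: [Frontal, Temporal, Parietal]

# Standalone non-hierarchical categories: kept in place, never redistributed.
standalone:
  - Subcallosal cortex
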