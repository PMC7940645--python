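# Default neurotransmitter pathway networks: two dopaminergic projection
# systems (striatocortical, mesolimbic) and five cholinergic systems
# (Ch1-3 forebrain, three Ch4 divisions of the nucleus basalis, Ch5-6
# brainstem).  Region names are descriptive anatomical labels, one left +
# one right column per bilateral region; the granularity of composite
# entries (e.g. which parcels make up "remaining" association cortices in
# the Ch4 lateral capsular division) is an editorial choice of this
# default config and is meant to be overridden with a user parcellation
# when real ROI tables are analysed.
pathways:
  - name: striatocortical
    rois:
      - {name: dorsal_caudate, laterality: bilateral}
      - {name: dorsal_putamen, laterality: bilateral}
      - {name: premotor_cortex, laterality: bilateral}
      - {name: motor_cortex, laterality: bilateral}
      - {name: dorsolateral_prefrontal_cortex, laterality: bilateral}
      - {name: somatosensory_cortex, laterality: bilateral}
  - name: mesolimbic
    rois:
      - {name: ventral_striatum, laterality: bilateral}
      - {name: ventral_frontal_cortex, laterality: bilateral}
      - {name: medial_frontal_cortex, laterality: bilateral}
      - {name: anterior_cingulate_cortex, laterality: bilateral}
      - {name: middle_cingulate_cortex, laterality: bilateral}
      - {name: amygdala, laterality: bilateral}
      - {name: parahippocampal_cortex, laterality: bilateral}
  - name: ch1_3
    rois:
      - {name: hippocampus, laterality: bilateral}
      - {name: hypothalamus, laterality: bilateral}
      - {name: olfactory_cortex, laterality: bilateral}
      - {name: parahippocampal_cortex, laterality: bilateral}
  - name: ch4_medial
    rois:
      - {name: cingulate_cortex, laterality: bilateral}
      - {name: retrosplenial_cortex, laterality: bilateral}
      - {name: orbitofrontal_cortex, laterality: bilateral}
  - name: ch4_lateral_perisylvian
    rois:
      - {name: olfactory_cortex, laterality: bilateral}
      - {name: superior_temporal_cortex, laterality: bilateral}
      - {name: insula, laterality: bilateral}
      - {name: frontoparietal_operculum, laterality: bilateral}
  - name: ch4_lateral_capsular
    rois:
      - {name: lateral_frontal_cortex, laterality: bilateral}
      - {name: parietal_cortex, laterality: bilateral}
      - {name: temporal_cortex, laterality: bilateral}
      - {name: occipital_cortex, laterality: bilateral}
      - {name: amygdala, laterality: bilateral}
  - name: ch5_6
    rois:
      - {name: thalamus, laterality: bilateral}
      - {name: ventral_striatum, laterality: bilateral}
      - {name: dorsal_striatum, laterality: bilateral}
      - {name: globus_pallidus, laterality: bilateral}
      - {name: pons, laterality: midline}
      - {name: midbrain, laterality: midline}
      - {name: medulla, laterality: midline}
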