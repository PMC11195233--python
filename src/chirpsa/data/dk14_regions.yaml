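# Desikan-Killiany label -> lobar region grouping (applied to both
# hemispheres; "lh-<label>" maps to "left_<region>", "rh-" to "right_").
# The insula is grouped with the cingulate/deep-source region.
version: 1
regions:
  prefrontal:
    - frontalpole
    - rostralmiddlefrontal
    - lateralorbitofrontal
    - medialorbitofrontal
    - parsorbitalis
  frontal:
    - superiorfrontal
    - caudalmiddlefrontal
    - parsopercularis
    - parstriangularis
  central:
    - precentral
    - postcentral
    - paracentral
  temporal:
    - superiortemporal
    - middletemporal
    - inferiortemporal
    - bankssts
    - transversetemporal
    - temporalpole
    - entorhinal
    - parahippocampal
    - fusiform
  parietal:
    - superiorparietal
    - inferiorparietal
    - supramarginal
    - precuneus
  occipital:
    - lateraloccipital
    - lingual
    - cuneus
    - pericalcarine
  cingulate:
    - rostralanteriorcingulate
    - caudalanteriorcingulate
    - posteriorcingulate
    - isthmuscingulate
    - insula
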