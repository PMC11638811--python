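# Electrode axes for the built-in montage templates, keyed by template.
# Channels are listed POSTERIOR FIRST (the stacking order of the analysis);
# custom axis files follow the same schema:
#
#   <template>:
#     <axis name>:            # one of midline / left / right, or custom
#       - <most posterior channel>
#       - ...
#       - <most anterior channel>
#
DS1:
  midline: [Oz, Pz, Cz, Fz]
  left: [O1, PO7, P7, CP5, FC5, F7]
  right: [O2, PO8, P8, CP6, FC6, F8]
DS2:
  # The source montage description prints the midline axis with "Fz" twice
  # ("Fz, Cz, Fz, Poz"), which cannot form a valid axis (labels must be
  # unique).  The default below is the corrected reading (Pz in third
  # position); the literal variant is kept here for reference:
  #   midline_literal: [POz, Fz, Cz, Fz]
  midline: [POz, Pz, Cz, Fz]
  left: [O1, PO3, P3, C3, F3]
  right: [O2, PO4, P4, C4, F4]
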