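"""Unit conversion constants.

All internal geometry is in micrometres (μm) and cubic micrometres
(μm³); gonad volumes cross the API boundary in mm³ and section areas in
mm², matching how the quantities are reported in the shellfish
literature.
"""

UM3_PER_MM3 = 1.0e9
UM2_PER_MM2 = 1.0e6
UM_PER_MM = 1.0e3
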