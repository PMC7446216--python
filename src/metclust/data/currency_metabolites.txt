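# Default currency/recurrent metabolite exclusion list.
# One bare metabolite name per line; matching is case-insensitive and
# applies across all compartments. Replace with your own list via the
# exclusion-list option of the pipeline.
H2O
CO2
O2
ATP
ADP
AMP
Pi
PPi
NAD+
NADH
NADP+
NADPH
CoA
H+
FAD
FADH2
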