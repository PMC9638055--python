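halloween
christmas
christmas eve
thanksgiving
easter
new year's day
new year's eve
new year's
independence day
fourth of july
labor day
memorial day
veterans day
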