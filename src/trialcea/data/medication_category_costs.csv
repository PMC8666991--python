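category,avg_cost
oral_opioid,12.50
oral_nsaid,4.60
topical_nsaid,6.20
antidepressant_neuropathic,8.40
other_analgesic,3.10
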