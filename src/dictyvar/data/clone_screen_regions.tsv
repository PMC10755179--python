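region	carriers_nonfruiting	noncarriers_nonfruiting	carriers_fruiting	noncarriers_fruiting
5prime	55	7	1	26
3prime	37	2	34	5
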