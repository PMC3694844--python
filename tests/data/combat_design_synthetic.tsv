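sample_id	batch	timepoint
s00	B1	before
s01	B1	after
s02	B1	before
s03	B1	after
s04	B1	before
s05	B1	after
s06	B2	before
s07	B2	after
s08	B2	before
s09	B2	after
s10	B2	before
s11	B2	after
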