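ligand	receptor
CD274	PDCD1
LGALS9	HAVCR2
CD80	CTLA4
IL2	IL2RA
IFNG	IFNGR1
CXCL8	CXCR1
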