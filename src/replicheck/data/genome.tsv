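chrom	length
chrI	230000
chrII	810000
chrIII	315000
chrVII	1090000
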