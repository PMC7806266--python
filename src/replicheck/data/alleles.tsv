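name	position	substitution
sld3-38A	306	A
sld3-38A	310	A
sld3-38A	421	A
sld3-38A	434	A
sld3-38A	435	A
sld3-38A	438	A
sld3-38A	442	A
sld3-38A	445	A
sld3-38A	450	A
sld3-38A	451	A
sld3-38A	452	A
sld3-38A	456	A
sld3-38A	458	A
sld3-38A	459	A
sld3-38A	479	A
sld3-38A	482	A
sld3-38A	507	A
sld3-38A	509	A
sld3-38A	514	A
sld3-38A	519	A
sld3-38A	521	A
sld3-38A	524	A
sld3-38A	539	R
sld3-38A	540	A
sld3-38A	541	A
sld3-38A	546	A
sld3-38A	547	A
sld3-38A	548	A
sld3-38A	550	A
sld3-38A	556	A
sld3-38A	558	A
sld3-38A	559	A
sld3-38A	565	A
sld3-38A	569	A
sld3-38A	582	A
sld3-38A	607	A
sld3-38A	653	A
sld3-38A	654	A
dbf4-19A	53	A
dbf4-19A	59	A
dbf4-19A	188	A
dbf4-19A	192	A
dbf4-19A	203	A
dbf4-19A	222	A
dbf4-19A	224	A
dbf4-19A	226	A
dbf4-19A	228	A
dbf4-19A	318	A
dbf4-19A	319	A
dbf4-19A	328	A
dbf4-19A	374	A
dbf4-19A	375	A
dbf4-19A	377	A
dbf4-19A	518	A
dbf4-19A	521	A
dbf4-19A	526	A
dbf4-19A	528	A
dbf4-4A	518	A
dbf4-4A	521	A
dbf4-4A	526	A
dbf4-4A	528	A
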