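ppm,metabolite
4.299,pseudouridine
4.290,pseudouridine
3.887,4-hydroxy-3-methoxymandelate
8.219,inosine
3.874,homovanillate
4.315,adenosine
0.982,2-aminobutyrate
3.156,ethanolamine
6.494,deoxyinosine
7.328,phenylacetic acid
7.312,phenylacetic acid
2.157,acetylcholine
6.907,l-tyrosine
7.138,anserine
1.493,alanine
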