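# Synthetic severity-graded penalty points over the standard GHS H-statement
# catalog, authored for this package (not an official registry). Scale 1-10:
# fatal/CMR effects 8-10, serious irreversible harm 6-8, moderate acute or
# chronic hazards 4-6, irritation and mild effects 2-3. Override with any
# two-column code,points CSV or YAML mapping to assess a different convention.
code,points
H200,10
H201,10
H202,9
H203,9
H204,6
H205,9
H206,9
H207,8
H208,6
H220,8
H221,6
H222,8
H223,6
H224,8
H225,6
H226,4
H228,4
H229,4
H230,8
H231,7
H232,7
H240,9
H241,8
H242,6
H250,8
H251,6
H252,5
H260,8
H261,6
H270,6
H271,8
H272,5
H280,3
H281,3
H290,3
H300,10
H301,8
H302,4
H304,6
H310,10
H311,8
H312,4
H314,7
H315,2
H317,4
H318,6
H319,2
H330,10
H331,8
H332,4
H334,7
H335,3
H336,3
H340,10
H341,6
H350,10
H350I,10
H351,6
H360,10
H360F,10
H360D,10
H360FD,10
H360DF,10
H361,6
H361F,6
H361D,6
H361FD,6
H362,4
H370,9
H371,5
H372,8
H373,5
H400,6
H410,8
H411,6
H412,4
H413,2
H420,7
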