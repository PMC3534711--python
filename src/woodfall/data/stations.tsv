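id	location	position	deployed	recovered
wood1	Close to carbonate crusts	N 32°32.0496 E 30°21.1248	2006-11-19	2007-11-11
wood2	On carbonate crust	N 32°31.9626 E 30°21.1752	2006-11-19	2007-11-11
wood5	On sediments	N 32°32.0790 E 30°21.3840	2006-11-20	2007-11-13
wood6	Reference, sampled after <1 d at seafloor	N 32°32.0124 E 30°21.1920	2007-11-10	2007-11-11
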