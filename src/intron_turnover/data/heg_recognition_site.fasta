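>heg_recognition_site 18-nt exon target cleaved by the omega-intron homing endonuclease
TAGGGATAACAGGGTAAT
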