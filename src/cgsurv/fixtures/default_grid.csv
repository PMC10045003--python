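family,alpha
clayton,1
clayton,2
clayton,4
clayton,15
gumbel,0
gumbel,1
gumbel,2
gumbel,10
frank,-14
frank,-5
frank,5
frank,14
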