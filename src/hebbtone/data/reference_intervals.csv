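name,num,den,cents,helmholtz_rank,five_limit
unison,1,1,0.0,1,true
minor_second,16,15,111.73128526977774,12,true
lesser_major_second,10,9,182.40371213406007,,true
greater_major_second,9,8,203.91000173077484,10,true
minor_third,6,5,315.64128700055255,7,true
major_third,5,4,386.3137138648348,6,true
perfect_fourth,4,3,498.0449991346125,4,true
tritone,45,32,590.2237155956096,13,true
perfect_fifth,3,2,701.9550008653874,3,true
minor_sixth,8,5,813.6862861351652,8,true
major_sixth,5,3,884.3587129994474,5,true
lesser_minor_seventh,16,9,996.089998269225,,true
greater_minor_seventh,9,5,1017.5962878659401,9,true
major_seventh,15,8,1088.2687147302222,11,true
octave,2,1,1200.0,2,true
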