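>BLG_BOVINE mature beta-lactoglobulin, Bos taurus (canonical, 162 aa)
LIVTQTMKGLDIQKVAGTWYSLAMAASDISLLDAQSAPLRVYVEELKPTPEGDLEILLQK
WENGECAQKKIIAEKTKIPAVFKIDALNENKVLVLDTDYKKYLLFCMENSAEPEQSLACQ
CLVRTPEVDDEALEKFDKALKALPMHIRLSFNPTQLEEQCHI
>BLG_CAPRINE synthetic mature caprine homolog (bovine scaffold with I1/H20/N64/K130 diagnostic substitutions)
IIVTQTMKGLDIQKVAGTWHSLAMAASDISLLDAQSAPLRVYVEELKPTPEGNLEILLQK
WENGECAQKKIIAEKTKIPAVFKIDALNENKVLVLDTDYKKYLLFCMENSAEPEQSLACQ
CLVRTPEVDKEALEKFDKALKALPMHIRLSFNPTQLEEQCHI
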