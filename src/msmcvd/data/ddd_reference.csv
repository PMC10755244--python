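drug_code,drug_class,who_ddd_mg
N06AB03,SSRI,20
N06AB04,SSRI,20
N06AB05,SSRI,20
N06AB06,SSRI,50
N06AB08,SSRI,100
N06AB10,SSRI,10
N06AX16,SNRI,100
N06AX21,SNRI,60
N06AX23,SNRI,50
N06AX17,SNRI,100
N06AA09,TCA,75
N06AA10,TCA,75
N06AA02,TCA,100
N06AA04,TCA,100
N06AA12,TCA,100
N06AX11,other,30
N06AX05,other,300
N06AX12,other,300
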