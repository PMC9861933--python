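code,source,family,superfamily
nAra h 1,Peanut,vicilins,Cupins
nCor a 11,Hazelnut,vicilins,Cupins
nJug r 6,Walnut,vicilins,Cupins
nJug r 2,Walnut,vicilins,Cupins
nPis v 3,Pistachio,vicilins,Cupins
rGly m 5,Soy,vicilins,Cupins
nAra h 3,Peanut,legumins,Cupins
nCor a 9,Hazelnut,legumins,Cupins
nJug r 4,Walnut,legumins,Cupins
rGly m 6,Soy,legumins,Cupins
rAna o 2,Cashew nut,legumins,Cupins
nPis v 2,Pistachio,legumins,Cupins
nAra h 2,Peanut,2S albumins,Prolamins
nAra h 6,Peanut,2S albumins,Prolamins
nCor a 14,Hazelnut,2S albumins,Prolamins
nSes i 1,Sesame,2S albumins,Prolamins
nSin a 1,Mustard,2S albumins,Prolamins
nJug r 1,Walnut,2S albumins,Prolamins
rAna o 3,Cashew nut,2S albumins,Prolamins
nMac i,Macadamia,2S albumins,Prolamins
nBer e 1,Brazil nut,2S albumins,Prolamins
rPis v 1,Pistachio,2S albumins,Prolamins
nPap s,Poppy seeds,2S albumins,Prolamins
nFag e 2,Buckwheat,2S albumins,Prolamins
rGly m 8,Soy,2S albumins,Prolamins
rTri a 19,Wheat,cereal prolamins,Prolamins
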