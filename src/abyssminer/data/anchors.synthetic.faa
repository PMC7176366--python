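>AbyU
NDVNQTNEWRQNILSNDMSEQCKVERKNSKDDEMMNYYMDKNMRHCWHMWAYLDSIQPTM
LFMAELFHQFARHLWIKVPFFEHMTIERHRFSQHWDTNMEPYFKGDIREGEYSMMPNWGR
STAKEKPAQQYQSDGHTEIMRCQWKAANEWQLCVDVNLDEIHPDWNIQQCTYTLPFGMLW
SNNMQKVGQQEFVCKQKNVNWEYLWDFTHRRLYWYINKAKLFCQEECHACQQLHSGSPVY
NVSNLPCSWAQWQKHGLVDSHEKHPRNCYHEKGQGIRLEETGEWDTGEAVPNAKIMCWRN
GMMEEIKKWTQIKE
>AbsU
KDSFAHCTKMGLWPSFSDPSEVSGQVEQHQKNPCNVSLVFMPDTWEFYTVAMQCGPWEMI
AKFRSYNDTGPWCNPTPGPFCVRFTEEESKDQGPLNCPAYWVGYNMCRTPMIWWEHQRFT
NYKGNGAGAWDHEVACDRPLDDDVAYCMRYMACHCVHKIIDCFYDNELGLAIETVNNCIM
DLPMIMNERTEGANYPNMSCVYRCFCGFNTLWLHKGQWYRPATDQEVEAQSVSKYFHSTD
ADVYEVHGMYIRNVEQVKRALSDVKYQRQFETCVKICMDTPQIPKGGWWMLFWPFQVDCV
LMNYIPCSCPSALQRNKETTWNMRDKLHCVELHCTCQVGCSMWRVAYTMGPYDESAFREW
DWSYVTALQMNLAKYLWSCYEVHPTTQPAVSYCFDMWLIRC
>AbmU
KQETAKCFPYYLMVIRCRFNPSEMHHWLEMTHNPENHCNRQMMMNFCLIQDTMWIQWHKQ
DSLDMSAFTCFEWFTKCPSMGCIVLFYQVANLDKACKWCWAAHEHEWDFGFTAVHDKITE
CKNKRCGRQQHCGTPCNVLEMSVYQRTQDMVGEGCWYMPVQQTTRYGSFVFQWGQYFSKC
P
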